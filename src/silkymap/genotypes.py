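"""Genotype matrices, variant tables and their readers/writers.

Genotype calls are stored unphased as small integer codes:

===========  =====
call         code
===========  =====
hom_ref      0
het          1
hom_alt      2
missing      -1
===========  =====

Phenotype labels come from a closed set: ``case`` (recessive homozygote,
h/h), ``control`` (wild-type, H/H or H/h), ``obligate_het`` (known H/h by
pedigree) and ``unknown``.  Autozygosity makes case haplotypes directly
readable from homozygous calls, so phasing is never needed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

PHENOTYPE_LABELS = ("case", "control", "obligate_het", "unknown")

_CODE_TO_SYMBOL = {HOM_REF: "0", HET: "1", HOM_ALT: "2", MISSING: "NA"}
_SYMBOL_TO_CODE = {
    "0": HOM_REF, "1": HET, "2": HOM_ALT,
    "NA": MISSING, ".": MISSING, "-1": MISSING,
    "hom_ref": HOM_REF, "het": HET, "hom_alt": HOM_ALT, "missing": MISSING,
}


@dataclass(frozen=True)
class Individual:
    id: str
    phenotype: str = "unknown"
    population: str = ""

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPE_LABELS:
            raise ValueError(
                f"phenotype {self.phenotype!r} not in {PHENOTYPE_LABELS}"
            )


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype calls with phenotype labels."""

    individuals: list[Individual]
    marker_ids: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if n != len(self.individuals):
            raise ValueError("calls rows != number of individuals")
        if m != len(self.marker_ids):
            raise ValueError("calls columns != number of markers")
        valid = np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            bad = self.calls[~valid].flat[0]
            raise ValueError(f"genotype code outside alphabet: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def phenotypes(self) -> list[str]:
        return [ind.phenotype for ind in self.individuals]

    def subset_phenotype(self, *labels: str) -> "GenotypeMatrix":
        idx = [i for i, ind in enumerate(self.individuals) if ind.phenotype in labels]
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], list(self.marker_ids), self.calls[idx]
        )

    def subset_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            list(self.individuals),
            [self.marker_ids[j] for j in indices],
            self.calls[:, indices],
        )

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_ids.index(marker_id)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls, index=self.ids, columns=self.marker_ids)
        df.index.name = "individual"
        return df


@dataclass
class VariantTable:
    """Biallelic variants (sorted positions) with per-individual calls.

    Multi-allelic records are rejected at read time rather than silently
    split: every analysis downstream assumes two alleles.
    """

    chrom: str
    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not (np.diff(self.positions) > 0).all():
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.ref = [self.ref[i] for i in order]
            self.alt = [self.alt[i] for i in order]
            self.genotypes = self.genotypes.subset_markers(order)
        if len(self.positions) != self.genotypes.n_markers:
            raise ValueError("positions and genotype columns differ in length")
        if not (len(self.positions) == len(self.ref) == len(self.alt)):
            raise ValueError("positions/ref/alt lengths differ")

    @property
    def n_variants(self) -> int:
        return len(self.positions)


# ----------------------------------------------------------------------------
# readers / writers


def read_phenotypes(path) -> dict[str, str]:
    """Read a TSV of individual id -> phenotype label (optional population col)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("id", cols.get("individual", df.columns[0]))
    label_col = cols.get("label", cols.get("phenotype", df.columns[1]))
    out = {}
    for _, row in df.iterrows():
        label = row[label_col]
        if label not in PHENOTYPE_LABELS:
            raise ValueError(f"phenotype label {label!r} not in {PHENOTYPE_LABELS}")
        out[str(row[id_col])] = label
    return out


def read_populations(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "population" not in df.columns:
        return {}
    id_col = "id" if "id" in df.columns else df.columns[0]
    return dict(zip(df[id_col], df["population"]))


def _attach_phenotypes(ids: list[str], phenotypes: Optional[dict[str, str]],
                       populations: Optional[dict[str, str]] = None) -> list[Individual]:
    phenotypes = phenotypes or {}
    populations = populations or {}
    return [
        Individual(i, phenotypes.get(i, "unknown"), populations.get(i, ""))
        for i in ids
    ]


def read_genotypes(path, format: str = "vcf",
                   phenotypes: Optional[dict[str, str]] = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF, PLINK .ped(+.map), or a code TSV.

    Individuals absent from the phenotype mapping are labeled ``unknown``.
    """
    if format == "vcf":
        return read_vcf(path, phenotypes=phenotypes).genotypes
    if format == "plink_ped":
        return _read_ped(path, phenotypes)
    if format == "tsv_matrix":
        return _read_tsv_matrix(path, phenotypes)
    raise ValueError(f"unknown genotype format: {format}")


def read_vcf(path, phenotypes: Optional[dict[str, str]] = None) -> VariantTable:
    """Read a (single-chromosome) VCF into a VariantTable via cyvcf2; GT only."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    positions, ref, alt, cols, chroms = [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; biallelic input required"
            )
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        # gts012=True: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        cols.append(gt)
    if not positions:
        raise ValueError("no variant records in VCF")
    if len(set(chroms)) > 1:
        raise ValueError("expected a single-chromosome VCF")
    calls = np.stack(cols, axis=1)
    gm = GenotypeMatrix(_attach_phenotypes(samples, phenotypes),
                        [f"{chroms[0]}:{p}" for p in positions], calls)
    return VariantTable(chroms[0], np.asarray(positions), ref, alt, gm)


def _read_ped(path, phenotypes: Optional[dict[str, str]]) -> GenotypeMatrix:
    """Parse a PLINK .ped; alleles recoded per marker, first allele seen = ref."""
    path = Path(path)
    rows, ids = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 8 or (len(fields) - 6) % 2:
                raise ValueError(f"malformed .ped line {lineno}")
            ids.append(fields[1])
            rows.append(fields[6:])
    n_markers = len(rows[0]) // 2
    if any(len(r) != 2 * n_markers for r in rows):
        raise ValueError("inconsistent marker count across .ped lines")
    alleles: list[dict[str, int]] = [dict() for _ in range(n_markers)]
    calls = np.full((len(rows), n_markers), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        for j in range(n_markers):
            a, b = row[2 * j], row[2 * j + 1]
            if a in ("0", ".") or b in ("0", "."):
                continue
            codes = []
            for al in (a, b):
                if al not in alleles[j]:
                    if len(alleles[j]) == 2:
                        raise ValueError(
                            f"marker {j} has more than two alleles (saw {al!r})"
                        )
                    alleles[j][al] = len(alleles[j])
                codes.append(alleles[j][al])
            calls[i, j] = codes[0] + codes[1]
    marker_ids = [f"m{j}" for j in range(n_markers)]
    map_path = path.with_suffix(".map")
    if map_path.exists():
        from .markers import read_marker_map

        marker_ids = read_marker_map(map_path, format="plink_map").ids
    return GenotypeMatrix(_attach_phenotypes(ids, phenotypes), marker_ids, calls)


def _read_tsv_matrix(path, phenotypes: Optional[dict[str, str]]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    calls = np.empty(df.shape, dtype=np.int8)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, value in enumerate(row):
            sym = str(value)
            if sym not in _SYMBOL_TO_CODE:
                raise ValueError(f"genotype symbol outside alphabet: {sym!r}")
            calls[i, j] = _SYMBOL_TO_CODE[sym]
    ids = [str(i) for i in df.index]
    return GenotypeMatrix(_attach_phenotypes(ids, phenotypes), list(df.columns), calls)


def write_tsv_matrix(matrix: GenotypeMatrix, path) -> None:
    """Write genotype codes as TSV; round-trips every call including missing."""
    df = pd.DataFrame(
        [[_CODE_TO_SYMBOL[c] for c in row] for row in matrix.calls],
        index=matrix.ids,
        columns=matrix.marker_ids,
    )
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def write_phenotypes(matrix: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "id": matrix.ids,
            "label": matrix.phenotypes,
            "population": [ind.population for ind in matrix.individuals],
        }
    )
    df.to_csv(path, sep="\t", index=False)
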