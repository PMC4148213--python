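"""Identical-by-descent fine mapping and causal-variant filtering.

A recessive affected individual is autozygous around the causal locus, so
the causal region must lie inside a haplotype that every case carries
homozygously.  The engine here implements that logic as deterministic set
operations on a genotype matrix:

1. ``shared_homozygous_blocks`` — maximal runs of consecutive markers at
   which all cases are homozygous for one common allele;
2. ``exclude_control_matches`` — drop blocks for which some control carries
   the full shared haplotype homozygously;
3. ``narrow_boundaries`` — het-exclusive boundary refinement from an
   extended case panel (the new boundary starts 1 bp inside the outermost
   discordant marker);
4. ``variant_exclusion_filter`` — retain only variants whose genotypes
   segregate perfectly with the phenotype (cases one homozygote, controls
   never that homozygote, obligate heterozygotes heterozygous);
5. ``association_table`` — per-population genotype tabulation at a
   candidate variant with a complete-association predicate.

No probabilistic IBD model is involved; the procedure is filtering, not
hypothesis testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING,
                        VariantTable)
from .intervals import GenomicInterval, interval_length_kb
from .markers import MarkerMap


@dataclass
class SharedBlock:
    """A contiguous marker run homozygously shared by all cases."""

    interval: GenomicInterval
    start_idx: int  # inclusive indices into the MarkerMap
    end_idx: int
    shared_alleles: np.ndarray  # per-marker shared code (0/2; MISSING if no data)
    n_supporting_cases: int
    excluded_by: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def excluded(self) -> bool:
        return bool(self.excluded_by)


def _column_shared_allele(col: np.ndarray, missing_policy: str,
                          max_case_exceptions: int = 0) -> Optional[int]:
    """Shared homozygous allele of one marker column, or None if sharing breaks.

    Under the default ``compatible`` policy a missing call neither breaks
    nor supports sharing; ``breaking`` counts missing as a violation.  Up
    to ``max_case_exceptions`` discordant cases may be tolerated per
    marker (default 0, strict).  A column with no informative call is
    compatible with either allele and reports MISSING as its allele.
    """
    n_ref = int((col == HOM_REF).sum())
    n_alt = int((col == HOM_ALT).sum())
    n_het = int((col == HET).sum())
    n_miss = int((col == MISSING).sum())
    miss_penalty = n_miss if missing_policy == "breaking" else 0
    candidates = []  # (violations, -support, allele)
    for allele, support, other in ((HOM_REF, n_ref, n_alt), (HOM_ALT, n_alt, n_ref)):
        violations = n_het + other + miss_penalty
        if violations <= max_case_exceptions:
            candidates.append((violations, -support, allele))
    if not candidates:
        return None
    violations, neg_support, allele = min(candidates)
    if neg_support == 0 and violations == 0:
        return MISSING  # no data at all: compatible, zero support
    return allele


def shared_homozygous_blocks(cases: GenotypeMatrix, marker_map: MarkerMap,
                             missing_policy: str = "compatible",
                             max_case_exceptions: int = 0) -> list[SharedBlock]:
    """Maximal case-shared homozygous runs, in map order.

    Requires at least one case; blocks of a single marker are returned.
    """
    if cases.n_individuals < 1:
        raise ValueError("at least one case required")
    if missing_policy not in ("compatible", "breaking"):
        raise ValueError(f"unknown missing policy: {missing_policy}")
    if cases.n_markers != len(marker_map):
        raise ValueError("genotype matrix and marker map disagree on marker count")

    chrom = marker_map.table["chrom"].iloc[0]
    positions = marker_map.positions
    shared = [
        _column_shared_allele(cases.calls[:, j], missing_policy, max_case_exceptions)
        for j in range(cases.n_markers)
    ]

    blocks: list[SharedBlock] = []
    j = 0
    while j < cases.n_markers:
        if shared[j] is None:
            j += 1
            continue
        k = j
        while k + 1 < cases.n_markers and shared[k + 1] is not None:
            k += 1
        alleles = np.array([shared[i] for i in range(j, k + 1)], dtype=np.int8)
        support = _block_support(cases.calls[:, j:k + 1], alleles)
        blocks.append(
            SharedBlock(
                GenomicInterval(chrom, int(positions[j]), int(positions[k])),
                j, k, alleles, support,
            )
        )
        j = k + 1
    return blocks


def _block_support(calls: np.ndarray, alleles: np.ndarray) -> int:
    """Cases carrying the shared haplotype with at least one observed call."""
    informative = alleles != MISSING
    if not informative.any():
        return 0
    match = calls[:, informative] == alleles[informative]
    return int((match.any(axis=1)).sum())


def _matches_block(calls_row: np.ndarray, block: SharedBlock) -> bool:
    """True if an individual is homozygous for the full shared haplotype.

    Missing cells are compatible; at least one informative matching call is
    required so an untyped individual never counts as a match.
    """
    segment = calls_row[block.start_idx:block.end_idx + 1]
    informative = block.shared_alleles != MISSING
    seg = segment[informative]
    ref = block.shared_alleles[informative]
    observed = seg != MISSING
    if not observed.any():
        return False
    return bool((seg[observed] == ref[observed]).all())


def exclude_control_matches(blocks: list[SharedBlock],
                            controls: GenotypeMatrix) -> list[SharedBlock]:
    """Mark blocks whose full shared haplotype is carried by some control.

    A block is excluded iff at least one control is homozygous for the
    shared allele at every marker of the block where it has a call; the
    matching control ids are recorded in ``excluded_by``.
    """
    for block in blocks:
        block.excluded_by = [
            ind.id
            for ind, row in zip(controls.individuals, controls.calls)
            if _matches_block(row, block)
        ]
    return blocks


@dataclass
class NarrowedInterval:
    interval: GenomicInterval
    open_left: bool  # True when no informative boundary individual was found
    open_right: bool
    boundary_markers: tuple[Optional[int], Optional[int]] = (None, None)


def _panel_discordance(block: SharedBlock, panel: GenotypeMatrix,
                       panel_map: MarkerMap) -> tuple[np.ndarray, np.ndarray]:
    """Positions of panel markers inside the block and their discordance.

    A panel marker is discordant when the extended cases are not jointly
    compatible with homozygous sharing there (some case heterozygous, or
    homozygous for the other allele).
    """
    positions = panel_map.positions
    inside = (positions >= block.interval.start) & (positions <= block.interval.end)
    idx = np.where(inside)[0]
    disc = np.array([
        _column_shared_allele(panel.calls[:, j], "compatible") is None
        for j in idx
    ])
    return positions[idx], disc


def narrow_boundaries(block: SharedBlock, extended_panel: GenotypeMatrix,
                      panel_map: MarkerMap) -> NarrowedInterval:
    """Het-exclusive boundary refinement of a surviving block.

    The boundary marker on each side is the outermost panel marker, among
    those flanking the largest discordance-free segment, at which some
    extended-panel case is heterozygous or homozygous for the non-shared
    allele.  The refined interval starts 1 bp inside the boundary marker
    (position + 1 proximally, position - 1 distally).  When panel
    discordance splits the block, the longest clean segment is kept
    (ties resolved toward the proximal side).  A side with no informative
    discordant marker keeps the block coordinate and is flagged open.
    """
    positions, disc = _panel_discordance(block, extended_panel, panel_map)
    if positions.size == 0 or not disc.any():
        return NarrowedInterval(block.interval, True, True)

    # clean segments between discordant markers
    segments: list[tuple[int, int]] = []  # index ranges into `positions`
    start = None
    for i, bad in enumerate(disc):
        if bad:
            if start is not None:
                segments.append((start, i - 1))
                start = None
        elif start is None:
            start = i
    if start is not None:
        segments.append((start, len(disc) - 1))
    if not segments:
        raise ValueError("every panel marker in the block is discordant")

    def seg_len(seg: tuple[int, int]) -> int:
        return int(positions[seg[1]] - positions[seg[0]])

    best = max(segments, key=seg_len)  # max() keeps the first (proximal) on ties

    left_disc = positions[best[0] - 1] if best[0] > 0 else None
    right_disc = positions[best[1] + 1] if best[1] < len(positions) - 1 else None
    start_bp = int(left_disc) + 1 if left_disc is not None else block.interval.start
    end_bp = int(right_disc) - 1 if right_disc is not None else block.interval.end
    return NarrowedInterval(
        GenomicInterval(block.interval.chrom, start_bp, end_bp),
        open_left=left_disc is None,
        open_right=right_disc is None,
        boundary_markers=(
            int(left_disc) if left_disc is not None else None,
            int(right_disc) if right_disc is not None else None,
        ),
    )


# ----------------------------------------------------------------------------
# variant-level filtering


@dataclass(frozen=True)
class ExclusionReason:
    clause: str  # "case_not_homozygous", "control_matches", "het_not_het", "no_data"
    witness: Optional[str] = None


def variant_exclusion_filter(
    variants: VariantTable,
) -> tuple[list[int], list[Optional[ExclusionReason]]]:
    """Retain variants in perfect segregation with the recessive phenotype.

    A variant is retained iff (a) all cases share one homozygous genotype,
    (b) no control is homozygous for that same genotype, and (c) every
    obligate heterozygote is heterozygous.  Missing calls are ignored
    clause-wise; an all-missing variant is excluded with reason "no data".
    Returns retained variant indices and a per-variant reason (None for
    retained variants) naming the first violated clause and a witness.
    """
    gm = variants.genotypes
    labels = gm.phenotypes
    for ind in gm.individuals:
        if ind.phenotype == "unknown":
            raise ValueError(f"individual {ind.id} lacks a phenotype label")
    case_rows = [i for i, l in enumerate(labels) if l == "case"]
    control_rows = [i for i, l in enumerate(labels) if l == "control"]
    het_rows = [i for i, l in enumerate(labels) if l == "obligate_het"]

    retained: list[int] = []
    reasons: list[Optional[ExclusionReason]] = []
    for v in range(variants.n_variants):
        col = gm.calls[:, v]
        if (col == MISSING).all():
            reasons.append(ExclusionReason("no_data"))
            continue
        reason = None
        case_calls = [(i, col[i]) for i in case_rows if col[i] != MISSING]
        shared = None
        for i, call in case_calls:
            if call == HET:
                reason = ExclusionReason("case_not_homozygous", gm.individuals[i].id)
                break
            if shared is None:
                shared = call
            elif call != shared:
                reason = ExclusionReason("case_not_homozygous", gm.individuals[i].id)
                break
        if reason is None and shared is None:
            reason = ExclusionReason("no_data")
        if reason is None:
            for i in control_rows:
                if col[i] == shared:
                    reason = ExclusionReason("control_matches", gm.individuals[i].id)
                    break
        if reason is None:
            for i in het_rows:
                if col[i] not in (HET, MISSING):
                    reason = ExclusionReason("het_not_het", gm.individuals[i].id)
                    break
        reasons.append(reason)
        if reason is None:
            retained.append(v)
    return retained, reasons


# ----------------------------------------------------------------------------
# association tabulation


@dataclass
class AssociationTable:
    """Per-population genotype counts at one candidate variant."""

    counts: pd.DataFrame  # index population, columns hom_alt/het/hom_ref/missing
    phenotype_of: dict[str, str]
    complete_association: bool

    @property
    def class_totals(self) -> dict[str, int]:
        classes = {}
        for pop, row in self.counts.iterrows():
            cls = self.phenotype_of[pop]
            classes[cls] = classes.get(cls, 0) + int(
                row[["hom_alt", "het", "hom_ref"]].sum()
            )
        return classes

    @property
    def grand_total(self) -> int:
        return int(self.counts[["hom_alt", "het", "hom_ref"]].to_numpy().sum())


def association_table(calls: np.ndarray, individuals) -> AssociationTable:
    """Tabulate one biallelic variant by population and phenotype class.

    ``complete_association`` is true iff every case is hom_alt, every
    control hom_ref and every obligate het heterozygous; missing calls go
    to a separate column and are excluded from the predicate.
    """
    if len(individuals) == 0:
        raise ValueError("no individuals")
    calls = np.asarray(calls)
    if calls.shape != (len(individuals),):
        raise ValueError("one call per individual required")
    rows: dict[str, dict[str, int]] = {}
    pheno_of: dict[str, str] = {}
    complete = True
    for ind, call in zip(individuals, calls):
        pop = ind.population or ind.phenotype
        if pop in pheno_of and pheno_of[pop] != ind.phenotype:
            raise ValueError(f"population {pop!r} mixes phenotype classes")
        pheno_of[pop] = ind.phenotype
        row = rows.setdefault(pop, {"hom_alt": 0, "het": 0, "hom_ref": 0, "missing": 0})
        key = {HOM_ALT: "hom_alt", HET: "het", HOM_REF: "hom_ref", MISSING: "missing"}[int(call)]
        row[key] += 1
        if call != MISSING:
            expected = {"case": HOM_ALT, "control": HOM_REF, "obligate_het": HET}
            if ind.phenotype not in expected or call != expected[ind.phenotype]:
                complete = False
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "population"
    return AssociationTable(counts, pheno_of, complete)


def association_from_counts(panel: pd.DataFrame) -> AssociationTable:
    """Build an AssociationTable from per-population genotype counts.

    Expects columns population / phenotype / hom_alt / het / hom_ref, e.g.
    a published breed-panel tabulation re-entered as input.
    """
    from .genotypes import Individual

    individuals, calls = [], []
    for _, row in panel.iterrows():
        for code, col in ((HOM_ALT, "hom_alt"), (HET, "het"), (HOM_REF, "hom_ref")):
            for i in range(int(row[col])):
                individuals.append(
                    Individual(f"{row['population']}_{col}_{i}",
                               row["phenotype"], row["population"])
                )
                calls.append(code)
    return association_table(np.array(calls), individuals)


# ----------------------------------------------------------------------------
# pipeline


@dataclass
class IbdReport:
    steps: list[tuple[str, Optional[GenomicInterval], Optional[float]]]
    blocks: list[SharedBlock]
    surviving_blocks: list[SharedBlock]
    minimal_interval: Optional[GenomicInterval]
    retained_variants: list[int]
    exclusion_reasons: list[Optional[ExclusionReason]]
    association: Optional[AssociationTable]

    def summary(self) -> str:
        lines = []
        for name, interval, kb in self.steps:
            if interval is None:
                lines.append(f"{name}: (no interval)")
            else:
                lines.append(f"{name}: {interval} ({kb} kb)")
        return "\n".join(lines)


def run_ibd_pipeline(cases: GenotypeMatrix, controls: GenotypeMatrix,
                     extended_panel: Optional[GenotypeMatrix],
                     variants: Optional[VariantTable],
                     marker_map: MarkerMap,
                     missing_policy: str = "compatible",
                     max_case_exceptions: int = 0) -> IbdReport:
    """Compose the fine-mapping steps into one narrative report.

    Blocks are found in the cases, control-matched blocks excluded, the
    largest surviving block boundary-narrowed with the extended panel, and
    the variant filter plus association tabulation applied inside the
    candidate interval.
    """
    steps: list[tuple[str, Optional[GenomicInterval], Optional[float]]] = []
    full_span = marker_map.span()
    steps.append(("mapped region", full_span, interval_length_kb(full_span)))

    blocks = shared_homozygous_blocks(cases, marker_map, missing_policy,
                                      max_case_exceptions)
    for b in blocks:
        steps.append(("case-shared block", b.interval, interval_length_kb(b.interval)))

    blocks = exclude_control_matches(blocks, controls)
    surviving = [b for b in blocks if not b.excluded]
    minimal: Optional[GenomicInterval] = None
    if surviving:
        best = max(surviving, key=lambda b: b.interval.length_bp)
        steps.append(("surviving block", best.interval,
                      interval_length_kb(best.interval)))
        minimal = best.interval
        if extended_panel is not None:
            narrowed = narrow_boundaries(best, extended_panel, marker_map)
            minimal = narrowed.interval
            steps.append(("narrowed candidate", minimal, interval_length_kb(minimal)))
    else:
        steps.append(("surviving block", None, None))

    retained: list[int] = []
    reasons: list[Optional[ExclusionReason]] = []
    assoc = None
    if variants is not None and minimal is not None:
        keep = [i for i, p in enumerate(variants.positions)
                if minimal.contains(int(p))]
        sub = VariantTable(
            variants.chrom, variants.positions[keep],
            [variants.ref[i] for i in keep], [variants.alt[i] for i in keep],
            variants.genotypes.subset_markers(keep),
        )
        kept_local, reasons = variant_exclusion_filter(sub)
        retained = [keep[i] for i in kept_local]
        if len(retained) >= 1:
            v = retained[0]
            assoc = association_table(variants.genotypes.calls[:, v],
                                      variants.genotypes.individuals)
    return IbdReport(steps, blocks, surviving, minimal, retained, reasons, assoc)
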