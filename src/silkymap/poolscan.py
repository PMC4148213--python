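"""Fixation scanning of pooled-sequencing allele counts.

In a DNA pool of individuals sharing an IBD haplotype, every segregating
site inside the haplotype shows a variant allele frequency (VAF) near 1.
The scan computes per-site VAFs from read counts and extracts maximal runs
of near-fixed sites — the computational contract behind detecting one
extended fixed region in a pooled whole-genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


@dataclass
class PoolSiteCounts:
    """Ordered per-site reference/variant read counts from one DNA pool."""

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    pool_size: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        if not (len(self.positions) == len(self.ref) == len(self.alt)):
            raise ValueError("positions/ref/alt must have equal length")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("read counts must be non-negative")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def coverage(self) -> np.ndarray:
        return self.ref + self.alt


def read_pool_counts(path, chrom: str = "", pool_size: int = 0) -> PoolSiteCounts:
    """Read a TSV of position / ref_count / alt_count (optional chrom column)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "chrom" in cols and not chrom:
        chrom = str(df[cols["chrom"]].iloc[0])
    return PoolSiteCounts(
        chrom=chrom,
        positions=df[cols.get("position", cols.get("pos", df.columns[0]))].to_numpy(),
        ref=df[cols.get("ref_count", cols.get("ref", df.columns[-2]))].to_numpy(),
        alt=df[cols.get("alt_count", cols.get("alt", df.columns[-1]))].to_numpy(),
        pool_size=pool_size,
    )


def site_vaf(counts: PoolSiteCounts, min_coverage: int = 4) -> np.ndarray:
    """Per-site variant allele frequency; NaN where coverage < min_coverage.

    Low-coverage sites are undefined, not frequency 0: a site with no reads
    carries no information about the pool frequency.
    """
    total = counts.coverage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = counts.alt / total
    vaf[total < min_coverage] = np.nan
    return vaf


@dataclass
class FixedRun:
    """A maximal run of near-fixed sites, spanning first to last passing site."""

    interval: GenomicInterval
    n_sites: int
    mean_vaf: float
    min_coverage: int


def fixed_runs(counts: PoolSiteCounts, fixation_threshold: float = 0.95,
               min_sites: int = 5, max_gap_sites: int = 0,
               min_coverage: int = 4,
               vaf: Optional[np.ndarray] = None) -> list[FixedRun]:
    """Maximal runs of defined-VAF sites at or above the fixation threshold.

    Undefined (low-coverage) sites are skipped entirely — they neither
    extend nor break a run.  Up to ``max_gap_sites`` defined sites below
    the threshold are tolerated inside a run; runs always start and end at
    passing sites, and runs with fewer than ``min_sites`` passing sites
    are dropped.  Output runs are disjoint and ordered.
    """
    if vaf is None:
        vaf = site_vaf(counts, min_coverage=min_coverage)
    defined = ~np.isnan(vaf)
    idx = np.where(defined)[0]
    passing = vaf[idx] >= fixation_threshold

    runs: list[list[int]] = []
    current: list[int] = []
    gaps = 0
    pending_gap = 0
    for local, site in enumerate(idx):
        if passing[local]:
            if current and pending_gap:
                gaps += pending_gap
            pending_gap = 0
            current.append(int(site))
        else:
            if not current:
                continue
            pending_gap += 1
            if gaps + pending_gap > max_gap_sites:
                runs.append(current)
                current = []
                gaps = pending_gap = 0
    if current:
        runs.append(current)

    out: list[FixedRun] = []
    for run in runs:
        if len(run) < min_sites:
            continue
        sites = np.array(run)
        lo, hi = int(counts.positions[sites[0]]), int(counts.positions[sites[-1]])
        # include interior tolerated-gap sites in the span but not in n_sites
        span = (counts.positions >= lo) & (counts.positions <= hi) & defined
        out.append(
            FixedRun(
                GenomicInterval(counts.chrom or "?", lo, hi),
                n_sites=len(run),
                mean_vaf=float(np.nanmean(vaf[sites])),
                min_coverage=int(counts.coverage[span].min()),
            )
        )
    return out


def runs_to_frame(runs: list[FixedRun]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in runs],
            "start": [r.interval.start for r in runs],
            "end": [r.interval.end for r in runs],
            "n_sites": [r.n_sites for r in runs],
            "mean_vaf": [r.mean_vaf for r in runs],
            "min_coverage": [r.min_coverage for r in runs],
        }
    )
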