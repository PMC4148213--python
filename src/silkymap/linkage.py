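"""Segregation testing and two-point linkage for an F2 intercross.

The trait is a fully penetrant autosomal recessive (h), the markers are
codominant and biallelic.  Each F2 offspring is formed from two independent
F1 gametes; with the trait allele h coupled to marker allele B in the F1,
gamete frequencies are

    hB = HA = (1 - theta) / 2        hA = HB = theta / 2

where theta is the recombination fraction.  The phenotype pools the HH and
Hh trait genotypes (wild-type), so the data per marker reduce to a 6-cell
table of marker genotype {AA, AB, BB} x phenotype {wild-type, case}.  The
LOD score is log10 L(theta_hat) - log10 L(1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING
from .markers import MarkerMap

PHENO_WT, PHENO_CASE = 0, 1  # row order of count tables
GENO_AA, GENO_AB, GENO_BB = 0, 1, 2  # column order of count tables

_LN10 = math.log(10.0)


def segregation_chi_square(n_dominant: int, n_recessive: int,
                           expected_ratio: tuple[float, float] = (3, 1)):
    """Pearson chi-square of observed phenotype counts against a Mendelian ratio.

    Returns ``(chi2, df, p_value)`` with df = 1 for a two-category ratio.
    """
    if n_dominant < 0 or n_recessive < 0:
        raise ValueError("counts must be non-negative")
    total = n_dominant + n_recessive
    if total == 0:
        raise ValueError("zero total count")
    ratio_sum = expected_ratio[0] + expected_ratio[1]
    expected = (
        total * expected_ratio[0] / ratio_sum,
        total * expected_ratio[1] / ratio_sum,
    )
    chi2, p = stats.chisquare([n_dominant, n_recessive], f_exp=expected)
    return float(chi2), 1, float(p)


def class_probabilities(theta: float) -> np.ndarray:
    """The six (phenotype x marker genotype) class probabilities for one F2.

    Rows: wild-type, case; columns: AA, AB, BB.  Sums to 1 for any theta.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must be in [0, 0.5], got {theta}")
    r = theta / 2.0  # gamete carries h with marker allele A
    s = (1.0 - theta) / 2.0  # gamete carries h with marker allele B
    case = np.array([r * r, 2 * r * s, s * s])
    marg = np.array([0.25, 0.5, 0.25])
    return np.vstack([marg - case, case])


def joint_probability(marker_genotype: str, phenotype: str, theta: float) -> float:
    """Probability of one (marker genotype, phenotype) class at a given theta."""
    geno = {"AA": GENO_AA, "AB": GENO_AB, "BB": GENO_BB}[marker_genotype]
    pheno = {"wild-type": PHENO_WT, "wild_type": PHENO_WT, "case": PHENO_CASE}[phenotype]
    return float(class_probabilities(theta)[pheno, geno])


def loglik(counts: np.ndarray, theta: float) -> float:
    """Natural-log likelihood of a 6-cell count table; 0*log(0) = 0."""
    counts = np.asarray(counts, dtype=float)
    probs = class_probabilities(theta)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = counts > 0
    return float((counts[mask] * logp[mask]).sum())


@dataclass
class TwoPointResult:
    """MLE recombination fraction and LOD for one marker-trait pair."""

    marker_id: str
    theta_hat: float
    lod: float
    loglik_at_hat: float
    loglik_at_half: float
    counts: np.ndarray
    informative: bool = True
    position_bp: Optional[int] = None


def _golden_section(counts: np.ndarray, lo: float, hi: float, tol: float) -> float:
    """Maximize the log-likelihood on [lo, hi] by golden-section search."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = loglik(counts, c), loglik(counts, d)
    while b - a > tol:
        if fc >= fd:  # ties move toward smaller theta
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = loglik(counts, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = loglik(counts, d)
    return (a + b) / 2.0


def two_point_lod(counts, marker_id: str = "", tol: float = 1e-6) -> TwoPointResult:
    """Maximum-likelihood theta and LOD for a 6-cell count table.

    A coarse grid brackets the optimum before golden-section refinement, so
    the estimate is robust to flat or boundary-maximized likelihoods; the
    endpoints 0 and 1/2 are always evaluated exactly, with ties broken
    toward smaller theta.  Boundary solutions are returned, never raised.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 3):
        raise ValueError("counts must be a 2x3 (phenotype x genotype) table")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() <= 0:
        raise ValueError("empty count table")

    grid = np.linspace(0.0, 0.5, 501)
    ll_grid = np.array([loglik(counts, t) for t in grid])
    best = int(np.argmax(ll_grid))  # argmax takes the first (smallest theta) on ties
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    candidates = [0.0, 0.5, _golden_section(counts, lo, hi, tol)]
    lls = [loglik(counts, t) for t in candidates]
    order = sorted(range(3), key=lambda i: (-lls[i], candidates[i]))
    theta_hat = candidates[order[0]]
    ll_hat = lls[order[0]]
    ll_half = loglik(counts, 0.5)
    lod = max(0.0, (ll_hat - ll_half) / _LN10)
    return TwoPointResult(marker_id, theta_hat, lod, ll_hat, ll_half, counts)


def counts_from_calls(calls: np.ndarray, phenotypes: list[str]) -> np.ndarray:
    """6-cell table from per-individual genotype codes, complete-case.

    Genotype code 2 (hom_alt) is taken as BB, i.e. the marker allele carried
    by the case-founder line is the alt allele; `two_point_phased=False`
    callers should evaluate both orientations.
    """
    table = np.zeros((2, 3), dtype=float)
    for call, pheno in zip(calls, phenotypes):
        if call == MISSING:
            continue
        row = PHENO_CASE if pheno == "case" else PHENO_WT
        col = {HOM_REF: GENO_AA, HET: GENO_AB, HOM_ALT: GENO_BB}[int(call)]
        table[row, col] += 1
    return table


def scan_markers(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                 tol: float = 1e-6) -> list[TwoPointResult]:
    """Two-point scan of every marker against the trait, ordered by position.

    Missing calls are dropped per marker (complete-case).  The phase of the
    marker alleles relative to the trait is not assumed: both orientations
    are evaluated and the better-supported one reported.  Monomorphic or
    all-missing markers are flagged non-informative rather than raising.
    """
    for ind in genotypes.individuals:
        if ind.phenotype not in ("case", "control"):
            raise ValueError(
                f"individual {ind.id} is {ind.phenotype!r}; scan requires case/control"
            )
    phenos = genotypes.phenotypes
    results = []
    for marker_id, chrom, pos in marker_map.table.itertuples(index=False):
        calls = genotypes.column(marker_id)
        observed = calls[calls != MISSING]
        monomorphic = (
            observed.size == 0
            or (not (observed == HET).any()
                and (np.unique(observed).size == 1))
        )
        counts = counts_from_calls(calls, phenos)
        if monomorphic:
            results.append(
                TwoPointResult(marker_id, math.nan, math.nan,
                               math.nan, math.nan, counts,
                               informative=False, position_bp=int(pos))
            )
            continue
        res_fwd = two_point_lod(counts, marker_id, tol=tol)
        res_rev = two_point_lod(counts[:, ::-1], marker_id, tol=tol)
        res = res_fwd if res_fwd.lod >= res_rev.lod else res_rev
        res.position_bp = int(pos)
        results.append(res)
    return results


def scan_to_frame(results: list[TwoPointResult]):
    """Tidy per-marker table (marker, pos, theta_hat, lod) mirroring a scan report."""
    import pandas as pd

    return pd.DataFrame(
        {
            "marker": [r.marker_id for r in results],
            "position_bp": [r.position_bp for r in results],
            "theta_hat": [round(r.theta_hat, 2) if r.informative else float("nan")
                          for r in results],
            "lod": [r.lod for r in results],
            "informative": [r.informative for r in results],
        }
    )
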