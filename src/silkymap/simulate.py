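"""Synthetic-data generators for every pipeline input.

Four generators emulate the statistical structure of a recessive-trait
mapping study in chickens:

* ``simulate_f2_cross`` — an intercross between two inbred lines fixed for
  alternative alleles at all markers and at a fully penetrant recessive
  trait locus.  F1 gametes are produced under the Haldane map function
  (no interference, sex-averaged), so the recombination fraction between
  loci d Morgans apart is theta = (1 - exp(-2 d)) / 2.
* ``simulate_breed_panel`` — case breeds carrying one shared ancestral
  haplotype whose edges have been eroded by historical recombination
  (exponential in genetic distance, a standard descent-segment
  approximation); control genotypes are Hardy-Weinberg draws.
* ``simulate_pool_counts`` — per-site sequencing read counts from a DNA
  pool: coverage is Poisson, alt reads binomial in the site frequency,
  frequency 1 inside a planted fixed interval.
* ``simulate_qpcr`` / ``simulate_aei`` / ``simulate_luciferase`` — Gaussian
  replicate draws for the downstream expression statistics.

All generators take one integer seed and derive independent child streams
from it, so a fixed seed reproduces outputs bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import (GenotypeMatrix, HET, HOM_ALT, HOM_REF, Individual,
                        MISSING)
from .intervals import GenomicInterval
from .markers import MarkerMap


def haldane_theta(d_morgans: float) -> float:
    """Recombination fraction for a genetic distance in Morgans (Haldane)."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_morgans))


def haldane_distance(theta: float) -> float:
    """Inverse Haldane map: Morgans for a recombination fraction < 0.5."""
    if not 0.0 <= theta < 0.5:
        raise ValueError("theta must be in [0, 0.5)")
    return -0.5 * math.log(1.0 - 2.0 * theta)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


# ----------------------------------------------------------------------------
# F2 intercross


@dataclass
class CrossConfig:
    """Parameters of the simulated F2 intercross.

    Defaults reproduce the mapping population's size: 229 F2 offspring
    phenotyped for a fully penetrant recessive trait.
    """

    n_f2: int = 229
    n_markers: int = 22
    marker_spacing_cM: float = 1.0
    causal_index: float = 11.0  # marker index; fractional = between markers
    penetrance: float = 1.0
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    chrom: str = "3"
    start_bp: int = 70_000_000
    bp_per_cM: float = 330_000.0  # ~3 cM/Mb, a chicken-like genome average

    def __post_init__(self) -> None:
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        if self.marker_spacing_cM <= 0:
            raise ValueError("marker spacing must be > 0")
        for name in ("penetrance", "genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class F2Cross:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    true_theta: np.ndarray  # per-marker theta to the trait locus
    causal_cM: float


def _meiosis(rng: np.random.Generator, theta_adjacent: np.ndarray,
             n_gametes: int) -> np.ndarray:
    """Parental-origin sequences (0/1) of gametes along ordered loci."""
    n_loci = len(theta_adjacent) + 1
    origins = np.empty((n_gametes, n_loci), dtype=np.int8)
    origins[:, 0] = rng.integers(0, 2, size=n_gametes)
    switches = rng.random((n_gametes, n_loci - 1)) < theta_adjacent
    origins[:, 1:] = switches
    return np.cumsum(origins, axis=1) % 2


def simulate_f2_cross(config: CrossConfig) -> F2Cross:
    """Simulate F2 genotypes and phenotypes from two phase-known F1 parents.

    Founder line S is fixed for the alt marker alleles and the recessive
    trait allele h; line W for ref alleles and H.  Every F2 receives two
    independent F1 gametes generated with Haldane recombination; the
    phenotype is ``case`` iff the trait genotype is h/h and a penetrance
    draw succeeds.  Genotyping error flips a call uniformly to one of the
    other two states.
    """
    cfg = config
    marker_cM = np.arange(cfg.n_markers) * cfg.marker_spacing_cM
    causal_cM = cfg.causal_index * cfg.marker_spacing_cM
    # insert the trait locus into the locus sequence; if it coincides with a
    # marker the two loci sit at zero distance (theta 0 between them)
    loci_cM = np.sort(np.append(marker_cM, causal_cM))
    trait_idx = int(np.searchsorted(loci_cM, causal_cM))
    marker_slot = [i for i in range(len(loci_cM)) if i != trait_idx]

    d_adj = np.diff(loci_cM) / 100.0  # cM -> Morgans
    theta_adj = 0.5 * (1.0 - np.exp(-2.0 * d_adj))

    rng = _rng(cfg.seed, 1)
    gametes_a = _meiosis(rng, theta_adj, cfg.n_f2)
    gametes_b = _meiosis(rng, theta_adj, cfg.n_f2)
    origins_sum = gametes_a + gametes_b  # 0..2 copies of the S-line segment

    trait_geno = origins_sum[:, trait_idx]
    penetrant = rng.random(cfg.n_f2) < cfg.penetrance
    is_case = (trait_geno == 2) & penetrant

    calls = origins_sum[:, marker_slot].astype(np.int8)

    if cfg.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    positions = (cfg.start_bp + marker_cM * cfg.bp_per_cM).astype(np.int64)
    marker_map = MarkerMap.from_records(
        [(f"M{i:03d}", cfg.chrom, int(p)) for i, p in enumerate(positions)]
    )
    individuals = [
        Individual(f"F2_{i:04d}", "case" if is_case[i] else "control")
        for i in range(cfg.n_f2)
    ]
    genotypes = GenotypeMatrix(individuals, marker_map.ids, calls)
    true_theta = 0.5 * (1.0 - np.exp(-2.0 * np.abs(marker_cM - causal_cM) / 100.0))
    return F2Cross(genotypes, marker_map, true_theta, causal_cM)


# ----------------------------------------------------------------------------
# breed panel with a planted IBD haplotype


@dataclass
class PanelConfig:
    """Parameters of the simulated case/control breed panel.

    Defaults emulate the fine-mapping panel: 76 silky-feather cases and 95
    wild-type controls typed at 34 SNPs across a ~43 kb candidate region,
    with the ancestral case haplotype planted over the candidate interval.
    The erosion mean (0.0025 cM, ~0.8 kb at 0.33 Mb/cM) encodes a deeply
    ancestral haplotype predating breed formation.
    """

    n_cases: int = 76
    n_controls: int = 95
    shared_interval: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("3", 70_460_739, 70_484_959)
    )
    causal_position: Optional[int] = None  # default: interval midpoint
    erosion_cM: float = 0.0025
    bp_per_cM: float = 330_000.0
    background_freqs: Optional[np.ndarray] = None  # per-marker alt freq
    marker_map: Optional[MarkerMap] = None
    n_markers: int = 34
    region: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("3", 70_441_580, 70_484_959)
    )
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_map is None:
            pos = np.linspace(self.region.start, self.region.end,
                              self.n_markers).astype(np.int64)
            self.marker_map = MarkerMap.from_records(
                [(f"P{i:03d}", self.region.chrom, int(p))
                 for i, p in enumerate(pos)]
            )
        span = self.marker_map.span()
        if (self.shared_interval.chrom != span.chrom
                or self.shared_interval.start > span.end
                or self.shared_interval.end < span.start):
            raise ValueError("shared interval lies outside the marker map extent")
        if self.causal_position is None:
            clipped = (max(self.shared_interval.start, span.start),
                       min(self.shared_interval.end, span.end))
            self.causal_position = (clipped[0] + clipped[1]) // 2
        if self.background_freqs is not None:
            f = np.asarray(self.background_freqs, dtype=float)
            if f.shape != (len(self.marker_map),):
                raise ValueError("background_freqs must be one per marker")
            if ((f < 0) | (f > 1)).any():
                raise ValueError("allele frequencies must be in [0, 1]")
            self.background_freqs = f


@dataclass
class BreedPanel:
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    truth_interval: Optional[GenomicInterval]  # innermost eroded core
    causal_position: int
    shared_allele: int = HOM_ALT


def simulate_breed_panel(config: PanelConfig) -> BreedPanel:
    """Plant one ancestral haplotype in all cases, eroded at its edges.

    Every case is homozygous for the ancestral (alt) allele across the
    shared interval minus an exponential erosion (mean ``erosion_cM``)
    drawn independently per case per side; outside its core, and in
    controls throughout, genotypes are Hardy-Weinberg draws from the
    background allele frequencies.  The recoverable truth — the interval
    bounded by the innermost eroded edges — is returned alongside.
    """
    cfg = config
    rng = _rng(cfg.seed, 2)
    mm = cfg.marker_map
    positions = mm.positions
    n_markers = len(mm)

    freqs = cfg.background_freqs
    if freqs is None:
        freqs = rng.uniform(0.1, 0.9, size=n_markers)

    def hw_draw(n: int) -> np.ndarray:
        u1 = rng.random((n, n_markers)) < freqs
        u2 = rng.random((n, n_markers)) < freqs
        return (u1.astype(np.int8) + u2.astype(np.int8))

    mean_bp = cfg.erosion_cM * cfg.bp_per_cM
    lo = max(cfg.shared_interval.start, int(positions.min()))
    hi = min(cfg.shared_interval.end, int(positions.max()))

    case_calls = hw_draw(cfg.n_cases)
    inner_lo, inner_hi = lo, hi
    for i in range(cfg.n_cases):
        eros_l = rng.exponential(mean_bp) if mean_bp > 0 else 0.0
        eros_r = rng.exponential(mean_bp) if mean_bp > 0 else 0.0
        core_lo, core_hi = lo + eros_l, hi - eros_r
        inner_lo, inner_hi = max(inner_lo, core_lo), min(inner_hi, core_hi)
        inside = (positions >= core_lo) & (positions <= core_hi)
        case_calls[i, inside] = HOM_ALT
    control_calls = hw_draw(cfg.n_controls)

    calls = np.vstack([case_calls, control_calls]).astype(np.int8)
    if cfg.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    individuals = [Individual(f"case_{i:03d}", "case", "silky")
                   for i in range(cfg.n_cases)]
    individuals += [Individual(f"ctrl_{i:03d}", "control", "wildtype")
                    for i in range(cfg.n_controls)]
    genotypes = GenotypeMatrix(individuals, mm.ids, calls)

    truth = None
    if inner_hi >= inner_lo:
        truth = GenomicInterval(mm.span().chrom, int(math.ceil(inner_lo)),
                                int(math.floor(inner_hi)))
    return BreedPanel(genotypes, mm, truth, int(cfg.causal_position))


# ----------------------------------------------------------------------------
# pooled sequencing counts


@dataclass
class PoolConfig:
    """Parameters of the simulated pooled-sequencing site counts.

    Defaults emulate a 15-bird pool scanned across the ~182 kb combined
    linkage interval, with the fixed (alt frequency 1) haplotype planted
    over the pool-detected interval.  Background frequencies are drawn
    Uniform(0.1, 0.7): sites ascertained as segregating in a small pool
    rarely sit near fixation outside IBD tracts.
    """

    n_sites: int = 500
    region: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("3", 70_399_176, 70_581_126)
    )
    fixed_interval: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("3", 70_467_293, 70_489_020)
    )
    background_freq_range: tuple[float, float] = (0.1, 0.7)
    mean_coverage: float = 20.0
    pool_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean coverage must be > 0")


def simulate_pool_counts(config: PoolConfig):
    """Per-site (position, ref reads, alt reads) from a DNA pool.

    Coverage is Poisson(mean_coverage); alt reads are Binomial(coverage,
    site frequency); sites inside the fixed interval have frequency 1.
    Zero-coverage sites are kept with zero counts (they carry no frequency
    information and are flagged undefined downstream, not treated as 0).
    """
    from .poolscan import PoolSiteCounts

    cfg = config
    rng = _rng(cfg.seed, 3)
    positions = np.sort(
        rng.choice(
            np.arange(cfg.region.start, cfg.region.end + 1),
            size=cfg.n_sites, replace=False,
        )
    )
    freqs = rng.uniform(*cfg.background_freq_range, size=cfg.n_sites)
    inside = (positions >= cfg.fixed_interval.start) & (positions <= cfg.fixed_interval.end)
    freqs[inside] = 1.0
    coverage = rng.poisson(cfg.mean_coverage, size=cfg.n_sites)
    alt = rng.binomial(coverage, freqs)
    ref = coverage - alt
    return PoolSiteCounts(
        chrom=cfg.region.chrom,
        positions=positions.astype(np.int64),
        ref=ref.astype(np.int64),
        alt=alt.astype(np.int64),
        pool_size=cfg.pool_size,
    )


# ----------------------------------------------------------------------------
# expression-stage tables


def simulate_qpcr(groups: dict[str, dict], seed: int = 0, ct_sd: float = 0.3,
                  technical_sd: float = 0.05, n_technical: int = 3) -> pd.DataFrame:
    """Ct table for the relative-expression comparison.

    ``groups`` maps a group label to ``{"target_ct": mean, "reference_ct":
    mean, "n": individuals}``.  Per individual, true Ct values are Gaussian
    with the biological SD; technical replicates add Gaussian jitter.
    """
    rng = _rng(seed, 4)
    rows = []
    for label, spec in groups.items():
        for i in range(int(spec["n"])):
            ind = f"{label}_{i:02d}"
            for gene, mean in (("target", spec["target_ct"]),
                               ("reference", spec["reference_ct"])):
                true_ct = rng.normal(mean, ct_sd)
                for rep in range(n_technical):
                    rows.append(
                        (ind, label, gene, rng.normal(true_ct, technical_sd), rep)
                    )
    return pd.DataFrame(rows, columns=["individual", "group", "gene", "ct", "replicate"])


def simulate_aei(n_het: int = 11, gdna_mean: float = 0.50, cdna_mean: float = 0.65,
                 gdna_sd: float = 0.02, cdna_sd: float = 0.03,
                 seed: int = 0, genotype: str = "H/h") -> pd.DataFrame:
    """Paired gDNA/cDNA major-allele fractions for the imbalance test."""
    rng = _rng(seed, 5)
    rows = []
    for i in range(n_het):
        ind = f"het_{i:02d}"
        g = float(np.clip(rng.normal(gdna_mean, gdna_sd), 0.0, 1.0))
        c = float(np.clip(rng.normal(cdna_mean, cdna_sd), 0.0, 1.0))
        rows.append((ind, genotype, "gDNA", g))
        rows.append((ind, genotype, "cDNA", c))
    return pd.DataFrame(rows, columns=["individual", "genotype", "template",
                                       "major_fraction"])


def simulate_luciferase(activities: Optional[dict[str, float]] = None,
                        cv: float = 0.10, n_technical: int = 3,
                        n_biological: int = 3, renilla_mean: float = 1.0e5,
                        seed: int = 0) -> pd.DataFrame:
    """Firefly/renilla luminescence table for promoter-activity fold changes.

    ``activities`` maps construct label to its true activity relative to the
    promoterless reference vector (which must be present, activity 1).
    """
    if activities is None:
        activities = {"pGL3-Basic": 1.0, "H-LF": 46.0, "h-LF": 8.0,
                      "H-SF": 53.0, "h-SF": 9.0}
    rng = _rng(seed, 6)
    rows = []
    for b in range(n_biological):
        scale = rng.uniform(0.5, 2.0)  # per-repeat transfection efficiency
        for construct, act in activities.items():
            for t in range(n_technical):
                renilla = renilla_mean * scale * rng.normal(1.0, cv)
                firefly = act * renilla_mean * scale * rng.normal(1.0, cv)
                rows.append((construct, max(firefly, 1.0), max(renilla, 1.0), t, b))
    return pd.DataFrame(rows, columns=["construct", "firefly", "renilla",
                                       "technical", "repeat"])
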