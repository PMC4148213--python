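"""Statistical contracts of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from silkymap.genotypes import HOM_ALT, MISSING
from silkymap.intervals import GenomicInterval
from silkymap.markers import MarkerMap
from silkymap.simulate import (CrossConfig, PanelConfig, PoolConfig,
                               haldane_distance, haldane_theta,
                               simulate_aei, simulate_breed_panel,
                               simulate_f2_cross, simulate_luciferase,
                               simulate_pool_counts, simulate_qpcr)


def test_haldane_round_trip():
    for theta in (0.0, 0.01, 0.1, 0.3, 0.49):
        assert haldane_theta(haldane_distance(theta)) == pytest.approx(theta)
    assert haldane_theta(1e9) == pytest.approx(0.5)


def test_fixed_seed_is_bit_identical():
    a = simulate_f2_cross(CrossConfig(seed=3, genotyping_error_rate=0.01,
                                      missing_rate=0.02))
    b = simulate_f2_cross(CrossConfig(seed=3, genotyping_error_rate=0.01,
                                      missing_rate=0.02))
    assert (a.genotypes.calls == b.genotypes.calls).all()
    assert a.genotypes.phenotypes == b.genotypes.phenotypes
    c = simulate_f2_cross(CrossConfig(seed=4))
    assert not (a.genotypes.calls == c.genotypes.calls).all()


def test_cosegregation_at_zero_distance():
    # the trait locus coincides with marker 10: with no genotyping error
    # every case must be homozygous for the case-line (alt) allele there
    cross = simulate_f2_cross(CrossConfig(seed=1, causal_index=10))
    cases = cross.genotypes.subset_phenotype("case")
    assert (cases.calls[:, 10] == HOM_ALT).all()
    assert cross.true_theta[10] == 0.0


def test_unlinked_markers_recombine_freely():
    # 10^4 F2 with one marker 10 Morgans from the trait locus: the
    # case-class marker frequencies approach the 1:2:1 marginal
    cross = simulate_f2_cross(
        CrossConfig(seed=2, n_f2=10_000, n_markers=2, marker_spacing_cM=1000.0,
                    causal_index=1.0)
    )
    assert cross.true_theta[0] == pytest.approx(0.5)
    cases = cross.genotypes.subset_phenotype("case")
    freq_alt = cases.calls[:, 0].mean() / 2  # allele frequency among cases
    se = np.sqrt(0.25 / (2 * cases.n_individuals))
    assert abs(freq_alt - 0.5) < 3 * se


def test_case_fraction_matches_mendelian_quarter():
    # over many seeds the case count should leave a 99% binomial(229, 1/4)
    # interval about 1% of the time
    lo, hi = stats.binom.ppf([0.005, 0.995], 229, 0.25)
    outside = 0
    n_seeds = 300
    for seed in range(n_seeds):
        cross = simulate_f2_cross(CrossConfig(seed=seed))
        n_cases = sum(p == "case" for p in cross.genotypes.phenotypes)
        if not lo <= n_cases <= hi:
            outside += 1
    # expect ~1% outside; 10/300 is > 3 binomial SDs above that
    assert outside <= 10


def test_f2_marginal_genotype_ratio():
    cross = simulate_f2_cross(CrossConfig(seed=5, n_f2=2000))
    counts = np.bincount(cross.genotypes.calls[:, 0], minlength=3)
    _, p = stats.chisquare(counts, f_exp=2000 * np.array([0.25, 0.5, 0.25]))
    assert p > 0.001


def test_penetrance_and_noise_parameters():
    cross = simulate_f2_cross(CrossConfig(seed=6, penetrance=0.0))
    assert all(p == "control" for p in cross.genotypes.phenotypes)
    cross = simulate_f2_cross(CrossConfig(seed=6, missing_rate=1.0))
    assert (cross.genotypes.calls == MISSING).all()
    with pytest.raises(ValueError):
        CrossConfig(penetrance=1.5)
    with pytest.raises(ValueError):
        CrossConfig(n_f2=0)


# ---------------------------------------------------------------------------
# breed panel


def test_zero_erosion_plants_exact_interval():
    cfg = PanelConfig(seed=0, erosion_cM=0.0, missing_rate=0.0)
    panel = simulate_breed_panel(cfg)
    positions = panel.marker_map.positions
    inside = ((positions >= cfg.shared_interval.start)
              & (positions <= cfg.shared_interval.end))
    cases = panel.genotypes.subset_phenotype("case")
    assert (cases.calls[:, inside] == HOM_ALT).all()
    assert panel.truth_interval.start == cfg.shared_interval.start
    assert panel.truth_interval.end == cfg.shared_interval.end


def test_single_case_truth_is_its_own_core():
    cfg = PanelConfig(seed=9, n_cases=1, missing_rate=0.0)
    panel = simulate_breed_panel(cfg)
    positions = panel.marker_map.positions
    case_row = panel.genotypes.subset_phenotype("case").calls[0]
    t = panel.truth_interval
    inside = (positions >= t.start) & (positions <= t.end)
    assert (case_row[inside] == HOM_ALT).all()


def test_shared_interval_outside_map_rejected():
    with pytest.raises(ValueError, match="outside"):
        PanelConfig(shared_interval=GenomicInterval("3", 1, 2))


def test_panel_controls_are_polymorphic():
    panel = simulate_breed_panel(PanelConfig(seed=1))
    controls = panel.genotypes.subset_phenotype("control")
    observed = controls.calls[controls.calls != MISSING]
    assert set(np.unique(observed)) == {0, 1, 2}


# ---------------------------------------------------------------------------
# pooled counts


def test_pool_fixed_interval_is_all_alt():
    cfg = PoolConfig(seed=0)
    pool = simulate_pool_counts(cfg)
    inside = ((pool.positions >= cfg.fixed_interval.start)
              & (pool.positions <= cfg.fixed_interval.end))
    covered = inside & (pool.coverage > 0)
    assert covered.any()
    assert (pool.alt[covered] == pool.coverage[covered]).all()


def test_pool_low_coverage_sites_are_kept_not_zeroed():
    pool = simulate_pool_counts(PoolConfig(seed=1, mean_coverage=0.1))
    assert (pool.coverage == 0).sum() > 0  # zero-coverage sites retained
    from silkymap.poolscan import site_vaf

    vaf = site_vaf(pool, min_coverage=4)
    assert np.isnan(vaf[pool.coverage == 0]).all()


def test_pool_background_frequency_sampling():
    cfg = PoolConfig(seed=2, n_sites=10_000, background_freq_range=(0.5, 0.5),
                     fixed_interval=GenomicInterval("3", 70_399_176, 70_399_276),
                     region=GenomicInterval("3", 70_399_176, 70_999_176))
    pool = simulate_pool_counts(cfg)
    from silkymap.poolscan import site_vaf

    vaf = site_vaf(pool)
    background = pool.positions > cfg.fixed_interval.end
    mean_vaf = np.nanmean(vaf[background])
    se = np.nanstd(vaf[background]) / np.sqrt(background.sum())
    assert abs(mean_vaf - 0.5) < 3 * se


# ---------------------------------------------------------------------------
# expression tables


def test_qpcr_zero_sd_is_deterministic():
    table = simulate_qpcr(
        {"HH": {"target_ct": 24.0, "reference_ct": 20.0, "n": 4}},
        seed=0, ct_sd=0.0, technical_sd=0.0,
    )
    assert (table.loc[table["gene"] == "target", "ct"] == 24.0).all()
    assert (table.loc[table["gene"] == "reference", "ct"] == 20.0).all()


def test_aei_table_is_paired():
    table = simulate_aei(seed=0)
    wide = table.pivot(index="individual", columns="template",
                       values="major_fraction")
    assert len(wide) == 11
    assert wide.notna().all().all()


def test_luciferase_requires_reference_and_is_reproducible():
    a = simulate_luciferase(seed=1)
    b = simulate_luciferase(seed=1)
    assert a.equals(b)
    assert set(a["construct"]) == {"pGL3-Basic", "H-LF", "h-LF", "H-SF", "h-SF"}
    assert (a["renilla"] > 0).all()
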