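"""IBD block finding, control exclusion, boundary narrowing, variant filter."""

import numpy as np
import pytest

from conftest import make_matrix
from silkymap import datasets
from silkymap.genotypes import (HET, HOM_ALT, HOM_REF, MISSING, Individual,
                                VariantTable)
from silkymap.ibd import (association_from_counts, association_table,
                          exclude_control_matches, narrow_boundaries,
                          run_ibd_pipeline, shared_homozygous_blocks,
                          variant_exclusion_filter)
from silkymap.markers import MarkerMap
from silkymap.simulate import PanelConfig, simulate_breed_panel

H, A, E, M = HOM_REF, HOM_ALT, HET, MISSING


def brute_force_blocks(calls):
    """Oracle: test every (start, end) window for the sharing predicate."""
    n, m = calls.shape

    def window_shares(j, k):
        for c in range(j, k + 1):
            column = calls[:, c]
            for allele in (H, A):
                if all(x == allele or x == M for x in column):
                    break
            else:
                return False
        return True

    sharing = {(j, k) for j in range(m) for k in range(j, m) if window_shares(j, k)}
    return sorted(
        (j, k)
        for (j, k) in sharing
        if (j - 1, k) not in sharing and (j, k + 1) not in sharing
    )


# ---------------------------------------------------------------------------
# block finding


def test_single_block_direct_construction(small_map):
    calls = np.full((3, 8), E, dtype=np.int8)
    calls[:, 2:6] = A  # all three cases hom-alt at markers 2-5
    calls[0, 5] = A
    gm = make_matrix(calls)
    blocks = shared_homozygous_blocks(gm, small_map)
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.start_idx, b.end_idx) == (2, 5)
    assert b.interval.start == small_map.positions[2]
    assert b.interval.end == small_map.positions[5]
    assert (b.shared_alleles == A).all()
    assert b.n_supporting_cases == 3


def test_two_blocks_split_by_one_het_case(small_map):
    """Case-sharing limited to two blocks separated by one het genotype —
    the canonical two-haplotype-block configuration of recessive fine
    mapping (here markers 1-3 and 5-7)."""
    calls = np.full((4, 8), A, dtype=np.int8)
    calls[:, 0] = [H, A, A, A]  # one case hom-other: breaks sharing
    calls[2, 4] = E  # one het case splits the run
    gm = make_matrix(calls)
    blocks = shared_homozygous_blocks(gm, small_map)
    assert [(b.start_idx, b.end_idx) for b in blocks] == [(1, 3), (5, 7)]


def test_missing_policy_compatible_vs_breaking(small_map):
    calls = np.full((2, 8), A, dtype=np.int8)
    calls[0, 4] = M
    gm = make_matrix(calls)
    compatible = shared_homozygous_blocks(gm, small_map)
    assert [(b.start_idx, b.end_idx) for b in compatible] == [(0, 7)]
    breaking = shared_homozygous_blocks(gm, small_map, missing_policy="breaking")
    assert [(b.start_idx, b.end_idx) for b in breaking] == [(0, 3), (5, 7)]


def test_max_case_exceptions_tolerates_one_het(small_map):
    calls = np.full((5, 8), A, dtype=np.int8)
    calls[1, 4] = E  # a single heterozygous case inside the haplotype
    gm = make_matrix(calls)
    strict = shared_homozygous_blocks(gm, small_map)
    assert len(strict) == 2
    tolerant = shared_homozygous_blocks(gm, small_map, max_case_exceptions=1)
    assert [(b.start_idx, b.end_idx) for b in tolerant] == [(0, 7)]


def test_block_finder_matches_brute_force_oracle(small_map):
    rng = np.random.default_rng(17)
    for _ in range(300):
        n = int(rng.integers(1, 8))
        m = int(rng.integers(1, 9))
        weights = rng.dirichlet([2, 1, 2, 0.5])
        calls = rng.choice([H, E, A, M], size=(n, m), p=weights).astype(np.int8)
        mm = MarkerMap.from_records(
            [(f"M{j}", "3", 1000 + j * 10) for j in range(m)]
        )
        gm = make_matrix(calls)
        got = [(b.start_idx, b.end_idx)
               for b in shared_homozygous_blocks(gm, mm)]
        assert got == brute_force_blocks(calls)


def test_adding_a_case_never_widens_blocks(small_map):
    rng = np.random.default_rng(23)
    for _ in range(50):
        calls = rng.choice([H, E, A, M], size=(4, 8), p=[0.25, 0.1, 0.55, 0.1])
        base = shared_homozygous_blocks(make_matrix(calls[:3]), small_map)
        extended = shared_homozygous_blocks(make_matrix(calls), small_map)
        base_cols = {j for b in base for j in range(b.start_idx, b.end_idx + 1)}
        ext_cols = {j for b in extended for j in range(b.start_idx, b.end_idx + 1)}
        assert ext_cols <= base_cols


# ---------------------------------------------------------------------------
# control exclusion


def test_control_matching_one_block_excludes_it(small_map):
    case_calls = np.full((3, 8), A, dtype=np.int8)
    case_calls[:, 4] = E  # two blocks: 0-3 and 5-7
    blocks = shared_homozygous_blocks(make_matrix(case_calls), small_map)
    assert len(blocks) == 2

    control_calls = np.full((2, 8), E, dtype=np.int8)
    control_calls[0, 0:4] = A  # control 0 carries the proximal haplotype
    controls = make_matrix(control_calls, phenotype="control")
    blocks = exclude_control_matches(blocks, controls)
    assert blocks[0].excluded and blocks[0].excluded_by == ["control_0"]
    assert not blocks[1].excluded


def test_partial_control_match_does_not_exclude(small_map):
    case_calls = np.full((3, 8), A, dtype=np.int8)
    blocks = shared_homozygous_blocks(make_matrix(case_calls), small_map)
    control_calls = np.full((1, 8), A, dtype=np.int8)
    control_calls[0, 3] = E  # het at one marker: no full-haplotype match
    blocks = exclude_control_matches(blocks, make_matrix(control_calls, "control"))
    assert not blocks[0].excluded

    no_controls = make_matrix(np.empty((0, 8), dtype=np.int8), phenotype=[])
    blocks = exclude_control_matches(blocks, no_controls)
    assert not blocks[0].excluded


# ---------------------------------------------------------------------------
# boundary narrowing


def narrowing_fixture():
    """A panel map encoding the reported boundary facts: the surviving
    block spans 70,447,648-70,504,365 and extended-panel cases are
    heterozygous at the boundary marker 70,460,738."""
    positions = [70_447_648, 70_455_000, 70_460_738, 70_470_000,
                 70_481_788, 70_504_365]
    mm = MarkerMap.from_records(
        [(f"S{i}", "3", p) for i, p in enumerate(positions)]
    )
    case_calls = np.full((3, 6), A, dtype=np.int8)
    cases = make_matrix(case_calls)
    block = shared_homozygous_blocks(cases, mm)[0]
    assert block.interval.start == 70_447_648
    panel_calls = np.full((3, 6), A, dtype=np.int8)
    panel_calls[0, 2] = E  # two heterozygous and
    panel_calls[1, 2] = E
    panel_calls[2, 2] = H  # one opposite-homozygote bird at 70,460,738
    panel = make_matrix(panel_calls)
    return block, panel, mm


def test_het_exclusive_boundary_convention():
    block, panel, mm = narrowing_fixture()
    narrowed = narrow_boundaries(block, panel, mm)
    assert narrowed.interval.start == 70_460_739  # 1 bp inside the boundary
    assert narrowed.interval.end == 70_504_365
    assert not narrowed.open_left and narrowed.open_right
    assert narrowed.boundary_markers[0] == 70_460_738


def test_concordant_panel_leaves_block_open():
    block, _, mm = narrowing_fixture()
    panel = make_matrix(np.full((3, 6), A, dtype=np.int8))
    narrowed = narrow_boundaries(block, panel, mm)
    assert narrowed.interval == block.interval
    assert narrowed.open_left and narrowed.open_right


def test_interior_discordance_agrees_with_pooled_block_finder():
    block, panel, mm = narrowing_fixture()
    panel.calls[:] = A
    panel.calls[1, 3] = E  # discordance at an interior marker splits the block
    narrowed = narrow_boundaries(block, panel, mm)
    pooled = make_matrix(np.vstack([np.full((3, 6), A, dtype=np.int8),
                                    panel.calls]))
    pooled_blocks = shared_homozygous_blocks(pooled, mm)
    spans = [(b.interval.start, b.interval.end) for b in pooled_blocks]
    # the narrowed interval is the longest clean segment, +-1 bp inside the
    # discordant marker; the pooled block finder splits at the same marker
    assert spans == [(70_447_648, 70_460_738), (70_481_788, 70_504_365)]
    assert narrowed.interval.start == 70_470_000 + 1
    assert narrowed.interval.end == 70_504_365


# ---------------------------------------------------------------------------
# variant exclusion filter


def truth_table_variants():
    """Five variants, exactly one in perfect segregation.

    Individuals: 2 cases, 2 controls, 1 obligate het.
    """
    individuals = [Individual("case_a", "case"), Individual("case_b", "case"),
                   Individual("ctrl_a", "control"), Individual("ctrl_b", "control"),
                   Individual("het_a", "obligate_het")]
    columns = {
        "perfect": [A, A, H, H, E],
        "case_het": [A, E, H, H, E],
        "control_shares": [A, A, A, H, E],
        "het_is_hom": [A, A, H, H, A],
        "cases_differ": [A, H, H, H, E],
    }
    calls = np.array(list(columns.values()), dtype=np.int8).T
    gm = make_matrix(calls, phenotype=[i.phenotype for i in individuals],
                     ids=[i.id for i in individuals],
                     marker_ids=list(columns))
    gm.individuals = individuals
    return VariantTable("3", np.arange(100, 600, 100), ["C"] * 5, ["G"] * 5, gm)


def test_variant_filter_truth_table():
    table = truth_table_variants()
    retained, reasons = variant_exclusion_filter(table)
    assert retained == [0]
    assert reasons[0] is None
    assert reasons[1].clause == "case_not_homozygous" and reasons[1].witness == "case_b"
    assert reasons[2].clause == "control_matches" and reasons[2].witness == "ctrl_a"
    assert reasons[3].clause == "het_not_het" and reasons[3].witness == "het_a"
    assert reasons[4].clause == "case_not_homozygous"


def test_variant_filter_no_data_and_unlabeled():
    table = truth_table_variants()
    table.genotypes.calls[:, 1] = M
    _, reasons = variant_exclusion_filter(table)
    assert reasons[1].clause == "no_data"

    table.genotypes.individuals[0] = Individual("case_a", "unknown")
    with pytest.raises(ValueError, match="phenotype"):
        variant_exclusion_filter(table)


# ---------------------------------------------------------------------------
# association tabulation


def test_association_panel_totals():
    """Re-entered breed-panel counts: 337 cases, 40 hets, 341 controls."""
    table = association_from_counts(datasets.association_panel_frame())
    totals = table.class_totals
    assert totals == {"case": 337, "obligate_het": 40, "control": 341}
    assert table.grand_total == 718
    assert table.complete_association


def test_association_single_discordant_control():
    frame = datasets.association_panel_frame().copy()
    frame.loc[frame["population"] == "Anak", ["hom_alt", "hom_ref"]] = [1, 9]
    table = association_from_counts(frame)
    assert not table.complete_association
    assert table.grand_total == 718


def test_association_missing_and_empty():
    individuals = [Individual("a", "case"), Individual("b", "case")]
    table = association_table(np.array([A, M]), individuals)
    assert table.complete_association  # missing excluded from the predicate
    assert table.counts.loc["case", "missing"] == 1
    with pytest.raises(ValueError, match="no individuals"):
        association_table(np.array([]), [])


# ---------------------------------------------------------------------------
# pipeline


def test_pipeline_recovers_planted_interval():
    panel = simulate_breed_panel(PanelConfig(seed=42))
    report = run_ibd_pipeline(
        panel.genotypes.subset_phenotype("case"),
        panel.genotypes.subset_phenotype("control"),
        None, None, panel.marker_map,
    )
    assert report.minimal_interval is not None
    assert report.minimal_interval.contains(panel.causal_position)
    assert "case-shared block" in report.summary()


def test_pipeline_cases_equal_controls_no_survivor(small_map):
    calls = np.full((4, 8), A, dtype=np.int8)
    cases = make_matrix(calls)
    controls = make_matrix(calls.copy(), phenotype="control")
    report = run_ibd_pipeline(cases, controls, None, None, small_map)
    assert report.surviving_blocks == []
    assert report.minimal_interval is None


def test_pipeline_single_case_no_controls(small_map):
    # hets at markers 3 and 6; note a hom-ref call is still homozygous for
    # a single case, so runs break only at heterozygous calls
    calls = np.array([[A, A, A, E, A, H, E, A]], dtype=np.int8)
    cases = make_matrix(calls)
    controls = make_matrix(np.empty((0, 8), dtype=np.int8), phenotype=[])
    report = run_ibd_pipeline(cases, controls, None, None, small_map)
    # the longest homozygous run of the single case: markers 0-2
    assert report.minimal_interval.start == small_map.positions[0]
    assert report.minimal_interval.end == small_map.positions[2]
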