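import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trajkl.datatypes import CellRecord, CountMatrix, RunConfig
from trajkl.preprocess import (
    capture_variance_ratio,
    exclude_high_marker_cells,
    filter_cells_by_mapped_reads,
    log_transform_counts,
    median_of_ratios_size_factors,
    normalize_and_transform,
    preprocess,
    remove_invariant_transcripts,
    select_analysis_genes,
)
from conftest import make_cells


# ---------------------------------------------------------------------------
# mapped-read filter


def test_read_filter_boundary_inclusive():
    cells = [CellRecord("lo", 0.0, 5_999_999), CellRecord("eq", 0.0, 6_000_000), CellRecord("hi", 0.0, 6_000_001)]
    assert filter_cells_by_mapped_reads(cells, 6_000_000) == ["eq", "hi"]


def test_read_filter_empty():
    assert filter_cells_by_mapped_reads([], 6_000_000) == []


# ---------------------------------------------------------------------------
# transform


@pytest.mark.parametrize("x,expected", [(0, 0.0), (99, 2.0), (9, 1.0)])
def test_log_transform_values(x, expected):
    m = CountMatrix(["g"], ["c"], np.array([[float(x)]]))
    assert log_transform_counts(m).values[0, 0] == pytest.approx(expected)


def test_log_transform_rejects_negative():
    m = CountMatrix(["g"], ["c"], np.array([[1.0]]))
    m.values[0, 0] = -1.0
    with pytest.raises(ValueError):
        log_transform_counts(m)


# ---------------------------------------------------------------------------
# invariant-gene removal


def test_invariant_gene_removed_kept():
    m = CountMatrix(["const", "vary"], ["a", "b", "c"], np.array([[5.0, 5, 5], [5, 5, 6]]))
    out = remove_invariant_transcripts(m)
    assert out.genes == ["vary"]


def test_all_constant_matrix_empties():
    m = CountMatrix(["g1", "g2"], ["a", "b"], np.array([[1.0, 1], [2, 2]]))
    assert remove_invariant_transcripts(m).genes == []


# ---------------------------------------------------------------------------
# marker exclusion


def _marker_setup(value_48h, value_0h=0.0):
    m = CountMatrix(
        ["Tfcp2l1"], ["c0", "c48"], np.array([[value_0h, value_48h]])
    )
    cells = [CellRecord("c0", 0.0, 7_000_000), CellRecord("c48", 48.0, 7_000_000)]
    return m, cells


def test_marker_excludes_strictly_above_threshold():
    m, cells = _marker_setup(1.51)
    assert exclude_high_marker_cells(m, cells, "Tfcp2l1", 1.5, 48.0) == ["c0"]


def test_marker_boundary_value_retained():
    m, cells = _marker_setup(1.5)
    assert exclude_high_marker_cells(m, cells, "Tfcp2l1", 1.5, 48.0) == ["c0", "c48"]


def test_marker_other_group_never_excluded():
    m, cells = _marker_setup(0.0, value_0h=1.51)
    assert exclude_high_marker_cells(m, cells, "Tfcp2l1", 1.5, 48.0) == ["c0", "c48"]


def test_marker_absent_is_hard_error():
    m = CountMatrix(["other"], ["c"], np.array([[1.0]]))
    with pytest.raises(ValueError, match="Tfcp2l1"):
        exclude_high_marker_cells(m, [CellRecord("c", 48.0, 7_000_000)], "Tfcp2l1", 1.5, 48.0)


# ---------------------------------------------------------------------------
# size factors


def test_size_factor_worked_example(tiny_matrix):
    sf = median_of_ratios_size_factors(tiny_matrix)
    assert sf.to_numpy() == pytest.approx([0.7071, 1.4142], abs=1e-4)


def test_size_factor_identical_cells_all_one():
    m = CountMatrix(["g1", "g2"], ["a", "b", "c"], np.array([[4.0, 4, 4], [9, 9, 9]]))
    assert median_of_ratios_size_factors(m).to_numpy() == pytest.approx([1.0, 1.0, 1.0])


def test_size_factor_no_positive_gene_errors():
    m = CountMatrix(["g1"], ["a", "b"], np.array([[0.0, 5.0]]))
    with pytest.raises(ValueError, match="positive"):
        median_of_ratios_size_factors(m)


def _brute_force_size_factors(values):
    """Independent oracle: literal formula with explicit loops."""
    n_genes, n_cells = values.shape
    ref = []
    ok = []
    for g in range(n_genes):
        if all(values[g, c] > 0 for c in range(n_cells)):
            prod = 1.0
            for c in range(n_cells):
                prod *= values[g, c]
            ref.append(prod ** (1.0 / n_cells))
            ok.append(g)
    sf = []
    for c in range(n_cells):
        ratios = sorted(values[g, c] / r for g, r in zip(ok, ref))
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        sf.append(med)
    return np.array(sf)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=40, deadline=None)
def test_size_factor_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
    values = rng.integers(0, 50, size=shape).astype(float) + rng.integers(0, 2, size=shape)
    if not np.any(np.all(values > 0, axis=1)):
        values[0] = rng.integers(1, 50, size=shape[1])
    m = CountMatrix([f"g{i}" for i in range(shape[0])], [f"c{j}" for j in range(shape[1])], values)
    np.testing.assert_allclose(
        median_of_ratios_size_factors(m).to_numpy(), _brute_force_size_factors(values), rtol=1e-12
    )


def test_size_factor_scale_equivariance(rng):
    values = rng.integers(1, 100, size=(5, 4)).astype(float)
    m = CountMatrix([f"g{i}" for i in range(5)], [f"c{j}" for j in range(4)], values)
    sf = median_of_ratios_size_factors(m)
    doubled = values.copy()
    doubled[:, 2] *= 2.0
    m2 = CountMatrix(m.genes, m.cells, doubled)
    sf2 = median_of_ratios_size_factors(m2)
    # the reference shifts by 2^(1/n_cells); correct for it and compare
    shift = 2.0 ** (1.0 / 4.0)
    np.testing.assert_allclose(sf2.to_numpy() * shift, sf.to_numpy() * np.array([1, 1, 2, 1]), rtol=1e-12)


# ---------------------------------------------------------------------------
# normalize + transform


def test_normalize_identity_when_sf_one(tiny_matrix):
    sf = pd.Series([1.0, 1.0], index=tiny_matrix.cells)
    out = normalize_and_transform(tiny_matrix, sf)
    np.testing.assert_allclose(out.values, log_transform_counts(tiny_matrix).values)


def test_normalize_direct_value():
    m = CountMatrix(["g"], ["c"], np.array([[9.0]]))
    out = normalize_and_transform(m, pd.Series([10.0], index=["c"]))
    assert out.values[0, 0] == pytest.approx(np.log10(1.9), abs=1e-10)
    assert out.values[0, 0] == pytest.approx(0.2788, abs=1e-4)


def test_normalize_zero_count_stays_zero():
    m = CountMatrix(["g"], ["c"], np.array([[0.0]]))
    assert normalize_and_transform(m, pd.Series([17.0], index=["c"])).values[0, 0] == 0.0


def test_normalize_mismatched_length_errors(tiny_matrix):
    with pytest.raises(ValueError):
        normalize_and_transform(tiny_matrix, pd.Series([1.0], index=["c1"]))


# ---------------------------------------------------------------------------
# variance ratio


def test_variance_ratio_worked_example():
    m = CountMatrix(["g"], ["a", "b", "c", "d"], np.array([[1.0, 2, 3, 4]]))
    cells = make_cells([0, 0, 48, 48], ids=list("abcd"))
    score = capture_variance_ratio(m, cells)
    assert score["g"] == pytest.approx(4.0)


def test_variance_ratio_zero_within_is_inf():
    m = CountMatrix(["g"], ["a", "b", "c", "d"], np.array([[2.0, 2, 5, 5]]))
    assert np.isinf(capture_variance_ratio(m, make_cells([0, 0, 48, 48], ids=list("abcd")))["g"])


def test_variance_ratio_zero_over_zero_is_zero():
    m = CountMatrix(["g"], ["a", "b", "c", "d"], np.array([[3.0, 3, 3, 3]]))
    assert capture_variance_ratio(m, make_cells([0, 0, 48, 48], ids=list("abcd")))["g"] == 0.0


def test_variance_ratio_shift_invariant(rng):
    vals = rng.normal(size=(3, 6))
    m1 = CountMatrix(["a", "b", "c"], [f"c{j}" for j in range(6)], vals)
    m2 = CountMatrix(["a", "b", "c"], [f"c{j}" for j in range(6)], vals + 7.5)
    cells = make_cells([0, 0, 24, 24, 48, 48])
    np.testing.assert_allclose(
        capture_variance_ratio(m1, cells).to_numpy(), capture_variance_ratio(m2, cells).to_numpy()
    )


def test_variance_ratio_small_group_errors():
    m = CountMatrix(["g"], ["a", "b", "c"], np.array([[1.0, 2, 3]]))
    with pytest.raises(ValueError, match="48"):
        capture_variance_ratio(m, make_cells([0, 0, 48], ids=list("abc")))


def _brute_force_variance_ratio(values, times):
    groups = sorted(set(times))
    means = [np.mean([v for v, t in zip(values, times) if t == g]) for g in groups]
    variances = [np.var([v for v, t in zip(values, times) if t == g], ddof=1) for g in groups]
    between = np.var(means, ddof=1)
    within = np.mean(variances)
    if within == 0:
        return np.inf if between > 0 else 0.0
    return between / within


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None)
def test_variance_ratio_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    times = [0, 0, 0, 24, 24, 48, 48, 48]
    values = rng.normal(size=len(times))
    m = CountMatrix(["g"], [f"c{j}" for j in range(len(times))], values[None, :])
    got = capture_variance_ratio(m, make_cells(times))["g"]
    assert got == pytest.approx(_brute_force_variance_ratio(values, times), rel=1e-10)


# ---------------------------------------------------------------------------
# gene selection


def test_select_top_by_score():
    scores = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0})
    assert select_analysis_genes(scores, [], 2) == ["a", "c"]


def test_select_curated_union():
    scores = pd.Series({"a": 3.0, "b": 1.0, "c": 2.0})
    assert select_analysis_genes(scores, ["b"], 2) == ["b", "a"]


def test_select_tie_breaks_lexicographically():
    scores = pd.Series({"zz": 1.0, "aa": 1.0, "mm": 2.0})
    assert select_analysis_genes(scores, [], 2) == ["mm", "aa"]


def test_select_curated_exceeds_total_errors():
    scores = pd.Series({"a": 1.0, "b": 2.0})
    with pytest.raises(ValueError):
        select_analysis_genes(scores, ["a", "b"], 1)


def test_select_missing_curated_skipped(caplog):
    scores = pd.Series({"a": 3.0, "b": 1.0})
    assert select_analysis_genes(scores, ["ghost"], 1) == ["a"]


# ---------------------------------------------------------------------------
# full chain


def test_preprocess_counts_monotone(small_sim):
    matrix, cells, _ = small_sim
    cfg = RunConfig(kl_direction="symmetrized", n_analysis_genes=15, seed=0)
    working, surviving, report = preprocess(matrix, cells, cfg)
    assert report.cells_in >= report.cells_after_read_filter >= report.cells_after_marker_filter
    assert report.genes_in >= report.genes_after_invariant_filter
    assert (report.size_factors > 0).all()
    assert np.isfinite(report.size_factors).all()
    assert len(report.analysis_genes) == 15
    assert len(surviving) == report.cells_after_marker_filter == len(working.cells)


def test_preprocess_read_filter_applied(small_sim):
    matrix, cells, _ = small_sim
    from trajkl.simulate import SimConfig, simulate_expression

    m2, c2, _ = simulate_expression(
        SimConfig(seed=9, n_cells_per_group=8, n_down=8, n_up=8, n_flat=8, n_qc_failures=3)
    )
    cfg = RunConfig(kl_direction="symmetrized", n_analysis_genes=10, seed=0)
    _, surviving, report = preprocess(m2, c2, cfg)
    assert report.cells_after_read_filter == report.cells_in - 3
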