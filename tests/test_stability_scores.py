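"""Score algebra: CV, the stable dot matrix, HR/HS vectors, the aggregate
resampling/signature scores, and dependency typing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperstab.datamodel import AUCGrid
from hyperstab.errors import ParameterError
from hyperstab.stability_scores import (
    aggregate_scores,
    classify_dependency,
    coefficient_of_variation,
    hr_vector,
    hs_vector,
    hyper_stable_matrix,
    stability_matrix,
)


def make_grid(auc: np.ndarray, backend_id: str = "b", ntree: int = 10) -> AUCGrid:
    auc = np.asarray(auc, dtype=float)
    return AUCGrid(
        auc=auc,
        runtime_seconds=np.zeros_like(auc),
        q=auc.shape[2],
        backend_id=backend_id,
        ntree=ntree,
        signature_ids=[f"s{i:03d}" for i in range(auc.shape[0])],
    )


# ---------------------------------------------------------------------------
# coefficient_of_variation
# ---------------------------------------------------------------------------

def test_cv_identical_values_exactly_zero():
    assert coefficient_of_variation([1.0] * 25) == 0.0
    assert coefficient_of_variation([0.1] * 7) == 0.0  # no float residue


def test_cv_hand_values():
    assert coefficient_of_variation([0.8, 0.9, 1.0]) == pytest.approx(0.1 / 0.9)
    assert coefficient_of_variation([0.5, 0.5, 0.5, 0.7]) == pytest.approx(0.1 / 0.55)


def test_cv_preconditions():
    with pytest.raises(ParameterError):
        coefficient_of_variation([0.5])
    with pytest.raises(ParameterError):
        coefficient_of_variation([0.0, 0.0, 0.3, -0.3])  # mean 0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(min_value=0.01, max_value=1.0, allow_nan=False), min_size=2, max_size=30))
def test_cv_matches_definition(values):
    x = np.asarray(values)
    expected = 0.0 if np.all(x == x[0]) else x.std(ddof=1) / x.mean()
    assert coefficient_of_variation(values) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# stability matrix
# ---------------------------------------------------------------------------

def test_constant_replicates_all_stable_at_zero():
    auc = np.full((4, 6, 5), 0.97)
    report = stability_matrix(make_grid(auc), t=0.0)
    assert report.stable.all()
    assert report.resampling_score == 1.0 and report.signature_score == 1.0


def test_single_perturbed_replicate_breaks_one_cell():
    auc = np.full((4, 6, 5), 0.97)
    auc[2, 3, 0] = 0.9700001
    report = stability_matrix(make_grid(auc), t=0.0)
    assert (~report.stable).sum() == 1
    assert not report.stable[2, 3]


def test_stable_matrix_matches_per_cell_oracle():
    rng = np.random.default_rng(42)
    auc = rng.uniform(0.5, 1.0, size=(5, 7, 4))
    auc[1, 2] = 0.9  # one hyper-stable cell
    t = 0.002
    report = stability_matrix(make_grid(auc), t=t)
    for s in range(5):
        for n in range(7):
            cv = coefficient_of_variation(auc[s, n])
            assert report.cv[s, n] == pytest.approx(cv, abs=1e-15)
            assert report.stable[s, n] == (cv <= t)


def test_zero_mean_cell_flagged_not_scored():
    auc = np.full((2, 2, 3), 0.8)
    auc[0, 0] = 0.0
    report = stability_matrix(make_grid(auc), t=0.0)
    assert np.isnan(report.cv[0, 0])
    assert not report.stable[0, 0]
    assert report.stable[1, 1]


def test_hyper_stability_is_relative_stability_at_zero():
    rng = np.random.default_rng(7)
    auc = rng.uniform(0.4, 1.0, size=(6, 8, 5))
    for s, n in [(0, 0), (2, 5), (4, 1)]:
        auc[s, n] = rng.uniform(0.4, 1.0)
    grid = make_grid(auc)
    np.testing.assert_array_equal(
        stability_matrix(grid, 0.0).stable, hyper_stable_matrix(grid)
    )


def test_stable_cells_monotone_in_threshold():
    rng = np.random.default_rng(3)
    base = rng.uniform(0.7, 1.0, size=(10, 12, 1))
    auc = np.clip(base + rng.normal(0, 0.002, size=(10, 12, 6)), 0, 1)
    auc[:3, :4] = auc[:3, :4, :1]  # a hyper-stable corner
    grid = make_grid(auc)
    prev = None
    for t in (0.0, 0.002, 0.004, 0.008):
        stable = stability_matrix(grid, t).stable
        if prev is not None:
            assert (prev <= stable).all()  # cellwise subset
            assert stable.sum() >= prev.sum()
        prev = stable


# ---------------------------------------------------------------------------
# HR / HS / aggregates
# ---------------------------------------------------------------------------

def test_hr_hs_hand_counts():
    stable = np.zeros((21, 50), dtype=bool)
    stable[:7, 0] = True
    stable[5, :10] = True
    hr = hr_vector(stable)
    hs = hs_vector(stable)
    assert hr[0] == pytest.approx(7 / 21)
    assert hs[5] == pytest.approx(10 / 50)
    assert hr_vector(np.ones((21, 50), dtype=bool)).tolist() == [1.0] * 50
    assert hs_vector(np.zeros((3, 4), dtype=bool)).tolist() == [0.0] * 3


def test_aggregate_scores_nonzero_mean_convention():
    assert aggregate_scores(np.array([0.5, 0.0, 0.25]), np.array([1.0]))[0] == 0.375
    assert aggregate_scores(np.zeros(5), np.zeros(3)) == (0.0, 0.0)
    assert aggregate_scores(np.ones(5), np.ones(3)) == (1.0, 1.0)
    # singleton nonzero entry: mean of one value
    assert aggregate_scores(np.array([0.0, 0.4, 0.0]), np.array([0.4]))[0] == pytest.approx(0.4)


def test_scores_match_counting_oracle_on_random_matrices():
    """1000 seeded random boolean matrices against an exhaustive
    cell-counting oracle."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        S, k = rng.integers(2, 8), rng.integers(2, 9)
        stable = rng.uniform(size=(S, k)) < rng.uniform(0.05, 0.95)
        hr = hr_vector(stable)
        hs = hs_vector(stable)
        # oracle: explicit loops
        for n in range(k):
            assert hr[n] == sum(1 for s in range(S) if stable[s, n]) / S
        for s in range(S):
            assert hs[s] == sum(1 for n in range(k) if stable[s, n]) / k
        hrs, hss = aggregate_scores(hr, hs)
        nz_hr = [v for v in hr if v > 0]
        nz_hs = [v for v in hs if v > 0]
        assert hrs == pytest.approx(sum(nz_hr) / len(nz_hr) if nz_hr else 0.0)
        assert hss == pytest.approx(sum(nz_hs) / len(nz_hs) if nz_hs else 0.0)
        assert 0.0 <= hrs <= 1.0 and 0.0 <= hss <= 1.0


# ---------------------------------------------------------------------------
# dependency typing
# ---------------------------------------------------------------------------

def _matrix_with_blanks(blank_rows=0, blank_cols=0, fill=0.9, shape=(10, 10), seed=0):
    rng = np.random.default_rng(seed)
    m = rng.uniform(size=shape) < fill
    m[:blank_rows, :] = False
    m[:, :blank_cols] = False
    return m


def test_blank_rows_typed_signature_dependent():
    m = _matrix_with_blanks(blank_rows=3)
    assert classify_dependency(m) == "signature_dependent"


def test_blank_columns_typed_resampling_dependent():
    m = _matrix_with_blanks(blank_cols=3)
    assert classify_dependency(m) == "resampling_dependent"


def test_dense_trendless_matrix_is_mixed():
    m = _matrix_with_blanks(fill=0.99)
    assert classify_dependency(m) == "mixed"


def test_sparse_matrix_unclassified():
    m = np.zeros((10, 10), dtype=bool)
    m[4, 7] = m[2, 2] = True  # density 0.02 < 0.05
    assert classify_dependency(m) == "unclassified"


def test_classifier_threshold_bounds():
    with pytest.raises(ParameterError):
        classify_dependency(np.ones((2, 2), dtype=bool), row_gap_frac=0.0)
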