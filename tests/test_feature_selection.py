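"""Variance prefilter, importance rank aggregation and rank-stability
indices (Kuncheva / Spearman), plus the stable-size search."""

import itertools

import numpy as np
import pytest

from hyperstab.datamodel import ExpressionDataset
from hyperstab.errors import CapabilityError, ParameterError
from hyperstab.feature_selection import (
    ImportanceRanking,
    kuncheva_index,
    rank_features,
    select_stable_size,
    spearman_rank_stability,
    variance_prefilter,
)
from hyperstab.synthetic_data import generate

from conftest import MockScoreBackend, tiny_dataset


# ---------------------------------------------------------------------------
# variance prefilter
# ---------------------------------------------------------------------------

def test_prefilter_keeps_dominant_variance_feature():
    rng = np.random.default_rng(0)
    values = np.exp2(rng.normal(5, 0.5, size=(20, 5)))
    values[:, 2] = np.exp2(rng.normal(5, 5.0, size=20))  # f2: 10x the log-variance
    ds = ExpressionDataset(
        values=values,
        labels=np.array(["a", "b"] * 10, dtype=object),
        sample_ids=[f"s{i}" for i in range(20)],
        feature_ids=[f"f{j}" for j in range(5)],
    )
    kept = variance_prefilter(ds, 1)
    assert kept.feature_ids == ["f2"]
    assert kept.sample_ids == ds.sample_ids


def test_prefilter_identity_at_full_count():
    ds = tiny_dataset(n_per_class=5, n_features=6)
    assert variance_prefilter(ds, 6).feature_ids == ds.feature_ids


def test_prefilter_recovers_inflated_features():
    """10 inflated-variance features among 100 equal-variance noise features
    are recovered in >= 95 of 100 seeded runs."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        values = np.exp2(rng.normal(6, 1.0, size=(30, 110)))
        inflated = [f"f{j:03d}" for j in range(10)]
        values[:, :10] = np.exp2(rng.normal(6, 3.0, size=(30, 10)))
        ds = ExpressionDataset(
            values=values,
            labels=np.array(["a", "b"] * 15, dtype=object),
            sample_ids=[f"s{i}" for i in range(30)],
            feature_ids=[f"f{j:03d}" for j in range(110)],
        )
        if set(variance_prefilter(ds, 10).feature_ids) == set(inflated):
            hits += 1
    assert hits >= 95


def test_prefilter_bounds():
    ds = tiny_dataset()
    with pytest.raises(ParameterError):
        variance_prefilter(ds, 0)
    with pytest.raises(ParameterError):
        variance_prefilter(ds, ds.n_features + 1)


# ---------------------------------------------------------------------------
# importance ranking
# ---------------------------------------------------------------------------

def test_perfect_separator_ranked_first(rf_backend):
    ds = tiny_dataset(n_per_class=15, n_features=6, seed=3)
    ds.values[:, 4] = np.where(ds.labels == "case", 100.0, 1.0)
    ranking = rank_features(ds, rf_backend, n_repeats=3, seed=1, ntree=50)
    assert ranking.feature_ids[0] == "f4"
    assert ranking.aggregate_rank[0] == 1.0


def test_duplicated_informative_features_share_top(rf_backend):
    """Two identical informative columns both land in the top 2 by aggregate
    rank when averaged over 20 repeated fits."""
    ds = generate(n_pairs=20, n_features=6, n_informative=1, effect_size=3.0, seed=5)
    ds.values[:, 1] = ds.values[:, 0]  # duplicate the informative column
    ranking = rank_features(ds, rf_backend, n_repeats=20, seed=2, ntree=40)
    assert set(ranking.feature_ids[:2]) == {"g00000", "g00001"}


def test_all_noise_ranking_is_diffuse(rf_backend):
    """Pure-noise data: no feature is ranked first in > 20% of 100 repeats."""
    first = {}
    for seed in range(100):
        ds = generate(n_pairs=12, n_features=12, n_informative=0,
                      effect_size=0.0, seed=2000 + seed)
        r = rank_features(ds, rf_backend, n_repeats=1, seed=seed, ntree=25,
                          n_permutation_repeats=2)
        first[r.feature_ids[0]] = first.get(r.feature_ids[0], 0) + 1
    assert max(first.values()) <= 20


def test_ranking_reproducible_bit_for_bit(rf_backend, noisy_dataset):
    a = rank_features(noisy_dataset, rf_backend, n_repeats=2, seed=9, ntree=30)
    b = rank_features(noisy_dataset, rf_backend, n_repeats=2, seed=9, ntree=30)
    assert a.feature_ids == b.feature_ids
    np.testing.assert_array_equal(a.aggregate_rank, b.aggregate_rank)
    np.testing.assert_array_equal(a.impurity_score, b.impurity_score)


def test_backend_without_importances_rejected(noisy_dataset):
    with pytest.raises(CapabilityError, match="importance"):
        rank_features(noisy_dataset, MockScoreBackend(), n_repeats=1, seed=0)


# ---------------------------------------------------------------------------
# Kuncheva index
# ---------------------------------------------------------------------------

def test_kuncheva_closed_form_values():
    assert kuncheva_index({"a", "b", "c", "d", "e"}, {"a", "b", "c", "d", "e"}, 100) == 1.0
    assert kuncheva_index({"a", "b", "c"}, {"d", "e", "f"}, 10) == pytest.approx(-0.9 / 2.1)
    assert kuncheva_index({"a", "b", "c"}, {"a", "e", "f"}, 10) == pytest.approx(0.1 / 2.1)


def test_kuncheva_parameter_errors():
    with pytest.raises(ParameterError):
        kuncheva_index({"a"}, {"a", "b"}, 10)
    with pytest.raises(ParameterError):
        kuncheva_index(set(), set(), 10)
    with pytest.raises(ParameterError):
        kuncheva_index({"a", "b"}, {"a", "b"}, 2)  # s == n_total


def test_kuncheva_symmetric_bounded_identity_bruteforce():
    """All size-2 subset pairs of a 5-feature universe: symmetry, bounds, and
    value 1 only for identical subsets."""
    universe = ["a", "b", "c", "d", "e"]
    subsets = list(itertools.combinations(universe, 2))
    for sa in subsets:
        for sb in subsets:
            k = kuncheva_index(sa, sb, 5)
            assert k == kuncheva_index(sb, sa, 5)
            assert -1.0 <= k <= 1.0
            assert (k == 1.0) == (set(sa) == set(sb))


# ---------------------------------------------------------------------------
# Spearman rank stability
# ---------------------------------------------------------------------------

def _ranking_from_order(feature_ids):
    n = len(feature_ids)
    return ImportanceRanking(
        feature_ids=list(feature_ids),
        impurity_score=np.zeros(n),
        permutation_score=np.zeros(n),
        aggregate_rank=np.arange(1.0, n + 1.0),
    )


def test_spearman_identity_and_reversal():
    r = _ranking_from_order(["a", "b", "c", "d"])
    assert spearman_rank_stability(r, r) == pytest.approx(1.0)
    rev = _ranking_from_order(["d", "c", "b", "a"])
    assert spearman_rank_stability(r, rev) == pytest.approx(-1.0)


def test_spearman_mismatched_universe_rejected():
    with pytest.raises(ParameterError):
        spearman_rank_stability(
            _ranking_from_order(["a", "b"]), _ranking_from_order(["a", "c"])
        )


def test_spearman_null_centre():
    """Independent random permutations of 50 features: mean correlation over
    200 seeded draws sits within +/-0.05 of 0."""
    rng = np.random.default_rng(55)
    feats = [f"f{i}" for i in range(50)]
    vals = []
    for _ in range(200):
        a = _ranking_from_order(rng.permutation(feats))
        b = _ranking_from_order(rng.permutation(feats))
        vals.append(spearman_rank_stability(a, b))
    assert abs(np.mean(vals)) < 0.05


# ---------------------------------------------------------------------------
# stable-size selection
# ---------------------------------------------------------------------------

def test_four_separators_drive_selection(rf_backend):
    """Four strong separators among noise: selected size <= 6 with all four
    separators inside the selected set in >= 90% of 20 seeded runs."""
    ok = 0
    for seed in range(20):
        ds = generate(n_pairs=30, n_features=12, n_informative=4,
                      effect_size=4.0, seed=3000 + seed)
        sel = select_stable_size(
            ds, rf_backend, candidate_sizes=range(2, 11), n_resamples=5,
            P=0.5, seed=seed, ntree=60,
            kuncheva_floor=0.85, spearman_floor=0.5,
        )
        separators = set(ds.feature_ids[:4])
        if sel.n_selected <= 6 and separators <= set(sel.selected_features):
            ok += 1
    assert ok >= 18


def test_single_candidate_forced_choice(rf_backend, noisy_dataset):
    sel = select_stable_size(
        noisy_dataset, rf_backend, candidate_sizes=[5], n_resamples=3,
        P=0.5, seed=0, ntree=30,
    )
    assert sel.n_selected == 5
    assert len(sel.selected_features) == 5


def test_pure_noise_carries_flag(rf_backend):
    ds = generate(n_pairs=15, n_features=10, n_informative=0,
                  effect_size=0.0, seed=77)
    sel = select_stable_size(
        ds, rf_backend, candidate_sizes=[3, 5, 7], n_resamples=3,
        P=0.5, seed=1, ntree=30,
    )
    assert sel.flagged
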