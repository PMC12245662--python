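"""Feature selection: variance prefilter, forest-importance rank aggregation
and rank-stability indices.

The raw feature space is first reduced by variance of the log2(x+1) values
(a generic stand-in for platform-specific intensity-variation filters). The
surviving features are then ranked by a combination of the two standard
forest importances — impurity decrease (mean decrease in Gini, MDG) and
permutation importance (mean decrease in accuracy, MDA) — averaged over
repeated fits and combined by mean-of-ranks. Finally, the selected feature
count Nv' is the smallest candidate size whose top-size subsets are stable
across balanced resamples, judged by the chance-corrected Kuncheva overlap
index and the Spearman correlation of the rankings.

The mean-of-ranks combination and the default stability floors (0.6 for both
indices) are package choices; both floors are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import rankdata, spearmanr

from ._seeds import derive_seed
from .datamodel import ExpressionDataset
from .errors import CapabilityError, ParameterError
from .forest_adapters import ForestBackend
from .resampling import make_partitions


# ---------------------------------------------------------------------------
# Variance prefilter
# ---------------------------------------------------------------------------

def variance_prefilter(dataset: ExpressionDataset, n_keep: int) -> ExpressionDataset:
    """Keep the ``n_keep`` features with highest variance of log2(x+1).

    Sample set unchanged; ties broken by original feature order (stable sort).
    """
    if not 1 <= n_keep <= dataset.n_features:
        raise ParameterError(
            f"n_keep must lie in [1, {dataset.n_features}], got {n_keep}"
        )
    logged = np.log2(dataset.values + 1.0)
    variances = logged.var(axis=0, ddof=1)
    order = np.argsort(-variances, kind="stable")[:n_keep]
    keep = sorted(order)  # preserve original column order
    return dataset.subset_features([dataset.feature_ids[i] for i in keep])


# ---------------------------------------------------------------------------
# Importance ranking
# ---------------------------------------------------------------------------

@dataclass
class ImportanceRanking:
    """Per-feature importances and their rank aggregation, best feature first.

    ``aggregate_rank`` is the mean of the impurity-rank and permutation-rank
    positions (1 = most important); the output ordering is by ascending
    aggregate rank with ties broken by ascending feature id.
    """

    feature_ids: list[str]
    impurity_score: np.ndarray
    permutation_score: np.ndarray
    aggregate_rank: np.ndarray

    def top(self, n: int) -> list[str]:
        return self.feature_ids[:n]

    def rank_of(self) -> dict[str, float]:
        return dict(zip(self.feature_ids, map(float, self.aggregate_rank)))


def rank_features(
    dataset: ExpressionDataset,
    backend: ForestBackend,
    n_repeats: int,
    seed: int,
    ntree: int | None = None,
    n_permutation_repeats: int = 5,
) -> ImportanceRanking:
    """Rank features by averaged (impurity, permutation) importances.

    Each repeat fits the backend with an independent derived seed; the two
    importance vectors are averaged over repeats, ranked separately (average
    ranks on ties), and combined by mean-of-ranks.
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    if not backend.spec.supports_impurity_importance:
        raise CapabilityError(
            f"backend '{backend.spec.backend_id}' lacks impurity importance"
        )
    if not backend.spec.supports_permutation_importance:
        raise CapabilityError(
            f"backend '{backend.spec.backend_id}' lacks permutation importance"
        )
    X = dataset.values
    y = dataset.labels.astype(str)

    imp = np.zeros(dataset.n_features)
    perm = np.zeros(dataset.n_features)
    for r in range(n_repeats):
        i, p = backend.importances(
            X, y, ntree, derive_seed(seed, "rank", r), n_permutation_repeats
        )
        imp += i
        perm += p
    imp /= n_repeats
    perm /= n_repeats

    rank_imp = rankdata(-imp, method="average")
    rank_perm = rankdata(-perm, method="average")
    aggregate = (rank_imp + rank_perm) / 2.0

    order = np.lexsort((np.array(dataset.feature_ids, dtype=object), aggregate))
    return ImportanceRanking(
        feature_ids=[dataset.feature_ids[i] for i in order],
        impurity_score=imp[order],
        permutation_score=perm[order],
        aggregate_rank=aggregate[order],
    )


# ---------------------------------------------------------------------------
# Stability indices
# ---------------------------------------------------------------------------

def kuncheva_index(
    subset_a: Sequence[str] | set, subset_b: Sequence[str] | set, n_total: int
) -> float:
    """Chance-corrected overlap of two equal-size feature subsets.

    ``(r - s^2/N) / (s - s^2/N)`` with r the intersection size, s the common
    subset size and N the feature-universe size; 1 iff identical, negative
    when the overlap is below the chance expectation s^2/N. Undefined for
    s in {0, N}.
    """
    a, b = set(subset_a), set(subset_b)
    s = len(a)
    if len(b) != s:
        raise ParameterError(f"subset sizes differ: {s} vs {len(b)}")
    if s == 0 or s >= n_total:
        raise ParameterError(f"index undefined for subset size {s} of universe {n_total}")
    r = len(a & b)
    expected = s * s / n_total
    return (r - expected) / (s - expected)


def spearman_rank_stability(ranking_a: ImportanceRanking, ranking_b: ImportanceRanking) -> float:
    """Spearman correlation of two aggregate-rank vectors over one universe."""
    if set(ranking_a.feature_ids) != set(ranking_b.feature_ids):
        raise ParameterError("rankings cover different feature universes")
    rank_b = ranking_b.rank_of()
    a = ranking_a.aggregate_rank
    b = np.array([rank_b[f] for f in ranking_a.feature_ids])
    rho = spearmanr(a, b).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Stable-size selection
# ---------------------------------------------------------------------------

@dataclass
class SizeSelection:
    """Outcome of the stable-size search.

    ``flagged`` is set when no candidate size met both stability floors; the
    reported size is then the candidate with the greatest mean Kuncheva
    index, and downstream use should be treated with caution.
    """

    n_selected: int
    flagged: bool
    selected_features: list[str]
    mean_kuncheva: dict[int, float] = field(default_factory=dict)
    mean_spearman: dict[int, float] = field(default_factory=dict)

    def __int__(self) -> int:
        return self.n_selected

    def curve_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("size\tmean_kuncheva\tmean_spearman\n")
            for s in sorted(self.mean_kuncheva):
                fh.write(f"{s}\t{self.mean_kuncheva[s]:.6g}\t{self.mean_spearman[s]:.6g}\n")


def select_stable_size(
    dataset: ExpressionDataset,
    backend: ForestBackend,
    candidate_sizes: Sequence[int],
    n_resamples: int,
    P: float,
    seed: int,
    kuncheva_floor: float = 0.6,
    spearman_floor: float = 0.6,
    ntree: int | None = None,
    n_repeats: int = 1,
) -> SizeSelection:
    """Pick the smallest candidate size whose top-size feature subsets are
    stable across balanced resamples.

    For each of ``n_resamples`` partitions at rate P a ranking is fitted on
    the training side. Per candidate size s the mean pairwise Kuncheva index
    of the top-s subsets is computed; the mean pairwise Spearman correlation
    of the full rankings (size-independent) supplies the second floor. The
    smallest size meeting both floors wins; if none does, the size with the
    greatest mean Kuncheva is returned flagged.

    ``selected_features`` are the top-``n_selected`` features of a final
    ranking fitted on the full dataset.
    """
    sizes = sorted(set(int(s) for s in candidate_sizes))
    if not sizes:
        raise ParameterError("candidate_sizes must be non-empty")
    if sizes[-1] >= dataset.n_features:
        raise ParameterError(
            f"candidate sizes must be < n_features ({dataset.n_features})"
        )
    if n_resamples < 2:
        raise ParameterError("n_resamples must be >= 2 for pairwise stability")

    partitions = make_partitions(dataset, P, n_resamples, seed=derive_seed(seed, "fs"))
    rankings = [
        rank_features(
            _training_view(dataset, train),
            backend,
            n_repeats=n_repeats,
            seed=derive_seed(seed, "fs_rank", n),
            ntree=ntree,
        )
        for n, train in enumerate(partitions.train_indices)
    ]

    pairs = list(combinations(range(n_resamples), 2))
    spearman_mean = float(
        np.mean([spearman_rank_stability(rankings[i], rankings[j]) for i, j in pairs])
    )

    mean_kuncheva: dict[int, float] = {}
    mean_spearman: dict[int, float] = {}
    for s in sizes:
        ks = [
            kuncheva_index(rankings[i].top(s), rankings[j].top(s), dataset.n_features)
            for i, j in pairs
        ]
        mean_kuncheva[s] = float(np.mean(ks))
        mean_spearman[s] = spearman_mean

    chosen = None
    for s in sizes:
        if mean_kuncheva[s] >= kuncheva_floor and mean_spearman[s] >= spearman_floor:
            chosen = s
            break
    flagged = chosen is None
    if flagged:
        chosen = max(sizes, key=lambda s: mean_kuncheva[s])

    final = rank_features(
        dataset, backend, n_repeats=n_repeats, seed=derive_seed(seed, "fs_final"), ntree=ntree
    )
    return SizeSelection(
        n_selected=chosen,
        flagged=flagged,
        selected_features=final.top(chosen),
        mean_kuncheva=mean_kuncheva,
        mean_spearman=mean_spearman,
    )


def _training_view(dataset: ExpressionDataset, train: np.ndarray) -> ExpressionDataset:
    return ExpressionDataset(
        values=dataset.values[train],
        labels=dataset.labels[train],
        sample_ids=[dataset.sample_ids[i] for i in train],
        feature_ids=list(dataset.feature_ids),
        pair_ids=None,  # a one-sided split breaks pairs; ranking does not need them
        positive_label=dataset.positive_label,
        rpkm_like=dataset.rpkm_like,
    )


def write_feature_list(features: Sequence[str], path) -> None:
    """One feature id per line."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f}\n")


def read_feature_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
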