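"""Balanced train/validation resampling.

Generates the k random training partitions at resampling rate P used by the
benchmark: per class, ``round_half_up(P * class_size)`` samples are drawn
without replacement into training and the complement forms validation, so a
perfectly balanced dataset contributes equally from both classes (e.g. 96
balanced samples at P = 0.5 give 48 training samples, 24 per class).
"""

from __future__ import annotations

import math

import numpy as np

from ._seeds import derive_seed
from .datamodel import ExpressionDataset, PartitionSet
from .errors import ParameterError


def round_half_up(x: float) -> int:
    """Deterministic commercial rounding (0.5 always rounds up)."""
    return int(math.floor(x + 0.5))


def make_partitions(
    dataset: ExpressionDataset,
    P: float,
    k: int,
    seed: int,
    pair_aware: bool = False,
) -> PartitionSet:
    """Draw k independent stratified train/validation splits.

    Per class the training count is ``round_half_up(P * class_size)``;
    sampling is without replacement and the validation side is the exact
    complement. With ``pair_aware`` pairs are sampled as units so both members
    of a pair land on the same side (the per-pair one-case-one-control
    structure then keeps the split stratified automatically).

    Raises
    ------
    ParameterError
        If P or k is out of range, or a per-class (or per-pair) training
        count would leave either side empty.
    """
    if not (0.0 < P < 1.0):
        raise ParameterError(f"P must lie in (0, 1), got {P}")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")

    rng = np.random.default_rng(seed)
    train_sets: list[np.ndarray] = []

    if pair_aware:
        if dataset.pair_ids is None:
            raise ParameterError("pair_aware resampling requires pair_ids")
        pair_order: list[str] = []
        members: dict[str, list[int]] = {}
        for i, pid in enumerate(dataset.pair_ids):
            if pid not in members:
                pair_order.append(pid)
            members.setdefault(pid, []).append(i)
        n_pairs = len(pair_order)
        n_train_pairs = round_half_up(P * n_pairs)
        if n_train_pairs in (0, n_pairs):
            raise ParameterError(
                f"P={P} with {n_pairs} pairs leaves an empty training or validation side"
            )
        for _ in range(k):
            chosen = rng.choice(n_pairs, size=n_train_pairs, replace=False)
            idx = np.sort(
                np.concatenate([members[pair_order[c]] for c in chosen]).astype(int)
            )
            train_sets.append(idx)
    else:
        by_class = dataset.class_indices()
        counts = {}
        for c, idx in by_class.items():
            t_c = round_half_up(P * len(idx))
            if t_c in (0, len(idx)):
                raise ParameterError(
                    f"P={P} gives class '{c}' a training count of {t_c} "
                    f"out of {len(idx)} (one side empty)"
                )
            counts[c] = t_c
        for _ in range(k):
            parts = [
                rng.choice(idx, size=counts[c], replace=False)
                for c, idx in by_class.items()
            ]
            train_sets.append(np.sort(np.concatenate(parts)).astype(int))

    return PartitionSet(
        rate=P, k=k, train_indices=train_sets, seed=seed, n_samples=dataset.n_samples
    )


def variable_sample_ratio(n_variables: int, n_training_samples: float) -> float:
    """Number of signature variables per training sample.

    Ratios below ~0.5 are associated with well-stabilised AUCs; the ratio
    shrinks either by shortening the signature or by raising the resampling
    rate (more training samples, less data perturbation).
    """
    if n_training_samples <= 0:
        raise ParameterError("n_training_samples must be > 0")
    return n_variables / n_training_samples


__all__ = ["make_partitions", "variable_sample_ratio", "round_half_up", "derive_seed"]
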