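"""Candidate-signature enumeration and sampling.

From Nv' selected features there are ``2^Nv' - 1`` non-empty candidate
signatures — far too many to evaluate. The default planner instead draws
three distinct signatures uniformly at random for every size in
``{2, ..., Nv' - 1}``, giving ``S = 3 * (Nv' - 2)`` candidates in total
(e.g. Nv' = 9 -> 21, Nv' = 28 -> 78, Nv' = 38 -> 108).

The top size Nv' is excluded from the range: only one subset of that size
exists, so "three distinct signatures per size" would be impossible there,
and only the range 2..Nv'-1 is arithmetically consistent with the
``3 * (Nv' - 2)`` count.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .datamodel import SignaturePlan
from .errors import ParameterError

# Below this subset-space size we enumerate exactly instead of rejection-sampling.
_ENUMERATION_LIMIT = 10_000
_SIGNATURES_PER_SIZE = 3


def count_all_signatures(n_selected: int) -> int:
    """Count of non-empty feature subsets: ``2**n_selected - 1`` (exact int)."""
    if n_selected < 1:
        raise ParameterError(f"n_selected must be >= 1, got {n_selected}")
    return 2**n_selected - 1


def planned_signature_count(n_selected: int) -> int:
    """Size of the default plan: ``3 * (n_selected - 2)``."""
    if n_selected < 3:
        raise ParameterError(f"plan undefined for n_selected={n_selected} (< 3)")
    return _SIGNATURES_PER_SIZE * (n_selected - 2)


def _sample_size_subsets(
    rng: np.random.Generator, features: list[str], size: int, count: int
) -> list[tuple[str, ...]]:
    """Draw ``count`` distinct size-``size`` subsets uniformly without replacement."""
    n = len(features)
    total = math.comb(n, size)
    if total < count:
        raise ParameterError(f"only {total} subsets of size {size} exist, need {count}")
    if total <= _ENUMERATION_LIMIT:
        combos = list(itertools.combinations(features, size))
        picked = rng.choice(total, size=count, replace=False)
        return [combos[i] for i in picked]
    # Rejection sampling with a generous cap; duplicate probability is tiny
    # when total >> count, so the cap is a safety net, not a hot path.
    out: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(1000 * count):
        combo = tuple(features[i] for i in np.sort(rng.choice(n, size=size, replace=False)))
        if combo not in seen:
            seen.add(combo)
            out.append(combo)
            if len(out) == count:
                return out
    raise ParameterError(f"could not draw {count} distinct subsets of size {size}")


def plan_signatures(selected_features: list[str], seed: int) -> SignaturePlan:
    """Build the default signature plan from the Nv' selected features.

    For each size s in {2, ..., Nv'-1} three distinct subsets are drawn
    uniformly from the C(Nv', s) possibilities; deterministic under ``seed``.
    """
    features = [str(f) for f in selected_features]
    n = len(features)
    if n < 4:
        raise ParameterError(f"planner needs Nv' >= 4 selected features, got {n}")
    if len(set(features)) != n:
        raise ParameterError("duplicate feature ids in selected_features")

    rng = np.random.default_rng(seed)
    signatures: list[tuple[str, ...]] = []
    for size in range(2, n):
        signatures.extend(_sample_size_subsets(rng, features, size, _SIGNATURES_PER_SIZE))

    assert len(signatures) == planned_signature_count(n)
    return SignaturePlan(
        n_selected_features=n,
        signatures=signatures,
        sizes=[len(s) for s in signatures],
        seed=seed,
    )
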