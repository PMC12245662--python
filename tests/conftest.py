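"""Shared fixtures: small synthetic datasets, reference backends and
lightweight mock backends that satisfy the ForestBackend contract without
fitting anything (for counting/arithmetic tests)."""

from __future__ import annotations

import numpy as np
import pytest

from hyperstab.datamodel import ExpressionDataset
from hyperstab.errors import CapabilityError
from hyperstab.forest_adapters import BackendSpec, get_backend
from hyperstab.synthetic_data import generate


@pytest.fixture(scope="session")
def separable_dataset() -> ExpressionDataset:
    """48 pairs, every feature informative with a huge class shift."""
    return generate(
        n_pairs=24, n_features=6, n_informative=6, effect_size=6.0, seed=11
    )


@pytest.fixture(scope="session")
def noisy_dataset() -> ExpressionDataset:
    """Weak signal: AUCs vary between replicate models."""
    return generate(
        n_pairs=20, n_features=6, n_informative=3, effect_size=0.6, seed=13
    )


@pytest.fixture(scope="session")
def rf_backend():
    return get_backend("random_forest", ntree=50)


@pytest.fixture(scope="session")
def et_backend():
    return get_backend("extra_trees", ntree=50)


@pytest.fixture(scope="session")
def frozen_backend():
    return get_backend("random_forest_frozen", ntree=50)


class MockScoreBackend:
    """Contract-compatible backend that emits pseudo-random validation scores
    derived from the seed — no model is fitted. Used for cell-count and
    determinism arithmetic where a real forest is irrelevant."""

    def __init__(self, backend_id: str = "mock_scores", replicate_invariant: bool = False):
        self.spec = BackendSpec(
            backend_id=backend_id,
            supports_oob=False,
            supports_impurity_importance=False,
            supports_permutation_importance=False,
            replicate_invariant=replicate_invariant,
        )
        self.calls = 0

    @property
    def backend_id(self) -> str:
        return self.spec.backend_id

    def fit_score(self, X_train, y_train, X_val, positive_label, ntree, seed,
                  compute_oob=False):
        if compute_oob:
            raise CapabilityError("mock_scores has no out-of-bag mode")
        self.calls += 1
        rng = np.random.default_rng(seed)
        return rng.uniform(size=len(X_val)), None


class MockOOBBackend:
    """Contract-compatible backend whose OOB error is a supplied function of
    the tree count; counts every oob_error call."""

    def __init__(self, error_fn, backend_id: str = "mock_oob"):
        self.spec = BackendSpec(
            backend_id=backend_id,
            supports_oob=True,
            supports_impurity_importance=False,
            supports_permutation_importance=False,
        )
        self._error_fn = error_fn
        self.calls = 0

    @property
    def backend_id(self) -> str:
        return self.spec.backend_id

    def oob_error(self, X, y, ntree, seed):
        self.calls += 1
        return float(self._error_fn(ntree))


@pytest.fixture
def mock_score_backend() -> MockScoreBackend:
    return MockScoreBackend()


def tiny_dataset(n_per_class: int = 6, n_features: int = 4, seed: int = 0) -> ExpressionDataset:
    """Unpaired minimal dataset for partition/mock arithmetic."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    return ExpressionDataset(
        values=rng.uniform(0.1, 10.0, size=(n, n_features)),
        labels=np.array(["case"] * n_per_class + ["control"] * n_per_class, dtype=object),
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=[f"f{j}" for j in range(n_features)],
        positive_label="case",
        rpkm_like=True,
    )
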