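"""Uniform backend contract for ensemble-forest classifiers.

Every backend exposes the same three capabilities behind :class:`ForestBackend`:

* ``fit_score`` — train on a training split, score the validation split
  (higher score = more case-like), optionally returning the out-of-bag error;
* ``oob_error`` — OOB error of a fit, for tree-count tuning;
* ``importances`` — impurity-decrease (MDG-analog) and permutation
  (MDA-analog) feature importances.

Two reference backends with distinct split strategies ship in the registry:
``random_forest`` (orthogonal splits on bootstrap samples, OOB-capable) and
``extra_trees`` (extremely randomized split thresholds, no bagging hence no
OOB). ``random_forest_frozen`` is the replicate-invariant variant: the
benchmark engine gives every replicate of a grid cell the same seed, so a
frozen backend reproduces identical AUCs across replicates by construction —
the reference point for a perfectly self-reproducible implementation.

Tree-count tuning (:func:`tune_ntree`) averages k×q OOB errors per grid value
and picks the smallest tree count whose mean error has entered — and stays
inside — a tolerance band around the grid minimum ("optimised and stabilised").
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score

from ._seeds import derive_seed
from .datamodel import AUCGrid, ExpressionDataset, PartitionSet  # noqa: F401 (re-export convenience)
from .errors import BackendError, CapabilityError, ParameterError
from .resampling import make_partitions

DEFAULT_NTREE = 500

# Default tuning grid: {10, 20, ..., 100} ∪ {150, 200, ..., 1200}. A coarsened
# version of the full {10, 20, ..., 1200} ladder (available via config) since
# every grid point costs k×q forest fits.
DEFAULT_NTREE_GRID = tuple(range(10, 101, 10)) + tuple(range(150, 1201, 50))


@dataclass(frozen=True)
class BackendSpec:
    """Capability and hyperparameter card for a registered backend."""

    backend_id: str
    supports_oob: bool
    supports_impurity_importance: bool
    supports_permutation_importance: bool
    hyperparameters: dict = field(default_factory=dict)
    split_strategy: str = "orthogonal"  # metadata only
    replicate_invariant: bool = False


class ForestBackend:
    """Scikit-learn-backed reference implementation of the backend contract."""

    def __init__(self, spec: BackendSpec, estimator) -> None:
        self.spec = spec
        self._estimator = estimator

    @property
    def backend_id(self) -> str:
        return self.spec.backend_id

    def _make(self, ntree: int | None, seed: int, oob: bool):
        est = clone(self._estimator)
        est.set_params(
            n_estimators=int(ntree or self.spec.hyperparameters.get("ntree", DEFAULT_NTREE)),
            random_state=int(seed),
        )
        if oob:
            est.set_params(oob_score=True)
        return est

    # -- contract ----------------------------------------------------------
    def fit_score(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray,
        positive_label: str,
        ntree: int | None,
        seed: int,
        compute_oob: bool = False,
    ) -> tuple[np.ndarray, float | None]:
        """Fit on the training split, return validation scores for the
        positive class (and the OOB error when requested)."""
        if compute_oob and not self.spec.supports_oob:
            raise CapabilityError(f"backend '{self.backend_id}' has no out-of-bag mode")
        try:
            est = self._make(ntree, seed, oob=compute_oob)
            est.fit(X_train, y_train)
            col = list(est.classes_).index(positive_label)
            scores = est.predict_proba(X_val)[:, col]
            oob = float(1.0 - est.oob_score_) if compute_oob else None
        except CapabilityError:
            raise
        except Exception as exc:  # pragma: no cover - defensive wrap
            raise BackendError(self.backend_id, str(exc)) from exc
        return scores, oob

    def oob_error(self, X: np.ndarray, y: np.ndarray, ntree: int, seed: int) -> float:
        if not self.spec.supports_oob:
            raise CapabilityError(f"backend '{self.backend_id}' has no out-of-bag mode")
        try:
            est = self._make(ntree, seed, oob=True)
            with warnings.catch_warnings():
                # tiny forests can leave a sample with no OOB prediction
                warnings.simplefilter("ignore", UserWarning)
                est.fit(X, y)
            return float(1.0 - est.oob_score_)
        except Exception as exc:
            raise BackendError(self.backend_id, str(exc)) from exc

    def importances(
        self,
        X: np.ndarray,
        y: np.ndarray,
        ntree: int | None,
        seed: int,
        n_permutation_repeats: int = 5,
    ) -> tuple[np.ndarray, np.ndarray]:
        """(impurity-decrease, permutation) importance per feature."""
        if not self.spec.supports_impurity_importance:
            raise CapabilityError(
                f"backend '{self.backend_id}' lacks impurity importance"
            )
        if not self.spec.supports_permutation_importance:
            raise CapabilityError(
                f"backend '{self.backend_id}' lacks permutation importance"
            )
        try:
            est = self._make(ntree, seed, oob=False)
            est.fit(X, y)
            impurity = np.asarray(est.feature_importances_, dtype=float)
            perm = permutation_importance(
                est, X, y, n_repeats=n_permutation_repeats, random_state=int(seed)
            )
            return impurity, np.asarray(perm.importances_mean, dtype=float)
        except CapabilityError:
            raise
        except Exception as exc:  # pragma: no cover
            raise BackendError(self.backend_id, str(exc)) from exc


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _build_random_forest(frozen: bool = False, **hyper) -> ForestBackend:
    backend_id = "random_forest_frozen" if frozen else "random_forest"
    mtry = hyper.pop("mtry", "sqrt")
    spec = BackendSpec(
        backend_id=backend_id,
        supports_oob=True,
        supports_impurity_importance=True,
        supports_permutation_importance=True,
        hyperparameters={"ntree": hyper.pop("ntree", DEFAULT_NTREE), "mtry": mtry, **hyper},
        split_strategy="orthogonal",
        replicate_invariant=frozen,
    )
    est = RandomForestClassifier(max_features=mtry, bootstrap=True)
    return ForestBackend(spec, est)


def _build_extra_trees(**hyper) -> ForestBackend:
    mtry = hyper.pop("mtry", "sqrt")
    spec = BackendSpec(
        backend_id="extra_trees",
        supports_oob=False,  # no bagging, hence no out-of-bag samples
        supports_impurity_importance=True,
        supports_permutation_importance=True,
        hyperparameters={"ntree": hyper.pop("ntree", DEFAULT_NTREE), "mtry": mtry, **hyper},
        split_strategy="extremely_randomized",
    )
    est = ExtraTreesClassifier(max_features=mtry, bootstrap=False)
    return ForestBackend(spec, est)


_REGISTRY = {
    "random_forest": lambda **h: _build_random_forest(frozen=False, **h),
    "random_forest_frozen": lambda **h: _build_random_forest(frozen=True, **h),
    "extra_trees": _build_extra_trees,
}


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(backend_id: str, **hyperparameters) -> ForestBackend:
    try:
        factory = _REGISTRY[backend_id]
    except KeyError:
        raise ParameterError(
            f"unknown backend '{backend_id}'; available: {available_backends()}"
        ) from None
    return factory(**hyperparameters)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def fit_predict_auc(
    backend: ForestBackend,
    dataset: ExpressionDataset,
    signature: Sequence[str],
    partition: np.ndarray,
    seed: int,
    ntree: int | None = None,
    compute_oob: bool = False,
) -> tuple[float, float, float | None]:
    """Train on the training side restricted to the signature's features,
    score the validation side, and return ``(auc, runtime_seconds, oob)``.

    AUC is computed with respect to the dataset's declared positive class;
    runtime is the wall time of fit + predict only.
    """
    cols = dataset.feature_index(signature)
    train = np.asarray(partition, dtype=int)
    mask = np.ones(dataset.n_samples, dtype=bool)
    mask[train] = False
    val = np.flatnonzero(mask)
    if len(train) == 0 or len(val) == 0:
        raise ParameterError("partition leaves an empty training or validation side")

    positive = dataset.positive()
    X = dataset.values[:, cols]
    y = dataset.labels.astype(str)

    t0 = time.perf_counter()
    scores, oob = backend.fit_score(
        X[train], y[train], X[val], positive, ntree, seed, compute_oob=compute_oob
    )
    runtime = time.perf_counter() - t0

    y_val = (y[val] == positive).astype(int)
    if y_val.min() == y_val.max():
        raise ParameterError("validation side contains a single class; AUC undefined")
    auc = float(roc_auc_score(y_val, scores))
    return auc, runtime, oob


# ---------------------------------------------------------------------------
# ntree tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Mean OOB error as a function of the tree count, plus the selected count."""

    grid: list[int]
    mean_oob_error: list[float]
    selected_ntree: int

    def __post_init__(self) -> None:
        if list(self.grid) != sorted(set(self.grid)):
            raise ParameterError("grid must be strictly increasing")
        if len(self.grid) != len(self.mean_oob_error):
            raise ParameterError("grid and mean_oob_error length mismatch")
        for e in self.mean_oob_error:
            if not 0.0 <= e <= 1.0:
                raise ParameterError(f"mean OOB error {e} outside [0, 1]")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ntree\tmean_oob_error\n")
            for nt, e in zip(self.grid, self.mean_oob_error):
                fh.write(f"{nt}\t{e:.10g}\n")


def select_plateau(grid: Sequence[int], means: Sequence[float], tolerance: float) -> int:
    """Smallest grid value whose mean error is within ``tolerance`` of the
    grid minimum *and stays* within tolerance at every larger grid value."""
    means = np.asarray(means, dtype=float)
    ceiling = means.min() + tolerance
    ok = means <= ceiling
    # suffix-AND: stabilised from this point onward
    stabilised = np.flip(np.logical_and.accumulate(np.flip(ok)))
    return int(np.asarray(grid)[stabilised][0])


def tune_ntree(
    backend: ForestBackend,
    dataset: ExpressionDataset,
    grid: Sequence[int],
    k: int,
    q: int,
    P: float,
    seed: int,
    plateau_tolerance: float = 0.005,
    pair_aware: bool = False,
) -> TuningCurve:
    """OOB-driven tree-count tuning.

    For every grid value, q models are fitted on the training side of each of
    k partitions at rate P (k×q OOB errors per grid point, e.g. 50 × 25 =
    1250 models) and averaged; the selected tree count is the plateau rule of
    :func:`select_plateau`.
    """
    if not backend.spec.supports_oob:
        raise CapabilityError(
            f"backend '{backend.backend_id}' has no out-of-bag mode; cannot tune ntree"
        )
    grid = [int(g) for g in grid]
    if not grid or grid != sorted(set(grid)):
        raise ParameterError("grid must be non-empty and strictly ascending")

    partitions = make_partitions(
        dataset, P, k, seed=derive_seed(seed, "tune_partitions"), pair_aware=pair_aware
    )
    X = dataset.values
    y = dataset.labels.astype(str)

    means: list[float] = []
    for ntree in grid:
        errs = np.empty((k, q))
        for n, train in enumerate(partitions.train_indices):
            for m in range(q):
                s = derive_seed(seed, backend.backend_id, "tune", ntree, n, m)
                errs[n, m] = backend.oob_error(X[train], y[train], ntree, s)
        means.append(float(errs.mean()))

    return TuningCurve(
        grid=grid,
        mean_oob_error=means,
        selected_ntree=select_plateau(grid, means, plateau_tolerance),
    )
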