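"""AUC-dispersion stability scoring — the core statistic of the package.

For each (signature, partition) combination the q replicate AUCs are reduced
to a coefficient of variation CV = sd / mean (sample sd, n-1 denominator).
A combination is *stable* at threshold t when CV <= t; at t = 0 this is
hyper-stability: all q replicate AUCs are bit-identical (AUC on a finite
validation set is a ratio of integer counts, so exact equality is
well-defined). The S×k boolean stable matrix is the "dot matrix".

Two aggregates summarise the matrix:

* HR[n] = (stable signatures in partition n) / S, and the resampling-sensitive
  score HRS = mean of the nonzero HR values (RRS when t > 0);
* HS[s] = (stable partitions for signature s) / k, and the signature-sensitive
  score HSS = mean of the nonzero HS values (RSS when t > 0).

An all-false matrix scores (0, 0): total instability is a meaningful worst
score. Dot-matrix shapes are typed as signature-dependent (blank rows),
resampling-dependent (blank columns), mixed, or unclassified (too sparse).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datamodel import AUCGrid, StabilityReport
from .errors import ParameterError


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean.

    Returns exactly 0.0 when all values are identical (no floating-point
    residue), which is what makes the t = 0 hyper-stability test literal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("coefficient of variation needs >= 2 values")
    if np.all(x == x[0]):
        return 0.0
    mean = x.mean()
    if mean <= 0:
        raise ParameterError(f"coefficient of variation undefined for mean {mean}")
    return float(x.std(ddof=1) / mean)


def _cv_matrix(grid: AUCGrid) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-cell CV over the replicate axis; flagged cells (mean AUC 0) are NaN."""
    auc = grid.auc
    identical = np.all(auc == auc[:, :, :1], axis=2)
    means = auc.mean(axis=2)
    sd = auc.std(axis=2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(identical, 0.0, sd / means)
    flagged = means <= 0
    cv = np.where(flagged, np.nan, cv)
    return cv, [(int(s), int(n)) for s, n in zip(*np.nonzero(flagged))]


def stability_matrix(grid: AUCGrid, t: float) -> StabilityReport:
    """CV matrix and binary stable matrix at threshold t (report fields hr/hs
    and aggregates filled in too — they are free once the matrix exists).

    At t = 0 a cell is stable iff its q replicate AUCs are bit-identical.
    Cells whose mean AUC is 0 are flagged (CV undefined): NaN in the CV
    matrix, unstable in the dot matrix.
    """
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"threshold t must lie in [0, 1], got {t}")
    if grid.q < 2:
        raise ParameterError("grid must hold q >= 2 replicates per combination")

    cv, _ = _cv_matrix(grid)
    with np.errstate(invalid="ignore"):
        stable = np.where(np.isnan(cv), False, cv <= t)

    hr = hr_vector(stable)
    hs = hs_vector(stable)
    hrs, hss = aggregate_scores(hr, hs)
    from .benchmark_engine import summarize_grid  # local import: no cycle at module load

    mean_auc, mean_rt = summarize_grid(grid)
    return StabilityReport(
        cv=cv,
        threshold=float(t),
        stable=stable.astype(bool),
        hr=hr,
        hs=hs,
        resampling_score=hrs,
        signature_score=hss,
        mean_auc=mean_auc,
        mean_runtime_seconds=mean_rt,
        dependency_class=classify_dependency(stable),
        backend_id=grid.backend_id,
        signature_ids=list(grid.signature_ids),
    )


def hyper_stable_matrix(grid: AUCGrid) -> np.ndarray:
    """Direct hyper-stability path: True iff all q replicate AUCs of a cell
    are bit-identical (and not the flagged all-zero case). Equals
    ``stability_matrix(grid, 0).stable`` exactly."""
    identical = np.all(grid.auc == grid.auc[:, :, :1], axis=2)
    return identical & (grid.auc.mean(axis=2) > 0)


def hr_vector(stable: np.ndarray) -> np.ndarray:
    """Per-partition stable-signature fraction: hr[n] = S0 / S for column n."""
    stable = np.asarray(stable, dtype=bool)
    if stable.ndim != 2 or stable.size == 0:
        raise ParameterError("stable matrix must be a non-empty S x k matrix")
    return stable.mean(axis=0)


def hs_vector(stable: np.ndarray) -> np.ndarray:
    """Per-signature stable-partition fraction: hs[s] = k0 / k for row s."""
    stable = np.asarray(stable, dtype=bool)
    if stable.ndim != 2 or stable.size == 0:
        raise ParameterError("stable matrix must be a non-empty S x k matrix")
    return stable.mean(axis=1)


def aggregate_scores(hr: np.ndarray, hs: np.ndarray) -> tuple[float, float]:
    """(resampling_score, signature_score): mean of the strictly positive
    entries of each vector, 0.0 when a vector has none."""
    hr = np.asarray(hr, dtype=float)
    hs = np.asarray(hs, dtype=float)
    hrs = float(hr[hr > 0].mean()) if (hr > 0).any() else 0.0
    hss = float(hs[hs > 0].mean()) if (hs > 0).any() else 0.0
    return hrs, hss


def classify_dependency(
    stable: np.ndarray,
    row_gap_frac: float = 0.2,
    col_gap_frac: float = 0.2,
    min_density: float = 0.05,
) -> str:
    """Type the dot matrix by its blank-row/blank-column structure.

    * density < ``min_density``      -> ``unclassified`` (too few stable cells)
    * blank-row fraction dominates   -> ``signature_dependent`` (Type A)
    * blank-column fraction dominates-> ``resampling_dependent`` (Type B)
    * otherwise                      -> ``mixed`` (Type C)
    """
    for name, v in (("row_gap_frac", row_gap_frac), ("col_gap_frac", col_gap_frac),
                    ("min_density", min_density)):
        if not 0.0 < v < 1.0:
            raise ParameterError(f"{name} must lie in (0, 1), got {v}")
    stable = np.asarray(stable, dtype=bool)
    density = stable.mean()
    if density < min_density:
        return "unclassified"
    blank_rows = (~stable).all(axis=1).mean()
    blank_cols = (~stable).all(axis=0).mean()
    if blank_rows >= row_gap_frac and blank_cols < col_gap_frac:
        return "signature_dependent"
    if blank_cols >= col_gap_frac and blank_rows < row_gap_frac:
        return "resampling_dependent"
    return "mixed"
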