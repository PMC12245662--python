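"""Execution of the full signature × partition × replicate model grid.

One classifier is fitted per grid cell; the resulting S·k·q validation AUCs
and runtimes form the :class:`~hyperstab.datamodel.AUCGrid` consumed by the
scoring stage. Replicates on the same (signature, partition) cell differ only
by the backend's internal randomisation: the m-th replicate uses a seed
derived from (base_seed, backend_id, signature_id, partition, m), while a
replicate-invariant ("frozen") backend drops m so all its replicates are
identical by construction.

Cell evaluations are mutually independent; ``n_jobs > 1`` maps them over a
thread pool as a pure throughput concern — parallel and serial runs produce
identical tensors under a fixed seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from ._seeds import derive_seed
from .datamodel import AUCGrid, ExpressionDataset, PartitionSet, SignaturePlan
from .errors import GridExecutionError, ParameterError
from .forest_adapters import ForestBackend, fit_predict_auc


def run_grid(
    backend: ForestBackend,
    dataset: ExpressionDataset,
    plan: SignaturePlan,
    partitions: PartitionSet,
    q: int,
    ntree: int,
    seed: int,
    n_jobs: int = 1,
    cell_order: Sequence[tuple[int, int, int]] | None = None,
) -> AUCGrid:
    """Fit one model per (signature, partition, replicate) cell.

    The tensor is complete or the call fails: any cell failure aborts with a
    :class:`GridExecutionError` naming the cell; partial grids are never
    returned.

    ``cell_order`` overrides the evaluation order (testing hook for the
    cell-independence property); the tensor layout is unaffected.
    """
    if q < 2:
        raise ParameterError("q must be >= 2 (the coefficient of variation needs >= 2 values)")
    if partitions.n_samples != dataset.n_samples:
        raise ParameterError("partitions were built for a different sample count")

    S, k = len(plan), partitions.k
    cells = list(cell_order) if cell_order is not None else [
        (s, n, m) for s in range(S) for n in range(k) for m in range(q)
    ]
    if sorted(cells) != [(s, n, m) for s in range(S) for n in range(k) for m in range(q)]:
        raise ParameterError("cell_order must be a permutation of the full grid")

    frozen = backend.spec.replicate_invariant

    def _cell(s: int, n: int, m: int) -> tuple[int, int, int, float, float]:
        sig_id = plan.signature_ids[s]
        cell_seed = derive_seed(
            seed, backend.backend_id, sig_id, n, 0 if frozen else m
        )
        try:
            auc, runtime, _ = fit_predict_auc(
                backend,
                dataset,
                plan.signatures[s],
                partitions.train_indices[n],
                seed=cell_seed,
                ntree=ntree,
            )
        except Exception as exc:
            raise GridExecutionError(
                f"grid cell failed: signature '{sig_id}', partition {n}, "
                f"replicate {m}: {exc}"
            ) from exc
        return s, n, m, auc, runtime

    if n_jobs == 1:
        results = [_cell(s, n, m) for s, n, m in cells]
    else:
        results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_cell)(s, n, m) for s, n, m in cells
        )

    auc = np.full((S, k, q), np.nan)
    runtime = np.full((S, k, q), np.nan)
    for s, n, m, a, r in results:
        auc[s, n, m] = a
        runtime[s, n, m] = r

    return AUCGrid(
        auc=auc,
        runtime_seconds=runtime,
        q=q,
        backend_id=backend.backend_id,
        ntree=int(ntree),
        signature_ids=list(plan.signature_ids),
    )


def summarize_grid(grid: AUCGrid) -> tuple[float, float]:
    """Arithmetic mean AUC and mean per-model runtime over all S·k·q cells."""
    return float(grid.auc.mean()), float(grid.runtime_seconds.mean())


# ---------------------------------------------------------------------------
# Flat-TSV persistence (re-score without re-fitting)
# ---------------------------------------------------------------------------

_GRID_COLUMNS = ["backend_id", "signature_id", "partition", "replicate", "auc", "runtime_seconds"]


def write_grid_tsv(grid: AUCGrid, path: str | Path) -> None:
    rows = []
    for s, sig_id in enumerate(grid.signature_ids):
        for n in range(grid.n_partitions):
            for m in range(grid.q):
                rows.append(
                    (grid.backend_id, sig_id, n, m, grid.auc[s, n, m], grid.runtime_seconds[s, n, m])
                )
    df = pd.DataFrame(rows, columns=_GRID_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# ntree={grid.ntree}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_grid_tsv(path: str | Path) -> AUCGrid:
    """Load a persisted grid; raises ParameterError naming the first bad line
    on a malformed or incomplete file."""
    path = Path(path)
    ntree = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "ntree=" in first:
                ntree = int(first.split("ntree=")[1].strip())
            header_offset = 1
        else:
            header_offset = 0
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParameterError(f"cannot parse grid file {path}: {exc}") from exc
    missing = [c for c in _GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(
            f"grid file {path} line {header_offset + 1}: missing column(s) {missing}"
        )
    backends = df["backend_id"].unique()
    if len(backends) != 1:
        raise ParameterError(f"grid file {path} mixes backends: {list(backends)}")

    sig_ids = list(dict.fromkeys(df["signature_id"].astype(str)))
    k = int(df["partition"].max()) + 1
    q = int(df["replicate"].max()) + 1
    S = len(sig_ids)
    if len(df) != S * k * q:
        raise ParameterError(
            f"grid file {path}: {len(df)} rows but S*k*q = {S}*{k}*{q} = {S * k * q}; "
            "grid is incomplete or has duplicate cells"
        )
    auc = np.full((S, k, q), np.nan)
    runtime = np.full((S, k, q), np.nan)
    sig_index = {sid: i for i, sid in enumerate(sig_ids)}
    for row_no, row in enumerate(df.itertuples(index=False), start=header_offset + 2):
        s = sig_index[str(row.signature_id)]
        n, m = int(row.partition), int(row.replicate)
        if not np.isnan(auc[s, n, m]):
            raise ParameterError(f"grid file {path} line {row_no}: duplicate cell")
        auc[s, n, m] = float(row.auc)
        runtime[s, n, m] = float(row.runtime_seconds)
    if np.isnan(auc).any():
        raise ParameterError(f"grid file {path}: holes in the tensor")
    return AUCGrid(
        auc=auc,
        runtime_seconds=runtime,
        q=q,
        backend_id=str(backends[0]),
        ntree=ntree,
        signature_ids=sig_ids,
    )
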