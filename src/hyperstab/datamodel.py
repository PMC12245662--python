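"""Core typed containers for the stability benchmark.

The benchmark substrate is an :class:`ExpressionDataset` (samples × features,
binary labels, optional case/control pairing). Candidate feature subsets live
in a :class:`SignaturePlan`, balanced train/validation splits in a
:class:`PartitionSet`, the fitted-model results in an :class:`AUCGrid`
(signatures × partitions × replicates), and the scoring output in a
:class:`StabilityReport`.

All containers validate eagerly where an invariant is cheap; the full dataset
audit is :func:`validate_dataset`, which reports violations instead of
throwing so a caller can surface every problem at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

# Header cells that mark a genes-in-rows matrix file (features in the first
# column, samples across the header).
_FEATURE_HEADER_TOKENS = {"feature_id", "gene_id", "gene", "probe_id", "mirna_id"}

DEPENDENCY_CLASSES = (
    "signature_dependent",   # Type A: blank rows dominate the dot matrix
    "resampling_dependent",  # Type B: blank columns dominate
    "mixed",                 # Type C: no row/column trend
    "unclassified",          # too few stable combinations to type
)


# ---------------------------------------------------------------------------
# ExpressionDataset
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Samples × features expression matrix with binary class labels.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float matrix. Non-negative when
        ``rpkm_like`` is set (RPKM-normalised abundances are positive).
    labels
        One class label string per sample; exactly two levels expected.
    sample_ids, feature_ids
        Unique identifier strings.
    pair_ids
        Optional per-sample pair identifier linking a case to its matched
        control (paired tumour–healthy design). Each pair id must occur exactly
        twice, once per class.
    positive_label
        The class treated as "positive" when computing ROC AUC. When ``None``
        the lexicographically larger class label is used (and recorded by
        :meth:`positive`).
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    pair_ids: list[str] | None = None
    positive_label: str | None = None
    rpkm_like: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.pair_ids is not None:
            self.pair_ids = [str(p) for p in self.pair_ids]

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list[str]:
        return sorted({str(l) for l in self.labels})

    def positive(self) -> str:
        if self.positive_label is not None:
            return self.positive_label
        return self.classes()[-1]

    def feature_index(self, feature_ids: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in lookup]
        if missing:
            raise ParameterError(f"unknown feature id(s): {missing[:5]}")
        return np.array([lookup[f] for f in feature_ids], dtype=int)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        idx = self.feature_index(feature_ids)
        return ExpressionDataset(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in idx],
            pair_ids=list(self.pair_ids) if self.pair_ids is not None else None,
            positive_label=self.positive_label,
            rpkm_like=self.rpkm_like,
        )

    def class_indices(self) -> dict[str, np.ndarray]:
        return {c: np.flatnonzero(self.labels == c) for c in self.classes()}


def validate_dataset(dataset: ExpressionDataset) -> list[str]:
    """Audit every dataset invariant; return human-readable violations.

    Returns an empty list iff the dataset is valid. Never raises: the point is
    to report *all* defects (with offending identifiers) in one pass.
    """
    v: list[str] = []
    values = dataset.values
    n_s, n_f = values.shape if values.ndim == 2 else (len(dataset.sample_ids), -1)

    if values.ndim != 2:
        v.append(f"values must be a 2-D matrix, got ndim={values.ndim}")
        return v
    if len(dataset.sample_ids) != n_s:
        v.append(f"{len(dataset.sample_ids)} sample ids for {n_s} rows")
    if len(dataset.feature_ids) != n_f:
        v.append(f"{len(dataset.feature_ids)} feature ids for {n_f} columns")
    if len(dataset.labels) != n_s:
        v.append(f"{len(dataset.labels)} labels for {n_s} samples")

    bad = ~np.isfinite(values)
    if bad.any():
        for i, j in zip(*np.nonzero(bad)):
            v.append(
                "non-finite value at sample "
                f"'{dataset.sample_ids[i]}', feature '{dataset.feature_ids[j]}'"
            )
            if len(v) > 20:  # cap the flood on a corrupt matrix
                v.append("... further non-finite cells suppressed")
                break
    elif dataset.rpkm_like and (values < 0).any():
        i, j = next(zip(*np.nonzero(values < 0)))
        v.append(
            f"negative value in rpkm_like matrix at sample "
            f"'{dataset.sample_ids[i]}', feature '{dataset.feature_ids[j]}'"
        )

    levels = dataset.classes()
    if len(levels) != 2:
        v.append(f"labels must take exactly two levels, found {levels}")
    if dataset.positive_label is not None and dataset.positive_label not in levels:
        v.append(f"declared positive label '{dataset.positive_label}' not among {levels}")

    for kind, ids in (("sample", dataset.sample_ids), ("feature", dataset.feature_ids)):
        seen: set[str] = set()
        dupes = {i for i in ids if i in seen or seen.add(i)}  # type: ignore[func-returns-value]
        if dupes:
            v.append(f"duplicate {kind} id(s): {sorted(dupes)[:5]}")

    if dataset.pair_ids is not None:
        if len(dataset.pair_ids) != n_s:
            v.append(f"{len(dataset.pair_ids)} pair ids for {n_s} samples")
        else:
            by_pair: dict[str, list[str]] = {}
            for pid, lab in zip(dataset.pair_ids, dataset.labels):
                by_pair.setdefault(pid, []).append(str(lab))
            for pid, labs in sorted(by_pair.items()):
                if len(labs) != 2:
                    v.append(f"pair id '{pid}' occurs {len(labs)} time(s), expected 2")
                elif len(set(labs)) != 2:
                    v.append(f"pair id '{pid}' has both members in class '{labs[0]}'")
    return v


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

def _infer_sep(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def write_expression_matrix(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    """Write the matrix (header = feature ids, first column = sample ids) and,
    optionally, the companion labels file (sample_id, label[, pair_id])."""
    matrix_path = Path(matrix_path)
    df = pd.DataFrame(dataset.values, index=dataset.sample_ids, columns=dataset.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep=sep, float_format="%.10g")
    if labels_path is not None:
        cols = {"sample_id": dataset.sample_ids, "label": [str(l) for l in dataset.labels]}
        if dataset.pair_ids is not None:
            cols["pair_id"] = dataset.pair_ids
        pd.DataFrame(cols).to_csv(labels_path, sep=sep, index=False)


def read_labels(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParameterError(f"labels file {path} needs >=2 columns (sample_id, label)")
    df = df.rename(
        columns={df.columns[0]: "sample_id", df.columns[1]: "label"}
        | ({df.columns[2]: "pair_id"} if df.shape[1] >= 3 else {})
    )
    return df


def read_expression_matrix(
    matrix_path: str | Path,
    labels_path: str | Path,
    sep: str | None = None,
    genes_in_rows: bool | str = "auto",
    positive_label: str | None = None,
    rpkm_like: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus its labels file.

    ``genes_in_rows="auto"`` transposes the matrix when the top-left header
    cell follows a feature-id convention (``gene_id``, ``feature_id``, ...);
    expression files ship in both orientations.
    """
    matrix_path = Path(matrix_path)
    sep_m = sep or _infer_sep(matrix_path)
    df = pd.read_csv(matrix_path, sep=sep_m, index_col=0)
    if genes_in_rows == "auto":
        genes_in_rows = str(df.index.name or "").strip().lower() in _FEATURE_HEADER_TOKENS
    if genes_in_rows:
        df = df.T

    lab = read_labels(labels_path, sep=sep)
    lab = lab.set_index("sample_id")
    missing = [s for s in df.index if s not in lab.index]
    if missing:
        raise ParameterError(f"samples without labels: {missing[:5]}")
    labels = lab.loc[df.index, "label"].to_numpy(dtype=object)
    pair_ids = None
    if "pair_id" in lab.columns and lab["pair_id"].notna().all():
        pair_ids = lab.loc[df.index, "pair_id"].astype(str).tolist()

    return ExpressionDataset(
        values=df.to_numpy(dtype=float),
        labels=labels,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        pair_ids=pair_ids,
        positive_label=positive_label,
        rpkm_like=rpkm_like,
    )


# ---------------------------------------------------------------------------
# SignaturePlan
# ---------------------------------------------------------------------------

@dataclass
class SignaturePlan:
    """The S candidate feature subsets drawn from the Nv' selected features."""

    n_selected_features: int
    signatures: list[tuple[str, ...]]
    sizes: list[int]
    seed: int
    signature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.signature_ids:
            self.signature_ids = [
                f"s{i:03d}_n{len(sig)}" for i, sig in enumerate(self.signatures)
            ]
        if self.sizes != [len(s) for s in self.signatures]:
            raise ParameterError("sizes field disagrees with signature lengths")

    def __len__(self) -> int:
        return len(self.signatures)

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "n_selected_features": self.n_selected_features,
            "seed": self.seed,
            "signatures": {
                sid: list(sig) for sid, sig in zip(self.signature_ids, self.signatures)
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=1) + "\n")
        return obj

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SignaturePlan":
        obj = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        sigs = [tuple(v) for v in obj["signatures"].values()]
        return cls(
            n_selected_features=int(obj["n_selected_features"]),
            signatures=sigs,
            sizes=[len(s) for s in sigs],
            seed=int(obj["seed"]),
            signature_ids=list(obj["signatures"].keys()),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("signature_id\tfeatures\n")
            for sid, sig in zip(self.signature_ids, self.signatures):
                fh.write(f"{sid}\t{','.join(sig)}\n")


# ---------------------------------------------------------------------------
# PartitionSet
# ---------------------------------------------------------------------------

@dataclass
class PartitionSet:
    """k balanced train/validation splits at resampling rate P.

    ``train_indices[n]`` holds the (sorted) training sample indices of
    partition n; the validation side is always the complement.
    """

    rate: float
    k: int
    train_indices: list[np.ndarray]
    seed: int
    n_samples: int

    def __post_init__(self) -> None:
        if not (0.0 < self.rate < 1.0):
            raise ParameterError(f"rate must lie in (0, 1), got {self.rate}")
        if self.k != len(self.train_indices):
            raise ParameterError("k disagrees with the number of partitions")
        self.train_indices = [np.asarray(t, dtype=int) for t in self.train_indices]
        for n, tr in enumerate(self.train_indices):
            if len(np.unique(tr)) != len(tr):
                raise ParameterError(f"partition {n}: repeated training index")
            if len(tr) == 0 or len(tr) == self.n_samples:
                raise ParameterError(f"partition {n}: empty training or validation side")

    def validation_indices(self, n: int) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        mask[self.train_indices[n]] = False
        return np.flatnonzero(mask)

    def to_json(self, sample_ids: Sequence[str], path: str | Path | None = None) -> dict:
        obj = {
            "rate": self.rate,
            "k": self.k,
            "seed": self.seed,
            "train_sample_ids": {
                str(n): [sample_ids[i] for i in tr]
                for n, tr in enumerate(self.train_indices)
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=1) + "\n")
        return obj


# ---------------------------------------------------------------------------
# AUCGrid
# ---------------------------------------------------------------------------

@dataclass
class AUCGrid:
    """The S × k × q tensor of validation AUCs plus per-model runtimes."""

    auc: np.ndarray
    runtime_seconds: np.ndarray
    q: int
    backend_id: str
    ntree: int
    signature_ids: list[str]

    def __post_init__(self) -> None:
        self.auc = np.asarray(self.auc, dtype=float)
        self.runtime_seconds = np.asarray(self.runtime_seconds, dtype=float)
        if self.auc.ndim != 3:
            raise ParameterError(f"auc tensor must be 3-D (S, k, q), got ndim={self.auc.ndim}")
        S, k, q = self.auc.shape
        if q != self.q:
            raise ParameterError(f"tensor replicate axis {q} != declared q={self.q}")
        if S != len(self.signature_ids):
            raise ParameterError(
                f"tensor signature axis {S} != {len(self.signature_ids)} signature ids"
            )
        if self.runtime_seconds.shape != self.auc.shape:
            raise ParameterError("runtime tensor shape disagrees with auc tensor")
        if np.isnan(self.auc).any() or (self.auc < 0).any() or (self.auc > 1).any():
            raise ParameterError("AUC values must lie in [0, 1] with no holes")
        if (self.runtime_seconds < 0).any():
            raise ParameterError("runtimes must be non-negative")

    @property
    def n_signatures(self) -> int:
        return self.auc.shape[0]

    @property
    def n_partitions(self) -> int:
        return self.auc.shape[1]

    @property
    def n_models(self) -> int:
        """Total fitted-model count S·k·q."""
        return int(np.prod(self.auc.shape))


# ---------------------------------------------------------------------------
# StabilityReport
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Scored output for one backend: CV matrix, stable dot matrix, HR/HS
    vectors and the aggregate resampling/signature scores.

    At threshold 0 the aggregates are the hyper-stability scores (HRS/HSS);
    for t > 0 the same numbers are the relative-stability scores (RRS/RSS).
    """

    cv: np.ndarray                 # S × k, NaN where a combination was flagged
    threshold: float
    stable: np.ndarray             # S × k booleans, cv <= threshold
    hr: np.ndarray                 # length k
    hs: np.ndarray                 # length S
    resampling_score: float        # HRS (t == 0) / RRS (t > 0)
    signature_score: float         # HSS / RSS
    mean_auc: float
    mean_runtime_seconds: float
    dependency_class: str
    backend_id: str = ""
    signature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dependency_class not in DEPENDENCY_CLASSES:
            raise ParameterError(f"unknown dependency class '{self.dependency_class}'")

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "backend_id": self.backend_id,
            "threshold": self.threshold,
            "resampling_score": self.resampling_score,
            "signature_score": self.signature_score,
            "mean_auc": self.mean_auc,
            "mean_runtime_seconds": self.mean_runtime_seconds,
            "dependency_class": self.dependency_class,
            "hr": [float(x) for x in self.hr],
            "hs": [float(x) for x in self.hs],
            "cv": [[None if np.isnan(x) else float(x) for x in row] for row in self.cv],
            "stable": [[bool(x) for x in row] for row in self.stable],
            "signature_ids": self.signature_ids,
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=1) + "\n")
        return obj

    def _matrix_frame(self, mat: np.ndarray) -> pd.DataFrame:
        rows = self.signature_ids or [f"s{i:03d}" for i in range(mat.shape[0])]
        cols = [f"partition_{n}" for n in range(mat.shape[1])]
        return pd.DataFrame(mat, index=rows, columns=cols)

    def cv_to_tsv(self, path: str | Path) -> None:
        df = self._matrix_frame(self.cv)
        df.index.name = "signature_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    def stable_to_tsv(self, path: str | Path) -> None:
        """The dot-matrix artifact: 1 = stable combination, 0 = unstable."""
        df = self._matrix_frame(self.stable.astype(int))
        df.index.name = "signature_id"
        df.to_csv(path, sep="\t")
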