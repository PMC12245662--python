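"""Benchmark orchestration and report assembly.

Ties the stages together: dataset loading (file or synthetic preset),
feature selection (or a provided feature list), signature planning, balanced
resampling, per-backend grid execution and stability scoring. Outputs are a
per-backend stability report (JSON), the cv/dot-matrix TSVs, the persisted
AUC grids, and a cross-backend ranking TSV sorted by combined stability
score (runtime ascending as tie-break — runtime is reported, never scored).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from ._seeds import derive_seed
from .benchmark_engine import run_grid, summarize_grid, write_grid_tsv
from .datamodel import (
    ExpressionDataset,
    StabilityReport,
    read_expression_matrix,
    validate_dataset,
)
from .errors import ParameterError
from .feature_selection import read_feature_list, select_stable_size
from .forest_adapters import DEFAULT_NTREE, available_backends, get_backend
from .resampling import make_partitions, variable_sample_ratio
from .signature_planning import plan_signatures
from .stability_scores import stability_matrix
from .synthetic_data import generate_paper_scale_profiles


@dataclass
class BenchmarkConfig:
    """Complete description of one benchmark run.

    ``features`` may be "all" (use every dataset feature — appropriate for
    post-selection matrices and the synthetic presets), a list of feature
    ids, a path to a one-column feature file, or None to run the built-in
    feature-selection stage first.
    """

    backends: list[str]
    preset: str | None = None
    matrix: str | None = None
    labels: str | None = None
    positive_label: str | None = None
    genes_in_rows: bool | str = "auto"
    features: Any = "all"
    k: int = 50
    q: int = 25
    P: float = 0.5
    t: float = 0.0
    ntree: int = DEFAULT_NTREE
    seed: int = 0
    pair_aware: bool = False
    n_jobs: int = 1
    out_dir: str = "hyperstab_out"
    fs_candidate_sizes: list[int] | None = None
    fs_n_resamples: int = 5
    fs_backend: str = "random_forest"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "BenchmarkConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def validate_config(cfg: BenchmarkConfig) -> list[str]:
    """Every config defect, reported before any compute starts."""
    errs: list[str] = []
    if not cfg.backends:
        errs.append("at least one backend must be configured")
    for b in cfg.backends:
        if b not in available_backends():
            errs.append(f"unknown backend '{b}'; available: {available_backends()}")
    if cfg.preset is None and (cfg.matrix is None or cfg.labels is None):
        errs.append("config must name either a synthetic preset or matrix+labels files")
    if cfg.preset is not None and cfg.preset not in generate_paper_scale_profiles():
        errs.append(
            f"unknown preset '{cfg.preset}'; "
            f"available: {sorted(generate_paper_scale_profiles())}"
        )
    if cfg.q < 2:
        errs.append("q must be >= 2 (the coefficient of variation needs >= 2 values)")
    if cfg.k < 1:
        errs.append("k must be >= 1")
    if not 0.0 < cfg.P < 1.0:
        errs.append(f"P must lie in (0, 1), got {cfg.P}")
    if not 0.0 <= cfg.t <= 1.0:
        errs.append(f"t must lie in [0, 1], got {cfg.t}")
    if cfg.ntree < 1:
        errs.append("ntree must be >= 1")
    return errs


def _load_dataset(cfg: BenchmarkConfig) -> ExpressionDataset:
    if cfg.preset is not None:
        profile = generate_paper_scale_profiles()[cfg.preset]
        return profile.generate(seed=derive_seed(cfg.seed, "dataset", cfg.preset))
    return read_expression_matrix(
        cfg.matrix,
        cfg.labels,
        genes_in_rows=cfg.genes_in_rows,
        positive_label=cfg.positive_label,
        rpkm_like=False,
    )


def _resolve_features(cfg: BenchmarkConfig, dataset: ExpressionDataset) -> list[str]:
    if cfg.features == "all":
        return list(dataset.feature_ids)
    if isinstance(cfg.features, (list, tuple)):
        return [str(f) for f in cfg.features]
    if isinstance(cfg.features, str):
        return read_feature_list(cfg.features)
    # None: run the feature-selection stage
    sizes = cfg.fs_candidate_sizes or list(range(4, min(11, dataset.n_features)))
    selection = select_stable_size(
        dataset,
        get_backend(cfg.fs_backend),
        candidate_sizes=sizes,
        n_resamples=cfg.fs_n_resamples,
        P=cfg.P,
        seed=derive_seed(cfg.seed, "fs"),
        ntree=min(cfg.ntree, 200),
    )
    return selection.selected_features


_RANKING_COLUMNS = (
    "backend_id",
    "resampling_score",
    "signature_score",
    "mean_auc",
    "mean_runtime_seconds",
    "dependency_class",
)


def write_ranking_tsv(reports: list[StabilityReport], cfg: BenchmarkConfig, path: Path) -> None:
    ordered = sorted(
        reports,
        key=lambda r: (
            -(r.resampling_score + r.signature_score),
            r.mean_runtime_seconds,
            r.backend_id,
        ),
    )
    with open(path, "w") as fh:
        fh.write(
            f"# seed={cfg.seed} k={cfg.k} q={cfg.q} P={cfg.P} t={cfg.t} ntree={cfg.ntree}\n"
        )
        fh.write("\t".join(_RANKING_COLUMNS) + "\n")
        for r in ordered:
            fh.write(
                f"{r.backend_id}\t{r.resampling_score:.6f}\t{r.signature_score:.6f}\t"
                f"{r.mean_auc:.6f}\t{r.mean_runtime_seconds:.6g}\t{r.dependency_class}\n"
            )


def run_benchmark(cfg: BenchmarkConfig) -> dict[str, StabilityReport]:
    """Execute the full workflow; returns the per-backend reports and writes
    all artifacts under ``cfg.out_dir``."""
    errs = validate_config(cfg)
    if errs:
        raise ParameterError("invalid benchmark config:\n- " + "\n- ".join(errs))

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = _load_dataset(cfg)
    violations = validate_dataset(dataset)
    if violations:
        raise ParameterError("invalid dataset:\n- " + "\n- ".join(violations))

    features = _resolve_features(cfg, dataset)
    plan = plan_signatures(features, seed=derive_seed(cfg.seed, "plan"))
    plan.to_json(out / "signature_plan.json")
    partitions = make_partitions(
        dataset, cfg.P, cfg.k, seed=derive_seed(cfg.seed, "partitions"),
        pair_aware=cfg.pair_aware,
    )
    partitions.to_json(dataset.sample_ids, out / "partitions.json")

    n_train = len(partitions.train_indices[0])
    reports: dict[str, StabilityReport] = {}
    for backend_id in cfg.backends:
        backend = get_backend(backend_id)
        grid = run_grid(
            backend, dataset, plan, partitions,
            q=cfg.q, ntree=cfg.ntree, seed=cfg.seed, n_jobs=cfg.n_jobs,
        )
        write_grid_tsv(grid, out / f"grid_{backend_id}.tsv")
        report = stability_matrix(grid, cfg.t)
        report.cv_to_tsv(out / f"cv_{backend_id}.tsv")
        report.stable_to_tsv(out / f"dotmatrix_{backend_id}.tsv")
        obj = report.to_json()
        obj["diagnostics"] = {
            "n_training_samples": n_train,
            "variable_sample_ratio_max_signature": variable_sample_ratio(
                max(plan.sizes), n_train
            ),
            "variable_sample_ratio_selected": variable_sample_ratio(
                plan.n_selected_features, n_train
            ),
        }
        import json as _json

        (out / f"report_{backend_id}.json").write_text(_json.dumps(obj, indent=1) + "\n")
        reports[backend_id] = report

    write_ranking_tsv(list(reports.values()), cfg, out / "ranking.tsv")
    return reports
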