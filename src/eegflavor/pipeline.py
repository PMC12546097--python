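"""End-to-end orchestration: simulate → extract → build → optimize → report.

Every stage reads and writes files under the run's output directory, so
the equivalent CLI subcommands compose to exactly the same results
bundle as :func:`run_pipeline`.  All randomness derives from the master
seed; rerunning an identical configuration reproduces the results JSON
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import (
    DATASET_TAGS,
    FeatureTable,
    assemble_dataset,
    demographics_frame,
    extract_panel_features,
    ratings_frame,
    standardize,
)
from .evaluation import (
    ModelResult,
    SearchSpace,
    aggregate_importance,
    bayes_optimize,
    cohens_d,
    cv_mae,
    summarize_models,
)
from .io import _config_to_dict, read_panel, write_panel
from .models import LSBoostHyperParams, feature_importance, fit_lsboost
from .synthetic import ATTRIBUTES, PanelConfig, simulate_panel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """A complete, reproducible pipeline run."""

    panel: PanelConfig = field(default_factory=PanelConfig)
    master_seed: int = 1
    max_evaluations: int = 100
    output_dir: str = "eegflavor_run"
    datasets: tuple[str, ...] = DATASET_TAGS
    targets: tuple[str, ...] = ATTRIBUTES
    #: overrides for SearchSpace bounds, e.g. {"leaf_size": (1, 5)}
    space_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.master_seed is None:
            raise ValueError("master_seed is mandatory")
        for d in self.datasets:
            if d not in DATASET_TAGS:
                raise ValueError(f"unknown dataset tag {d!r}")
        for t in self.targets:
            if t not in ATTRIBUTES:
                raise ValueError(f"unknown target {t!r}")


def combo_seed(master_seed: int, dataset: str, target: str) -> int:
    """Deterministic per-(dataset, target) seed below 2³¹."""
    d_idx = DATASET_TAGS.index(dataset)
    t_idx = ATTRIBUTES.index(target)
    ss = np.random.SeedSequence([master_seed, d_idx, t_idx])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# stages (file-in, file-out; the CLI maps one subcommand to each)


def stage_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Generate the virtual panel and persist it."""
    t0 = time.monotonic()
    panel_dir = Path(outdir) / "panel"
    subjects, sessions = simulate_panel(config.panel)
    write_panel(subjects, sessions, config.panel, panel_dir)
    logger.info(
        "simulate: %d subjects, %d sessions in %.1fs",
        len(subjects), len(sessions), time.monotonic() - t0,
    )
    return panel_dir


def stage_extract(panel_dir: str | Path, outdir: str | Path) -> Path:
    """Per-epoch feature records from a persisted panel."""
    t0 = time.monotonic()
    feats_dir = Path(outdir) / "features"
    feats_dir.mkdir(parents=True, exist_ok=True)
    subjects, sessions, _config = read_panel(panel_dir)
    records = extract_panel_features(subjects, sessions)
    records.to_csv(feats_dir / "epoch_features.csv", index=False)
    demographics_frame(subjects).to_csv(feats_dir / "demographics.csv", index=False)
    ratings_frame(sessions).to_csv(feats_dir / "ratings.csv", index=False)
    logger.info("extract: %d epoch records in %.1fs", len(records), time.monotonic() - t0)
    return feats_dir


def stage_build(feats_dir: str | Path, outdir: str | Path,
                datasets: tuple[str, ...] = DATASET_TAGS) -> Path:
    """Assemble the Be/Co/BeCo feature tables."""
    t0 = time.monotonic()
    feats_dir = Path(feats_dir)
    ds_dir = Path(outdir) / "datasets"
    ds_dir.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(feats_dir / "epoch_features.csv", float_precision="round_trip")
    demographics = pd.read_csv(feats_dir / "demographics.csv")
    ratings = pd.read_csv(feats_dir / "ratings.csv", float_precision="round_trip")
    for tag in datasets:
        table = assemble_dataset(records, demographics, ratings, tag)
        table.to_csv(ds_dir / f"{tag}.csv")
        logger.info("build: %s table %d×%d", tag, table.n_rows, table.X.shape[1])
    logger.info("build: done in %.1fs", time.monotonic() - t0)
    return ds_dir


def stage_optimize(ds_dir: str | Path, outdir: str | Path, config: RunConfig) -> Path:
    """Run the CASH search for every (dataset, target) combination."""
    opt_dir = Path(outdir) / "optimize"
    opt_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    for dataset in config.datasets:
        table = FeatureTable.from_csv(Path(ds_dir) / f"{dataset}.csv")
        for target in config.targets:
            t0 = time.monotonic()
            seed = combo_seed(config.master_seed, dataset, target)
            space = SearchSpace(
                max_evaluations=config.max_evaluations, seed=seed,
                **config.space_overrides,
            )
            best, log = bayes_optimize(table, target, space)
            results[f"{dataset}/{target}"] = {
                "dataset": dataset,
                "target": target,
                "seed": seed,
                "best_params": best,
                "best_objective": log.best_value,
                "n_trials": log.n_trials,
                "trial_values": [t.value for t in log.trials],
            }
            logger.info(
                "optimize: %s/%s best MAE %.4f (%.1fs)",
                dataset, target, log.best_value, time.monotonic() - t0,
            )
    payload = json.dumps(_jsonable(results), indent=2, sort_keys=True)
    (opt_dir / "best_configurations.json").write_text(payload)
    return opt_dir


def stage_report(ds_dir: str | Path, opt_dir: str | Path, outdir: str | Path,
                 config: RunConfig) -> Path:
    """Benchmarks, effect sizes, significance filter, importance, bundle."""
    report_dir = Path(outdir) / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    best_configs = json.loads(
        (Path(opt_dir) / "best_configurations.json").read_text()
    )
    tables = {
        dataset: FeatureTable.from_csv(Path(ds_dir) / f"{dataset}.csv")
        for dataset in config.datasets
    }
    model_results: list[ModelResult] = []
    combo_details = {}
    importance_inputs = []
    for key, entry in sorted(best_configs.items()):
        dataset, target = entry["dataset"], entry["target"]
        table = tables[dataset]
        seed = entry["seed"]
        bp = entry["best_params"]
        hp = LSBoostHyperParams(
            n=bp["n"], rho=bp["rho"], leaf_size=bp["leaf_size"],
            max_splits=bp["max_splits"],
        )
        std = bp["standardizer"]
        cv_ls = cv_mae("lsboost", table, target, standardizer=std, seed=seed, hp=hp)
        cv_me = cv_mae("mean", table, target, standardizer=std, seed=seed)
        cv_lr = cv_mae("lasso", table, target, standardizer=std, seed=seed)
        d_me = cohens_d(cv_me, cv_ls)
        d_lr = cohens_d(cv_lr, cv_ls)
        result = ModelResult(
            dataset=dataset, target=target,
            lsboost=cv_ls, me=cv_me, lr=cv_lr, d_me=d_me, d_lr=d_lr,
        )
        model_results.append(result)
        combo_details[key] = {
            "best_params": bp,
            "seed": seed,
            "fold_maes": {
                "lsboost": cv_ls.fold_maes.tolist(),
                "me": cv_me.fold_maes.tolist(),
                "lasso": cv_lr.fold_maes.tolist(),
            },
            "mae": {"lsboost": [cv_ls.mean, cv_ls.sd],
                    "me": [cv_me.mean, cv_me.sd],
                    "lasso": [cv_lr.mean, cv_lr.sd]},
            "d_me": {"d": d_me.d, "ci95": list(d_me.ci95),
                     "significant": d_me.significant},
            "d_lr": {"d": d_lr.d, "ci95": list(d_lr.ci95),
                     "significant": d_lr.significant},
            "significant": result.significant,
        }
        if result.significant:
            # refit on the complete dataset with optimal hyperparameters
            std_table = standardize(table, std)
            model = fit_lsboost(
                std_table.X.to_numpy(float),
                std_table.y[target].to_numpy(float),
                hp, seed=seed, feature_names=list(std_table.X.columns),
            )
            importance_inputs.append(
                (dataset, target, feature_importance(model), list(std_table.X.columns))
            )

    summary = summarize_models(model_results)
    bundle = {
        "provenance": {
            "package_version": __version__,
            "master_seed": config.master_seed,
            "max_evaluations": config.max_evaluations,
            "panel_config": _config_to_dict(config.panel),
            "space_overrides": config.space_overrides,
        },
        "combinations": combo_details,
        "summary": {
            "n_significant": summary.n_significant,
            "empty": summary.empty,
            "overall_mae": list(summary.overall_mae),
            "overall_mae_antilog": list(summary.overall_mae_antilog),
            "d_me": list(summary.d_me),
            "d_lr": list(summary.d_lr),
        },
    }
    (report_dir / "results.json").write_text(
        json.dumps(_jsonable(bundle), indent=2, sort_keys=True)
    )
    if not summary.empty:
        summary.rows.to_csv(report_dir / "significant_models.csv", index=False)
    if importance_inputs:
        imp = aggregate_importance(importance_inputs)
        imp.class_table.to_csv(report_dir / "importance_classes.csv", index=False)
        imp.topography.to_csv(report_dir / "topography.csv", index=False)
    return report_dir


@dataclass
class ResultsBundle:
    """In-memory view of a finished run."""

    summary: dict
    combinations: dict
    provenance: dict
    report_dir: Path

    @classmethod
    def load(cls, report_dir: str | Path) -> "ResultsBundle":
        payload = json.loads((Path(report_dir) / "results.json").read_text())
        return cls(
            summary=payload["summary"],
            combinations=payload["combinations"],
            provenance=payload["provenance"],
            report_dir=Path(report_dir),
        )


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute every stage; identical config + seed ⇒ identical bundle."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = {
        "master_seed": config.master_seed,
        "max_evaluations": config.max_evaluations,
        "datasets": list(config.datasets),
        "targets": list(config.targets),
        "space_overrides": config.space_overrides,
        "panel": _config_to_dict(config.panel),
    }
    (outdir / "run_config.json").write_text(
        json.dumps(_jsonable(resolved), indent=2, sort_keys=True)
    )
    stages = [
        ("simulate", lambda: stage_simulate(config, outdir)),
        ("extract", lambda: stage_extract(outdir / "panel", outdir)),
        ("build", lambda: stage_build(outdir / "features", outdir, config.datasets)),
        ("optimize", lambda: stage_optimize(outdir / "datasets", outdir, config)),
        ("report", lambda: stage_report(outdir / "datasets", outdir / "optimize",
                                        outdir, config)),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return ResultsBundle.load(outdir / "report")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
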