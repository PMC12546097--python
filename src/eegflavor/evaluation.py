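"""Model evaluation: LOSO cross-validation, CASH search, effect sizes.

The evaluation scheme is leave-one-subject-out (LOSO): every fold holds
out all tasting trials of one subject, so performance reflects
generalization to unseen panelists.  The objective is the cross-validated
mean absolute error (MAE) on log(1+rating) targets.

Hyperparameters and the standardizer choice are optimized jointly (a
CASH problem) with the Bayesian optimizer in :mod:`eegflavor.search`:

    (n*, ρ*, l_s*, n_s*, S*) = argmin L(n, ρ, l_s, n_s, S)

Benchmarks are the constant-mean regressor (Me) and the lasso (LR).
LSBoost is compared to each through Cohen's d on fold MAEs,

    d = (m_bench − m_LSBoost) / s̄,   s̄ = sqrt((s_bench² + s_model²)/2),

with a 95 % confidence interval from the noncentral-t distribution
(df = 2·n_folds − 2, noncentrality d·sqrt(n_folds/2)); a model is
"significant" when both CIs exclude zero.  The anti-log transform
exp(MAE) − 1 maps errors back toward the 0–10 rating scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import nct, norm

from . import search
from .dataset import FeatureTable, STANDARDIZERS, canonical_standardizer, standardize
from .features import BAND_NAMES
from .models import (
    HP_BOUNDS,
    LSBoostHyperParams,
    fit_lasso,
    fit_lsboost,
    fit_mean,
    lasso_lambda,
)
from .montage import LAYOUT_2D

logger = logging.getLogger(__name__)

IMPORTANCE_CLASSES: tuple[str, ...] = (
    "Age", "Group", "p_delta", "p_theta", "p_alpha", "p_beta", "p_gamma",
    "A", "M", "C",
)


@dataclass(frozen=True)
class SearchSpace:
    """CASH search space: LSBoost bounds plus the standardizer choice."""

    n: tuple[int, int] = HP_BOUNDS["n"]
    rho: tuple[float, float] = HP_BOUNDS["rho"]
    leaf_size: tuple[int, int] = HP_BOUNDS["leaf_size"]
    max_splits: tuple[int, int] = HP_BOUNDS["max_splits"]
    standardizers: tuple[str, ...] = STANDARDIZERS
    max_evaluations: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be ≥ 1")
        for s in self.standardizers:
            canonical_standardizer(s)

    def dimensions(self) -> dict[str, search.Dimension]:
        return {
            "n": search.Integer(*self.n),
            "rho": search.Real(*self.rho),
            "leaf_size": search.Integer(*self.leaf_size),
            "max_splits": search.Integer(*self.max_splits),
            "standardizer": search.Categorical(tuple(self.standardizers)),
        }


@dataclass
class CVResult:
    """Per-fold (held-out subject) MAEs and their summary."""

    fold_maes: np.ndarray
    fold_subjects: list[str]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_maes = np.asarray(self.fold_maes, dtype=float)
        if np.any(self.fold_maes < 0):
            raise ValueError("MAE cannot be negative")
        self.mean = float(self.fold_maes.mean())
        self.sd = float(self.fold_maes.std(ddof=1)) if self.fold_maes.size > 1 else 0.0

    @property
    def objective(self) -> float:
        return self.mean

    @property
    def n_folds(self) -> int:
        return self.fold_maes.size


@dataclass
class EffectSize:
    """Cohen's d with its 95 % CI and significance flag."""

    d: float
    ci95: tuple[float, float]
    significant: bool


def loso_splits(subject_ids: Sequence[str]) -> list[tuple[list[str], str]]:
    """One (train_subjects, test_subject) split per unique subject.

    Splits are keyed by unique subject (in order of first appearance),
    never by row, so repeated rows of one subject stay together.
    """
    unique = list(dict.fromkeys(subject_ids))
    if len(unique) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    return [([s for s in unique if s != test], test) for test in unique]


def _fit_for_spec(kind: str, X, y, hp: LSBoostHyperParams | None, seed: int):
    if kind == "lsboost":
        return fit_lsboost(X, y, hp, seed=seed)
    if kind == "mean":
        return fit_mean(y)
    if kind == "lasso":
        return fit_lasso(X, y, lasso_lambda(X.shape[0], X.shape[1]))
    raise ValueError(f"unknown model kind {kind!r}")


def cv_mae(
    kind: str,
    table: FeatureTable,
    target: str,
    standardizer: str = "none",
    seed: int = 0,
    hp: LSBoostHyperParams | None = None,
) -> CVResult:
    """LOSO cross-validated MAE of one model on one target attribute.

    Standardization is subject-wise, hence applied once to the whole
    table without leaking information across subjects; each fold then
    fits on the training subjects and scores the held-out subject's
    trials.  MAEs are in transformed (log) units.
    """
    if target not in table.y.columns:
        raise KeyError(f"target {target!r} not in table (has {list(table.y.columns)})")
    std_table = standardize(table, standardizer)
    X = std_table.X.to_numpy(dtype=float)
    y = std_table.y[target].to_numpy(dtype=float)
    subjects = std_table.subject_ids
    maes, fold_subjects = [], []
    for train_subjects, test_subject in loso_splits(subjects):
        train_mask = np.isin(subjects, train_subjects)
        test_mask = subjects == test_subject
        model = _fit_for_spec(kind, X[train_mask], y[train_mask], hp, seed)
        pred = model.predict(X[test_mask])
        maes.append(float(np.abs(pred - y[test_mask]).mean()))
        fold_subjects.append(test_subject)
    return CVResult(fold_maes=np.asarray(maes), fold_subjects=fold_subjects)


def bayes_optimize(
    table: FeatureTable,
    target: str,
    space: SearchSpace,
) -> tuple[dict, search.OptimizationResult]:
    """Solve the CASH problem for one (dataset, target) combination.

    Returns the best configuration (n, ρ, l_s, n_s, standardizer) and
    the full trial log.  Deterministic given ``space.seed``.
    """

    def objective(params: dict) -> float:
        hp = LSBoostHyperParams(
            n=params["n"],
            rho=params["rho"],
            leaf_size=params["leaf_size"],
            max_splits=params["max_splits"],
        )
        return cv_mae(
            "lsboost", table, target,
            standardizer=params["standardizer"], seed=space.seed, hp=hp,
        ).objective

    result = search.minimize(
        objective,
        space.dimensions(),
        n_calls=space.max_evaluations,
        n_initial=min(10, space.max_evaluations),
        seed=space.seed,
    )
    return result.best_params, result


def _mean_sd(sample) -> tuple[float, float, int | None]:
    """Interpret a fold list or an (m, s) pair."""
    if isinstance(sample, CVResult):
        return sample.mean, sample.sd, sample.n_folds
    sample = np.asarray(sample, dtype=float)
    if sample.shape == (2,):
        return float(sample[0]), float(sample[1]), None
    return float(sample.mean()), float(sample.std(ddof=1)), sample.size


def cohens_d(mae_bench, mae_model, n_folds: int | None = None) -> EffectSize:
    """Cohen's d of benchmark vs model fold MAEs, with noncentral-t CI.

    Inputs are fold-MAE vectors, :class:`CVResult` objects, or (mean,
    SD) pairs (then ``n_folds`` is required for the CI).  Positive d
    means the model beats the benchmark.
    """
    m_b, s_b, n_b = _mean_sd(mae_bench)
    m_m, s_m, n_m = _mean_sd(mae_model)
    n = n_folds or n_b or n_m
    pooled = np.sqrt((s_b**2 + s_m**2) / 2.0)
    if pooled == 0:
        if m_b == m_m:
            return EffectSize(d=0.0, ci95=(0.0, 0.0), significant=False)
        raise ValueError("zero pooled SD with unequal means: d undefined")
    d = (m_b - m_m) / pooled
    if n is None:
        raise ValueError("n_folds required when passing (mean, SD) pairs")
    if n < 2:
        raise ValueError("need ≥ 2 folds for a confidence interval")
    df = 2 * n - 2
    scale = np.sqrt(n / 2.0)
    t_obs = d * scale
    lo, hi = _noncentrality_ci(t_obs, df)
    ci = (lo / scale, hi / scale)
    significant = not (ci[0] <= 0.0 <= ci[1])
    return EffectSize(d=float(d), ci95=ci, significant=significant)


def _nct_cdf_safe(t_obs: float, df: int, ncp: float) -> float:
    """nct.cdf with a normal-approximation fallback where scipy yields NaN."""
    with np.errstate(all="ignore"):
        v = nct.cdf(t_obs, df, ncp)
    if np.isnan(v):
        # Satterthwaite-style normal approximation to the noncentral t
        num = t_obs * (1.0 - 1.0 / (4.0 * df)) - ncp
        den = np.sqrt(1.0 + t_obs**2 / (2.0 * df))
        v = float(norm.cdf(num / den))
    return float(v)


def _noncentrality_ci(t_obs: float, df: int, level: float = 0.95) -> tuple[float, float]:
    """CI for the noncentrality parameter of a noncentral-t observation."""
    alpha = (1.0 - level) / 2.0
    span = 10.0 + 5.0 * abs(t_obs)

    def lower_eq(ncp):
        return _nct_cdf_safe(t_obs, df, ncp) - (1.0 - alpha)

    def upper_eq(ncp):
        return _nct_cdf_safe(t_obs, df, ncp) - alpha

    lo = brentq(lower_eq, t_obs - span, t_obs + span, xtol=1e-10)
    hi = brentq(upper_eq, t_obs - span, t_obs + span, xtol=1e-10)
    return float(lo), float(hi)


def antilog_mae(mae_log_scale: float) -> float:
    """Map a log(1+y)-scale MAE back toward the rating scale: exp(MAE)−1."""
    if mae_log_scale < 0:
        raise ValueError("MAE cannot be negative")
    return float(np.expm1(mae_log_scale))


@dataclass
class ModelResult:
    """Everything evaluated for one (dataset, target) combination."""

    dataset: str
    target: str
    lsboost: CVResult | tuple[float, float]
    me: CVResult | tuple[float, float]
    lr: CVResult | tuple[float, float]
    d_me: EffectSize
    d_lr: EffectSize

    @property
    def significant(self) -> bool:
        return self.d_me.significant and self.d_lr.significant

    def mae_mean_sd(self) -> tuple[float, float]:
        m, s, _ = _mean_sd(self.lsboost)
        return m, s


@dataclass
class SummaryReport:
    """Aggregate statistics over the significant models."""

    rows: pd.DataFrame  # per-model table (Table-2 analog)
    overall_mae: tuple[float, float]  # mean ± SD of per-model MAE means
    overall_mae_antilog: tuple[float, float]
    d_me: tuple[float, float]
    d_lr: tuple[float, float]
    n_significant: int
    empty: bool = False


def summarize_models(results: Sequence[ModelResult]) -> SummaryReport:
    """Filter to significant models and compute the headline aggregates.

    A model is significant when both its d_Me and d_LR confidence
    intervals exclude zero.  Aggregates (mean ± sample SD) are over the
    per-model MAE means, their anti-logs, and the two d-score sets.  No
    significant model yields an explicitly flagged empty report.
    """
    significant = [r for r in results if r.significant]
    if not significant:
        return SummaryReport(
            rows=pd.DataFrame(), overall_mae=(np.nan, np.nan),
            overall_mae_antilog=(np.nan, np.nan), d_me=(np.nan, np.nan),
            d_lr=(np.nan, np.nan), n_significant=0, empty=True,
        )
    rows = []
    for r in significant:
        m, s = r.mae_mean_sd()
        m_me, s_me, _ = _mean_sd(r.me)
        m_lr, s_lr, _ = _mean_sd(r.lr)
        rows.append(
            {
                "dataset": r.dataset, "target": r.target,
                "lsboost_mae": m, "lsboost_sd": s,
                "me_mae": m_me, "me_sd": s_me,
                "lr_mae": m_lr, "lr_sd": s_lr,
                "d_me": r.d_me.d, "d_lr": r.d_lr.d,
            }
        )
    frame = pd.DataFrame(rows)

    def agg(values) -> tuple[float, float]:
        values = np.asarray(values, dtype=float)
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return float(values.mean()), sd

    maes = frame["lsboost_mae"].to_numpy()
    return SummaryReport(
        rows=frame,
        overall_mae=agg(maes),
        overall_mae_antilog=agg([antilog_mae(m) for m in maes]),
        d_me=agg(frame["d_me"]),
        d_lr=agg(frame["d_lr"]),
        n_significant=len(significant),
    )


@dataclass
class ImportanceSummary:
    """Channel-aggregated importance (Table-3 analog) plus topography."""

    class_table: pd.DataFrame  # rows per (dataset, target), cols IMPORTANCE_CLASSES
    topography: pd.DataFrame  # channel, x, y, score (averaged across models)


def aggregate_importance(
    models: Sequence[tuple[str, str, np.ndarray, list[str]]],
) -> ImportanceSummary:
    """Aggregate normalized importance vectors across channels and models.

    ``models`` holds (dataset, target, importance_vector, feature_names)
    for each significant model refit on its complete dataset.  Per model,
    scores are summed over the 38 channels within each feature class
    (p_δ…p_γ, A, M, C) with Age and Group kept as-is; the topography is
    the per-channel total, averaged across models.
    """
    class_rows = []
    per_model_channel: list[dict[str, float]] = []
    for dataset, target, imp, names in models:
        imp = np.asarray(imp, dtype=float)
        if imp.shape != (len(names),):
            raise ValueError("importance vector length does not match feature names")
        if abs(imp.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"importance vector not normalized (sums to {imp.sum():.6f})"
            )
        by_name = dict(zip(names, imp))
        row = {"dataset": dataset, "target": target}
        row["Age"] = by_name.get("age", 0.0)
        row["Group"] = by_name.get("group", 0.0)
        for band in BAND_NAMES:
            row[f"p_{band}"] = sum(
                v for k, v in by_name.items() if k.endswith(f".p_{band}")
            )
        for param in ("A", "M", "C"):
            row[param] = sum(
                v for k, v in by_name.items() if k.endswith(f".hjorth_{param}")
            )
        class_rows.append(row)
        chan_sums: dict[str, float] = {}
        for name, v in by_name.items():
            if "." in name:
                chan = name.split(".", 1)[0]
                chan_sums[chan] = chan_sums.get(chan, 0.0) + v
        per_model_channel.append(chan_sums)

    channels = sorted(set().union(*per_model_channel)) if per_model_channel else []
    topo_rows = []
    for chan in channels:
        x, y = LAYOUT_2D.get(chan, (np.nan, np.nan))
        score = float(np.mean([cs.get(chan, 0.0) for cs in per_model_channel]))
        topo_rows.append({"channel": chan, "x": x, "y": y, "score": score})
    return ImportanceSummary(
        class_table=pd.DataFrame(class_rows),
        topography=pd.DataFrame(topo_rows),
    )
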