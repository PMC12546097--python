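"""Regressors: least-squares boosted trees and the two benchmarks.

LSBoost is stagewise least-squares gradient boosting: the initial
prediction is the training-target mean; each stage fits a regression
tree (squared-error criterion, minimum leaf size ``l_s``, at most
``n_s`` internal splits, grown best-first by impurity reduction) to the
current residuals and is added with shrinkage ρ.

Two implementations coexist:

* :func:`fit_lsboost` — the production path, backed by scikit-learn's
  ``GradientBoostingRegressor`` with a one-to-one hyperparameter map
  (``n_estimators=n``, ``learning_rate=ρ``, ``min_samples_leaf=l_s``,
  ``max_leaf_nodes=n_s+1`` for best-first growth, squared-error split
  criterion).
* :class:`LSBoostReference` — a small, fully deterministic pure-NumPy
  implementation (exact greedy split search over midpoints, ties broken
  by lowest feature index then lowest threshold) that serves as the
  readable contract and as an independent cross-check in the test
  suite.

Benchmarks are the constant-mean regressor (Me) and an L1-penalized
linear model (LR) whose penalty defaults to λ = 2·ln(p)/n with the
objective scaling (1/(2n))·RSS + λ·Σ|β| (unpenalized intercept).

Feature importance is impurity-based: per-feature squared-error
reduction summed over every split node of every tree, normalized to
unit sum.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Lasso

HP_BOUNDS = {
    "n": (1, 500),
    "rho": (0.01, 1.0),
    "leaf_size": (1, 100),
    "max_splits": (1, 100),
}


@dataclass(frozen=True)
class LSBoostHyperParams:
    """LSBoost tuning knobs: n learners, learning rate ρ, minimum leaf
    size l_s, and maximum number of splits n_s per tree."""

    n: int
    rho: float
    leaf_size: int
    max_splits: int

    def __post_init__(self) -> None:
        for name, value in (
            ("n", self.n),
            ("rho", self.rho),
            ("leaf_size", self.leaf_size),
            ("max_splits", self.max_splits),
        ):
            lo, hi = HP_BOUNDS[name if name != "rho" else "rho"]
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")
        for name in ("n", "leaf_size", "max_splits"):
            if int(getattr(self, name)) != getattr(self, name):
                raise ValueError(f"{name} must be an integer")


@dataclass
class LSBoostModel:
    """A fitted boosted-tree ensemble (scikit-learn backend)."""

    estimator: GradientBoostingRegressor
    hp: LSBoostHyperParams
    n_features: int
    feature_names: list[str] | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got shape {X.shape}"
            )
        return self.estimator.predict(X)


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    return X, y


def fit_lsboost(
    X,
    y,
    hp: LSBoostHyperParams,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> LSBoostModel:
    """Fit the LSBoost ensemble; deterministic given ``seed``."""
    X, y = _validate_xy(X, y)
    if X.shape[0] < 2 * hp.leaf_size:
        raise ValueError(
            f"{X.shape[0]} rows cannot support leaf_size={hp.leaf_size} "
            "(need ≥ 2·leaf_size)"
        )
    est = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=int(hp.n),
        learning_rate=float(hp.rho),
        min_samples_leaf=int(hp.leaf_size),
        max_leaf_nodes=int(hp.max_splits) + 1,
        max_depth=None,
        random_state=int(seed),
    )
    est.fit(X, y)
    return LSBoostModel(
        estimator=est, hp=hp, n_features=X.shape[1], feature_names=feature_names
    )


def predict(model, X) -> np.ndarray:
    """Predict with any fitted model from this module."""
    return model.predict(X)


def feature_importance(model: LSBoostModel | "LSBoostReference") -> np.ndarray:
    """Impurity-based importance, normalized to sum 1.

    Per-feature squared-error impurity reduction summed across every
    split node of every tree.  An ensemble with no splits at all yields
    a zero vector with a warning.
    """
    if isinstance(model, LSBoostReference):
        raw = model._importance_raw
    else:
        raw = np.zeros(model.n_features)
        for tree in model.estimator.estimators_.ravel():
            raw += tree.tree_.compute_feature_importances(normalize=False)
    total = raw.sum()
    if total <= 0:
        warnings.warn("model has no splits; importance is all-zero", stacklevel=2)
        return np.zeros_like(raw)
    return raw / total


# ---------------------------------------------------------------------------
# benchmarks


@dataclass
class MeanModel:
    """Constant predictor at the training-target mean (Me benchmark)."""

    mean: float
    n_features: int | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0] if X.ndim == 2 else len(X)
        return np.full(n, self.mean)


def fit_mean(y) -> MeanModel:
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("cannot fit the mean of an empty target vector")
    return MeanModel(mean=float(y.mean()))


def lasso_lambda(n: int, p: int) -> float:
    """Default L1 penalty λ = 2·ln(p)/n for an n-row, p-feature design."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if p < 2:
        raise ValueError("p must be ≥ 2")
    return 2.0 * np.log(p) / n


@dataclass
class LinearModel:
    """Linear regressor (lasso benchmark or its λ=0 OLS limit)."""

    coef: np.ndarray
    intercept: float
    lam: float

    @property
    def n_features(self) -> int:
        return self.coef.size

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coef.size:
            raise ValueError(
                f"expected {self.coef.size} feature columns, got shape {X.shape}"
            )
        return X @ self.coef + self.intercept


def fit_lasso(X, y, lam: float) -> LinearModel:
    """L1-penalized least squares, objective (1/(2n))·RSS + λ·Σ|β|.

    The intercept is unpenalized.  λ = 0 falls back to ordinary least
    squares (minimum-norm solution on rank-deficient designs).
    """
    X, y = _validate_xy(X, y)
    if X.shape[0] < 2:
        raise ValueError("need ≥ 2 rows to fit the lasso")
    if lam < 0:
        raise ValueError("λ must be ≥ 0")
    if lam == 0:
        A = np.column_stack([np.ones(X.shape[0]), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return LinearModel(coef=beta[1:], intercept=float(beta[0]), lam=0.0)
    est = Lasso(alpha=lam, fit_intercept=True, tol=1e-6, max_iter=500_000)
    est.fit(X, y)
    return LinearModel(coef=est.coef_.copy(), intercept=float(est.intercept_), lam=lam)


# ---------------------------------------------------------------------------
# reference implementation


@dataclass
class _Leaf:
    indices: np.ndarray
    value: float


@dataclass
class _Split:
    feature: int
    threshold: float
    left: "object"
    right: "object"


class _RegressionTree:
    """Exact greedy regression tree, best-first growth, squared error."""

    def __init__(self, min_leaf: int, max_splits: int):
        self.min_leaf = min_leaf
        self.max_splits = max_splits
        self.root = None
        self.split_gains: list[tuple[int, float]] = []  # (feature, SSE reduction)

    @staticmethod
    def _best_split(X, y, idx, min_leaf):
        """Best (gain, feature, threshold) at a node, or None."""
        n = idx.size
        if n < 2 * min_leaf:
            return None
        ysub = y[idx]
        sse_parent = ((ysub - ysub.mean()) ** 2).sum()
        best = None
        for j in range(X.shape[1]):
            xj = X[idx, j]
            order = np.argsort(xj, kind="stable")
            xs, ys = xj[order], ysub[order]
            # candidate split after position k (1-based count on the left)
            csum = np.cumsum(ys)
            total = csum[-1]
            ks = np.arange(min_leaf, n - min_leaf + 1)
            if ks.size == 0:
                continue
            valid = xs[ks - 1] < xs[np.minimum(ks, n - 1)]
            # exclude k == n (no right side) — ks max is n-min_leaf ≤ n-1
            left_sum = csum[ks - 1]
            right_sum = total - left_sum
            gain = left_sum**2 / ks + right_sum**2 / (n - ks) - total**2 / n
            gain = np.where(valid, gain, -np.inf)
            k_best = int(np.argmax(gain))
            if not np.isfinite(gain[k_best]):
                continue
            thr = 0.5 * (xs[ks[k_best] - 1] + xs[ks[k_best]])
            cand = (float(gain[k_best]), -j, -thr)
            if best is None or cand > (best[0], -best[1], -best[2]):
                best = (float(gain[k_best]), j, float(thr))
        if best is None or best[0] <= 1e-15 * max(1.0, sse_parent):
            return None
        return best

    def fit(self, X, y):
        idx_all = np.arange(X.shape[0])
        self.root = _Leaf(idx_all, float(y.mean()))
        # best-first frontier: (-gain, tie-break counter, leaf, split info)
        frontier = []
        counter = 0

        def push(leaf):
            nonlocal counter
            found = self._best_split(X, y, leaf.indices, self.min_leaf)
            if found is not None:
                gain, j, thr = found
                heapq.heappush(frontier, (-gain, j, thr, counter, leaf))
                counter += 1

        push(self.root)
        n_splits = 0
        while frontier and n_splits < self.max_splits:
            neg_gain, j, thr, _, leaf = heapq.heappop(frontier)
            mask = X[leaf.indices, j] <= thr
            left = _Leaf(leaf.indices[mask], float(y[leaf.indices[mask]].mean()))
            right = _Leaf(leaf.indices[~mask], float(y[leaf.indices[~mask]].mean()))
            split = _Split(feature=j, threshold=thr, left=left, right=right)
            self._replace(leaf, split)
            self.split_gains.append((j, -neg_gain))
            n_splits += 1
            push(left)
            push(right)
        return self

    def _replace(self, leaf, split):
        if self.root is leaf:
            self.root = split
            return
        stack = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, _Split):
                if node.left is leaf:
                    node.left = split
                    return
                if node.right is leaf:
                    node.right = split
                    return
                stack.extend([node.left, node.right])
        raise AssertionError("leaf not found in tree")

    def predict(self, X):
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            node = self.root
            while isinstance(node, _Split):
                node = node.left if X[i, node.feature] <= node.threshold else node.right
            out[i] = node.value
        return out


class LSBoostReference:
    """Pure-NumPy stagewise least-squares boosting (reference contract).

    Fully deterministic: exact greedy split search over midpoints of
    sorted distinct values, ties broken by lowest feature index then
    lowest threshold; trees grown best-first up to ``max_splits``
    internal nodes.
    """

    def __init__(self, hp: LSBoostHyperParams):
        self.hp = hp
        self.f0: float = 0.0
        self.trees: list[_RegressionTree] = []
        self.n_features: int = 0

    def fit(self, X, y) -> "LSBoostReference":
        X, y = _validate_xy(X, y)
        if X.shape[0] < 2 * self.hp.leaf_size:
            raise ValueError(
                f"{X.shape[0]} rows cannot support leaf_size={self.hp.leaf_size}"
            )
        self.n_features = X.shape[1]
        self.f0 = float(y.mean())
        pred = np.full(y.shape, self.f0)
        for _ in range(int(self.hp.n)):
            tree = _RegressionTree(
                min_leaf=int(self.hp.leaf_size), max_splits=int(self.hp.max_splits)
            ).fit(X, y - pred)
            self.trees.append(tree)
            pred += self.hp.rho * tree.predict(X)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got shape {X.shape}"
            )
        pred = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            pred += self.hp.rho * tree.predict(X)
        return pred

    def staged_train_mse(self, X, y) -> np.ndarray:
        """Training MSE after each boosting stage (monotonicity check)."""
        X, y = _validate_xy(X, y)
        pred = np.full(y.shape, self.f0)
        out = []
        for tree in self.trees:
            pred += self.hp.rho * tree.predict(X)
            out.append(float(((y - pred) ** 2).mean()))
        return np.asarray(out)

    @property
    def _importance_raw(self) -> np.ndarray:
        raw = np.zeros(self.n_features)
        for tree in self.trees:
            for j, gain in tree.split_gains:
                raw[j] += gain
        return raw


# ---------------------------------------------------------------------------
# serialization (audit trail)


def _tree_to_dict(node) -> dict:
    if isinstance(node, _Leaf):
        return {"leaf": node.value}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _tree_to_dict(node.left),
        "right": _tree_to_dict(node.right),
    }


def save_reference_model(model: LSBoostReference, path: str | Path) -> None:
    """Serialize a reference ensemble to JSON (nested split/leaf records)."""
    payload = {
        "f0": model.f0,
        "hp": {
            "n": model.hp.n,
            "rho": model.hp.rho,
            "leaf_size": model.hp.leaf_size,
            "max_splits": model.hp.max_splits,
        },
        "n_features": model.n_features,
        "trees": [_tree_to_dict(t.root) for t in model.trees],
    }
    Path(path).write_text(json.dumps(payload))
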