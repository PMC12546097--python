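"""Sequential model-based minimization over a mixed search space.

A small Bayesian optimizer for the combined algorithm-selection and
hyperparameter (CASH) search: Gaussian-process surrogate (Matérn 5/2 +
white noise) with expected-improvement acquisition.  Integer dimensions
are relaxed to the unit interval and rounded on decoding; categorical
dimensions are one-hot encoded.  The first ``n_initial`` evaluations are
quasi-random (Latin hypercube).  Fully deterministic given the seed.

A trial whose objective raises is recorded as failed and the search
continues; failed trials are excluded from the surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Real:
    low: float
    high: float

    @property
    def width(self) -> int:
        return 1

    def decode(self, u: np.ndarray) -> float:
        return float(self.low + (self.high - self.low) * u[0])


@dataclass(frozen=True)
class Integer:
    low: int
    high: int

    @property
    def width(self) -> int:
        return 1

    def decode(self, u: np.ndarray) -> int:
        return int(round(self.low + (self.high - self.low) * float(u[0])))


@dataclass(frozen=True)
class Categorical:
    options: tuple

    @property
    def width(self) -> int:
        return len(self.options)

    def decode(self, u: np.ndarray):
        return self.options[int(np.argmax(u))]


Dimension = Real | Integer | Categorical


@dataclass
class Trial:
    params: dict[str, Any]
    value: float | None  # None ⇔ failed
    encoded: np.ndarray = field(repr=False, default=None)


@dataclass
class OptimizationResult:
    best_params: dict[str, Any]
    best_value: float
    trials: list[Trial]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _decode(space: dict[str, Dimension], u: np.ndarray) -> dict[str, Any]:
    out, pos = {}, 0
    for name, dim in space.items():
        out[name] = dim.decode(u[pos : pos + dim.width])
        pos += dim.width
    return out


def _expected_improvement(gp, candidates: np.ndarray, best: float, xi: float = 0.01):
    mu, sigma = gp.predict(candidates, return_std=True)
    sigma = np.maximum(sigma, 1e-12)
    improvement = best - mu - xi
    z = improvement / sigma
    return improvement * norm.cdf(z) + sigma * norm.pdf(z)


def minimize(
    objective: Callable[[dict[str, Any]], float],
    space: dict[str, Dimension],
    n_calls: int = 100,
    n_initial: int = 10,
    seed: int = 0,
    n_candidates: int = 1024,
) -> OptimizationResult:
    """Minimize ``objective`` over ``space`` in ``n_calls`` evaluations.

    The reported best is the minimum over the trial log (bookkeeping
    invariant: ``best_value == min(t.value for successful trials)``).
    """
    if n_calls < 1:
        raise ValueError("n_calls must be ≥ 1")
    total_dim = sum(dim.width for dim in space.values())
    rng = np.random.default_rng([0x5EED, seed])
    n_initial = min(n_initial, n_calls)
    sampler = qmc.LatinHypercube(d=total_dim, seed=rng)
    initial = sampler.random(n_initial)

    trials: list[Trial] = []

    def evaluate(u: np.ndarray) -> None:
        params = _decode(space, u)
        try:
            value = float(objective(params))
        except Exception as exc:  # noqa: BLE001 — a failed trial must not kill the search
            logger.warning("trial %d failed: %s", len(trials), exc)
            value = None
        trials.append(Trial(params=params, value=value, encoded=u.copy()))

    for u in initial:
        evaluate(u)

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.full(total_dim, 0.5), length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-6, (1e-10, 1e-1))
    )
    while len(trials) < n_calls:
        ok = [t for t in trials if t.value is not None]
        if len(ok) < 2:
            evaluate(rng.random(total_dim))
            continue
        X = np.vstack([t.encoded for t in ok])
        y = np.array([t.value for t in ok])
        y_mu, y_sd = y.mean(), y.std()
        y_std = (y - y_mu) / (y_sd if y_sd > 0 else 1.0)
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=False,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with np.errstate(all="ignore"):
            gp.fit(X, y_std)
            candidates = rng.random((n_candidates, total_dim))
            ei = _expected_improvement(gp, candidates, best=y_std.min())
        evaluate(candidates[int(np.argmax(ei))])

    ok = [t for t in trials if t.value is not None]
    if not ok:
        raise RuntimeError("every optimization trial failed")
    best = min(ok, key=lambda t: t.value)
    return OptimizationResult(best_params=best.params, best_value=best.value, trials=trials)
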