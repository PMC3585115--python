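"""Parameter estimation: training set assembly, objective, annealing fits.

The objective is the summed squared difference between predicted and observed
transcription rates over every (construct, axis position) pair in the
training set; quality is conventionally reported as the root-mean-square
residual.  Three optimizer backends share one interface:

``lam_sa``
    Simulated annealing with an adaptive schedule in the style of Lam &
    Delosme: the temperature decrement is controlled online from running
    estimates of the energy mean/variance so the system stays near quasi-
    equilibrium, and per-parameter move sizes adapt toward a target
    acceptance ratio.
``generic_sa``
    Plain Metropolis annealing with geometric cooling; a robust baseline.
``multistart_local``
    Repeated L-BFGS-B from random starting points inside the bounds; the
    search runs on the optimizer scale (log for scale-type parameters).

All backends respect bounds, are deterministic given the seed, stop on an
evaluation budget, and return the best parameters plus an objective trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import ModelParams
from .pipeline import Construct, ConstructEvaluator
from .pwm import PWM

__all__ = ["TrainingSet", "FitResult", "objective", "fit"]


class AlignmentError(ValueError):
    """Model output grid does not match the observation grid."""


@dataclass
class TrainingSet:
    """Constructs, shared A-P grid, TF profiles and observed expression.

    ``observed`` has one column per construct id on the same position index
    as ``tf_profiles``.
    """

    constructs: list[Construct]
    tf_profiles: pd.DataFrame
    observed: pd.DataFrame
    true_params: ModelParams | None = None  # set by the synthetic generator

    def __post_init__(self) -> None:
        if not self.tf_profiles.index.equals(self.observed.index):
            raise AlignmentError("TF profiles and observations use different grids")
        missing = [
            c.construct_id
            for c in self.constructs
            if c.construct_id not in self.observed.columns
        ]
        if missing:
            raise AlignmentError(f"no observed profile for construct(s) {missing}")

    @property
    def n_positions(self) -> int:
        return len(self.tf_profiles.index)

    @property
    def n_observations(self) -> int:
        return self.n_positions * len(self.constructs)


@dataclass
class FitResult:
    params: ModelParams
    ssq: float
    rms: float
    trace: np.ndarray  # best-so-far ssq per evaluation
    n_evaluations: int
    optimizer: str
    seed: int


def _make_objective(
    data: TrainingSet, pwms: dict[str, PWM], template: ModelParams
) -> tuple[Callable[[ModelParams], float], int]:
    evaluators = [
        ConstructEvaluator(c, pwms, data.tf_profiles, template)
        for c in data.constructs
    ]
    obs = [
        data.observed[c.construct_id].to_numpy(dtype=float)
        for c in data.constructs
    ]
    n = data.n_observations

    def ssq_of(params: ModelParams) -> float:
        total = 0.0
        for ev, y in zip(evaluators, obs):
            r = ev.evaluate(params)
            total += float(((r - y) ** 2).sum())
        return total

    return ssq_of, n


def objective(
    params: ModelParams, data: TrainingSet, pwms: dict[str, PWM]
) -> tuple[float, float]:
    """Sum of squared residuals and rms over all observations."""
    ssq_of, n = _make_objective(data, pwms, params)
    ssq = ssq_of(params)
    return ssq, float(np.sqrt(ssq / n))


# ---------------------------------------------------------------------------
# optimizer backends (operate on the free vector, search scale)
# ---------------------------------------------------------------------------

def _clip(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(x, bounds[:, 0], bounds[:, 1])


def _generic_sa(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: np.ndarray,
    budget: int,
    rng: np.random.Generator,
    t0: float | None = None,
    cooling: float | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    span = bounds[:, 1] - bounds[:, 0]
    step = 0.1 * span
    x, fx = x0.copy(), f(x0)
    best_x, best_f = x.copy(), fx
    trace = [fx]
    n_eval = 1
    # calibrate initial temperature from random-walk energy spread
    probes = []
    for _ in range(min(50, budget // 10 or 1)):
        xp = _clip(x + rng.normal(scale=step), bounds)
        probes.append(f(xp))
        n_eval += 1
    t = t0 if t0 is not None else max(np.std(probes), 1e-12)
    remaining = budget - n_eval
    lam_cool = cooling if cooling is not None else (1e-6) ** (1.0 / max(remaining, 1))
    accepted = 0
    window = 0
    while n_eval < budget:
        i = rng.integers(len(x))
        xp = x.copy()
        xp[i] = np.clip(x[i] + rng.normal() * step[i], bounds[i, 0], bounds[i, 1])
        fp = f(xp)
        n_eval += 1
        window += 1
        if fp <= fx or rng.random() < np.exp(-(fp - fx) / max(t, 1e-300)):
            x, fx = xp, fp
            accepted += 1
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        t *= lam_cool
        if window >= 100:  # adapt step toward ~40% acceptance
            ratio = accepted / window
            step *= 1.3 if ratio > 0.5 else (0.8 if ratio < 0.3 else 1.0)
            step = np.minimum(np.maximum(step, 1e-9 * span + 1e-12), span)
            accepted = window = 0
        trace.append(best_f)
    return best_x, best_f, trace


def _lam_sa(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: np.ndarray,
    budget: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[float]]:
    """Adaptive-schedule annealing (Lam-style quasi-equilibrium control).

    The inverse temperature ``s`` increases each step by an amount
    proportional to ``1 / (sigma(s) * (ds estimated from energy variance))``,
    keeping the annealer close to equilibrium; move sizes adapt toward the
    0.44 acceptance ratio that schedule analysis recommends.
    """
    span = bounds[:, 1] - bounds[:, 0]
    step = 0.1 * span
    x, fx = x0.copy(), f(x0)
    best_x, best_f = x.copy(), fx
    trace = [fx]
    n_eval = 1
    energies = [fx]
    for _ in range(min(50, budget // 10 or 1)):
        xp = _clip(x + rng.normal(scale=step), bounds)
        e = f(xp)
        energies.append(e)
        n_eval += 1
        if e < fx:
            x, fx = xp, e
            if fx < best_f:
                best_x, best_f = x.copy(), fx
    sigma = max(float(np.std(energies)), 1e-12)
    s = 1.0 / (10.0 * sigma)  # hot start: T ~ 10 sigma
    lam_rate = 1.0  # schedule speed constant
    mean_e, var_e = float(np.mean(energies)), sigma**2
    accepted = 0
    window = 0
    target = 0.44
    while n_eval < budget:
        i = rng.integers(len(x))
        xp = x.copy()
        xp[i] = np.clip(x[i] + rng.normal() * step[i], bounds[i, 0], bounds[i, 1])
        fp = f(xp)
        n_eval += 1
        window += 1
        if fp <= fx or rng.random() < np.exp(-(fp - fx) * s):
            x, fx = xp, fp
            accepted += 1
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        # running energy statistics (exponential forgetting)
        beta = 0.02
        mean_e = (1 - beta) * mean_e + beta * fx
        var_e = (1 - beta) * var_e + beta * (fx - mean_e) ** 2
        sd = max(np.sqrt(var_e), 1e-12)
        # quasi-equilibrium schedule: ds proportional to 1/(sd * s^2 * sd^2)
        s += lam_rate / (sd * max(s, 1e-12) ** 2 * sd**2 + 1e-300) * (
            1.0 / max(budget, 1)
        )
        if window >= 50:
            ratio = accepted / window
            adj = np.exp(0.5 * (ratio - target))
            step = np.minimum(np.maximum(step * adj, 1e-9 * span + 1e-12), span)
            accepted = window = 0
        trace.append(best_f)
    return best_x, best_f, trace


def _multistart_local(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: np.ndarray,
    budget: int,
    rng: np.random.Generator,
    n_restarts: int = 10,
) -> tuple[np.ndarray, float, list[float]]:
    """L-BFGS-B from ``n_restarts`` starting points (the supplied start plus
    uniform draws inside the bounds); the evaluation budget is a hard cap."""
    n_eval = 0
    trace: list[float] = []
    best_x, best_f = x0.copy(), np.inf

    def counted(x: np.ndarray) -> float:
        nonlocal n_eval, best_f, best_x
        v = f(x)
        n_eval += 1
        if v < best_f:
            best_f, best_x = v, x.copy()
        trace.append(best_f)
        return v

    lo, hi = bounds[:, 0], bounds[:, 1]
    starts = [x0] + [rng.uniform(lo, hi) for _ in range(max(n_restarts - 1, 0))]
    per_start = max(budget // max(len(starts), 1), 10)
    for x_start in starts:
        rem = budget - n_eval
        if rem <= 0:
            break
        optimize.minimize(
            counted,
            _clip(x_start, bounds),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": min(per_start, rem), "ftol": 1e-12, "gtol": 1e-10},
        )
    return best_x, best_f, trace


_BACKENDS = {
    "lam_sa": _lam_sa,
    "generic_sa": _generic_sa,
    "multistart_local": _multistart_local,
}


def fit(
    data: TrainingSet,
    pwms: dict[str, PWM],
    start: ModelParams,
    optimizer: str = "generic_sa",
    seed: int = 0,
    budget: int = 200_000,
) -> FitResult:
    """Fit the free parameters of ``start`` to a training set.

    Deterministic given ``(seed, budget, optimizer)``.  Returns best-found
    parameters (always within bounds) and the best-so-far objective trace.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    if optimizer not in _BACKENDS:
        raise ValueError(
            f"unknown optimizer {optimizer!r}; choose from {sorted(_BACKENDS)}"
        )
    free = start.free_names
    if not free:
        raise ValueError("no free parameters to fit")
    bounds = np.array(start.free_bounds())
    if not np.all(np.isfinite(bounds)):
        raise ValueError("all free parameters need finite bounds for fitting")

    ssq_of, n_obs = _make_objective(data, pwms, start)

    def f(x: np.ndarray) -> float:
        v = ssq_of(start.with_free_vector(x))
        if not np.isfinite(v):
            raise FloatingPointError(
                f"objective diverged (non-finite ssq) at free vector {x}"
            )
        return v

    rng = np.random.default_rng(seed)
    x0 = start.free_vector()
    best_x, best_f, trace = _BACKENDS[optimizer](f, x0, bounds, budget, rng)
    params = start.with_free_vector(best_x)
    return FitResult(
        params=params,
        ssq=best_f,
        rms=float(np.sqrt(best_f / n_obs)),
        trace=np.asarray(trace),
        n_evaluations=len(trace),
        optimizer=optimizer,
        seed=seed,
    )


def fit_repeated(
    data: TrainingSet,
    pwms: dict[str, PWM],
    start: ModelParams,
    optimizer: str = "generic_sa",
    seeds: Sequence[int] = range(10),
    budget: int = 200_000,
) -> list[FitResult]:
    """Independent fits from distinct seeds (annealing runs are repeated and
    judged by their rms scores); results sorted best-first."""
    results = [
        fit(data, pwms, start, optimizer=optimizer, seed=int(s), budget=budget)
        for s in seeds
    ]
    return sorted(results, key=lambda r: r.ssq)
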