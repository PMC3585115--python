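"""Self-contained benchmark experiments run by the test suite and scripts.

The central one is a reduced parameter-recovery study: forward-simulate the
four fusion-variant constructs with known parameters and 7.5% multiplicative
observation noise, free a six-parameter subset spanning the mechanism classes
(recruiting strengths, quenching/direct-repression/coactivation efficiencies,
the activation barrier), and refit from a displaced starting point.  Success
is judged by absolute error for efficiencies, fold error for scale-type
parameters, and the final rms against the injected noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import TrainingSet, fit
from .params import ModelParams
from .pipeline import ConstructEvaluator
from .pwm import PWM
from .synth import demo_training_set, toy_pwms

__all__ = ["RecoveryReport", "recovery_problem", "run_recovery"]

#: The freed subset: two scale-type (recruiting strength, barrier) and four
#: bounded efficiencies.  Chosen so each fusion-variant mechanism (activation,
#: coactivation, quenching, direct repression) constrains at least one entry.
FREE_SUBSET = (
    "alpha_bcd",
    "alpha_coact_hb",
    "theta",
    "beta_q_kr",
    "beta_d_kr",
    "coact_eff_bcd",
)
SCALE_TYPE = ("alpha_bcd", "alpha_coact_hb", "theta")
EFFICIENCY_TYPE = ("beta_q_kr", "beta_d_kr", "coact_eff_bcd")

#: Displaced starting values (roughly mid-bounds; far from the generating
#: values so the fit has real work to do).
START_VALUES = {
    "alpha_bcd": 1.0,
    "alpha_coact_hb": 1.0,
    "theta": 3.0,
    "beta_q_kr": 0.3,
    "beta_d_kr": 0.2,
    "coact_eff_bcd": 0.3,
}

FUSION_IDS = ("m32", "m3_2", "m23", "m2_3")


@dataclass
class RecoveryReport:
    recovered: dict[str, float]
    true: dict[str, float]
    rms: float
    noise_floor_rms: float
    n_observations: int
    n_evaluations: int

    @property
    def efficiency_abs_errors(self) -> dict[str, float]:
        return {
            n: abs(self.recovered[n] - self.true[n]) for n in EFFICIENCY_TYPE
        }

    @property
    def scale_fold_errors(self) -> dict[str, float]:
        out = {}
        for n in SCALE_TYPE:
            r, t = self.recovered[n], self.true[n]
            out[n] = max(r / t, t / r) if r > 0 and t > 0 else np.inf
        return out

    @property
    def rms_ratio(self) -> float:
        return self.rms / self.noise_floor_rms


def recovery_problem(
    seed: int, noise_sd: float = 0.075
) -> tuple[TrainingSet, dict[str, PWM], ModelParams]:
    """Training data (4 fusion constructs x 58 positions) and displaced start."""
    data = demo_training_set(
        seed=seed, noise_sd=noise_sd, construct_ids=FUSION_IDS
    )
    start = data.true_params.copy()
    start.fix_all_except(*FREE_SUBSET)
    for name, v in START_VALUES.items():
        start[name] = v
    # tighten the scale-type search boxes to a plausible order-of-magnitude
    # window; the generating values sit well inside
    for name in ("alpha_bcd", "alpha_coact_hb"):
        p = start.entries[name]
        start.entries[name] = type(p)(name, start[name], 0.0, 20.0, True, p.scale)
    return data, toy_pwms(), start


def noise_floor(data: TrainingSet, pwms: dict[str, PWM]) -> float:
    """rms of observations against the noiseless generating predictions."""
    assert data.true_params is not None
    resid = []
    for c in data.constructs:
        ev = ConstructEvaluator(c, pwms, data.tf_profiles, data.true_params)
        pred = np.asarray(ev.evaluate(data.true_params))
        resid.append(data.observed[c.construct_id].to_numpy() - pred)
    resid = np.concatenate(resid)
    return float(np.sqrt(np.mean(resid**2)))


def run_recovery(
    seed: int = 0,
    optimizer: str = "multistart_local",
    budget: int = 200_000,
    noise_sd: float = 0.075,
) -> RecoveryReport:
    """Run the reduced recovery experiment end to end."""
    data, pwms, start = recovery_problem(seed, noise_sd=noise_sd)
    res = fit(data, pwms, start, optimizer=optimizer, seed=seed, budget=budget)
    true = {n: data.true_params[n] for n in FREE_SUBSET}
    rec = {n: res.params[n] for n in FREE_SUBSET}
    return RecoveryReport(
        recovered=rec,
        true=true,
        rms=res.rms,
        noise_floor_rms=noise_floor(data, pwms),
        n_observations=data.n_observations,
        n_evaluations=res.n_evaluations,
    )
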