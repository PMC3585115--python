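"""From functional occupancies to a transcription rate.

Activators (including coactivated target sites) recruit a composite,
uniformly expressed adapter factor; recruiting contributions are summed with
per-factor strengths ``alpha`` to give the total lowering ``E`` of the
activation energy barrier for transcription initiation.  Quenchers bound
within short range of the transcription start site attenuate this total
(direct repression).  The transcription rate follows a diffusion-limited
Arrhenius law derived from a three-state Markov model of polymerase binding,
stalling and initiation: exponential in ``E`` while the barrier dominates and
saturating at ``R_max`` once polymerase diffusion becomes rate limiting.

Energies are dimensionless (RT = 1); ``theta`` is the remaining barrier at
which the rate is half-maximal under the adopted closed form
``R = R_max * K / (1 + K)`` with ``K = exp(E - theta)``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .interactions import FunctionalOccupancy, RangeFunction, _check_eff

__all__ = [
    "sum_activation",
    "apply_direct_repression",
    "three_state_steady_state",
    "transcription_rate",
    "rate_from_markov",
]


class InvalidRateError(ValueError):
    """A kinetic rate constant was not strictly positive."""


def sum_activation(
    func_occ: FunctionalOccupancy,
    alpha: Mapping[str, float],
    alpha_coact: Mapping[str, float] | None = None,
) -> float:
    """Summed adapter-factor recruitment ``E_raw = sum_i alpha_i * f_act_quenched_i``.

    ``alpha`` maps activator TFs to recruiting strengths; ``alpha_coact``
    supplies the strength used for activator-acting occupancy on
    coactivation-target sites (which are not in ``alpha``).  Activators act at
    any distance between the TSS and the construct boundary, so no range
    function enters here.
    """
    for name, a in {**alpha, **(alpha_coact or {})}.items():
        if a < 0:
            raise ValueError(f"recruiting strength alpha[{name}] must be >= 0")
    f_aq = func_occ.f_act_quenched
    if f_aq is None:
        f_aq = func_occ.f_act
    total = 0.0
    for i, s in enumerate(func_occ.sites):
        if s.tf_id in alpha:
            total += alpha[s.tf_id] * f_aq[i]
        elif alpha_coact and s.tf_id in alpha_coact:
            total += alpha_coact[s.tf_id] * f_aq[i]
    return float(total)


def apply_direct_repression(
    e_raw: float,
    func_occ: FunctionalOccupancy,
    beta_d: Mapping[str, float],
    tss_position: float,
    quench_range: RangeFunction | None = None,
) -> float:
    """Attenuate summed activation by quenchers within range of the TSS.

    ``E_eff = E_raw * prod_j (1 - beta_D(j) * f_quench_j * R(d_j,TSS))``.
    """
    if quench_range is None:
        quench_range = RangeFunction()
    for tf, b in beta_d.items():
        _check_eff(b, f"direct-repression efficiency of {tf}")
    e = float(e_raw)
    for j, s in enumerate(func_occ.sites):
        if s.tf_id not in beta_d or func_occ.f_quench[j] == 0:
            continue
        r = quench_range(abs(s.center - tss_position))
        if r:
            e *= 1.0 - beta_d[s.tf_id] * func_occ.f_quench[j] * r
    return e


def three_state_steady_state(
    k1: float, k_minus1: float, k2: float, k3: float
) -> tuple[float, float, float]:
    """Steady state of the three-state transcription-initiation Markov chain.

    States: (1) no polymerase at the basal promoter; (2) polymerase bound but
    stalled; (3) initiation in progress, blocking new binding.  Transitions:
    1->2 at ``k1``, 2->1 at ``k_minus1``, 2->3 at ``k2``, 3->1 at ``k3``.
    Each entry into state 3 initiates one transcript, so the transcription
    rate is proportional to ``P3``.

    Returns the steady-state probabilities ``(P1, P2, P3)``.
    """
    for name, k in (("k1", k1), ("k_minus1", k_minus1), ("k2", k2), ("k3", k3)):
        if not (k > 0):
            raise InvalidRateError(f"rate {name} must be > 0, got {k}")
    # Balance: k1*P1 = (k_minus1 + k2)*P2 ; k2*P2 = k3*P3 ; sum = 1.
    p2 = 1.0 / (1.0 + (k_minus1 + k2) / k1 + k2 / k3)
    p1 = (k_minus1 + k2) / k1 * p2
    p3 = k2 / k3 * p2
    return p1, p2, p3


def transcription_rate(e_eff: float, theta: float, r_max: float):
    """Diffusion-limited Arrhenius rate ``R = R_max * K / (1 + K)``.

    ``K = exp(E_eff - theta)`` is the Arrhenius term for crossing the residual
    activation barrier.  For ``K << 1`` the rate is exponential in ``E_eff``
    (greater-than-multiplicative synergy between activators); as the barrier
    vanishes the rate saturates at ``R_max`` because delivery of new
    polymerase becomes diffusion limited.  Accepts scalar or array ``e_eff``.
    """
    if r_max <= 0:
        raise ValueError("R_max must be > 0")
    e = np.asarray(e_eff, dtype=float)
    # logistic in energy; use logaddexp for overflow safety
    out = r_max * np.exp(e - theta - np.logaddexp(0.0, e - theta))
    return out if out.ndim else float(out)


def rate_from_markov(
    e_eff: float,
    theta: float,
    r_max: float,
    k1: float = 1.0,
    k_minus1: float = 1.0,
    k3: float = 1.0,
) -> float:
    """Transcription rate from the three-state chain directly.

    The Arrhenius term ``K = exp(E_eff - theta)`` enters through the
    barrier-crossing (initiation) rate, ``k2 = K * k3 (k1 + k_minus1) /
    (k1 + k3)``; the rate is ``R_max * P3 / P3_max`` where ``P3_max`` is the
    diffusion-limited ceiling ``k1 / (k1 + k3)`` reached as the barrier
    vanishes.  With this constant mapping (the default; the kinetic constants
    are configurable) the chain reproduces the closed form
    :func:`transcription_rate` identically, which pins the adopted shape to
    the underlying kinetic model.
    """
    K = float(np.exp(np.clip(e_eff - theta, -700, 700)))
    if K == 0.0:
        return 0.0
    k2 = K * k3 * (k1 + k_minus1) / (k1 + k3)
    _p1, _p2, p3 = three_state_steady_state(k1, k_minus1, k2, k3)
    p3_max = k1 / (k1 + k3)
    return float(r_max * p3 / p3_max)
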