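"""Protein-protein interaction layers: coactivation and short-range quenching.

Physical occupancies from the equilibrium calculation are split into
*functionally* activating and quenching components:

* Activator sites act with their full physical occupancy.
* Quencher (repressor) sites act with their full physical occupancy, unless
  the factor is a coactivation target.
* A coactivation-target site (Hb in the blastoderm) is a bound repressor that
  nearby bound coactivators (Bcd, Cad) convert into an activator.  The
  converted fraction is combined across coactivator sites in saturating
  (complement-product) form, and the activating and repressing components of
  the target are constrained to sum to its physical occupancy.

Short-range quenching then multiplies every activator-acting occupancy by a
survival factor ``(1 - beta_Q * f_quench * R(d))`` per quencher within range;
``R`` is a bounded, non-increasing distance function (trapezoid by default)
and ``d`` the center-to-center distance in bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pwm import BindingSite

__all__ = [
    "RangeFunction",
    "FunctionalOccupancy",
    "range_value",
    "apply_coactivation",
    "apply_quenching",
    "QUENCH_REACH_BP",
]

#: Total reach of short-range repression, set by published quenching data.
QUENCH_REACH_BP = 150.0
#: Fixed width of the linear falloff added on top of a fitted range parameter.
COACT_FALLOFF_BP = 20.0


class InvalidEfficiencyError(ValueError):
    """An interaction efficiency fell outside [0, 1]."""


@dataclass(frozen=True)
class RangeFunction:
    """Bounded distance-dependence of a short-range interaction.

    Value is 1 up to ``r_full`` bp, 0 at and beyond ``r_zero`` bp, and (for
    the trapezoid kind) linear in between.  ``kind='step'`` forces
    ``r_full == r_zero`` semantics (1 below, 0 at and beyond).
    """

    kind: str = "trapezoid"
    r_full: float = 100.0
    r_zero: float = QUENCH_REACH_BP

    def __post_init__(self) -> None:
        if self.kind not in ("step", "trapezoid"):
            raise ValueError(f"unknown range-function kind {self.kind!r}")
        if not (0 <= self.r_full <= self.r_zero):
            raise ValueError("need 0 <= r_full <= r_zero")

    def __call__(self, d) -> np.ndarray | float:
        return range_value(self, d)

    @staticmethod
    def coactivation(r: float, falloff: float = COACT_FALLOFF_BP) -> "RangeFunction":
        """Trapezoid with a single free plateau parameter ``r`` and fixed falloff."""
        return RangeFunction(kind="trapezoid", r_full=r, r_zero=r + falloff)


def range_value(rf: RangeFunction, d) -> np.ndarray | float:
    """Evaluate a range function at distance(s) ``d`` (bp, >= 0)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if rf.kind == "step" or rf.r_zero == rf.r_full:
        out = np.where(d < rf.r_zero, 1.0, 0.0)
        if rf.kind == "trapezoid" and rf.r_zero == rf.r_full:
            out = np.where(d <= rf.r_full, 1.0, 0.0)
    else:
        out = np.clip((rf.r_zero - d) / (rf.r_zero - rf.r_full), 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass
class FunctionalOccupancy:
    """Functional decomposition of physical occupancies (one axis position).

    Arrays are indexed like the site list they were computed from.
    ``f_act + f_quench == f_phys`` holds exactly for every site.
    """

    sites: tuple[BindingSite, ...]
    f_phys: np.ndarray
    f_act: np.ndarray
    f_quench: np.ndarray
    f_act_quenched: np.ndarray | None = None


def _check_eff(beta: float, name: str) -> float:
    if not (0.0 <= beta <= 1.0):
        raise InvalidEfficiencyError(f"{name} must lie in [0, 1], got {beta}")
    return float(beta)


def apply_coactivation(
    sites: Sequence[BindingSite],
    f_phys: Sequence[float] | np.ndarray,
    roles: Mapping[str, str],
    target_tfs: Sequence[str],
    coactivator_eff: Mapping[str, float],
    coactivator_range: Mapping[str, RangeFunction],
) -> FunctionalOccupancy:
    """Split physical occupancies into activating and quenching components.

    For a target site ``i`` the converted fraction is
    ``C_i = 1 - prod_j (1 - beta_co(j) * f_j * R_j(d_ij))`` over coactivator
    sites ``j``; then ``f_act_i = f_phys_i * C_i`` and
    ``f_quench_i = f_phys_i - f_act_i``.
    """
    sites = tuple(sites)
    f_phys = np.asarray(f_phys, dtype=float)
    for tf, b in coactivator_eff.items():
        _check_eff(b, f"coactivation efficiency of {tf}")
    targets = set(target_tfs)
    centers = np.array([s.center for s in sites])

    f_act = np.zeros_like(f_phys)
    f_quench = np.zeros_like(f_phys)
    coact_idx = [
        j for j, s in enumerate(sites) if s.tf_id in coactivator_eff
    ]
    for i, s in enumerate(sites):
        role = roles.get(s.tf_id)
        if role is None:
            raise KeyError(f"no role declared for TF {s.tf_id!r}")
        if s.tf_id in targets:
            survive = 1.0
            for j in coact_idx:
                if j == i:
                    continue
                cj = sites[j]
                beta = coactivator_eff[cj.tf_id]
                r = coactivator_range[cj.tf_id](abs(centers[i] - centers[j]))
                survive *= 1.0 - beta * f_phys[j] * r
            C = 1.0 - survive
            f_act[i] = f_phys[i] * C
            f_quench[i] = f_phys[i] - f_act[i]
        elif role == "activator":
            f_act[i] = f_phys[i]
        else:  # plain quencher
            f_quench[i] = f_phys[i]
    return FunctionalOccupancy(sites=sites, f_phys=f_phys, f_act=f_act, f_quench=f_quench)


def apply_quenching(
    func_occ: FunctionalOccupancy,
    beta_q: Mapping[str, float],
    quench_range: RangeFunction | None = None,
) -> FunctionalOccupancy:
    """Attenuate activator-acting occupancies by nearby quenchers.

    ``f_act_quenched_i = f_act_i * prod_j (1 - beta_Q(j) * f_quench_j * R(d_ij))``
    over quencher-acting sites ``j != i`` within range.  Sites beyond the
    range function's ``r_zero`` have exactly zero influence.
    """
    if quench_range is None:
        quench_range = RangeFunction()
    for tf, b in beta_q.items():
        _check_eff(b, f"quenching efficiency of {tf}")
    sites = func_occ.sites
    centers = np.array([s.center for s in sites])
    f_aq = func_occ.f_act.copy()
    quench_idx = [
        j for j, s in enumerate(sites)
        if s.tf_id in beta_q and func_occ.f_quench[j] > 0
    ]
    for i in range(len(sites)):
        if f_aq[i] == 0:
            continue
        for j in quench_idx:
            if j == i:
                continue
            r = quench_range(abs(centers[i] - centers[j]))
            if r == 0:
                continue
            f_aq[i] *= 1.0 - beta_q[sites[j].tf_id] * func_occ.f_quench[j] * r
    return FunctionalOccupancy(
        sites=sites,
        f_phys=func_occ.f_phys,
        f_act=func_occ.f_act,
        f_quench=func_occ.f_quench,
        f_act_quenched=f_aq,
    )
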