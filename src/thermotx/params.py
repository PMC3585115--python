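"""Free-parameter bookkeeping for the transcription model.

The full model over the nine-factor blastoderm roster carries, per factor, a
concentration scale ``D`` and a score-to-energy constant ``lambda``; per
activator a recruiting strength ``alpha``; per repressor quenching and
direct-repression efficiencies ``beta_Q`` and ``beta_D``; a single
cooperativity factor ``omega`` for Bcd; per coactivator (Bcd, Cad) a
coactivation efficiency and range acting on Hb; a recruiting strength for
coactivated Hb; the activation barrier ``theta``; a free PWM threshold for
every factor whose footprint data do not pin it (all but Bcd and Hb); and a
position-effect scale for every construct not integrated at the common
landing site.  Under the default configuration (4 activators, 5 repressors,
3 non-targeted constructs) this yields

    10 + 4*3 + 5*4 + 1 + 4 + 1 + 1 = 49

free parameters, the 10 being the position-effect scales and free thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .interactions import QUENCH_REACH_BP, RangeFunction
from .pwm import TFConfig

__all__ = [
    "Param",
    "ModelConfig",
    "ModelParams",
    "default_config",
    "count_free_parameters",
]

#: Default nine-factor roster: name -> (role, footprint bp)
DEFAULT_ROSTER: dict[str, tuple[str, int]] = {
    "bcd": ("activator", 14),
    "cad": ("activator", 14),
    "dst": ("activator", 14),
    "dic": ("activator", 14),
    "kr": ("quencher", 14),
    "kni": ("quencher", 14),
    "gt": ("quencher", 24),
    "tll": ("quencher", 14),
    "hb": ("quencher", 14),
}

#: Factors whose binding thresholds independent footprint data fix outright.
FIXED_THRESHOLD_TFS = ("bcd", "hb")

#: Coactivation range search bounds (bp): experimental constraints for Bcd,
#: unconstrained search interval for Cad.
COACT_RANGE_BOUNDS = {"bcd": (150.0, 200.0), "cad": (10.0, 200.0)}


class InvalidConfigError(ValueError):
    """Model configuration is inconsistent or incomplete."""


@dataclass
class Param:
    """One model parameter with bounds, free/fixed flag and search scale."""

    name: str
    value: float
    lo: float = 0.0
    hi: float = np.inf
    free: bool = True
    scale: str = "linear"  # 'linear' | 'log'

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise InvalidConfigError(f"{self.name}: bound lo > hi")
        if self.scale not in ("linear", "log"):
            raise InvalidConfigError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "log" and self.free and self.lo <= 0:
            raise InvalidConfigError(f"{self.name}: log-scaled bound must be > 0")


@dataclass
class ModelConfig:
    """Structural configuration: TF roles, coactivation wiring, constructs."""

    tfs: dict[str, TFConfig]
    coactivators: dict[str, str] = field(default_factory=dict)  # coactivator -> target
    construct_ids: tuple[str, ...] = ()
    targeted: dict[str, bool] = field(default_factory=dict)  # construct -> landing-site flag
    quench_range: RangeFunction = field(default_factory=RangeFunction)
    coact_falloff_bp: float = 20.0
    r_max_free: bool = False

    @property
    def activators(self) -> list[str]:
        return [t for t, c in self.tfs.items() if c.role == "activator"]

    @property
    def repressors(self) -> list[str]:
        return [t for t, c in self.tfs.items() if c.role == "quencher"]

    @property
    def coactivation_targets(self) -> list[str]:
        return [t for t, c in self.tfs.items() if c.is_coactivation_target]

    def validate(self) -> None:
        for co, target in self.coactivators.items():
            if co not in self.tfs:
                raise InvalidConfigError(f"coactivator {co!r} not in roster")
            if target not in self.tfs:
                raise InvalidConfigError(f"coactivation target {target!r} not in roster")
            if not self.tfs[target].is_coactivation_target:
                raise InvalidConfigError(
                    f"{target!r} is wired as a coactivation target but not flagged"
                )


def default_config(
    construct_ids: tuple[str, ...] = (
        "m3_2", "m32", "m2_3", "m23", "mse2", "mse3", "c1700",
    ),
    targeted: dict[str, bool] | None = None,
) -> ModelConfig:
    """The standard configuration: nine factors, Hb coactivated by Bcd/Cad.

    The four fusion constructs share a targeted landing site (position-effect
    scale fixed at 1); the three additional constructs each get a free scale.
    """
    tfs: dict[str, TFConfig] = {}
    for tf, (role, fp) in DEFAULT_ROSTER.items():
        tfs[tf] = TFConfig(
            tf_id=tf,
            role=role,
            footprint_size_bp=fp,
            is_cooperative=(tf == "bcd"),
            cooperativity_range_bp=60 if tf == "bcd" else None,
            is_coactivation_target=(tf == "hb"),
            coactivators=["bcd", "cad"] if tf == "hb" else [],
        )
    if targeted is None:
        targeted = {
            c: c in ("m3_2", "m32", "m2_3", "m23") for c in construct_ids
        }
    cfg = ModelConfig(
        tfs=tfs,
        coactivators={"bcd": "hb", "cad": "hb"},
        construct_ids=tuple(construct_ids),
        targeted=targeted,
    )
    cfg.validate()
    return cfg


def _default_params(config: ModelConfig) -> list[Param]:
    params: list[Param] = []
    for tf, tfc in config.tfs.items():
        params.append(Param(f"D_{tf}", 1.0, 1e-3, 1e3, True, "log"))
        params.append(Param(f"lambda_{tf}", 1.0, 0.05, 5.0, True, "linear"))
        if tfc.role == "activator":
            params.append(Param(f"alpha_{tf}", 1.0, 0.0, 50.0, True, "linear"))
        else:
            params.append(Param(f"beta_q_{tf}", 0.5, 0.0, 1.0, True, "linear"))
            params.append(Param(f"beta_d_{tf}", 0.5, 0.0, 1.0, True, "linear"))
        free_thr = tf not in FIXED_THRESHOLD_TFS
        params.append(Param(f"threshold_{tf}", 0.0, -2.0, 8.0, free_thr, "linear"))
    for tf, tfc in config.tfs.items():
        if tfc.is_cooperative:
            params.append(Param(f"omega_{tf}", 2.0, 1.0, 100.0, True, "linear"))
    for co, target in config.coactivators.items():
        lo, hi = COACT_RANGE_BOUNDS.get(co, (10.0, 200.0))
        params.append(Param(f"coact_eff_{co}", 0.5, 0.0, 1.0, True, "linear"))
        params.append(Param(f"coact_range_{co}", 0.5 * (lo + hi), lo, hi, True, "linear"))
    for target in config.coactivation_targets:
        params.append(Param(f"alpha_coact_{target}", 1.0, 0.0, 50.0, True, "linear"))
    params.append(Param("theta", 3.0, 0.0, 20.0, True, "linear"))
    params.append(Param("R_max", 255.0, 1.0, 1e4, config.r_max_free, "log"))
    for c in config.construct_ids:
        free = not config.targeted.get(c, True)
        params.append(Param(f"pos_scale_{c}", 1.0, 1e-2, 1e2, free, "log"))
    return params


@dataclass
class ModelParams:
    """The complete parameter vector for a model configuration.

    Access values with ``[]``; flip fixed/free flags with :meth:`fix` /
    :meth:`release`; export/import the free subvector (on search scale) with
    :meth:`free_vector` / :meth:`with_free_vector` for the optimizer.
    """

    config: ModelConfig
    entries: dict[str, Param] = field(default_factory=dict)

    @classmethod
    def defaults(cls, config: ModelConfig | None = None) -> "ModelParams":
        config = config or default_config()
        return cls(config=config, entries={p.name: p for p in _default_params(config)})

    # -- mapping-style access ------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.entries[name].value

    def __setitem__(self, name: str, value: float) -> None:
        p = self.entries[name]
        self.entries[name] = replace(p, value=float(value))

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def get(self, name: str, default: float = 0.0) -> float:
        return self.entries[name].value if name in self.entries else default

    # -- fixed/free management ----------------------------------------------
    def fix(self, *names: str, at: float | None = None) -> "ModelParams":
        for n in names:
            p = self.entries[n]
            self.entries[n] = replace(
                p, free=False, value=p.value if at is None else float(at)
            )
        return self

    def release(self, *names: str) -> "ModelParams":
        for n in names:
            self.entries[n] = replace(self.entries[n], free=True)
        return self

    def fix_all_except(self, *names: str) -> "ModelParams":
        keep = set(names)
        for n, p in self.entries.items():
            self.entries[n] = replace(p, free=n in keep)
        return self

    @property
    def free_names(self) -> list[str]:
        return [n for n, p in self.entries.items() if p.free]

    # -- optimizer interface -------------------------------------------------
    def _to_search(self, p: Param, v: float) -> float:
        return float(np.log(v)) if p.scale == "log" else float(v)

    def _from_search(self, p: Param, x: float) -> float:
        return float(np.exp(x)) if p.scale == "log" else float(x)

    def free_vector(self) -> np.ndarray:
        return np.array(
            [self._to_search(p, p.value) for p in self.entries.values() if p.free]
        )

    def free_bounds(self) -> list[tuple[float, float]]:
        return [
            (self._to_search(p, p.lo), self._to_search(p, p.hi))
            for p in self.entries.values()
            if p.free
        ]

    def with_free_vector(self, x: np.ndarray) -> "ModelParams":
        out = self.copy()
        i = 0
        for n, p in self.entries.items():
            if p.free:
                v = self._from_search(p, float(x[i]))
                v = min(max(v, p.lo), p.hi)
                out.entries[n] = replace(p, value=v)
                i += 1
        if i != len(x):
            raise ValueError("free vector length mismatch")
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            config=self.config, entries={n: replace(p) for n, p in self.entries.items()}
        )

    # -- grouped views used by the evaluator ---------------------------------
    def d_scales(self) -> dict[str, float]:
        return {tf: self[f"D_{tf}"] for tf in self.config.tfs}

    def lambdas(self) -> dict[str, float]:
        return {tf: self[f"lambda_{tf}"] for tf in self.config.tfs}

    def thresholds(self) -> dict[str, float]:
        return {tf: self[f"threshold_{tf}"] for tf in self.config.tfs}

    def alphas(self) -> dict[str, float]:
        return {tf: self[f"alpha_{tf}"] for tf in self.config.activators}

    def alpha_coact(self) -> dict[str, float]:
        return {
            t: self[f"alpha_coact_{t}"] for t in self.config.coactivation_targets
        }

    def betas_q(self) -> dict[str, float]:
        return {tf: self[f"beta_q_{tf}"] for tf in self.config.repressors}

    def betas_d(self) -> dict[str, float]:
        return {tf: self[f"beta_d_{tf}"] for tf in self.config.repressors}

    def omega(self, tf: str = "bcd") -> float:
        return self.get(f"omega_{tf}", 1.0)

    def coactivator_eff(self) -> dict[str, float]:
        return {co: self[f"coact_eff_{co}"] for co in self.config.coactivators}

    def coactivator_range(self) -> dict[str, RangeFunction]:
        return {
            co: RangeFunction.coactivation(
                self[f"coact_range_{co}"], self.config.coact_falloff_bp
            )
            for co in self.config.coactivators
        }


def count_free_parameters(
    params: ModelParams | ModelConfig,
    subset: str | None = None,
) -> int:
    """Number of free parameters, optionally restricted to a named subset.

    ``subset='position_threshold'`` counts only position-effect scales and PWM
    thresholds (the standard configuration gives 10: three non-targeted
    constructs plus seven factors with unpinned thresholds).
    """
    if isinstance(params, ModelConfig):
        params = ModelParams.defaults(params)
    names = params.free_names
    if subset is None:
        return len(names)
    if subset == "position_threshold":
        return sum(
            1 for n in names if n.startswith(("pos_scale_", "threshold_"))
        )
    raise InvalidConfigError(f"unknown subset {subset!r}")
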