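"""Synthetic data generation: toy PWMs, planted constructs, profiles, datasets.

Everything the pipeline consumes can be generated deterministically from a
seed, emulating the structure of the quantitative blastoderm dataset the
model is designed for: a 58-point anterior-posterior grid spanning 35-92% egg
length, nine factor concentration profiles (an anterior exponential gradient,
a posterior gradient, five bell-shaped gap-gene-like domains, two broad
activators), reporter constructs with planted binding-site architectures
including fusion/spacer variants, and noisy observed expression produced by
forward simulation of the model itself.

The fixtures are mechanistic test articles, not biological mimics: profile
shapes are idealized, sequences are random background with planted motifs,
and noise is position-independent multiplicative Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import TrainingSet
from .params import ModelConfig, ModelParams, default_config
from .pipeline import Construct, ConstructEvaluator
from .pwm import PWM, build_pwm, reverse_complement, scan_sequence

__all__ = [
    "SyntheticSpec",
    "PlantedConstruct",
    "toy_pwms",
    "generate_profiles",
    "generate_construct",
    "excise_spacer",
    "simulate_dataset",
    "demo_constructs",
    "demo_training_set",
]

#: Distinct 10-mer consensi.  Every ordered pair -- including each motif
#: against itself and against reverse complements, at alignment shifts of up
#: to 2 bp -- differs in at least 3 overlap positions, so a planted motif
#: (even carrying one engineered mismatch) can never deterministically
#: trigger another matrix, another offset, or the opposite strand at the
#: default one-mismatch threshold; random background rarely triggers
#: anything.
_CONSENSI = {
    "bcd": "TCGGAAAGGT",
    "cad": "GATTGGAACC",
    "dst": "ATCGACAGTA",
    "dic": "GACAGCCCCC",
    "kr": "GTCAAAAAAG",
    "kni": "TTGGCTGGGT",
    "gt": "CCGCTCAAAG",
    "tll": "CCGAGGAACC",
    "hb": "GCACTCGCTC",
}

#: Score drop per planted mismatch for the toy count matrices
#: (log 51, from counts 50/0 with pseudocount 1).
MISMATCH_DROP = float(np.log(51.0))

_PROFILE_SHAPES: dict[str, dict] = {
    "bcd": {"kind": "gradient_anterior", "length_pct": 16.0, "amplitude": 1.0},
    "cad": {"kind": "gradient_posterior", "center": 60.0, "width": 8.0, "amplitude": 1.0},
    "hb": {"kind": "step_plus_bump", "edge": 48.0, "width": 3.0, "bump_center": 88.0,
           "bump_width": 3.0, "amplitude": 1.0},
    "kr": {"kind": "bump", "center": 52.0, "width": 8.0, "amplitude": 1.0},
    "kni": {"kind": "bump", "center": 67.0, "width": 7.0, "amplitude": 1.0},
    "gt": {"kind": "bump", "center": 78.0, "width": 6.0, "amplitude": 1.0},
    "tll": {"kind": "bump", "center": 90.0, "width": 5.0, "amplitude": 1.0},
    "dst": {"kind": "bump", "center": 58.0, "width": 25.0, "amplitude": 0.6},
    "dic": {"kind": "bump", "center": 65.0, "width": 22.0, "amplitude": 0.6},
}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic dataset.

    Defaults mirror the training conditions the model targets: 58 axis
    positions over 35-92% egg length, nine factors, and multiplicative
    observation noise with relative sd 0.075 (inside the 5-10% accuracy of
    the quantitative expression data being emulated).
    """

    n_positions: int = 58
    ap_min: float = 35.0
    ap_max: float = 92.0
    shapes: dict[str, dict] = field(default_factory=lambda: {
        tf: dict(s) for tf, s in _PROFILE_SHAPES.items()
    })
    noise_sd: float = 0.075
    seed: int = 0

    def grid(self) -> np.ndarray:
        g = np.linspace(self.ap_min, self.ap_max, self.n_positions)
        if self.n_positions < 1 or not np.all(np.diff(g) > 0):
            raise ValueError("invalid axis grid")
        return g


@dataclass
class PlantedConstruct:
    """A construct with known planted sites and declared spacer segments."""

    construct: Construct
    planted: list[tuple[str, int, int]]  # (tf, offset, mismatch tier)
    spacers: list[tuple[int, int]] = field(default_factory=list)  # half-open bp


def toy_pwms(pseudocount: float = 1.0) -> dict[str, PWM]:
    """Sharp count-matrix PWMs for the nine-factor synthetic roster.

    Counts are 50 for the consensus base and 0 otherwise, so with the default
    pseudocount every mismatch costs ``log 51`` score units and the consensus
    scores ``width * log(51/13.5)``.
    """
    pwms = {}
    for tf, cons in _CONSENSI.items():
        counts = np.zeros((len(cons), 4))
        for i, b in enumerate(cons):
            counts[i, "ACGT".index(b)] = 50.0
        pwms[tf] = build_pwm(counts, pseudocount=pseudocount, tf_id=tf)
    return pwms


def synthetic_thresholds(pwms: dict[str, PWM], max_mismatches: int = 1) -> dict[str, float]:
    """Thresholds admitting planted sites up to ``max_mismatches`` and little else."""
    return {
        tf: p.max_score - (max_mismatches + 0.5) * MISMATCH_DROP
        for tf, p in pwms.items()
    }


def _shape_values(x: np.ndarray, shape: dict) -> np.ndarray:
    kind = shape["kind"]
    amp = float(shape.get("amplitude", 1.0))
    if amp < 0:
        raise ValueError("profile amplitude must be >= 0")
    if kind == "gradient_anterior":
        ln = float(shape["length_pct"])
        if ln <= 0:
            raise ValueError("gradient length must be > 0")
        return amp * np.exp(-(x - x.min()) / ln)
    if kind == "gradient_posterior":
        w = float(shape["width"])
        if w <= 0:
            raise ValueError("gradient width must be > 0")
        return amp / (1.0 + np.exp(-(x - shape["center"]) / w))
    if kind == "bump":
        w = float(shape["width"])
        if w <= 0:
            raise ValueError("bump width must be > 0")
        return amp * np.exp(-0.5 * ((x - shape["center"]) / w) ** 2)
    if kind == "step_plus_bump":
        w, bw = float(shape["width"]), float(shape["bump_width"])
        if w <= 0 or bw <= 0:
            raise ValueError("widths must be > 0")
        step = 1.0 / (1.0 + np.exp((x - shape["edge"]) / w))
        bump = np.exp(-0.5 * ((x - shape["bump_center"]) / bw) ** 2)
        return amp * (step + bump)
    raise ValueError(f"unknown profile shape kind {kind!r}")


def generate_profiles(spec: SyntheticSpec) -> pd.DataFrame:
    """Noise-free factor concentration profiles on the spec's axis grid.

    Fully determined by the spec (the seed only matters for observation
    noise, not for the underlying signals).
    """
    x = spec.grid()
    data = {tf: _shape_values(x, shape) for tf, shape in spec.shapes.items()}
    df = pd.DataFrame(data, index=pd.Index(x, name="position_pct_el"))
    if (df.to_numpy() < 0).any():
        raise ValueError("profiles must be non-negative")
    return df


class LayoutError(ValueError):
    """Planted motifs collide although overlap was not requested."""


def _plant(seq: list[str], motif: str, offset: int) -> None:
    seq[offset : offset + len(motif)] = list(motif)


def _mutate(cons: str, tier: int, rng: np.random.Generator) -> str:
    """Introduce ``tier`` mismatches at deterministic random positions."""
    if tier == 0:
        return cons
    s = list(cons)
    pos = rng.choice(len(s), size=tier, replace=False)
    for p in pos:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


def generate_construct(
    architecture: list[tuple[str, int, int]],
    length: int,
    seed: int = 0,
    construct_id: str = "synthetic",
    tss_position: int | None = None,
    spacers: list[tuple[int, int]] | None = None,
    pwms: dict[str, PWM] | None = None,
    thresholds: dict[str, float] | None = None,
    allow_overlap: bool = False,
    gc: float = 0.5,
    max_redraws: int = 50,
) -> PlantedConstruct:
    """Random-background sequence with planted degenerate motifs.

    ``architecture`` lists (tf, offset, mismatch tier); tier 0 plants the
    consensus, tier k plants k mismatches (a controlled affinity rung).  The
    background is redrawn (deterministically, from the same seed stream)
    until scanning at the synthetic thresholds recovers exactly the planted
    sites, so stray background matches cannot contaminate the architecture.
    """
    pwms = pwms or toy_pwms()
    thresholds = thresholds or synthetic_thresholds(pwms)
    rng = np.random.default_rng(seed)

    arch = sorted(architecture, key=lambda a: a[1])
    if not allow_overlap:
        prev_end = -1
        for tf, off, _tier in arch:
            w = pwms[tf].width
            if off < 0 or off + w > length:
                raise LayoutError(f"site {tf}@{off} falls outside the construct")
            if off < prev_end:
                raise LayoutError(
                    f"planted motifs collide at offset {off} (overlap not requested)"
                )
            prev_end = off + w

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    planted_motifs = [
        (tf, off, tier, _mutate(_CONSENSI[tf], tier, rng)) for tf, off, tier in arch
    ]
    for _ in range(max_redraws):
        seq = list(rng.choice(list("ACGT"), size=length, p=p))
        for tf, off, _tier, motif in planted_motifs:
            _plant(seq, motif, off)
        s = "".join(seq)
        ok = True
        for tf, pwm in pwms.items():
            hits = {
                h.start
                for h in scan_sequence(s, pwm, thresholds[tf], lam=1.0)
            }
            expect = {off for t2, off, _tier, _m in planted_motifs if t2 == tf}
            if hits != expect:
                ok = False
                break
        if ok:
            return PlantedConstruct(
                construct=Construct(
                    construct_id=construct_id,
                    sequence=s,
                    tss_position=length if tss_position is None else tss_position,
                ),
                planted=[(tf, off, tier) for tf, off, tier in arch],
                spacers=list(spacers or []),
            )
    raise LayoutError(
        "could not draw a background free of stray matches; "
        "loosen thresholds or shorten the construct"
    )


def excise_spacer(pc: PlantedConstruct, interval: tuple[int, int],
                  construct_id: str | None = None) -> PlantedConstruct:
    """Delete a declared spacer; downstream coordinates shift left exactly.

    Planted sites inside the excised interval are dropped.
    """
    a, b = interval
    seq = pc.construct.sequence
    if not (0 <= a < b <= len(seq)):
        raise ValueError("interval outside construct")
    shift = b - a
    new_seq = seq[:a] + seq[b:]
    tss = pc.construct.tss_position
    new_tss = tss - shift if tss >= b else (a if a <= tss < b else tss)
    planted = []
    for tf, off, tier in pc.planted:
        if off >= b:
            planted.append((tf, off - shift, tier))
        elif off + len(_CONSENSI[tf]) <= a:
            planted.append((tf, off, tier))
        # sites inside the spacer disappear with it
    return PlantedConstruct(
        construct=Construct(
            construct_id=construct_id or pc.construct.construct_id + "_fused",
            sequence=new_seq,
            tss_position=new_tss,
        ),
        planted=planted,
        spacers=[s for s in pc.spacers if s != interval],
    )


def simulate_dataset(
    constructs: list[Construct],
    tf_profiles: pd.DataFrame,
    true_params: ModelParams,
    pwms: dict[str, PWM] | None = None,
    noise_sd: float = 0.075,
    seed: int = 0,
) -> TrainingSet:
    """Forward-simulate observed expression: ``pred * (1 + eps)``, clipped at 0.

    ``eps`` is i.i.d. Gaussian with the given relative sd.  The generating
    parameters ride along on the returned training set for recovery tests.
    """
    pwms = pwms or toy_pwms()
    rng = np.random.default_rng(seed)
    obs = {}
    for c in constructs:
        ev = ConstructEvaluator(c, pwms, tf_profiles, true_params)
        pred = np.asarray(ev.evaluate(true_params))
        eps = rng.normal(scale=noise_sd, size=pred.shape) if noise_sd > 0 else 0.0
        obs[c.construct_id] = np.clip(pred * (1.0 + eps), 0.0, None)
    observed = pd.DataFrame(obs, index=tf_profiles.index)
    return TrainingSet(
        constructs=list(constructs),
        tf_profiles=tf_profiles,
        observed=observed,
        true_params=true_params,
    )


# ---------------------------------------------------------------------------
# ready-made fixture set emulating the fusion-construct experiment
# ---------------------------------------------------------------------------

#: Stripe-2-like element: paired cooperative anterior-activator sites, a
#: central-repressor quencher between them and near the 3' end.
_EL2 = [
    ("bcd", 20, 0),
    ("kr", 45, 0),
    ("bcd", 70, 1),  # 50 bp center-to-center from the first: cooperative pair
    ("dst", 150, 0),
    ("kr", 200, 1),
]
_EL2_LEN = 240

#: Stripe-3-like element: posterior activator, coactivation-target sites and
#: their repressors.
_EL3 = [
    ("gt", 15, 0),
    ("hb", 70, 0),
    ("cad", 120, 0),
    ("hb", 170, 1),
    ("kni", 215, 0),
]
_EL3_LEN = 250


def _offset_arch(arch, delta):
    return [(tf, off + delta, tier) for tf, off, tier in arch]


def demo_constructs(seed: int = 0, spacer_len: int = 172,
                    pwms: dict[str, PWM] | None = None) -> list[PlantedConstruct]:
    """Seven planted constructs emulating the fusion/spacer training design.

    Element A (stripe-2-like) and element B (stripe-3-like) appear alone, as
    direct fusions in both orders, and separated by a neutral spacer, plus a
    longer composite; the spacer variants move coactivator-target distances
    across the coactivation range exactly as the fusion experiment does.
    """
    pwms = pwms or toy_pwms()
    out = []

    def build(name, arch, length, spacers=(), s=0):
        out.append(
            generate_construct(
                arch, length, seed=seed * 101 + s, construct_id=name,
                spacers=list(spacers), pwms=pwms,
            )
        )

    # element B 5' of element A (B..A..TSS), direct fusion and spacer variant
    fuse_arch = _offset_arch(_EL3, 0) + _offset_arch(_EL2, _EL3_LEN)
    build("m32", fuse_arch, _EL3_LEN + _EL2_LEN, s=1)
    spaced_arch = _offset_arch(_EL3, 0) + _offset_arch(_EL2, _EL3_LEN + spacer_len)
    build(
        "m3_2", spaced_arch, _EL3_LEN + spacer_len + _EL2_LEN,
        spacers=[(_EL3_LEN, _EL3_LEN + spacer_len)], s=2,
    )
    # reverse order
    fuse_rev = _offset_arch(_EL2, 0) + _offset_arch(_EL3, _EL2_LEN)
    build("m23", fuse_rev, _EL2_LEN + _EL3_LEN, s=3)
    spaced_rev = _offset_arch(_EL2, 0) + _offset_arch(_EL3, _EL2_LEN + spacer_len)
    build(
        "m2_3", spaced_rev, _EL2_LEN + spacer_len + _EL3_LEN,
        spacers=[(_EL2_LEN, _EL2_LEN + spacer_len)], s=4,
    )
    # single elements and a longer composite
    build("mse2", _EL2, _EL2_LEN, s=5)
    build("mse3", _EL3, _EL3_LEN, s=6)
    long_arch = _offset_arch(_EL3, 30) + _offset_arch(_EL2, _EL3_LEN + 300)
    build("c1700", long_arch, _EL3_LEN + 300 + _EL2_LEN + 60, s=7)
    return out


def demo_true_params(config: ModelConfig | None = None) -> ModelParams:
    """Generating parameter values for forward simulation of the fixture set."""
    pwms = toy_pwms()
    thr = synthetic_thresholds(pwms)
    params = ModelParams.defaults(config or default_config())
    for tf in params.config.tfs:
        params[f"D_{tf}"] = 5.0
        params[f"lambda_{tf}"] = 0.4
        params[f"threshold_{tf}"] = thr[tf]
    for tf in params.config.activators:
        params[f"alpha_{tf}"] = 3.0
    params["alpha_bcd"] = 5.0
    for tf in params.config.repressors:
        params[f"beta_q_{tf}"] = 0.8
        params[f"beta_d_{tf}"] = 0.5
    params["omega_bcd"] = 5.0
    params["coact_eff_bcd"] = 0.8
    params["coact_range_bcd"] = 160.0
    params["coact_eff_cad"] = 0.6
    params["coact_range_cad"] = 60.0
    params["alpha_coact_hb"] = 4.0
    params["theta"] = 6.0
    params["R_max"] = 255.0
    for c in params.config.construct_ids:
        params[f"pos_scale_{c}"] = 1.0 if params.config.targeted.get(c, True) else 1.3
    return params


def demo_training_set(
    seed: int = 0,
    noise_sd: float = 0.075,
    construct_ids: tuple[str, ...] | None = None,
) -> TrainingSet:
    """Forward-simulated training set over the seven demo constructs.

    With the defaults this yields 58 positions x 7 constructs = 406
    observations, matching the bookkeeping of the design being emulated.
    """
    planted = demo_constructs(seed=seed)
    if construct_ids is not None:
        planted = [p for p in planted if p.construct.construct_id in construct_ids]
    ids = tuple(p.construct.construct_id for p in planted)
    config = default_config(construct_ids=ids, targeted={
        c: c in ("m3_2", "m32", "m2_3", "m23") for c in ids
    })
    params = demo_true_params(config)
    spec = SyntheticSpec(seed=seed, noise_sd=noise_sd)
    profiles = generate_profiles(spec)
    return simulate_dataset(
        [p.construct for p in planted], profiles, params,
        pwms=toy_pwms(), noise_sd=noise_sd, seed=seed,
    )
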