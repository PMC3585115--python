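"""Position-weight matrices, site scanning and affinity conversion.

A PWM is built from a count matrix (observed bases at each position of an
aligned site collection).  Counts are regularized with a pseudocount,
normalized to per-position base probabilities ``b`` and converted to log-odds
against a background base composition ``p``::

    logodds[i, beta] = log(b[i, beta] / p[beta])

The score of a DNA window is the sum of per-position log-odds and is
proportional to the free energy of binding; the relative affinity of a site
with score ``S`` is ``K = exp(lam * (S - S_max))`` where ``S_max`` is the
score of the consensus sequence and ``lam`` scales score to energy units.
Windows on both strands scoring above a per-factor threshold become binding
sites with a steric footprint at least as wide as the factor's physical
footprint on DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "PWM",
    "BindingSite",
    "TFConfig",
    "build_pwm",
    "score_to_affinity",
    "scan_sequence",
    "evaluate_pwm",
    "reverse_complement",
]


class DegenerateColumnError(ValueError):
    """A count column sums to zero and no pseudocount rescues it."""


class InvalidBackgroundError(ValueError):
    """Background base frequencies must be strictly positive."""


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside the IUPAC DNA alphabet."""


class InconsistentScoreError(ValueError):
    """A score exceeding the PWM maximum was supplied."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Log-odds matrix for one transcription factor.

    Attributes
    ----------
    tf_id : str
        Factor name.
    logodds : ndarray, shape (width, 4)
        Per-position log-odds scores, base order A, C, G, T.
    background : ndarray, shape (4,)
        Expected base frequencies (sum to 1).
    pseudocount : float
        Regularizer added per cell at construction.
    """

    tf_id: str
    logodds: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        lo = np.asarray(self.logodds, dtype=float)
        if lo.ndim != 2 or lo.shape[1] != 4 or lo.shape[0] < 1:
            raise ValueError("logodds must be a width x 4 matrix with width >= 1")
        if not np.all(np.isfinite(lo)):
            raise ValueError("logodds entries must be finite")
        object.__setattr__(self, "logodds", lo)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))

    @property
    def width(self) -> int:
        return self.logodds.shape[0]

    @property
    def max_score(self) -> float:
        """Score of the consensus sequence (sum of per-column maxima)."""
        return float(self.logodds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.logodds.argmax(axis=1))

    def score(self, window: str) -> float:
        """Score one window of length ``width`` (forward strand)."""
        if len(window) != self.width:
            raise ValueError("window length must equal PWM width")
        total = 0.0
        for i, base in enumerate(window.upper()):
            j = _BASE_INDEX.get(base)
            if j is None:
                return float("-inf")
            total += self.logodds[i, j]
        return total


@dataclass(frozen=True)
class BindingSite:
    """A scored PWM match on a construct (forward-strand coordinates)."""

    tf_id: str
    start: int
    end: int  # half-open
    strand: str  # '+' or '-'
    score: float
    rel_affinity: float
    footprint_start: int
    footprint_end: int

    @property
    def center(self) -> float:
        """Center of the match interval, in bp."""
        return 0.5 * (self.start + self.end)


@dataclass
class TFConfig:
    """Role and scanning configuration for one transcription factor."""

    tf_id: str
    role: str  # 'activator' | 'quencher'
    footprint_size_bp: int = 14
    threshold: float = 0.0
    is_cooperative: bool = False
    cooperativity_range_bp: int | None = None
    is_coactivation_target: bool = False
    coactivators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("activator", "quencher"):
            raise ValueError(f"unknown role {self.role!r} for TF {self.tf_id}")
        if self.is_coactivation_target and self.role != "quencher":
            raise ValueError("a coactivation target must have role 'quencher'")
        if self.is_cooperative and self.cooperativity_range_bp is None:
            raise ValueError("cooperative TFs must declare a pairing range")


def build_pwm(
    counts: Sequence[Sequence[float]] | np.ndarray,
    background: Sequence[float] | np.ndarray | None = None,
    pseudocount: float = 1.0,
    tf_id: str = "tf",
) -> PWM:
    """Build a log-odds PWM from a width x 4 count matrix.

    Parameters
    ----------
    counts : array-like, shape (width, 4)
        Observed base counts per position, base order A, C, G, T.
    background : array-like, shape (4,), optional
        Expected base frequencies; uniform 0.25 by default.
    pseudocount : float
        Added to every cell before normalization.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be a width x 4 matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise InvalidBackgroundError("background frequencies must be strictly positive")

    reg = counts + pseudocount
    col_tot = reg.sum(axis=1, keepdims=True)
    if np.any(col_tot == 0):
        raise DegenerateColumnError(
            "count column sums to zero; supply a positive pseudocount"
        )
    probs = reg / col_tot
    with np.errstate(divide="ignore"):
        logodds = np.log(probs) - np.log(background)
    if not np.all(np.isfinite(logodds)):
        raise DegenerateColumnError(
            "zero probability cell with zero pseudocount yields -inf log-odds"
        )
    return PWM(tf_id=tf_id, logodds=logodds, background=background, pseudocount=pseudocount)


def score_to_affinity(score: float, pwm: PWM, lam: float) -> float:
    """Relative binding affinity ``K = exp(lam * (score - max_score))``.

    ``K`` is 1 for the consensus site and decreases exponentially with the
    score deficit; ``lam`` is the proportionality constant between PWM score
    and binding free energy.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if score > pwm.max_score + 1e-9:
        raise InconsistentScoreError(
            f"score {score} exceeds max_score {pwm.max_score}"
        )
    return float(np.exp(lam * (min(score, pwm.max_score) - pwm.max_score)))


def _window_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Scores of all forward-strand windows; windows with non-ACGT bases -> -inf."""
    n, w = len(seq), pwm.width
    if n < w:
        return np.empty(0)
    idx = np.fromiter((_BASE_INDEX.get(b, 4) for b in seq), dtype=np.int8, count=n)
    # pad logodds with a -inf column for unknown bases
    lo = np.hstack([pwm.logodds, np.full((w, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    scores = lo[np.arange(w), windows].sum(axis=1)
    return scores


def scan_sequence(
    seq: str,
    pwm: PWM,
    threshold: float,
    lam: float,
    footprint_size_bp: int | None = None,
) -> list[BindingSite]:
    """Find all sites scoring above ``threshold`` on both strands.

    Coordinates are 0-based half-open on the forward strand; minus-strand
    matches are reported at the forward-strand interval they occupy.  The
    steric footprint is the match interval widened symmetrically to at least
    ``footprint_size_bp`` and clipped to the sequence.
    """
    seq = seq.upper()
    if any(b not in "ACGTN" for b in seq):
        raise InvalidSequenceError("sequence contains non-IUPAC characters")
    w = pwm.width
    if len(seq) < w:
        return []
    fp = max(w, footprint_size_bp or 0)

    sites: list[BindingSite] = []
    fwd = _window_scores(seq, pwm)
    rc = _window_scores(reverse_complement(seq), pwm)
    n_win = len(fwd)
    for strand, scores in (("+", fwd), ("-", rc)):
        for k in np.nonzero(scores > threshold)[0]:
            start = int(k) if strand == "+" else n_win - 1 - int(k)
            end = start + w
            pad = fp - w
            left = pad // 2
            f0 = max(0, start - left)
            f1 = min(len(seq), f0 + fp)
            f0 = max(0, f1 - fp)
            sites.append(
                BindingSite(
                    tf_id=pwm.tf_id,
                    start=start,
                    end=end,
                    strand=strand,
                    score=float(scores[k]),
                    rel_affinity=score_to_affinity(float(scores[k]), pwm, lam),
                    footprint_start=f0,
                    footprint_end=f1,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def best_score(seq: str, pwm: PWM) -> float:
    """Best window score over both strands (used for PWM evaluation)."""
    seq = seq.upper()
    if len(seq) < pwm.width:
        return float("-inf")
    fwd = _window_scores(seq, pwm)
    rc = _window_scores(reverse_complement(seq), pwm)
    return float(max(fwd.max(), rc.max()))


def evaluate_pwm(
    pwm: PWM,
    footprints: Sequence[str],
    negatives: Sequence[str] = (),
) -> tuple[float, int]:
    """Score a PWM against known footprint sites and negative sequences.

    A footprint (already extended by its flanks) is recovered when its best
    window score over both strands exceeds 0; a negative sequence is a false
    positive when any of its windows scores above 0.  A useful matrix
    recovers more than 70% of footprints while keeping false positives low.

    Returns
    -------
    (recovery_rate, false_positive_count)
    """
    if len(footprints) == 0:
        raise ValueError("undefined recovery: empty footprint list")
    recovered = sum(1 for s in footprints if best_score(s, pwm) > 0)
    false_pos = sum(1 for s in negatives if best_score(s, pwm) > 0)
    return recovered / len(footprints), false_pos
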