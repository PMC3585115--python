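"""PWM construction, scoring, scanning and footprint evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotx.pwm import (
    DegenerateColumnError,
    InconsistentScoreError,
    InvalidBackgroundError,
    InvalidSequenceError,
    build_pwm,
    evaluate_pwm,
    reverse_complement,
    scan_sequence,
    score_to_affinity,
)

UNIFORM = np.full(4, 0.25)


class TestBuildPwm:
    def test_background_matching_column_scores_zero(self):
        pwm = build_pwm([[25, 25, 25, 25]], UNIFORM, pseudocount=0)
        assert np.allclose(pwm.logodds, 0.0)

    def test_pure_column_without_pseudocount_is_degenerate(self):
        with pytest.raises(DegenerateColumnError):
            build_pwm([[10, 0, 0, 0]], UNIFORM, pseudocount=0)

    def test_hand_computed_log_odds_with_pseudocount(self):
        # counts (8,1,1,0), pseudocount 1: A entry = log((9/14)/0.25)
        pwm = build_pwm([[8, 1, 1, 0]], UNIFORM, pseudocount=1)
        assert pwm.logodds[0, 0] == pytest.approx(np.log((9 / 14) / 0.25))
        assert pwm.logodds[0, 3] == pytest.approx(np.log((1 / 14) / 0.25))

    def test_max_score_is_consensus_score(self):
        pwm = build_pwm([[8, 1, 1, 0], [0, 9, 1, 0]], UNIFORM, pseudocount=1)
        assert pwm.max_score == pytest.approx(pwm.score(pwm.consensus))

    def test_zero_background_entry_rejected(self):
        with pytest.raises(InvalidBackgroundError):
            build_pwm([[1, 1, 1, 1]], [0.5, 0.5, 0.0, 0.0])


class TestScoreToAffinity:
    @pytest.fixture()
    def pwm(self):
        return build_pwm([[8, 1, 1, 0], [0, 9, 1, 0]], UNIFORM, pseudocount=1)

    def test_consensus_affinity_is_one(self, pwm):
        assert score_to_affinity(pwm.max_score, pwm, lam=2.3) == pytest.approx(1.0)

    def test_lambda_zero_erases_specificity(self, pwm):
        assert score_to_affinity(pwm.max_score - 5.0, pwm, lam=0.0) == 1.0

    def test_two_unit_deficit_at_unit_lambda(self, pwm):
        k = score_to_affinity(pwm.max_score - 2.0, pwm, lam=1.0)
        assert k == pytest.approx(np.exp(-2.0))

    def test_score_above_max_rejected(self, pwm):
        with pytest.raises(InconsistentScoreError):
            score_to_affinity(pwm.max_score + 1.0, pwm, lam=1.0)

    def test_affinity_strictly_increasing_in_score(self, pwm):
        scores = pwm.max_score - np.linspace(5, 0, 20)
        ks = [score_to_affinity(s, pwm, lam=0.7) for s in scores]
        assert np.all(np.diff(ks) > 0)


def _random_background(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScanSequence:
    @pytest.fixture()
    def pwm(self):
        # sharp 4-column matrix, consensus ACGT
        counts = np.zeros((4, 4))
        for i in range(4):
            counts[i, i] = 50
        return build_pwm(counts, UNIFORM, pseudocount=1, tf_id="toy")

    def test_planted_consensus_found_at_offset(self, pwm):
        rng = np.random.default_rng(3)
        seq = _random_background(rng, 40)
        seq = seq[:10] + "ACGT" + seq[14:]
        hits = [
            s for s in scan_sequence(seq, pwm, pwm.max_score - 1e-6, lam=1.0)
            if s.strand == "+"
        ]
        assert [h.start for h in hits] == [10]
        assert hits[0].rel_affinity == pytest.approx(1.0)

    def test_reverse_complement_motif_reported_on_forward_strand(self, pwm):
        rng = np.random.default_rng(4)
        seq = _random_background(rng, 30)
        seq = seq[:5] + reverse_complement("ACGT") + seq[9:]
        hits = scan_sequence(seq, pwm, pwm.max_score - 1e-6, lam=1.0)
        minus = [h for h in hits if h.strand == "-"]
        assert [h.start for h in minus] == [5]
        assert minus[0].end == 9

    def test_palindrome_yields_both_strand_hits_at_one_interval(self):
        counts = np.zeros((4, 4))
        for i, b in enumerate("ACGT"):
            counts[i, "ACGT".index(b)] = 50
        pwm = build_pwm(counts, UNIFORM, pseudocount=1)  # ACGT is palindromic
        seq = "TTTTTACGTTTTTT"
        hits = scan_sequence(seq, pwm, pwm.max_score - 1e-6, lam=1.0)
        assert {(h.start, h.strand) for h in hits} == {(5, "+"), (5, "-")}

    def test_footprint_widened_and_clipped(self, pwm):
        seq = "ACGT" + "T" * 30
        (hit,) = [
            s for s in scan_sequence(
                seq, pwm, pwm.max_score - 1e-6, lam=1.0, footprint_size_bp=14
            )
            if s.strand == "+"
        ]
        assert hit.footprint_end - hit.footprint_start == 14
        assert hit.footprint_start == 0  # clipped at the 5' edge
        assert hit.footprint_start <= hit.start and hit.end <= hit.footprint_end

    def test_short_sequence_returns_empty(self, pwm):
        assert scan_sequence("ACG", pwm, -100, lam=1.0) == []

    def test_invalid_characters_rejected(self, pwm):
        with pytest.raises(InvalidSequenceError):
            scan_sequence("ACGTXACGT", pwm, 0.0, lam=1.0)

    def test_window_with_n_never_a_site(self, pwm):
        hits = scan_sequence("ACNT" * 5, pwm, -1e6, lam=1.0)
        assert hits == []

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(20, 60))
    def test_strand_symmetry(self, seed, n):
        """Scanning the reverse complement mirrors the site set."""
        pwm = _sharp_pwm()
        rng = np.random.default_rng(seed)
        seq = _random_background(rng, n)
        thr = pwm.max_score - 8.0
        fwd = scan_sequence(seq, pwm, thr, lam=1.0)
        rev = scan_sequence(reverse_complement(seq), pwm, thr, lam=1.0)
        flip = {("+", "-"): None}
        mirrored = {
            (n - s.end, n - s.start, "-" if s.strand == "+" else "+",
             round(s.score, 9))
            for s in rev
        }
        original = {
            (s.start, s.end, s.strand, round(s.score, 9)) for s in fwd
        }
        assert original == mirrored

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_score_additivity_against_per_column_oracle(self, seed):
        """Window scores equal the brute-force sum of per-column log-odds."""
        pwm = _sharp_pwm()
        rng = np.random.default_rng(seed)
        seq = _random_background(rng, 30)
        hits = scan_sequence(seq, pwm, -1e6, lam=1.0)
        for h in hits:
            window = seq[h.start : h.end]
            if h.strand == "-":
                window = reverse_complement(window)
            expected = sum(
                pwm.logodds[i, "ACGT".index(b)] for i, b in enumerate(window)
            )
            assert h.score == pytest.approx(expected, abs=1e-9)

    def test_raising_threshold_never_adds_sites(self):
        pwm = _sharp_pwm()
        rng = np.random.default_rng(11)
        seq = _random_background(rng, 200)
        thresholds = np.linspace(-10, pwm.max_score, 8)
        counts = [len(scan_sequence(seq, pwm, t, lam=1.0)) for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def _sharp_pwm():
    counts = np.zeros((4, 4))
    for i, b in enumerate("TGCA"):
        counts[i, "ACGT".index(b)] = 20
        counts[i] += 1
    return build_pwm(counts, UNIFORM, pseudocount=0.5, tf_id="sharp")


class TestEvaluatePwm:
    def test_consensus_footprints_fully_recovered(self):
        pwm = _sharp_pwm()
        flank = "AATTA"
        fps = [flank + pwm.consensus + flank] * 4
        recovery, fp = evaluate_pwm(pwm, fps, negatives=[])
        assert recovery == 1.0 and fp == 0

    def test_boundary_seven_of_ten(self):
        pwm = _sharp_pwm()
        good = "AATTA" + pwm.consensus + "AATTA"
        # poly-A scores far below 0 for this consensus
        bad = "A" * 20
        recovery, _ = evaluate_pwm(pwm, [good] * 7 + [bad] * 3)
        assert recovery == pytest.approx(0.7)

    def test_negatives_counted(self):
        pwm = _sharp_pwm()
        recovery, fp = evaluate_pwm(
            pwm, [pwm.consensus], negatives=["A" * 20, "C" * 20, pwm.consensus * 2]
        )
        assert fp == 1

    def test_empty_footprint_list_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_pwm(_sharp_pwm(), [])
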