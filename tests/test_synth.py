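"""Synthetic-data generator: determinism, shapes, planting, noise."""

import numpy as np
import pandas as pd
import pytest

from thermotx.occupancy import assign_cooperativity
from thermotx.pwm import scan_sequence
from thermotx.synth import (
    LayoutError,
    SyntheticSpec,
    demo_constructs,
    demo_training_set,
    excise_spacer,
    generate_construct,
    generate_profiles,
    simulate_dataset,
    synthetic_thresholds,
    toy_pwms,
)


class TestProfiles:
    def test_gradient_peaks_at_anterior_end(self):
        spec = SyntheticSpec()
        df = generate_profiles(spec)
        bcd = df["bcd"].to_numpy()
        assert bcd.argmax() == 0
        assert bcd[0] == pytest.approx(spec.shapes["bcd"]["amplitude"])

    def test_bump_argmax_at_declared_center(self):
        df = generate_profiles(SyntheticSpec())
        x = df.index.to_numpy()
        assert abs(x[df["kr"].to_numpy().argmax()] - 52.0) < 1.0

    def test_same_spec_is_deterministic(self):
        a = generate_profiles(SyntheticSpec(seed=3))
        b = generate_profiles(SyntheticSpec(seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_grid_and_nonnegativity(self):
        df = generate_profiles(SyntheticSpec())
        x = df.index.to_numpy()
        assert len(x) == 58 and x[0] == 35.0 and x[-1] == 92.0
        assert np.all(np.diff(x) > 0)
        assert (df.to_numpy() >= 0).all()

    def test_invalid_shape_rejected(self):
        spec = SyntheticSpec()
        spec.shapes["kr"]["width"] = 0.0
        with pytest.raises(ValueError):
            generate_profiles(spec)


class TestGenerateConstruct:
    def test_planted_consensus_recovered_exactly(self):
        pwms = toy_pwms()
        thr = synthetic_thresholds(pwms)
        pc = generate_construct([("bcd", 25, 0)], 120, seed=1)
        hits = scan_sequence(pc.construct.sequence, pwms["bcd"], thr["bcd"], 1.0)
        assert [h.start for h in hits] == [25]

    def test_affinity_tiers_rank_by_mismatches(self):
        pwms = toy_pwms()
        pc = generate_construct([("bcd", 10, 0), ("bcd", 60, 1)], 120, seed=2)
        thr = synthetic_thresholds(pwms)
        hits = scan_sequence(pc.construct.sequence, pwms["bcd"], thr["bcd"], 1.0)
        by_start = {h.start: h for h in hits}
        assert by_start[10].score > by_start[60].score

    def test_spacer_excision_shifts_downstream_sites(self):
        pc = generate_construct(
            [("bcd", 10, 0), ("cad", 250, 0)], 320, seed=3,
            spacers=[(40, 212)],
        )
        fused = excise_spacer(pc, (40, 212))
        assert ("cad", 250 - 172, 0) in fused.planted
        assert ("bcd", 10, 0) in fused.planted
        assert len(fused.construct.sequence) == 320 - 172
        # the shifted motif is still there verbatim
        pwms = toy_pwms()
        thr = synthetic_thresholds(pwms)
        hits = scan_sequence(fused.construct.sequence, pwms["cad"], thr["cad"], 1.0)
        assert [h.start for h in hits] == [78]

    def test_cooperativity_range_cutoff_behavior(self):
        """Planted pairs 50 bp apart pair up; 70 bp apart do not (60 bp range)."""
        pwms = toy_pwms()
        thr = synthetic_thresholds(pwms)
        close = generate_construct([("bcd", 10, 0), ("bcd", 60, 0)], 120, seed=4)
        sites = scan_sequence(close.construct.sequence, pwms["bcd"], thr["bcd"], 1.0)
        assert assign_cooperativity(sites, 60).pairs == ((0, 1),)
        far = generate_construct([("bcd", 10, 0), ("bcd", 80, 0)], 140, seed=5)
        sites = scan_sequence(far.construct.sequence, pwms["bcd"], thr["bcd"], 1.0)
        assert assign_cooperativity(sites, 60).pairs == ()

    def test_colliding_motifs_rejected(self):
        with pytest.raises(LayoutError):
            generate_construct([("bcd", 10, 0), ("kr", 15, 0)], 100, seed=6)

    def test_same_seed_same_sequence(self):
        a = generate_construct([("bcd", 10, 0)], 80, seed=7)
        b = generate_construct([("bcd", 10, 0)], 80, seed=7)
        assert a.construct.sequence == b.construct.sequence


class TestSimulateDataset:
    def test_zero_noise_equals_forward_prediction(self):
        data = demo_training_set(seed=4, noise_sd=0.0)
        from thermotx.pipeline import ConstructEvaluator

        pwms = toy_pwms()
        for c in data.constructs[:2]:
            ev = ConstructEvaluator(c, pwms, data.tf_profiles, data.true_params)
            np.testing.assert_allclose(
                data.observed[c.construct_id].to_numpy(),
                np.asarray(ev.evaluate(data.true_params)),
                atol=1e-12,
            )

    def test_seven_constructs_58_positions_406_observations(self):
        data = demo_training_set(seed=1)
        assert len(data.constructs) == 7
        assert data.n_positions == 58
        assert data.n_observations == 406

    def test_determinism_and_seed_sensitivity(self):
        a = demo_training_set(seed=5)
        b = demo_training_set(seed=5)
        c = demo_training_set(seed=6)
        pd.testing.assert_frame_equal(a.observed, b.observed)
        assert not a.observed.equals(c.observed)

    def test_noise_magnitude_matches_declared_sd(self):
        """Monte-Carlo: relative deviation of noisy from noiseless
        observations reproduces the declared sd."""
        rng_seed = 11
        noiseless = demo_training_set(seed=rng_seed, noise_sd=0.0)
        sd = 0.075
        devs = []
        planted = [c for c in noiseless.constructs]
        # many replicate noise draws over the same signals
        for k in range(30):
            noisy = simulate_dataset(
                planted, noiseless.tf_profiles, noiseless.true_params,
                noise_sd=sd, seed=1000 + k,
            )
            base = noiseless.observed.to_numpy()
            mask = base > 1.0  # avoid clipped / tiny-signal cells
            devs.append(
                ((noisy.observed.to_numpy()[mask] - base[mask]) / base[mask])
            )
        devs = np.concatenate(devs)
        assert devs.std() == pytest.approx(sd, rel=0.05)
        assert abs(devs.mean()) < 0.01

    def test_roundtrip_through_disk(self, tmp_path):
        from thermotx.io import read_profiles, write_profiles

        data = demo_training_set(seed=2)
        p = tmp_path / "obs.tsv"
        write_profiles(p, data.observed, meta={"seed": 2})
        back = read_profiles(p)
        np.testing.assert_allclose(back.to_numpy(), data.observed.to_numpy())
        assert list(back.columns) == list(data.observed.columns)


class TestDemoConstructs:
    def test_fusion_variants_share_element_architecture(self):
        by_id = {p.construct.construct_id: p for p in demo_constructs(seed=1)}
        assert set(by_id) == {"m32", "m3_2", "m23", "m2_3", "mse2", "mse3", "c1700"}
        # spacer variant declares its spacer and is longer by its length
        assert len(by_id["m3_2"].construct.sequence) == \
            len(by_id["m32"].construct.sequence) + 172
        assert by_id["m3_2"].spacers == [(250, 422)]

    def test_every_mechanism_has_an_exercising_fixture(self):
        """The roster covers cooperativity (paired bcd), coactivation
        (hb near bcd/cad), quenching and direct repression (kr near
        activators and the TSS)."""
        pwms = toy_pwms()
        thr = synthetic_thresholds(pwms)
        by_id = {p.construct.construct_id: p for p in demo_constructs(seed=1)}
        m32 = by_id["m32"]
        tfs = {tf for tf, _o, _t in m32.planted}
        assert {"bcd", "cad", "hb", "kr", "gt", "kni", "dst"} <= tfs
        bcd_sites = scan_sequence(
            m32.construct.sequence, pwms["bcd"], thr["bcd"], 1.0
        )
        assert assign_cooperativity(bcd_sites, 60).pairs  # at least one pair
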