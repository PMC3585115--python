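"""Cooperativity pairing, grouping and exact fractional occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_occupancy, make_site, random_sites
from thermotx.occupancy import (
    CooperativityPairing,
    GroupTooLargeError,
    InvalidConcentrationError,
    assign_cooperativity,
    build_groups,
    configuration_weights,
    fractional_occupancy,
    occupancy_landscape,
)


class TestAssignCooperativity:
    def test_strongest_pairs_within_range_third_too_far(self):
        sites = [
            make_site(100, tf="bcd", affinity=0.9),
            make_site(130, tf="bcd", affinity=0.5),
            make_site(400, tf="bcd", affinity=0.4),
        ]
        pairing = assign_cooperativity(sites, range_bp=60)
        assert pairing.pairs == ((0, 1),)

    def test_single_site_unpaired(self):
        assert assign_cooperativity([make_site(10, tf="bcd")]).pairs == ()

    def test_four_close_sites_pair_by_rank(self):
        sites = [
            make_site(0, tf="bcd", affinity=0.9),
            make_site(15, tf="bcd", affinity=0.8),
            make_site(30, tf="bcd", affinity=0.7),
            make_site(45, tf="bcd", affinity=0.6),
        ]
        pairing = assign_cooperativity(sites, range_bp=60)
        assert set(pairing.pairs) == {(0, 1), (2, 3)}

    def test_distance_is_center_to_center(self):
        # starts 61 apart but centers of equal-width sites also 61 apart: no pair
        sites = [
            make_site(0, tf="bcd", affinity=0.9),
            make_site(61, tf="bcd", affinity=0.8),
        ]
        assert assign_cooperativity(sites, range_bp=60).pairs == ()
        sites2 = [
            make_site(0, tf="bcd", affinity=0.9),
            make_site(60, tf="bcd", affinity=0.8),
        ]
        assert assign_cooperativity(sites2, range_bp=60).pairs == ((0, 1),)

    def test_empty_input(self):
        assert assign_cooperativity([]).pairs == ()

    def test_affinity_tie_broken_by_start(self):
        sites = [
            make_site(0, tf="bcd", affinity=0.5),
            make_site(20, tf="bcd", affinity=0.5),
            make_site(40, tf="bcd", affinity=0.5),
        ]
        pairing = assign_cooperativity(sites, range_bp=60)
        assert pairing.pairs == ((0, 1),)


class TestBuildGroups:
    def test_disjoint_sites_make_singletons(self):
        sites = [make_site(0), make_site(100)]
        groups = build_groups(sites)
        assert [g.indices for g in groups] == [(0,), (1,)]

    def test_overlap_chain_is_transitive(self):
        sites = [make_site(0, width=20), make_site(15, width=20), make_site(30, width=20)]
        (group,) = build_groups(sites)
        assert group.indices == (0, 1, 2)
        assert group.conflict[0, 1] and group.conflict[1, 2] and not group.conflict[0, 2]

    def test_cooperative_pair_joins_disjoint_sites(self):
        sites = [make_site(0), make_site(50)]
        pairing = CooperativityPairing(pairs=((0, 1),))
        (group,) = build_groups(sites, pairing)
        assert group.indices == (0, 1)
        assert group.coop_pairs == ((0, 1),)

    def test_oversized_group_raises_with_interval(self):
        sites = [make_site(i * 5, width=20) for i in range(25)]
        with pytest.raises(GroupTooLargeError, match="25 sites"):
            build_groups(sites)


class TestConfigurationWeights:
    def test_steric_exclusion_drops_joint_state(self):
        sites = [make_site(0, width=14), make_site(7, width=14)]
        (group,) = build_groups(sites)
        w = configuration_weights(group, {0: 1.0, 1: 1.0})
        assert w == {
            frozenset(): 1.0,
            frozenset({0}): 1.0,
            frozenset({1}): 1.0,
        }

    def test_cooperative_pair_weight(self):
        sites = [make_site(0), make_site(30)]
        pairing = CooperativityPairing(pairs=((0, 1),))
        (group,) = build_groups(sites, pairing)
        w = configuration_weights(group, {0: 1.0, 1: 1.0}, {(0, 1): 2.0})
        assert w[frozenset({0, 1})] == pytest.approx(2.0)
        assert w[frozenset()] == 1.0

    def test_unit_omega_factorizes(self):
        sites = [make_site(0), make_site(30)]
        pairing = CooperativityPairing(pairs=((0, 1),))
        (group,) = build_groups(sites, pairing)
        w = configuration_weights(group, {0: 2.0, 1: 3.0}, {(0, 1): 1.0})
        z = sum(w.values())
        assert z == pytest.approx((1 + 2) * (1 + 3))

    def test_negative_q_rejected(self):
        (group,) = build_groups([make_site(0)])
        with pytest.raises(InvalidConcentrationError):
            configuration_weights(group, {0: -0.1})


class TestFractionalOccupancy:
    def test_lone_site_is_langmuir(self):
        (group,) = build_groups([make_site(0)])
        f = fractional_occupancy(group, {0: 1.0})
        assert f[0] == pytest.approx(0.5, abs=1e-12)

    def test_two_overlapping_competitors(self):
        sites = [make_site(0, width=14), make_site(7, width=14)]
        (group,) = build_groups(sites)
        f = fractional_occupancy(group, {0: 1.0, 1: 1.0})
        assert f[0] == pytest.approx(1 / 3, abs=1e-12)
        assert f[1] == pytest.approx(1 / 3, abs=1e-12)

    def test_cooperative_pair_hand_enumeration(self):
        sites = [make_site(0), make_site(30)]
        pairing = CooperativityPairing(pairs=((0, 1),))
        (group,) = build_groups(sites, pairing)
        f = fractional_occupancy(group, {0: 1.0, 1: 1.0}, {(0, 1): 2.0})
        assert f[0] == pytest.approx(3 / 5, abs=1e-12)
        assert f[1] == pytest.approx(3 / 5, abs=1e-12)

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(5)
        sites = random_sites(rng, 8)
        for group in build_groups(sites):
            q = {i: float(rng.uniform(0, 5)) for i in group.indices}
            w = configuration_weights(group, q)
            z = sum(w.values())
            assert sum(v / z for v in w.values()) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 10))
    def test_grouped_equals_global_enumeration(self, seed, n):
        """Grouped computation is exact against the brute-force oracle."""
        rng = np.random.default_rng(seed)
        sites = random_sites(rng, n)
        q = [float(rng.uniform(0, 10)) for _ in range(n)]
        # random cooperativity among same-TF disjoint pairs
        omegas = {}
        used = set()
        for i in range(n):
            for j in range(i + 1, n):
                if (
                    sites[i].tf_id == sites[j].tf_id
                    and i not in used and j not in used
                    and rng.random() < 0.3
                ):
                    omegas[(i, j)] = float(rng.uniform(1, 5))
                    used |= {i, j}
        pairing = CooperativityPairing(pairs=tuple(omegas))
        expected = brute_force_occupancy(sites, q, omegas=omegas)
        got = np.zeros(n)
        for group in build_groups(sites, pairing):
            f = fractional_occupancy(group, dict(enumerate(q)), omegas)
            for i, v in f.items():
                got[i] = v
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_own_q_monotone_conflict_q_antitone(self, seed):
        rng = np.random.default_rng(seed)
        sites = [make_site(0, width=14), make_site(7, width=14), make_site(40)]
        (g1, g2) = build_groups(sites)
        q = {i: float(rng.uniform(0.1, 5)) for i in range(3)}
        f = fractional_occupancy(g1, q)
        q_up = dict(q)
        q_up[0] = q[0] * 2
        f_up = fractional_occupancy(g1, q_up)
        assert f_up[0] > f[0]  # own q up -> occupancy up
        assert f_up[1] < f[1]  # competitor q up -> occupancy down

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.floats(1.0, 10.0))
    def test_cooperativity_never_hurts_partners(self, seed, omega):
        rng = np.random.default_rng(seed)
        sites = [make_site(0), make_site(30)]
        pairing = CooperativityPairing(pairs=((0, 1),))
        (group,) = build_groups(sites, pairing)
        q = {0: float(rng.uniform(0.1, 5)), 1: float(rng.uniform(0.1, 5))}
        f_base = fractional_occupancy(group, q, {(0, 1): 1.0})
        f_coop = fractional_occupancy(group, q, {(0, 1): omega})
        assert f_coop[0] >= f_base[0] - 1e-12
        assert f_coop[1] >= f_base[1] - 1e-12


class TestOccupancyLandscape:
    def test_zero_concentration_means_zero_occupancy(self):
        sites = [make_site(0, tf="a"), make_site(40, tf="b")]
        land = occupancy_landscape(
            sites, {"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0}
        )
        assert all(v == 0.0 for v in land.f.values())

    def test_scale_and_concentration_interchangeable(self):
        sites = [make_site(0, tf="a"), make_site(40, tf="a")]
        a = occupancy_landscape(sites, {"a": 2.0}, {"a": 1.0})
        b = occupancy_landscape(sites, {"a": 1.0}, {"a": 2.0})
        assert a.f == b.f

    def test_missing_tf_raises(self):
        with pytest.raises(KeyError):
            occupancy_landscape([make_site(0, tf="a")], {}, {"a": 1.0})

    def test_matches_global_oracle_on_five_site_construct(self):
        rng = np.random.default_rng(42)
        sites = random_sites(rng, 5)
        conc = {t: float(rng.uniform(0.2, 2.0)) for t in ("a", "b", "c")}
        land = occupancy_landscape(sites, conc, {t: 1.0 for t in conc})
        q = [s.rel_affinity * conc[s.tf_id] for s in sites]
        expected = brute_force_occupancy(sites, q)
        got = np.array([land.f[i] for i in range(5)])
        np.testing.assert_allclose(got, expected, atol=1e-12)
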