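"""Shared fixtures: toy PWMs, synthetic profiles, random site machinery."""

from __future__ import annotations

import numpy as np
import pytest

from thermotx.pwm import BindingSite
from thermotx.synth import SyntheticSpec, generate_profiles, toy_pwms


@pytest.fixture(scope="session")
def pwms():
    return toy_pwms()


@pytest.fixture(scope="session")
def profiles():
    return generate_profiles(SyntheticSpec(seed=0))


def make_site(
    start: int,
    tf: str = "a",
    affinity: float = 1.0,
    width: int = 10,
    footprint: int | None = None,
    strand: str = "+",
) -> BindingSite:
    """Hand-built binding site for occupancy/interaction unit tests."""
    fp = footprint if footprint is not None else width
    pad = (fp - width) // 2
    return BindingSite(
        tf_id=tf,
        start=start,
        end=start + width,
        strand=strand,
        score=0.0,
        rel_affinity=affinity,
        footprint_start=max(0, start - pad),
        footprint_end=start + width + (fp - width - pad),
    )


def random_sites(
    rng: np.random.Generator,
    n: int,
    span: int = 300,
    tfs: tuple[str, ...] = ("a", "b", "c"),
) -> list[BindingSite]:
    """Random sites with random footprints/affinities; overlaps allowed."""
    sites = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(6, 15))
        sites.append(
            make_site(
                start,
                tf=str(rng.choice(list(tfs))),
                affinity=float(rng.uniform(0.05, 1.0)),
                width=width,
                footprint=width + int(rng.integers(0, 8)),
            )
        )
    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def brute_force_occupancy(sites, q, pairs=None, omegas=None):
    """Independent oracle: exact occupancy by global subset enumeration.

    Enumerates every subset of all sites (no grouping), discards subsets
    containing a footprint-overlapping pair, weights the rest by
    ``prod q_i * prod omega`` and normalizes.  O(2^n); keep n <= 12.
    """
    n = len(sites)
    conflict_mask = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and (
                sites[i].footprint_start < sites[j].footprint_end
                and sites[j].footprint_start < sites[i].footprint_end
            ):
                conflict_mask[i] |= 1 << j
    pair_list = []
    for (i, j), om in (omegas or {}).items():
        pair_list.append((1 << i | 1 << j, om))
    if pairs is not None and omegas is None:
        pair_list = [(1 << i | 1 << j, 1.0) for i, j in pairs]
    total = np.zeros(n)
    z = 0.0
    for mask in range(1 << n):
        ok = True
        w = 1.0
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if conflict_mask[i] & mask:
                ok = False
                break
            w *= q[i]
            m &= m - 1
        if not ok:
            continue
        for pm, om in pair_list:
            if mask & pm == pm:
                w *= om
        z += w
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            total[i] += w
            m &= m - 1
    return total / z
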