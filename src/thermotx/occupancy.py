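"""Equilibrium fractional occupancy with steric exclusion and cooperativity.

Bound-state statistics are computed exactly.  Each site ``i`` carries a
statistical weight ``q_i = K_i * D_a * v_a`` (relative affinity times scaled
factor concentration).  A *configuration* is a subset of sites in which no two
members have overlapping steric footprints; its weight is the product of the
member ``q_i`` times a cooperativity factor ``omega`` for every cooperative
pair whose two partners are both bound.  The fractional occupancy of a site is
the weight of all configurations containing it divided by the partition
function (sum over all configurations, including the empty one with weight 1).

Because weights factorize over connected components of the interaction graph
(footprint-overlap edges plus cooperativity edges), sites are partitioned into
independent groups and each group is enumerated separately; this is exact, not
an approximation.

Cooperativity pairing follows the greedy strongest-first rule: the
highest-affinity unpaired site of the cooperative factor is paired with the
strongest remaining site within range (60 bp center-to-center by default),
and the rule is repeated until no assignable pair remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .pwm import BindingSite

__all__ = [
    "CooperativityPairing",
    "SiteGroup",
    "OccupancyLandscape",
    "assign_cooperativity",
    "build_groups",
    "configuration_weights",
    "fractional_occupancy",
    "occupancy_landscape",
]

DEFAULT_COOP_RANGE_BP = 60
DEFAULT_GROUP_CAP = 20


class GroupTooLargeError(ValueError):
    """An interaction group exceeds the exact-enumeration cap."""


class InvalidConcentrationError(ValueError):
    """A statistical weight q was negative."""


class MissingTFError(KeyError):
    """A site's factor has no concentration or scale entry."""


@dataclass(frozen=True)
class CooperativityPairing:
    """Pairwise cooperative interactions among sites of one factor.

    ``pairs`` holds index pairs (into the site list the pairing was computed
    from); every site appears in at most one pair.
    """

    pairs: tuple[tuple[int, int], ...]
    range_bp: int = DEFAULT_COOP_RANGE_BP


@dataclass
class SiteGroup:
    """A connected component of the overlap + cooperativity interaction graph."""

    indices: tuple[int, ...]  # global site indices, ordered by start
    sites: tuple[BindingSite, ...]
    conflict: np.ndarray  # boolean, local indexing
    coop_pairs: tuple[tuple[int, int], ...] = ()  # local indexing


@dataclass
class OccupancyLandscape:
    """Per-site fractional occupancies at one axis position."""

    f: dict[int, float]
    q: dict[int, float] = field(default_factory=dict)


def _center(site: BindingSite) -> float:
    return site.center


def assign_cooperativity(
    sites: Sequence[BindingSite],
    range_bp: int = DEFAULT_COOP_RANGE_BP,
) -> CooperativityPairing:
    """Greedy strongest-first pairing of cooperative sites within range.

    Distance is center-to-center of the match intervals.  Affinity ties are
    broken by smaller start coordinate for determinism.
    """
    order = sorted(
        range(len(sites)),
        key=lambda i: (-sites[i].rel_affinity, sites[i].start, sites[i].strand),
    )
    unpaired = set(order)
    pairs: list[tuple[int, int]] = []
    for i in order:
        if i not in unpaired:
            continue
        best = None
        for j in order:
            if j == i or j not in unpaired:
                continue
            if abs(_center(sites[i]) - _center(sites[j])) <= range_bp:
                best = j
                break
        if best is not None:
            unpaired.discard(i)
            unpaired.discard(best)
            pairs.append((min(i, best), max(i, best)))
    return CooperativityPairing(pairs=tuple(pairs), range_bp=range_bp)


def _footprints_overlap(a: BindingSite, b: BindingSite) -> bool:
    return a.footprint_start < b.footprint_end and b.footprint_start < a.footprint_end


def build_groups(
    sites: Sequence[BindingSite],
    pairing: CooperativityPairing | None = None,
    group_cap: int = DEFAULT_GROUP_CAP,
) -> list[SiteGroup]:
    """Partition sites into independent interaction groups.

    An edge joins two sites when their steric footprints overlap or when they
    form a cooperative pair; connected components become groups.  Groups
    larger than ``group_cap`` raise :class:`GroupTooLargeError` because they
    would defeat exact enumeration.
    """
    n = len(sites)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i, j in combinations(range(n), 2):
        if _footprints_overlap(sites[i], sites[j]):
            union(i, j)
    coop = pairing.pairs if pairing is not None else ()
    for i, j in coop:
        union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    groups: list[SiteGroup] = []
    for members in comps.values():
        members.sort(key=lambda i: (sites[i].start, sites[i].end, sites[i].strand))
        if len(members) > group_cap:
            lo = min(sites[i].footprint_start for i in members)
            hi = max(sites[i].footprint_end for i in members)
            raise GroupTooLargeError(
                f"group of {len(members)} sites spanning [{lo}, {hi}) exceeds "
                f"the exact-enumeration cap of {group_cap}"
            )
        local = {g: k for k, g in enumerate(members)}
        conflict = np.zeros((len(members), len(members)), dtype=bool)
        for a, b in combinations(members, 2):
            if _footprints_overlap(sites[a], sites[b]):
                conflict[local[a], local[b]] = conflict[local[b], local[a]] = True
        local_pairs = tuple(
            (local[i], local[j]) for i, j in coop if i in local and j in local
        )
        groups.append(
            SiteGroup(
                indices=tuple(members),
                sites=tuple(sites[i] for i in members),
                conflict=conflict,
                coop_pairs=local_pairs,
            )
        )
    groups.sort(key=lambda g: g.indices[0] if g.indices else -1)
    return groups


def enumerate_configurations(group: SiteGroup) -> np.ndarray:
    """All conflict-free subsets of a group as a boolean (n_cfg, n_sites) matrix.

    The empty configuration is always row 0.
    """
    n = len(group.sites)
    conflict_masks = [
        int(sum(1 << j for j in range(n) if group.conflict[i, j]))
        for i in range(n)
    ]
    configs: list[int] = []

    def rec(i: int, chosen: int, forbidden: int) -> None:
        if i == n:
            configs.append(chosen)
            return
        rec(i + 1, chosen, forbidden)  # site i unbound
        if not (forbidden >> i) & 1:
            rec(i + 1, chosen | (1 << i), forbidden | conflict_masks[i])

    rec(0, 0, 0)
    configs.sort()
    out = np.zeros((len(configs), n), dtype=bool)
    for r, mask in enumerate(configs):
        for i in range(n):
            if (mask >> i) & 1:
                out[r, i] = True
    return out


def configuration_weights(
    group: SiteGroup,
    q: Mapping[int, float] | Sequence[float],
    omegas: Mapping[tuple[int, int], float] | None = None,
) -> dict[frozenset[int], float]:
    """Statistical weight of every conflict-free configuration of a group.

    ``q`` maps global site index -> statistical weight; ``omegas`` maps a
    cooperative pair (global indices, as stored in ``group.coop_pairs``
    translated to global) -> multiplicative factor.
    """
    qs = _local_q(group, q)
    om = _local_omegas(group, omegas)
    configs = enumerate_configurations(group)
    weights = _config_weight_vector(configs, qs, om)
    out: dict[frozenset[int], float] = {}
    for row, w in zip(configs, weights):
        key = frozenset(group.indices[i] for i in np.nonzero(row)[0])
        out[key] = float(w)
    return out


def _local_q(group: SiteGroup, q) -> np.ndarray:
    if isinstance(q, Mapping):
        qs = np.array([q[g] for g in group.indices], dtype=float)
    else:
        qarr = np.asarray(q, dtype=float)
        qs = qarr[list(group.indices)]
    if np.any(qs < 0):
        raise InvalidConcentrationError("statistical weights q must be >= 0")
    return qs


def _local_omegas(group: SiteGroup, omegas) -> list[tuple[int, int, float]]:
    out = []
    for i, j in group.coop_pairs:
        gi, gj = group.indices[i], group.indices[j]
        w = 1.0
        if omegas is not None:
            w = omegas.get((gi, gj), omegas.get((gj, gi), 1.0))
        out.append((i, j, float(w)))
    return out


def _config_weight_vector(
    configs: np.ndarray,
    qs: np.ndarray,
    local_omegas: list[tuple[int, int, float]],
) -> np.ndarray:
    n_cfg = configs.shape[0]
    weights = np.ones(n_cfg)
    for i in range(configs.shape[1]):
        weights[configs[:, i]] *= qs[i]
    for i, j, w in local_omegas:
        both = configs[:, i] & configs[:, j]
        weights[both] *= w
    return weights


def fractional_occupancy(
    group: SiteGroup,
    q: Mapping[int, float] | Sequence[float],
    omegas: Mapping[tuple[int, int], float] | None = None,
) -> dict[int, float]:
    """Exact fractional occupancy of every site in a group.

    ``f_i = (sum of weights of configurations containing i) / Z``.
    """
    qs = _local_q(group, q)
    om = _local_omegas(group, omegas)
    configs = enumerate_configurations(group)
    weights = _config_weight_vector(configs, qs, om)
    Z = weights.sum()
    if Z <= 0:  # unreachable: empty configuration contributes 1
        raise ZeroDivisionError("partition function vanished")
    return {
        group.indices[i]: float(weights[configs[:, i]].sum() / Z)
        for i in range(len(group.sites))
    }


def occupancy_landscape(
    sites: Sequence[BindingSite],
    concentrations: Mapping[str, float],
    d_scales: Mapping[str, float],
    pairing: CooperativityPairing | None = None,
    omega: float = 1.0,
    group_cap: int = DEFAULT_GROUP_CAP,
) -> OccupancyLandscape:
    """Fractional occupancy of every site at one axis position.

    ``q_i = rel_affinity_i * D_a * v_a`` where ``v_a`` is the measured
    fluorescence of factor ``a`` at this position and ``D_a`` its fitted
    concentration scale.  Cooperative pairs all share the single ``omega``.
    The result is independent of group evaluation order.
    """
    q: dict[int, float] = {}
    for i, s in enumerate(sites):
        if s.tf_id not in concentrations or s.tf_id not in d_scales:
            raise MissingTFError(f"no concentration/scale for TF {s.tf_id!r}")
        q[i] = s.rel_affinity * d_scales[s.tf_id] * concentrations[s.tf_id]
    omegas = None
    if pairing is not None:
        omegas = {p: omega for p in pairing.pairs}
    f: dict[int, float] = {}
    for group in build_groups(sites, pairing, group_cap=group_cap):
        f.update(fractional_occupancy(group, q, omegas))
    return OccupancyLandscape(f=f, q=q)
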