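"""Community detection by weighted modularity maximization (Louvain).

Communities are found with the Louvain scheme: greedy local node moves
maximizing the gain in Newman-Girvan weighted modularity

    Q = (1/2m) * sum_ij [ w_ij - s_i s_j / (2m) ] * delta(c_i, c_j)

alternating with graph aggregation until no further gain, at resolution 1.
Because the local-move order is randomized, detection is wrapped in a
seeded best-of-restarts loop: identical (network, seed, n_restarts)
always return the identical partition.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

__all__ = ["Partition", "modularity", "louvain", "filter_small"]


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment with its modularity score.

    Community ids are contiguous integers from 0, ordered by descending
    community size (ties broken by smallest member id as string).
    ``unassigned`` holds nodes removed by small-cluster filtering; they
    are excluded from downstream contingency tables.
    """

    membership: dict
    modularity: float | None = None
    unassigned: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = set(self.membership.values())
        if ids and ids != set(range(len(ids))):
            raise ValueError("community ids must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.n_communities)]
        for node, cid in self.membership.items():
            out[cid].add(node)
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities()]


def _canonical_membership(groups: list[set]) -> dict:
    """Relabel communities 0..k-1 by descending size, ties by member id."""
    order = sorted(
        range(len(groups)),
        key=lambda i: (-len(groups[i]), min(str(n) for n in groups[i])),
    )
    membership: dict = {}
    for new_id, old_id in enumerate(order):
        for node in groups[old_id]:
            membership[node] = new_id
    return membership


def modularity(net: nx.Graph, part: Partition | Mapping) -> float:
    """Weighted Newman-Girvan modularity of a partition at resolution 1.

    Q = (1/2m) sum_ij [w_ij - s_i s_j/(2m)] delta(c_i, c_j), with m the
    total edge weight and s the node strengths.
    """
    membership = part.membership if isinstance(part, Partition) else dict(part)
    missing = [n for n in net.nodes if n not in membership]
    if missing:
        raise ValueError(f"{len(missing)} node(s) missing from the partition")
    two_m = 2.0 * net.size(weight="weight")
    if two_m == 0:
        raise ValueError("modularity undefined on an edgeless network")
    strengths = dict(net.degree(weight="weight"))
    # accumulate per community: internal weight and total strength
    w_in: dict = {}
    s_tot: dict = {}
    for node, cid in membership.items():
        if node in net:
            s_tot[cid] = s_tot.get(cid, 0.0) + strengths[node]
    for u, v, w in net.edges(data="weight"):
        if membership[u] == membership[v]:
            w_in[membership[u]] = w_in.get(membership[u], 0.0) + w
    q = 0.0
    for cid, s in s_tot.items():
        q += 2.0 * w_in.get(cid, 0.0) / two_m - (s / two_m) ** 2
    return q


def louvain(net: nx.Graph, seed: int, n_restarts: int = 10) -> Partition:
    """Seeded best-of-restarts Louvain community detection.

    Runs ``n_restarts`` independent Louvain passes with restart seeds
    derived deterministically from ``seed`` and keeps the partition with
    the highest modularity (first encountered wins ties).  Identical
    (net, seed, n_restarts) give the identical partition.

    Raises
    ------
    ValueError
        If the network has no edges (modularity is undefined).
    """
    if net.number_of_edges() == 0:
        raise ValueError("community detection requires at least one edge")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = random.Random(int(seed))
    best_groups: list[set] | None = None
    best_q = -float("inf")
    for _ in range(n_restarts):
        restart_seed = rng.randrange(2**31)
        groups = [
            set(c)
            for c in nx.community.louvain_communities(
                net, weight="weight", resolution=1.0, seed=restart_seed
            )
        ]
        q = modularity(net, _canonical_membership(groups))
        if q > best_q:
            best_q = q
            best_groups = groups
    assert best_groups is not None
    return Partition(membership=_canonical_membership(best_groups), modularity=best_q)


def filter_small(part: Partition, min_size: int = 10) -> Partition:
    """Drop communities smaller than ``min_size``, marking members unassigned.

    Retained communities are re-indexed by descending size.  Removing
    every community is an error; ``min_size=1`` is the identity (up to
    canonical relabelling).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    groups = part.communities()
    kept = [g for g in groups if len(g) >= min_size]
    if not kept:
        raise ValueError(f"min_size={min_size} removed every community")
    dropped: set = set()
    for g in groups:
        if len(g) < min_size:
            dropped |= g
    return Partition(
        membership=_canonical_membership(kept),
        modularity=part.modularity,
        unassigned=part.unassigned | frozenset(dropped),
    )
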