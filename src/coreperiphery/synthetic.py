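"""Synthetic inputs: planted-community benchmarks, tissues, annotations, phenotypes.

Four generators cover every input the analysis consumes:

* :func:`generate_lfr` — a weighted LFR-style benchmark: power-law degree
  and community-size distributions with a weighted mixing fraction mu_w
  controlling the expected share of each node's strength that crosses
  community boundaries.  Edges are placed by a degree-corrected planted
  partition (Chung-Lu style expected-degree) construction, so only the
  distributional properties of the benchmark are reproduced, not the
  micro-behavior of any particular rewiring implementation.
* :func:`generate_tissue` — a tissue-network emulator with a planted
  core-gene set whose concordance with the full communities is tunable:
  at concordance 1 core genes sit in high-strength, community-aligned
  positions with strong core-core edges; at 0 they are scattered with
  weak connections.
* :func:`generate_annotations` — GMT-like term sets with signal terms
  concentrated in single planted clusters plus uniform noise terms.
* :func:`generate_phenotypes` — subject tables with per-gene disruptive
  variants and additive per-subcluster trait effects.

All generators take explicit seeds and are deterministic; none touches
global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .community import Partition, _canonical_membership, louvain
from .concordance import contingency, cramers_v, summarize_replicates, SamplingControl
from .strength import node_strength

logger = logging.getLogger("coreperiphery")

__all__ = [
    "LFRParams",
    "PlantedNetwork",
    "generate_lfr",
    "select_nodes",
    "benchmark_calibration",
    "TissueSimParams",
    "generate_tissue",
    "generate_annotations",
    "PhenotypeSimParams",
    "generate_phenotypes",
]


# ---------------------------------------------------------------------------
# Power-law helpers
# ---------------------------------------------------------------------------

def _truncated_powerlaw_pmf(exponent: float, lo: int, hi: int) -> np.ndarray:
    support = np.arange(lo, hi + 1, dtype=float)
    pmf = support**-exponent
    return pmf / pmf.sum()


def _choose_min_degree(avg: float, exponent: float, hi: int) -> int:
    """Smallest-support lower cutoff whose power-law mean is closest to avg."""
    best, best_err = 1, np.inf
    for lo in range(1, hi + 1):
        pmf = _truncated_powerlaw_pmf(exponent, lo, hi)
        mean = float((np.arange(lo, hi + 1) * pmf).sum())
        err = abs(mean - avg)
        if err < best_err:
            best, best_err = lo, err
        if mean > avg:
            break
    return best


# ---------------------------------------------------------------------------
# LFR-style weighted benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LFRParams:
    """Benchmark parameters (power-law degrees and community sizes).

    Defaults are the benchmark configuration used throughout:
    n=25000, average degree 300, max degree 3000, degree exponent 2,
    community-size exponent 1.5, weighted mixing 0.2, community sizes
    in [4000, 8000].  Scale ``n_nodes``, degrees and community bounds
    together for desk-scale runs (e.g. 1/10 of every count).
    """

    n_nodes: int = 25000
    avg_degree: float = 300.0
    max_degree: int = 3000
    tau_degree: float = 2.0
    tau_community: float = 1.5
    mu_w: float = 0.2
    min_comm: int = 4000
    max_comm: int = 8000
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.mu_w < 1):
            raise ValueError("mu_w must be in (0, 1)")
        if not (self.min_comm <= self.max_comm <= self.n_nodes):
            raise ValueError("need min_comm <= max_comm <= n_nodes")
        if self.avg_degree > self.max_degree:
            raise ValueError("avg_degree must not exceed max_degree")
        if (1 - self.mu_w) * self.max_degree > self.max_comm - 1:
            raise ValueError(
                "infeasible: largest internal degree cannot fit in the largest community"
            )
        if self.min_comm > self.n_nodes:
            raise ValueError("infeasible: min_comm exceeds n_nodes")


@dataclass(frozen=True)
class PlantedNetwork:
    network: nx.Graph
    truth: Partition


def _draw_community_sizes(p: LFRParams, rng: np.random.Generator) -> list[int]:
    pmf = _truncated_powerlaw_pmf(p.tau_community, p.min_comm, p.max_comm)
    support = np.arange(p.min_comm, p.max_comm + 1)
    sizes: list[int] = []
    while sum(sizes) < p.n_nodes:
        sizes.append(int(rng.choice(support, p=pmf)))
    excess = sum(sizes) - p.n_nodes
    # shave the excess off the last community; fold it into earlier ones if
    # that would push it below the minimum size
    if sizes[-1] - excess >= p.min_comm:
        sizes[-1] -= excess
    else:
        deficit = p.n_nodes - sum(sizes[:-1])
        sizes.pop()
        i = 0
        while deficit > 0 and sizes:
            room = p.max_comm - sizes[i % len(sizes)]
            add = min(room, deficit)
            sizes[i % len(sizes)] += add
            deficit -= add
            i += 1
            if i > 10 * len(sizes):
                raise ValueError("infeasible community-size configuration")
        if deficit > 0:
            raise ValueError("infeasible community-size configuration")
    return sizes


def generate_lfr(p: LFRParams) -> PlantedNetwork:
    """Generate a weighted planted-community benchmark network.

    Degrees are drawn from a truncated power law with exponent
    ``tau_degree`` whose lower cutoff is chosen so the mean matches
    ``avg_degree``; community sizes from a truncated power law with
    exponent ``tau_community`` on [min_comm, max_comm].  Each node's
    expected degree is split into an internal part (1 - mu_w) and an
    external part (mu_w); edges are realized as independent Bernoulli
    draws with Chung-Lu probabilities within and between communities, so
    the expected external strength fraction per node equals mu_w.  Edge
    weights are i.i.d. Uniform(0.3, 0.7).
    """
    p.validate()
    rng = np.random.default_rng(int(p.seed))
    n = p.n_nodes

    kmin = _choose_min_degree(p.avg_degree, p.tau_degree, p.max_degree)
    deg_pmf = _truncated_powerlaw_pmf(p.tau_degree, kmin, p.max_degree)
    degrees = rng.choice(np.arange(kmin, p.max_degree + 1), size=n, p=deg_pmf).astype(float)

    sizes = _draw_community_sizes(p, rng)
    perm = rng.permutation(n)
    comm_of = np.empty(n, dtype=int)
    blocks: list[np.ndarray] = []
    start = 0
    for cid, size in enumerate(sizes):
        members = perm[start : start + size]
        comm_of[members] = cid
        blocks.append(np.sort(members))
        start += size

    d_int = (1.0 - p.mu_w) * degrees
    d_ext = p.mu_w * degrees
    d_ext_total = d_ext.sum()
    share = np.array([d_ext[b].sum() for b in blocks]) / d_ext_total

    net = nx.Graph()
    net.add_nodes_from(range(n))

    # internal edges, community by community
    for cid, members in enumerate(blocks):
        d = d_int[members]
        dc = d.sum()
        if dc <= 0:
            continue
        prob = np.minimum(np.outer(d, d) / dc, 1.0)
        u = rng.random(prob.shape)
        iu = np.triu_indices(len(members), k=1)
        hit = u[iu] < prob[iu]
        aa = members[iu[0][hit]]
        bb = members[iu[1][hit]]
        w = rng.uniform(0.3, 0.7, size=aa.size)
        net.add_weighted_edges_from(zip(aa.tolist(), bb.tolist(), w.tolist()))

    # external edges, community-pair blocks; the sqrt correction keeps the
    # expected external degree at d_ext despite excluding same-community pairs
    n_comm = len(blocks)
    for a in range(n_comm):
        for b in range(a + 1, n_comm):
            ma, mb = blocks[a], blocks[b]
            denom = d_ext_total * np.sqrt((1 - share[a]) * (1 - share[b]))
            prob = np.minimum(np.outer(d_ext[ma], d_ext[mb]) / denom, 1.0)
            u = rng.random(prob.shape)
            ii, jj = np.nonzero(u < prob)
            aa = ma[ii]
            bb = mb[jj]
            w = rng.uniform(0.3, 0.7, size=aa.size)
            net.add_weighted_edges_from(zip(aa.tolist(), bb.tolist(), w.tolist()))

    groups = [set(b.tolist()) for b in blocks]
    truth = Partition(membership=_canonical_membership(groups))
    return PlantedNetwork(network=net, truth=truth)


def external_weight_fractions(planted: PlantedNetwork) -> np.ndarray:
    """Per-node fraction of strength on edges that leave the node's community."""
    member = planted.truth.membership
    fracs = []
    for node in planted.network.nodes:
        tot = ext = 0.0
        for _, v, w in planted.network.edges(node, data="weight"):
            tot += w
            if member[v] != member[node]:
                ext += w
        if tot > 0:
            fracs.append(ext / tot)
    return np.asarray(fracs)


# ---------------------------------------------------------------------------
# Node selection and benchmark calibration
# ---------------------------------------------------------------------------

def select_nodes(planted: PlantedNetwork, mode: str, size: int, seed: int = 0) -> list:
    """Select benchmark nodes for the subgraph-calibration experiment.

    ``top_strength`` takes the ``size`` highest-strength nodes (ties by
    node id); ``distribution_matched`` draws a uniform random sample,
    which reproduces the full strength distribution in expectation.
    """
    nodes = list(planted.network.nodes)
    if size > len(nodes):
        raise ValueError("size exceeds the number of nodes")
    if mode == "top_strength":
        s = node_strength(planted.network)
        return sorted(nodes, key=lambda x: (-s[x], x))[:size]
    if mode == "distribution_matched":
        rng = np.random.default_rng(int(seed))
        idx = rng.choice(len(nodes), size=size, replace=False)
        return [nodes[i] for i in sorted(idx.tolist())]
    raise ValueError(f"unknown selection mode: {mode!r}")


def _subgraph_v(
    planted: PlantedNetwork, nodes: list, seed: int, n_restarts: int
) -> float:
    sub = planted.network.subgraph(nodes).copy()
    if sub.number_of_edges() == 0:
        raise ValueError("induced subgraph has no edges")
    part = louvain(sub, seed=seed, n_restarts=n_restarts)
    return cramers_v(contingency(part, planted.truth)).v


def benchmark_calibration(
    p: LFRParams,
    size: int,
    n_replicates: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[float, SamplingControl]:
    """Cramér's V calibration of subgraph selection on a planted benchmark.

    Generates the benchmark, then measures the concordance of induced
    subgraph communities with the planted truth for two selection modes:
    the top-``size`` strength nodes (deterministic, reported once) and
    ``n_replicates`` uniform samples of the same size (aggregated with
    mean, sd and a t-based 95% CI).  Strong nodes are expected to retain
    the planted community structure (V = 1); distribution-matched
    samples score lower.
    """
    planted = generate_lfr(p)
    rng = np.random.default_rng(int(seed))
    strong = select_nodes(planted, "top_strength", size)
    v_strong = _subgraph_v(planted, strong, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
    vs = []
    for _ in range(n_replicates):
        for _attempt in range(6):
            sample = select_nodes(
                planted, "distribution_matched", size, seed=int(rng.integers(2**31))
            )
            sub = planted.network.subgraph(sample)
            if sub.number_of_edges() > 0:
                break
            logger.warning("edgeless distribution-matched sample, redrawing")
        else:
            raise ValueError("edgeless induced subgraph after repeated redraws")
        vs.append(
            _subgraph_v(planted, sample, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
        )
    return v_strong, summarize_replicates(vs)


# ---------------------------------------------------------------------------
# Tissue emulator with tunable core-periphery concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueSimParams:
    """Parameters of the tissue-network emulator.

    ``concordance`` interpolates between two regimes: at 1 every core
    gene is community-aligned and strength-central (strong core-core
    edges inside one full community); at 0 core genes are scattered
    uniformly with weak core-core edges.  ``weight_scale`` rescales the
    baseline edge weights (clipped into (0, 1]).
    """

    n_nodes: int = 600
    n_communities: int = 4
    core_size: int = 80
    concordance: float = 1.0
    weight_scale: float = 1.0
    avg_within_degree: float = 12.0
    avg_between_degree: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.concordance <= 1):
            raise ValueError("concordance must be in [0, 1]")
        if self.core_size <= 0:
            raise ValueError("core_size must be positive")
        if self.core_size > self.n_nodes:
            raise ValueError("core_size exceeds n_nodes")
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")


def _clip_weight(w: np.ndarray | float) -> np.ndarray | float:
    return np.clip(w, 1e-6, 1.0)


def generate_tissue(p: TissueSimParams) -> tuple[nx.Graph, set, Partition]:
    """Generate a tissue network, its planted core-gene set, and the truth.

    The backbone is a planted partition: ``n_communities`` equal groups,
    dense within (average within-degree ``avg_within_degree``) and
    sparse between, with strong intra-community weights and weak
    inter-community weights.  Core genes are then planted: each is
    "aligned" with probability ``concordance`` — kept in one community's
    high-strength stratum, given extra strong edges to its community and
    to fellow aligned cores there — and otherwise "scattered": it
    receives only a few weak core-core edges irrespective of community.
    """
    p.validate()
    rng = np.random.default_rng(int(p.seed))
    n, k = p.n_nodes, p.n_communities
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    comm_of = np.repeat(np.arange(k), sizes)
    comm_of = comm_of[rng.permutation(n)]
    blocks = [np.nonzero(comm_of == c)[0] for c in range(k)]

    net = nx.Graph()
    net.add_nodes_from(range(n))

    # backbone planted partition
    for c in range(k):
        members = blocks[c]
        m = len(members)
        p_in = min(1.0, p.avg_within_degree / max(m - 1, 1))
        u = rng.random((m, m))
        iu = np.triu_indices(m, k=1)
        hit = u[iu] < p_in
        aa, bb = members[iu[0][hit]], members[iu[1][hit]]
        w = _clip_weight(rng.uniform(0.4, 0.8, size=aa.size) * p.weight_scale)
        net.add_weighted_edges_from(zip(aa.tolist(), bb.tolist(), np.atleast_1d(w).tolist()))
    p_out = min(1.0, p.avg_between_degree / max(n - n // k, 1))
    for a in range(k):
        for b in range(a + 1, k):
            ma, mb = blocks[a], blocks[b]
            u = rng.random((len(ma), len(mb)))
            ii, jj = np.nonzero(u < p_out)
            w = _clip_weight(rng.uniform(0.05, 0.3, size=ii.size) * p.weight_scale)
            net.add_weighted_edges_from(
                zip(ma[ii].tolist(), mb[jj].tolist(), np.atleast_1d(w).tolist())
            )

    # plant the core genes
    core = rng.choice(n, size=p.core_size, replace=False)
    aligned_mask = rng.random(p.core_size) < p.concordance
    aligned = core[aligned_mask]
    scattered = core[~aligned_mask]

    # aligned cores: strength boost within their own community + dense strong
    # core-core edges among co-community aligned cores
    for g in aligned:
        members = blocks[comm_of[g]]
        others = members[members != g]
        extra = rng.choice(others, size=min(8, others.size), replace=False)
        for v in extra:
            w = float(_clip_weight(rng.uniform(0.7, 0.95) * p.weight_scale))
            net.add_edge(int(g), int(v), weight=w)
    for c in range(k):
        in_c = aligned[comm_of[aligned] == c]
        for i in range(len(in_c)):
            for j in range(i + 1, len(in_c)):
                if rng.random() < 0.6:
                    w = float(_clip_weight(rng.uniform(0.7, 0.95) * p.weight_scale))
                    net.add_edge(int(in_c[i]), int(in_c[j]), weight=w)

    # scattered cores: a few weak core-core edges, community-blind
    for g in scattered:
        others = core[core != g]
        partners = rng.choice(others, size=min(2, others.size), replace=False)
        for v in partners:
            if not net.has_edge(int(g), int(v)):
                w = float(_clip_weight(rng.uniform(0.05, 0.2) * p.weight_scale))
                net.add_edge(int(g), int(v), weight=w)

    truth = Partition(membership=_canonical_membership([set(b.tolist()) for b in blocks]))
    return net, set(core.tolist()), truth


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------

def generate_annotations(
    truth: Partition,
    core: set,
    n_terms: int = 50,
    signal_terms_per_cluster: int = 2,
    seed: int = 0,
) -> dict[str, tuple[str, frozenset]]:
    """Synthesize a GMT-like annotation set over the core genes.

    Signal terms draw >= 70% of their members from a single planted
    cluster (the rest uniformly); noise terms are uniform over the core
    universe.  Term sizes are logged.
    """
    rng = np.random.default_rng(int(seed))
    universe = sorted(g for g in truth.membership if g in core) if core else sorted(truth.membership)
    clusters: dict[int, list] = {}
    for g in universe:
        clusters.setdefault(truth.membership[g], []).append(g)
    n_signal = signal_terms_per_cluster * len(clusters)
    if n_terms < n_signal:
        raise ValueError("n_terms smaller than the number of signal terms")
    terms: dict[str, tuple[str, frozenset]] = {}
    t = 0
    for cid in sorted(clusters):
        home = clusters[cid]
        for _ in range(signal_terms_per_cluster):
            size = int(rng.integers(10, 26))
            n_home = min(len(home), max(1, int(np.ceil(0.8 * size))))
            members = set(rng.choice(home, size=n_home, replace=False).tolist())
            outside = [g for g in universe if g not in members]
            n_out = min(len(outside), size - n_home)
            if n_out > 0:
                members |= set(rng.choice(outside, size=n_out, replace=False).tolist())
            terms[f"SIG{t:03d}"] = (f"signal term for cluster {cid}", frozenset(members))
            t += 1
    for i in range(n_terms - n_signal):
        size = int(rng.integers(10, 26))
        members = frozenset(rng.choice(universe, size=min(size, len(universe)), replace=False).tolist())
        terms[f"NOISE{i:03d}"] = ("noise term", members)
    logger.info("generated %d terms, sizes %s...", len(terms), [len(v[1]) for v in list(terms.values())[:5]])
    return terms


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSimParams:
    """Parameters of the subject phenotype simulator.

    Defaults emulate an ASD cohort: non-carrier baseline IQ around 82
    points with population-like spread (sd 15), baseline age of walking
    13.8 months (sd 3), and a per-gene disruptive-variant probability of
    0.01.  ``effects`` maps a subcluster label to (iq_shift in points,
    walk_shift in months) added to carriers of a variant in that
    subcluster's genes.
    """

    n_subjects: int = 3000
    baseline_iq: float = 82.0
    baseline_walk: float = 13.8
    iq_sd: float = 15.0
    walk_sd: float = 3.0
    mutation_rate: float = 0.01
    effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.iq_sd <= 0 or self.walk_sd <= 0:
            raise ValueError("noise sds must be positive")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must be a probability")


def generate_phenotypes(
    p: PhenotypeSimParams, subclusters: Mapping[str, set]
) -> pd.DataFrame:
    """Simulate a subject table with disruptive variants and trait effects.

    Each subject carries each gene's disruptive variant independently
    with probability ``mutation_rate``; traits are baseline + the sum of
    the effects of every subcluster hit + Gaussian noise.  Subjects with
    no variant form the natural reference group.
    """
    p.validate()
    rng = np.random.default_rng(int(p.seed))
    genes = sorted({g for gs in subclusters.values() for g in gs})
    gene_idx = {g: i for i, g in enumerate(genes)}
    cell_masks = {
        cell: np.array([g in gs for g in genes]) for cell, gs in subclusters.items()
    }
    hits = rng.random((p.n_subjects, len(genes))) < p.mutation_rate
    iq = p.baseline_iq + rng.normal(0.0, p.iq_sd, size=p.n_subjects)
    walk = p.baseline_walk + rng.normal(0.0, p.walk_sd, size=p.n_subjects)
    for cell, (iq_shift, walk_shift) in p.effects.items():
        if cell not in cell_masks:
            raise ValueError(f"effect refers to unknown subcluster {cell!r}")
        carrier = hits[:, cell_masks[cell]].any(axis=1)
        iq[carrier] += iq_shift
        walk[carrier] += walk_shift
    gene_arr = np.array(genes, dtype=object)
    records = []
    for s in range(p.n_subjects):
        gset = frozenset(gene_arr[hits[s]].tolist())
        records.append((f"S{s:05d}", float(iq[s]), float(walk[s]), gset))
    return pd.DataFrame(records, columns=["subject_id", "iq", "age_of_walking", "disruptive_genes"])
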