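"""Core-periphery community concordance: contingency tables and Cramér's V.

The central question is how strongly the community structure detected on
a core-gene subgraph depends on the community structure of the full
tissue network.  Intersecting the two partitions yields a contingency
table (rows CC1..CCr = core clusters, columns FC1..FCk = full clusters);
its Pearson chi-squared statistic

    X^2 = sum_ij (n_ij - n_i. n_.j / n)^2 / (n_i. n_.j / n)

normalized by table shape gives Cramér's V,

    V = sqrt( (X^2 / n) / min(k - 1, r - 1) )  in [0, 1],

the concordance measure.  A strength-weighted node-sampling control
(same subgraph size as the core, nodes drawn with probability
proportional to strength) provides the reference distribution a
"representative" subgraph would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .community import Partition, louvain
from .strength import node_strength

logger = logging.getLogger("coreperiphery")

__all__ = [
    "core_subgraph",
    "ContingencyTable",
    "contingency",
    "reorder_diagonal",
    "pearson_chi2",
    "chi_squared",
    "CramersVResult",
    "cramers_v",
    "sample_nodes_by_strength",
    "SamplingControl",
    "sample_control",
]


def core_subgraph(net: nx.Graph, core: Iterable) -> nx.Graph:
    """Induced subgraph keeping only edges that join two core genes.

    Core genes absent from the network, and core genes left isolated
    (no core-core edge), are dropped with a logged count.  An edgeless
    result is an error — there is no subgraph to cluster.
    """
    core = set(core)
    present = core & set(net.nodes)
    absent = len(core) - len(present)
    sub = net.subgraph(present).copy()
    isolated = [n for n in sub.nodes if sub.degree(n) == 0]
    sub.remove_nodes_from(isolated)
    if absent:
        logger.info("%d core gene(s) absent from the network", absent)
    if isolated:
        logger.info("%d isolated core gene(s) dropped from the core subgraph", len(isolated))
    if sub.number_of_edges() == 0:
        raise ValueError("core subgraph has no edges")
    return sub


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of core-cluster vs full-cluster membership.

    ``counts[i, j]`` is the number of genes in core cluster i (row,
    CC{i+1}) and full cluster j (column, FC{j+1}).
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match the count matrix")

    @classmethod
    def from_counts(cls, counts) -> "ContingencyTable":
        c = np.asarray(counts, dtype=float)
        return cls(
            counts=c,
            row_labels=tuple(f"CC{i + 1}" for i in range(c.shape[0])),
            col_labels=tuple(f"FC{j + 1}" for j in range(c.shape[1])),
        )

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def drop_empty(self) -> "ContingencyTable":
        """Remove all-zero rows and columns (warned; X^2 is undefined on them)."""
        rows = self.row_totals > 0
        cols = self.col_totals > 0
        if rows.all() and cols.all():
            return self
        logger.warning(
            "dropping %d empty row(s) and %d empty column(s) from contingency table",
            int((~rows).sum()),
            int((~cols).sum()),
        )
        return ContingencyTable(
            counts=self.counts[np.ix_(rows, cols)],
            row_labels=tuple(l for l, k in zip(self.row_labels, rows) if k),
            col_labels=tuple(l for l, k in zip(self.col_labels, cols) if k),
        )

    def cell_genes(self, core_part: Partition, full_part: Partition) -> dict[str, set]:
        """Map each cell label 'CCi:FCj' to the genes it contains."""
        out: dict[str, set] = {}
        for g, i in core_part.membership.items():
            if g in full_part.membership:
                j = full_part.membership[g]
                out.setdefault(f"CC{i + 1}:FC{j + 1}", set()).add(g)
        return out


def contingency(core_part: Partition, full_part: Partition) -> ContingencyTable:
    """Intersect a core-subgraph partition with a full-network partition.

    Only genes assigned in *both* partitions are counted; core genes the
    full partition left unassigned (small-cluster filtering) are logged
    and excluded.
    """
    shared = [g for g in core_part.membership if g in full_part.membership]
    skipped = len(core_part.membership) - len(shared)
    if not shared:
        raise ValueError("partitions share no nodes")
    if skipped:
        logger.info("%d core gene(s) not assigned in the full partition; excluded", skipped)
    r = core_part.n_communities
    k = full_part.n_communities
    counts = np.zeros((r, k), dtype=float)
    for g in shared:
        counts[core_part.membership[g], full_part.membership[g]] += 1
    return ContingencyTable.from_counts(counts)


def reorder_diagonal(t: ContingencyTable) -> ContingencyTable:
    """Permute columns to put the largest intersections on the diagonal.

    The column order maximizes the diagonal sum via maximum-weight
    assignment; columns beyond the number of rows are appended in
    descending column-total order.  Counts are unchanged.
    """
    c = t.counts
    r, k = c.shape
    d = min(r, k)
    # assignment of rows to columns maximizing the matched sum
    row_ind, col_ind = optimize.linear_sum_assignment(c, maximize=True)
    matched = dict(zip(row_ind, col_ind))
    order = [matched[i] for i in range(d) if i in matched]
    rest = [j for j in range(k) if j not in set(order)]
    rest.sort(key=lambda j: (-c[:, j].sum(), j))
    order = order + rest
    return ContingencyTable(
        counts=c[:, order],
        row_labels=t.row_labels,
        col_labels=tuple(t.col_labels[j] for j in order),
    )


def pearson_chi2(counts: np.ndarray) -> float:
    """Uncorrected Pearson X^2 of a count matrix with positive marginals."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n == 0:
        raise ValueError("chi-squared undefined on an empty table")
    expected = np.outer(c.sum(axis=1), c.sum(axis=0)) / n
    if (expected == 0).any():
        raise ValueError("chi-squared undefined with zero marginals; drop empty lines first")
    return float(((c - expected) ** 2 / expected).sum())


def chi_squared(t: ContingencyTable) -> float:
    """X^2 of a contingency table after dropping empty rows/columns."""
    return pearson_chi2(t.drop_empty().counts)


@dataclass(frozen=True)
class CramersVResult:
    chi2: float
    v: float
    df_norm: int
    n: int
    r: int
    k: int


def cramers_v(t: ContingencyTable) -> CramersVResult:
    """Cramér's V = sqrt((X^2/n) / min(k-1, r-1)) on the non-empty table.

    Dimensions r (rows) and k (columns) refer to the table after empty
    rows/columns are dropped; fewer than 2 of either leaves the
    association undefined and raises.
    """
    td = t.drop_empty()
    r, k = td.shape
    if r < 2 or k < 2:
        raise ValueError(f"association undefined on a {r}x{k} table")
    chi2 = pearson_chi2(td.counts)
    n = td.n
    df_norm = min(k - 1, r - 1)
    v = float(np.sqrt((chi2 / n) / df_norm))
    # guard against floating round-up past the theoretical maximum of 1
    v = min(v, 1.0)
    return CramersVResult(chi2=chi2, v=v, df_norm=df_norm, n=int(n), r=r, k=k)


def sample_nodes_by_strength(
    net: nx.Graph, size: int, rng: np.random.Generator
) -> list:
    """Draw ``size`` distinct nodes with probability proportional to strength.

    Sequential draws without replacement with renormalization after each
    pick (numpy's weighted ``choice`` without replacement implements
    exactly this scheme).
    """
    nodes = list(net.nodes)
    if size > len(nodes):
        raise ValueError("sample size exceeds the number of nodes")
    s = np.array([d for _, d in net.degree(weight="weight")], dtype=float)
    if s.sum() == 0:
        raise ValueError("cannot strength-weight sampling on an edgeless network")
    p = s / s.sum()
    idx = rng.choice(len(nodes), size=size, replace=False, p=p)
    return [nodes[i] for i in idx]


@dataclass(frozen=True)
class SamplingControl:
    """Replicate Cramér's V values of strength-weighted sampled subgraphs."""

    n_replicates: int
    replicate_v: tuple[float, ...]
    mean_v: float
    sd_v: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.replicate_v) != self.n_replicates:
            raise ValueError("replicate count mismatch")


def summarize_replicates(values: Iterable[float]) -> SamplingControl:
    """Aggregate replicate V values: mean, sd, and t-based 95% CI."""
    vals = tuple(float(v) for v in values)
    arr = np.asarray(vals)
    mean = float(arr.mean())
    if arr.size > 1:
        sd = float(arr.std(ddof=1))
        half = float(stats.t.ppf(0.975, df=arr.size - 1)) * sd / np.sqrt(arr.size)
    else:
        sd = 0.0
        half = 0.0
    return SamplingControl(
        n_replicates=arr.size,
        replicate_v=vals,
        mean_v=mean,
        sd_v=sd,
        ci95=(mean - half, mean + half),
    )


def sample_control(
    net: nx.Graph,
    size: int,
    seed: int,
    n_replicates: int,
    full_part: Partition,
    n_restarts: int = 10,
    max_retries: int = 5,
) -> SamplingControl:
    """Strength-weighted sampling control for the concordance measure.

    Each replicate draws ``size`` nodes with probability proportional to
    their strength in ``net``, keeps only the edges joining sampled
    nodes, clusters that subgraph, and records Cramér's V of its
    partition against ``full_part``.  A replicate whose induced subgraph
    is edgeless is resampled (logged), at most ``max_retries`` times.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(int(seed))
    vs: list[float] = []
    for rep in range(n_replicates):
        for attempt in range(max_retries + 1):
            nodes = sample_nodes_by_strength(net, size, rng)
            sub = net.subgraph(nodes).copy()
            if sub.number_of_edges() > 0:
                break
            logger.warning("replicate %d: edgeless induced subgraph, resampling", rep)
        else:
            raise ValueError(f"replicate {rep}: edgeless subgraph after {max_retries} retries")
        part = louvain(sub, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
        vs.append(cramers_v(contingency(part, full_part)).v)
    return summarize_replicates(vs)
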