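"""Fixed target-vs-background hypergeometric gene-set enrichment.

For a background of N genes containing B members of a term, and a target
list of n genes containing b of them, enrichment is tested with the
hypergeometric upper tail P(X >= b) and quantified by the fold

    fold = (b / n) / (B / N).

q-values come from Benjamini-Hochberg step-up FDR across all terms
tested for one target list.  Genes without any annotation still count
toward N and n (two-list semantics: the background is a gene list, not
the annotated universe).  A size-matched regrouping of the target
partition provides the null control, and the per-cell term-count matrix
feeds the same Cramér's V machinery used for partition concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .community import Partition
from .concordance import ContingencyTable, CramersVResult, cramers_v

logger = logging.getLogger("coreperiphery")

__all__ = [
    "hypergeom_upper",
    "enrichment_fold",
    "bh_fdr",
    "EnrichmentRecord",
    "enrich_cluster",
    "CellSummary",
    "summarize_cells",
    "RegroupControl",
    "regroup_control",
    "term_table_v",
]


def hypergeom_upper(N: int, B: int, n: int, b: int) -> float:
    """Upper-tail P(X >= b) for X ~ Hypergeometric(N, B, n).

    Computed via the survival function in log space (scipy), stable for
    the small tail probabilities typical of strong enrichments.
    """
    if not (0 <= b <= min(B, n) and B <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, B={B}, n={n}, b={b}")
    if b == 0:
        return 1.0
    return float(stats.hypergeom.sf(b - 1, N, B, n))


def enrichment_fold(N: int, B: int, n: int, b: int) -> float:
    """Enrichment ratio (b/n)/(B/N); undefined (error) when B or n is 0."""
    if B <= 0:
        raise ValueError("fold undefined for a term absent from the background (B = 0)")
    if n <= 0:
        raise ValueError("fold undefined for an empty target (n = 0)")
    if not (b <= min(B, n) and B <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, B={B}, n={n}, b={b}")
    return (b / n) / (B / N)


def bh_fdr(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.  ``m`` defaults
    to the number of p-values; passing a larger ``m`` treats the list as
    part of a wider family of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = p.size if m is None else int(m)
    if m_eff < p.size:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_eff / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's hypergeometric result for a fixed target list."""

    term_id: str
    term_name: str
    N: int
    B: int
    n: int
    b: int
    fold: float
    p: float
    q: float
    significant: bool


def enrich_cluster(
    target: set,
    background: set,
    annotations: Mapping[str, tuple[str, frozenset]],
    p_cut: float = 0.001,
    q_cut: float = 0.05,
) -> tuple[list[EnrichmentRecord], dict[str, frozenset]]:
    """Hypergeometric enrichment of ``target`` against ``background``.

    One record per term with at least one background member; BH-FDR is
    applied across all tested terms of this target; a term is
    significant when both p < ``p_cut`` and q < ``q_cut``.  Records come
    back sorted by q (then p, then term id).  The second return value
    maps each term id to its overlap genes (term members inside the
    target), used for unique enriched-gene counting.

    Unannotated genes still count toward N and n.
    """
    if not target:
        raise ValueError("empty target gene set")
    if not target <= background:
        raise ValueError("target must be a subset of the background")
    N, n = len(background), len(target)
    rows: list[tuple[str, str, int, int, frozenset]] = []
    for term_id in sorted(annotations):
        name, genes = annotations[term_id]
        bg_genes = genes & background
        B = len(bg_genes)
        if B == 0:
            continue
        overlap = frozenset(bg_genes & target)
        rows.append((term_id, name, B, len(overlap), overlap))
    pvals = [hypergeom_upper(N, B, n, b) for _, _, B, b, _ in rows]
    qvals = bh_fdr(pvals)
    records = []
    overlaps: dict[str, frozenset] = {}
    for (term_id, name, B, b, overlap), p, q in zip(rows, pvals, qvals):
        fold = enrichment_fold(N, B, n, b) if b > 0 else 0.0
        sig = bool(p < p_cut and q < q_cut)
        records.append(
            EnrichmentRecord(
                term_id=term_id, term_name=name, N=N, B=B, n=n, b=b,
                fold=fold, p=p, q=q, significant=sig,
            )
        )
        overlaps[term_id] = overlap
    records.sort(key=lambda r: (r.q, r.p, r.term_id))
    return records, overlaps


@dataclass(frozen=True)
class CellSummary:
    """Functional-coherence summary of one cluster or subcluster cell.

    ``enriched_ratio`` is the unique count of cell genes appearing in at
    least one significant term divided by the cell size;
    ``median_neglog_q`` is the median of -log10 q over the significant
    terms (None when there is none).
    """

    cell: str
    genes_total: int
    genes_enriched: int
    enriched_ratio: float
    n_terms: int
    median_neglog_q: float | None


def summarize_cells(
    cell_genes: Mapping[str, set],
    cell_records: Mapping[str, Sequence[EnrichmentRecord]],
    cell_overlaps: Mapping[str, Mapping[str, frozenset]],
) -> list[CellSummary]:
    """Per-cell unique enriched-gene counts and significant-term summaries."""
    out = []
    for cell in sorted(cell_genes):
        genes = set(cell_genes[cell])
        records = [r for r in cell_records.get(cell, []) if r.significant]
        overlaps = cell_overlaps.get(cell, {})
        enriched: set = set()
        for r in records:
            enriched |= set(overlaps.get(r.term_id, frozenset())) & genes
        ratio = len(enriched) / len(genes) if genes else 0.0
        med = (
            float(np.median([-np.log10(max(r.q, 1e-300)) for r in records]))
            if records
            else None
        )
        out.append(
            CellSummary(
                cell=cell,
                genes_total=len(genes),
                genes_enriched=len(enriched),
                enriched_ratio=ratio,
                n_terms=len(records),
                median_neglog_q=med,
            )
        )
    return out


@dataclass(frozen=True)
class RegroupControl:
    """Null control: enrichment of size-matched random regroupings."""

    n_replicates: int
    terms_per_replicate: tuple[int, ...]
    genes_per_replicate: tuple[int, ...]
    mean_terms: float
    mean_genes: float
    ci95_terms: tuple[float, float]
    ci95_genes: tuple[float, float]


def _mean_ci(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    mean = float(values.mean())
    if values.size > 1 and values.std(ddof=1) > 0:
        half = float(stats.t.ppf(0.975, values.size - 1)) * float(values.std(ddof=1)) / np.sqrt(values.size)
    else:
        half = 0.0
    return mean, (mean - half, mean + half)


def regroup_control(
    clusters: Partition,
    annotations: Mapping[str, tuple[str, frozenset]],
    n_replicates: int = 10,
    seed: int = 0,
    p_cut: float = 0.001,
    q_cut: float = 0.05,
) -> RegroupControl:
    """Re-test enrichment after randomly regrouping genes into size-matched clusters.

    Each replicate permutes the gene -> cluster assignment while keeping
    every cluster's size, reruns the per-cluster enrichment against the
    full gene set as background, and records the total number of
    significant terms and the unique count of enriched genes.  Low
    replicate counts relative to the true clustering indicate that the
    detected functional homogeneity is not a size artifact.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(int(seed))
    genes = sorted(clusters.membership)
    labels = np.array([clusters.membership[g] for g in genes])
    background = set(genes)
    n_terms_rep, n_genes_rep = [], []
    for _ in range(n_replicates):
        perm = rng.permutation(len(genes))
        shuffled = labels[perm]
        total_terms = 0
        enriched: set = set()
        for cid in np.unique(shuffled):
            pseudo = {g for g, l in zip(genes, shuffled) if l == cid}
            records, overlaps = enrich_cluster(pseudo, background, annotations, p_cut, q_cut)
            for r in records:
                if r.significant:
                    total_terms += 1
                    enriched |= set(overlaps[r.term_id])
        n_terms_rep.append(total_terms)
        n_genes_rep.append(len(enriched))
    t_arr = np.asarray(n_terms_rep, dtype=float)
    g_arr = np.asarray(n_genes_rep, dtype=float)
    mean_t, ci_t = _mean_ci(t_arr)
    mean_g, ci_g = _mean_ci(g_arr)
    return RegroupControl(
        n_replicates=n_replicates,
        terms_per_replicate=tuple(int(x) for x in n_terms_rep),
        genes_per_replicate=tuple(int(x) for x in n_genes_rep),
        mean_terms=mean_t,
        mean_genes=mean_g,
        ci95_terms=ci_t,
        ci95_genes=ci_g,
    )


def term_table_v(
    term_counts: Mapping[str, int] | np.ndarray, shape: tuple[int, int] | None = None
) -> CramersVResult:
    """Cramér's V on the matrix of significant-term counts per cell.

    Accepts either a ready (r x k) count matrix, or a mapping from cell
    labels 'CCi:FCj' to term counts together with the table ``shape``
    (r, k).  Measures how concentrated functional signal is on the
    core-cluster x full-cluster grid.
    """
    if isinstance(term_counts, Mapping):
        if shape is None:
            raise ValueError("shape (r, k) required with a cell-label mapping")
        r, k = shape
        mat = np.zeros((r, k), dtype=float)
        for cell, count in term_counts.items():
            cc, fc = cell.split(":")
            mat[int(cc[2:]) - 1, int(fc[2:]) - 1] = count
    else:
        mat = np.asarray(term_counts, dtype=float)
    table = ContingencyTable.from_counts(mat)
    return cramers_v(table)
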