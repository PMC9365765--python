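"""Node strength and core-gene centrality testing.

Node strength — the weighted generalization of degree, s_i = sum of the
weights of node i's incident edges — is the centrality measure used
throughout.  Per tissue, core genes are tested for significantly higher
strength than the remaining (peripheral) genes with a two-sided
Mann-Whitney U test; across tissues, a 2x2 chi-squared contrasts the
brain-related and non-brain-related tissue groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "node_strength",
    "CentralityResult",
    "centrality_test",
    "TissueEnrichmentResult",
    "tissue_enrichment",
]


def node_strength(net: nx.Graph) -> dict:
    """Per-node sum of incident edge weights; isolated nodes get 0.

    Satisfies the weighted handshake identity
    ``sum(strengths) == 2 * total edge weight``.
    """
    return dict(net.degree(weight="weight"))


@dataclass(frozen=True)
class CentralityResult:
    """Outcome of one per-tissue core-vs-peripheral strength comparison.

    ``core_central`` requires both significance (p < alpha) and a higher
    core median — "central" means *higher* strength, not merely
    different.
    """

    tissue: str
    u_statistic: float
    p_value: float
    core_median: float
    peripheral_median: float
    core_central: bool


def centrality_test(
    strengths: Mapping, core: Iterable, alpha: float = 0.05, tissue: str = ""
) -> CentralityResult:
    """Two-sided Mann-Whitney U of core vs peripheral node strengths.

    Uses SciPy's exact null distribution for small tie-free groups and
    the tie-corrected normal approximation otherwise (``method="auto"``:
    exact when both groups have <= 8 observations and no ties).

    Raises
    ------
    ValueError
        If either group is empty, or if every observation is tied (the
        U statistic is then degenerate).
    """
    core = set(core)
    core_s = np.asarray([s for n, s in strengths.items() if n in core], dtype=float)
    peri_s = np.asarray([s for n, s in strengths.items() if n not in core], dtype=float)
    if core_s.size == 0:
        raise ValueError("degenerate core group: no core gene present in the network")
    if peri_s.size == 0:
        raise ValueError("degenerate peripheral group: every node is a core gene")
    pooled = np.concatenate([core_s, peri_s])
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate comparison: all strengths tied")
    res = stats.mannwhitneyu(core_s, peri_s, alternative="two-sided", method="auto")
    core_med = float(np.median(core_s))
    peri_med = float(np.median(peri_s))
    return CentralityResult(
        tissue=tissue,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        core_median=core_med,
        peripheral_median=peri_med,
        core_central=bool(res.pvalue < alpha and core_med > peri_med),
    )


@dataclass(frozen=True)
class TissueEnrichmentResult:
    """2x2 aggregation of per-tissue centrality calls by brain relatedness.

    ``enrichment_factor`` is the ratio of the proportion of brain-related
    tissues in which the core genes are central to the same proportion
    among non-brain tissues; ``None`` when undefined (no central
    non-brain tissue).
    """

    central_brain: int
    noncentral_brain: int
    central_nonbrain: int
    noncentral_nonbrain: int
    enrichment_factor: float | None
    chi2: float
    chi2_p: float


def tissue_enrichment(
    results: Iterable[CentralityResult], labels: pd.DataFrame
) -> TissueEnrichmentResult:
    """Aggregate per-tissue centrality calls into a brain-vs-rest 2x2 table.

    The chi-squared statistic is the uncorrected Pearson X^2 on the 2x2
    table (df = 1), i.e. the same formula applied to partition
    contingency tables elsewhere in the package.
    """
    label_map = dict(zip(labels["tissue"], labels["brain_related"]))
    counts = np.zeros((2, 2), dtype=int)  # rows: brain / nonbrain; cols: central / not
    for r in results:
        if r.tissue not in label_map:
            raise ValueError(f"tissue {r.tissue!r} has no brain-related label")
        i = 0 if label_map[r.tissue] else 1
        j = 0 if r.core_central else 1
        counts[i, j] += 1
    cb, ncb = int(counts[0, 0]), int(counts[0, 1])
    cn, ncn = int(counts[1, 0]), int(counts[1, 1])
    total_brain = cb + ncb
    total_nonbrain = cn + ncn
    if total_brain == 0 or total_nonbrain == 0:
        raise ValueError("both brain and non-brain tissue groups must be non-empty")
    if cn == 0:
        factor = None
    else:
        factor = (cb / total_brain) / (cn / total_nonbrain)
    # local import avoids a hard module cycle (concordance also uses strengths)
    from .concordance import pearson_chi2

    chi2 = pearson_chi2(counts.astype(float))
    p = float(stats.chi2.sf(chi2, df=1))
    return TissueEnrichmentResult(
        central_brain=cb,
        noncentral_brain=ncb,
        central_nonbrain=cn,
        noncentral_nonbrain=ncn,
        enrichment_factor=factor,
        chi2=chi2,
        chi2_p=p,
    )
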