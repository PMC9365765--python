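"""Genotype-to-phenotype stratification by gene-cluster membership.

Subjects are assigned to a tested subcluster when they carry at least
one disruptive variant in that subcluster's genes — exclusively, even if
they also carry variants elsewhere; everyone else (including carriers of
variants only outside the tested cell) forms the out-group.  Trait
differences are tested with Welch's unequal-variance two-sided t-test
and corrected per trait with BH-FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

logger = logging.getLogger("coreperiphery")

__all__ = ["GroupComparison", "assign_subjects", "welch_compare", "compare_all"]

TRAITS = ("iq", "age_of_walking")


@dataclass(frozen=True)
class GroupComparison:
    """Welch comparison of one trait between cell carriers and everyone else.

    ``difference`` is mean_out - mean_in (positive when carriers score
    lower); the 95% CI is for the mean difference on the same sign
    convention.  ``q`` is filled by :func:`compare_all`.
    """

    group_label: str
    trait: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    difference: float
    t_statistic: float
    df: float
    p: float
    ci95: tuple[float, float]
    q: float | None = None


def assign_subjects(
    subjects: pd.DataFrame, cluster_genes: Mapping[str, set], tested_cell: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split subjects into carriers of the tested cell and all others.

    A subject with variants both in the tested cell and elsewhere is
    assigned exclusively to the tested cell.  The two groups are
    disjoint and jointly exhaustive.  An empty carrier group logs a
    warning (the caller should skip the comparison).
    """
    if tested_cell not in cluster_genes:
        raise ValueError(f"unknown cell {tested_cell!r}")
    genes = set(cluster_genes[tested_cell])
    mask = subjects["disruptive_genes"].map(lambda s: bool(set(s) & genes))
    in_group = subjects[mask]
    out_group = subjects[~mask]
    if in_group.empty:
        logger.warning("cell %s has no variant carriers", tested_cell)
    return in_group, out_group


def welch_compare(
    in_group: pd.DataFrame, out_group: pd.DataFrame, trait: str, group_label: str = ""
) -> GroupComparison:
    """Welch's two-sided unequal-variance t-test on one trait.

    Reports the Welch-Satterthwaite degrees of freedom and the 95%
    confidence interval of the mean difference (out minus in).
    """
    if trait not in in_group.columns:
        raise ValueError(f"unknown trait {trait!r}")
    x = np.asarray(in_group[trait], dtype=float)
    y = np.asarray(out_group[trait], dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 subjects")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    # test statistic oriented as (out - in) so t > 0 when carriers score lower
    res = stats.ttest_ind(y, x, equal_var=False)
    ci = res.confidence_interval(0.95)
    return GroupComparison(
        group_label=group_label,
        trait=trait,
        n_in=x.size,
        n_out=y.size,
        mean_in=float(x.mean()),
        mean_out=float(y.mean()),
        difference=float(y.mean() - x.mean()),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        ci95=(float(ci.low), float(ci.high)),
    )


def compare_all(
    subjects: pd.DataFrame,
    cluster_genes: Mapping[str, set],
    traits: Sequence[str] = TRAITS,
    n_tests: int | None = None,
    min_carriers: int = 2,
) -> list[GroupComparison]:
    """Test every cell on every trait; BH-FDR per trait.

    Cells with fewer than ``min_carriers`` carriers are skipped with a
    warning.  ``n_tests`` overrides the FDR family size (it must be at
    least the number of comparisons actually run per trait); by default
    the family is the set of tested cells.
    """
    results: list[GroupComparison] = []
    for trait in traits:
        trait_results: list[GroupComparison] = []
        for cell in sorted(cluster_genes):
            in_g, out_g = assign_subjects(subjects, cluster_genes, cell)
            if len(in_g) < min_carriers:
                logger.warning("skipping %s / %s: only %d carrier(s)", cell, trait, len(in_g))
                continue
            trait_results.append(welch_compare(in_g, out_g, trait, group_label=cell))
        if not trait_results:
            continue
        qs = bh_fdr([r.p for r in trait_results], m=n_tests)
        for r, q in zip(trait_results, qs):
            results.append(
                GroupComparison(**{**r.__dict__, "q": float(q)})
            )
    return results
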