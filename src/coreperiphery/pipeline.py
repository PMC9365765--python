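"""End-to-end study orchestration from a declarative YAML config.

Per tissue the pipeline runs: node strengths and the core-centrality
test, full-network community detection, small-cluster filtering, the
core subgraph and its clustering, the core-vs-full contingency table
(diagonal-reordered), chi-squared / Cramér's V, the strength-weighted
sampling control, and — when annotations or subjects are configured —
gene-set enrichment with cell summaries plus phenotype stratification.
Every random stage draws its seed deterministically from the master
seed, so identical config + seed reproduce the bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import network_io
from .community import louvain, filter_small
from .concordance import (
    contingency,
    core_subgraph,
    cramers_v,
    reorder_diagonal,
    sample_control,
)
from .enrichment import enrich_cluster, regroup_control, summarize_cells, term_table_v
from .phenotype import compare_all
from .strength import centrality_test, node_strength, tissue_enrichment
from .synthetic import (
    PhenotypeSimParams,
    TissueSimParams,
    generate_annotations,
    generate_phenotypes,
    generate_tissue,
)

logger = logging.getLogger("coreperiphery")

__all__ = ["RunConfig", "run_study", "stage_seed"]


def stage_seed(master: int, *context: Any) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    key = ":".join([str(master), *map(str, context)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Validated study configuration.

    Each tissue entry either points to input files (``network`` and
    ``core_genes``) or carries a ``simulate`` block with tissue-emulator
    parameters.  Thresholds: ``alpha`` for centrality, ``p_cut`` /
    ``q_cut`` for enrichment significance, ``min_cluster_size`` for
    full-network small-cluster filtering.
    """

    seed: int = 0
    output_dir: str = "study_out"
    tissues: list[dict] = field(default_factory=list)
    alpha: float = 0.05
    p_cut: float = 0.001
    q_cut: float = 0.05
    min_cluster_size: int = 10
    n_replicates: int = 10
    n_restarts: int = 10
    annotations: str | dict | None = None
    subjects: str | dict | None = None
    tissue_labels: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = raw.pop("thresholds", {})
        cfg = cls(**{**raw, **thresholds})
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")
        for t in (self.alpha, self.p_cut, self.q_cut):
            if not (0 < t < 1):
                raise ValueError(f"threshold {t} outside (0, 1)")
        if not self.tissues:
            raise ValueError("config lists no tissues")
        for entry in self.tissues:
            if "simulate" in entry:
                continue
            for key in ("network", "core_genes"):
                if key not in entry:
                    raise ValueError(f"tissue entry {entry.get('name')!r} missing {key!r}")
                p = base / entry[key]
                if not p.exists():
                    raise ValueError(f"input file not found: {p}")
                entry[key] = str(p)
        for attr in ("annotations", "subjects", "tissue_labels"):
            val = getattr(self, attr)
            if isinstance(val, str):
                p = base / val
                if not p.exists():
                    raise ValueError(f"input file not found: {p}")
                setattr(self, attr, str(p))


def _load_tissue(entry: dict, master_seed: int):
    name = entry.get("name", "tissue")
    if "simulate" in entry:
        params = dict(entry["simulate"])
        params.setdefault("seed", stage_seed(master_seed, "tissue", name))
        net, core, truth = generate_tissue(TissueSimParams(**params))
        return net, core, truth
    net = network_io.read_network(entry["network"])
    core = set(Path(entry["core_genes"]).read_text().split())
    return net, core, None


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_study(cfg: RunConfig) -> dict:
    """Run the full per-tissue analysis; write artifacts; return the summary.

    Artifacts per tissue (TSV unless noted): strength report, full and
    core partitions, reordered contingency table, concordance JSON,
    sampling-control JSON, enrichment records, cell summaries, phenotype
    comparisons; plus a study-level ``summary.json`` and the aggregate
    brain-vs-rest tissue enrichment when labels are configured.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": cfg.seed, "tissues": {}}
    centrality_results = []

    annotations = None
    if isinstance(cfg.annotations, str):
        annotations = network_io.read_gmt(cfg.annotations)

    subjects = None
    if isinstance(cfg.subjects, str):
        subjects = network_io.read_subjects(cfg.subjects)

    for entry in cfg.tissues:
        name = entry.get("name", "tissue")
        tdir = out / name
        tdir.mkdir(exist_ok=True)
        logger.info("=== tissue %s ===", name)
        net, core, _truth = _load_tissue(entry, cfg.seed)

        # strengths + centrality
        strengths = node_strength(net)
        cres = centrality_test(strengths, core, alpha=cfg.alpha, tissue=name)
        centrality_results.append(cres)
        _write_tsv(
            pd.DataFrame(
                [(n, s, n in core) for n, s in sorted(strengths.items(), key=lambda x: str(x[0]))],
                columns=["gene", "strength", "is_core"],
            ),
            tdir / "strength.tsv",
        )

        # clustering
        full_part = louvain(net, seed=stage_seed(cfg.seed, "full", name), n_restarts=cfg.n_restarts)
        full_part = filter_small(full_part, cfg.min_cluster_size)
        sub = core_subgraph(net, core)
        core_part = louvain(sub, seed=stage_seed(cfg.seed, "core", name), n_restarts=cfg.n_restarts)
        for part, fname in ((full_part, "full_partition.tsv"), (core_part, "core_partition.tsv")):
            _write_tsv(
                pd.DataFrame(
                    sorted(((str(g), c) for g, c in part.membership.items())),
                    columns=["gene", "community"],
                ),
                tdir / fname,
            )

        # concordance
        table = reorder_diagonal(contingency(core_part, full_part))
        pd.DataFrame(table.counts, index=table.row_labels, columns=table.col_labels).to_csv(
            tdir / "contingency.tsv", sep="\t"
        )
        vres = cramers_v(table)
        control = sample_control(
            net,
            size=sub.number_of_nodes(),
            seed=stage_seed(cfg.seed, "sampling", name),
            n_replicates=cfg.n_replicates,
            full_part=full_part,
            n_restarts=cfg.n_restarts,
        )
        tissue_summary: dict[str, Any] = {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "core_subgraph_nodes": sub.number_of_nodes(),
            "core_subgraph_edges": sub.number_of_edges(),
            "core_central": cres.core_central,
            "centrality_p": cres.p_value,
            "full_modularity": full_part.modularity,
            "core_modularity": core_part.modularity,
            "chi2": vres.chi2,
            "cramers_v": vres.v,
            "table_shape": [vres.r, vres.k],
            "sampled_mean_v": control.mean_v,
            "sampled_sd_v": control.sd_v,
            "sampled_ci95": list(control.ci95),
        }
        (tdir / "concordance.json").write_text(
            json.dumps(
                {
                    "chi2": vres.chi2,
                    "v": vres.v,
                    "n": vres.n,
                    "r": vres.r,
                    "k": vres.k,
                    "sampling_control": dataclasses.asdict(control),
                },
                indent=2,
            )
        )

        # enrichment
        ann = annotations
        if ann is None and isinstance(cfg.annotations, dict):
            ann = generate_annotations(
                core_part,
                core,
                seed=stage_seed(cfg.seed, "annotations", name),
                **cfg.annotations,
            )
        cell_genes = table.cell_genes(core_part, full_part)
        if ann is not None:
            background = set(core_part.membership)
            rec_rows = []
            cell_records: dict[str, list] = {}
            cell_overlaps: dict[str, dict] = {}
            targets = {f"CC{c + 1}": g for c, g in enumerate(core_part.communities())}
            targets.update(cell_genes)
            for cell, genes in sorted(targets.items()):
                if not genes:
                    continue
                records, overlaps = enrich_cluster(
                    set(genes), background, ann, p_cut=cfg.p_cut, q_cut=cfg.q_cut
                )
                cell_records[cell] = records
                cell_overlaps[cell] = overlaps
                for r in records:
                    rec_rows.append((cell, r.term_id, r.N, r.B, r.n, r.b, r.fold, r.p, r.q, r.significant))
            _write_tsv(
                pd.DataFrame(
                    rec_rows,
                    columns=["cell", "term", "N", "B", "n", "b", "fold", "p", "q", "significant"],
                ),
                tdir / "enrichment.tsv",
            )
            summaries = summarize_cells(
                {**{k: set(v) for k, v in targets.items() if v}},
                cell_records,
                cell_overlaps,
            )
            _write_tsv(pd.DataFrame([dataclasses.asdict(s) for s in summaries]), tdir / "cell_summaries.tsv")
            term_counts = {
                cell: sum(1 for r in cell_records.get(cell, []) if r.significant)
                for cell in cell_genes
            }
            try:
                tv = term_table_v(term_counts, shape=(core_part.n_communities, full_part.n_communities))
                tissue_summary["term_table_v"] = tv.v
            except ValueError as exc:
                logger.warning("term-table V unavailable: %s", exc)
            rc = regroup_control(
                core_part,
                ann,
                n_replicates=cfg.n_replicates,
                seed=stage_seed(cfg.seed, "regroup", name),
                p_cut=cfg.p_cut,
                q_cut=cfg.q_cut,
            )
            tissue_summary["regroup_mean_terms"] = rc.mean_terms
            tissue_summary["regroup_mean_genes"] = rc.mean_genes

        # phenotype
        subj = subjects
        if subj is None and isinstance(cfg.subjects, dict):
            params = dict(cfg.subjects)
            effects = {k: tuple(v) for k, v in params.pop("effects", {}).items()}
            subj = generate_phenotypes(
                PhenotypeSimParams(
                    seed=stage_seed(cfg.seed, "phenotypes", name), effects=effects, **params
                ),
                {k: set(map(str, v)) for k, v in cell_genes.items()},
            )
        if subj is not None:
            comparisons = compare_all(subj, {k: set(map(str, v)) for k, v in cell_genes.items()})
            _write_tsv(
                pd.DataFrame([dataclasses.asdict(c) for c in comparisons]),
                tdir / "phenotype_comparisons.tsv",
            )
            tissue_summary["n_phenotype_comparisons"] = len(comparisons)

        summary["tissues"][name] = tissue_summary

    if cfg.tissue_labels is not None and len(centrality_results) > 1:
        labels = network_io.read_tissue_labels(cfg.tissue_labels)
        te = tissue_enrichment(centrality_results, labels)
        summary["tissue_enrichment"] = dataclasses.asdict(te)

    if summary["tissues"]:
        best = max(summary["tissues"], key=lambda t: summary["tissues"][t]["cramers_v"])
        summary["highest_v_tissue"] = best
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
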