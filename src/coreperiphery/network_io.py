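"""Readers and writers for the analysis inputs.

Weighted gene networks are exchanged as headerless 3-column edge lists
(gene_a, gene_b, weight), the format used by tissue-specific functional
network downloads ("Top Edges" style files).  Gene evidence scores,
identifier maps and tissue labels are small delimited tables; annotation
sets use the GMT convention; subject phenotype tables carry a
semicolon-separated gene list per subject.

Networks are held as :class:`networkx.Graph` objects with a ``weight``
attribute on every edge — the container every downstream stage consumes.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("coreperiphery")

__all__ = [
    "read_network",
    "write_network",
    "read_gene_scores",
    "select_core_genes",
    "read_identifier_map",
    "map_identifiers",
    "read_tissue_labels",
    "read_gmt",
    "write_gmt",
    "read_subjects",
    "write_subjects",
]


class NetworkParseError(ValueError):
    """Malformed edge-list line; message names the offending line number."""


class WeightValidationError(ValueError):
    """Edge weight outside the admissible interval (0, 1]."""


def _looks_like_header(fields: list[str]) -> bool:
    # A header is detected when the weight column is non-numeric.
    try:
        float(fields[2])
    except ValueError:
        return True
    return False


def read_network(path: str | Path, *, on_invalid_weight: str = "error") -> nx.Graph:
    """Read a weighted undirected gene network from a 3+ column edge list.

    Duplicate undirected pairs are collapsed keeping the maximum weight
    (with a warning); self-loops are dropped and counted.  Weights must
    lie in (0, 1]; set ``on_invalid_weight="clamp"`` to clip out-of-range
    weights into the interval instead of raising.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited file, no header by default; a header
        line is auto-detected when its third column is non-numeric.
    on_invalid_weight
        ``"error"`` (default) raises :class:`WeightValidationError`;
        ``"clamp"`` warns and clips into (0, 1].

    Returns
    -------
    networkx.Graph
        Simple undirected graph with ``weight`` on every edge.
    """
    if on_invalid_weight not in ("error", "clamp"):
        raise ValueError(f"unknown on_invalid_weight policy: {on_invalid_weight!r}")
    path = Path(path)
    net = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"\s+", line)
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            a, b = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise NetworkParseError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                ) from exc
            if not 0.0 < w <= 1.0:
                if on_invalid_weight == "error":
                    raise WeightValidationError(
                        f"{path}:{lineno}: weight {w} outside (0, 1]"
                    )
                logger.warning("%s:%d: clamping weight %g into (0, 1]", path, lineno, w)
                w = min(max(w, 1e-12), 1.0)
            if a == b:
                n_self_loops += 1
                continue
            if net.has_edge(a, b):
                n_duplicates += 1
                if w > net[a][b]["weight"]:
                    net[a][b]["weight"] = w
            else:
                net.add_edge(a, b, weight=w)
    if n_duplicates:
        logger.warning(
            "%s: collapsed %d duplicate undirected pair(s), keeping max weight",
            path,
            n_duplicates,
        )
    if n_self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_self_loops)
    return net


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a canonical tab-separated edge list.

    Edges are emitted with lexicographically sorted endpoints and sorted
    line order so that read -> write -> read round-trips bit-equal.
    """
    lines = []
    for u, v, w in net.edges(data="weight"):
        a, b = sorted((str(u), str(v)))
        lines.append((a, b, repr(float(w))))
    lines.sort()
    with Path(path).open("w") as fh:
        for a, b, w in lines:
            fh.write(f"{a}\t{b}\t{w}\n")


# ---------------------------------------------------------------------------
# Gene score tables and core-gene selection
# ---------------------------------------------------------------------------

def read_gene_scores(path: str | Path) -> pd.DataFrame:
    """Read a 2-column (gene_id, score) table into a DataFrame.

    Gene ids must be unique; scores are kept as strings (they are
    categorical evidence grades, e.g. "1".."6" or "S").
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["gene_id", "score"], dtype=str)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in score table: {dups[:5]}")
    return df


def select_core_genes(table: pd.DataFrame, excluded_scores: Iterable[str]) -> set[str]:
    """Return genes whose evidence score is not in ``excluded_scores``.

    The convention follows curated disease-gene catalogues where the
    weakest evidence grades are dropped before analysis.  An empty result
    is a warning, never an error.
    """
    excluded = {str(s) for s in excluded_scores}
    seen = set(table["score"].astype(str))
    core = set(table.loc[~table["score"].astype(str).isin(excluded), "gene_id"])
    unknown = excluded - seen
    if unknown:
        logger.info("excluded scores never observed in the table: %s", sorted(unknown))
    if not core:
        logger.warning("core gene selection produced an empty set")
    return core


# ---------------------------------------------------------------------------
# Identifier maps
# ---------------------------------------------------------------------------

def read_identifier_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column (symbol, numeric_id) map; duplicate symbols are an error."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["symbol", "numeric_id"], dtype=str)
    if df["symbol"].duplicated().any():
        dups = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate symbols in identifier map: {dups[:5]}")
    return dict(zip(df["symbol"], df["numeric_id"]))


def map_identifiers(
    genes: Iterable[str], idmap: Mapping[str, str]
) -> tuple[set[str], set[str]]:
    """Translate gene identifiers through a symbol -> numeric-id map.

    Returns ``(mapped, unmapped)``; unmapped inputs are logged, never
    fatal — missing conversions are expected between catalogues.
    """
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for g in genes:
        if g in idmap:
            mapped.add(idmap[g])
        else:
            unmapped.add(g)
    if unmapped:
        logger.warning("%d gene id(s) had no mapping and were dropped", len(unmapped))
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Tissue labels
# ---------------------------------------------------------------------------

def read_tissue_labels(path: str | Path) -> pd.DataFrame:
    """Read (tissue_name, brain_related) labels; accepts 1/0, true/false, yes/no."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["tissue", "brain_related"], dtype=str)
    if df["tissue"].duplicated().any():
        raise ValueError("duplicate tissue names in label table")
    truthy = {"1", "true", "yes", "brain"}
    df["brain_related"] = df["brain_related"].str.lower().isin(truthy)
    return df


# ---------------------------------------------------------------------------
# Annotation sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into ``{term_id: (description, gene set)}``.

    Terms with empty gene sets or repeated ids violate the format and
    raise.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term_id, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term_id!r} has no genes")
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            terms[term_id] = (desc, genes)
    return terms


def write_gmt(terms: Mapping[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term_id in sorted(terms):
            desc, genes = terms[term_id]
            fh.write("\t".join([term_id, desc, *sorted(map(str, genes))]) + "\n")


# ---------------------------------------------------------------------------
# Subject phenotype tables
# ---------------------------------------------------------------------------

def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read a subject phenotype table.

    Expected columns: subject_id, iq, age_of_walking, disruptive_genes
    (semicolon-separated; empty for subjects without qualifying
    variants).  Subjects missing either trait are dropped with a logged
    count — only fully phenotyped individuals enter group comparisons.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "disruptive_genes": str})
    required = {"subject_id", "iq", "age_of_walking", "disruptive_genes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids")
    n0 = len(df)
    df = df.dropna(subset=["iq", "age_of_walking"]).copy()
    if len(df) < n0:
        logger.info("dropped %d subject(s) lacking a phenotype value", n0 - len(df))
    df["disruptive_genes"] = [
        frozenset(g for g in str(s).split(";") if g) if pd.notna(s) else frozenset()
        for s in df["disruptive_genes"]
    ]
    return df.reset_index(drop=True)


def write_subjects(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["disruptive_genes"] = [";".join(sorted(s)) for s in out["disruptive_genes"]]
    out.to_csv(path, sep="\t", index=False)
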