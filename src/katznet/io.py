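"""Readers and writers for the pipeline's text formats.

Formats: STRING-style edge lists (gene1 <tab> gene2 <tab> score, integer
0-1000 or already-normalized real), GMT gene sets, BED-like locus tables,
expression/probe-map/group TSVs, plain gene lists, two-column abundance
tables, and GraphML export of subnetworks.  Readers reject malformed input
with the offending line number rather than coercing.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .enrich import ABUNDANCE_LEVELS, GeneSetCollection
from .expression import ExpressionDataset
from .network import Subnetwork
from .prioritize import WeightedNetwork

__all__ = [
    "read_weighted_network",
    "write_weighted_network",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_loci",
    "write_loci",
    "read_expression",
    "write_expression",
    "read_probe_map",
    "read_groups",
    "read_abundance_table",
    "write_abundance_table",
    "write_subnetwork_edges",
    "write_graphml",
]

PathLike = str | os.PathLike


def read_weighted_network(path: PathLike, score_scale: float = 1000) -> WeightedNetwork:
    """Read a STRING-style TSV edge list into a symmetric weighted network.

    Integer-scaled scores (any value > 1 present) are divided by
    ``score_scale``; already-normalized real scores pass through.
    Duplicate undirected edges collapse to the maximum weight; self-loops
    are dropped.  A header line whose score field is non-numeric is
    skipped.
    """
    edges: list[tuple[str, str, float]] = []
    raw_scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            a, b, score_str = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                score = float(score_str)
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric score {score_str!r}") from None
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            edges.append((a, b, score))
            raw_scores.append(score)
    if not edges:
        raise ValueError(f"{path}: no edges found")
    if max(raw_scores) > 1:
        edges = [(a, b, s / score_scale) for a, b, s in edges]
    for a, b, w in edges:
        if not 0 <= w <= 1:
            raise ValueError(f"{path}: weight {w} for edge ({a}, {b}) outside [0, 1]")
    return WeightedNetwork.from_edges(edges)


def write_weighted_network(
    network: WeightedNetwork, path: PathLike, score_scale: int = 1000
) -> None:
    """Write as STRING-style integer-scored TSV (deterministic edge order)."""
    coo = network.W.tocoo()
    with open(path, "w") as fh:
        for i, j, w in sorted(zip(coo.row, coo.col, coo.data), key=lambda t: (t[0], t[1])):
            if i < j:
                fh.write(f"{network.genes[i]}\t{network.genes[j]}\t{round(w * score_scale)}\n")


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: term_id <tab> name <tab> member genes...

    Trailing empty fields are ignored; duplicate term ids and empty member
    lists are rejected.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, name and >=1 member")
            term_id, name = parts[0], parts[1]
            members = frozenset(p for p in parts[2:] if p.strip())
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: term {term_id!r} has no members")
            terms[term_id] = (name, members)
    if not terms:
        raise ValueError(f"{path}: no terms found")
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(collection.terms):
            name, members = collection.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def read_gene_list(path: PathLike) -> list[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


_LOCI_COLUMNS = ["chrom", "start", "end", "gene"]


def read_loci(path: PathLike) -> pd.DataFrame:
    """BED-like locus table: chrom, start, end, gene (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_LOCI_COLUMNS, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty locus table")
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} must be integer coordinates")
    return df


def write_loci(loci: pd.DataFrame, path: PathLike) -> None:
    loci[_LOCI_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_expression(
    values_path: PathLike, groups_path: PathLike, platform_id: str
) -> ExpressionDataset:
    """Expression TSV (rows x samples, first column = row id) + group labels."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    groups = read_groups(groups_path)
    return ExpressionDataset(platform_id=platform_id, values=values, groups=groups)


def write_expression(dataset: ExpressionDataset, values_path: PathLike, groups_path: PathLike) -> None:
    dataset.values.to_csv(values_path, sep="\t", float_format="%.10g")
    dataset.groups.rename("group").to_csv(groups_path, sep="\t", header=True, index_label="sample")


def read_probe_map(path: PathLike) -> pd.DataFrame:
    """Two-column TSV probe <tab> gene (with header)."""
    df = pd.read_csv(path, sep="\t")
    if not {"probe", "gene"}.issubset(df.columns):
        raise ValueError(f"{path}: probe map needs 'probe' and 'gene' columns")
    return df[["probe", "gene"]]


def read_groups(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"}.issubset(df.columns):
        raise ValueError(f"{path}: group table needs 'sample' and 'group' columns")
    return pd.Series(df["group"].values, index=df["sample"].values)


def read_abundance_table(path: PathLike) -> dict[str, str]:
    """Two-column TSV gene <tab> level, levels on the four-level scale."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>level'")
            gene, level = parts[0].strip(), parts[1].strip()
            if lineno == 1 and level == "level":
                continue  # header
            if level not in ABUNDANCE_LEVELS:
                raise ValueError(f"{path}:{lineno}: unknown abundance level {level!r}")
            table[gene] = level
    return table


def write_abundance_table(table: Mapping[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gene in sorted(table):
            fh.write(f"{gene}\t{table[gene]}\n")


def write_subnetwork_edges(sub: Subnetwork, path: PathLike) -> None:
    with open(path, "w") as fh:
        for u, v, w in sorted(sub.edges()):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def write_graphml(sub: Subnetwork, path: PathLike, node_attrs: pd.DataFrame | None = None) -> None:
    """GraphML export for external viewers, optional per-node attributes."""
    G = sub.graph.copy()
    if node_attrs is not None:
        for col in node_attrs.columns:
            nx.set_node_attributes(
                G, {n: _plain(v) for n, v in node_attrs[col].items() if n in G}, name=col
            )
    nx.write_graphml(G, Path(path))


def _plain(v):
    try:
        return v.item()  # numpy scalar -> python scalar
    except AttributeError:
        return v
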