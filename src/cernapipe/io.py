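"""Readers and writers for every external table the pipeline touches.

Formats: gene x sample count TSV, GMT gene-set collections, STRING-style
scored protein-interaction edge TSV, Cytoscape SIF / edge-list network
exports, and plain TSV tables keyed by column name. All identifiers are
opaque case-sensitive strings; no symbol/ID conversion is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """An input file violates the expected dialect."""


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample table with group labels.

    ``counts`` is indexed by gene ID with one column per sample;
    ``groups`` maps every sample name to its group label.
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene IDs: {sorted(map(str, dupes))}")
        missing = set(self.groups) - set(self.counts.columns)
        if missing:
            raise FormatError(
                f"samples in group mapping absent from matrix: {sorted(missing)}")
        by_group: dict[str, list[str]] = {}
        for s, g in self.groups.items():
            by_group.setdefault(g, []).append(s)
        if self.groups and len(by_group) < 2:
            raise FormatError("need >= 2 groups with >= 1 sample each")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s in self.groups:
                seen.setdefault(self.groups[s], None)
        return list(seen)

    def subset_groups(self, keep: list[str]) -> "CountMatrix":
        samples = [s for s in self.samples if self.groups.get(s) in keep]
        return CountMatrix(self.counts[samples].copy(),
                           {s: self.groups[s] for s in samples})


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>group table (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    return dict(zip(df[0], df[1]))


def read_count_matrix(path: str | Path, groups: dict[str, str]) -> CountMatrix:
    """Read a TSV count table (gene-ID first column, integer cells).

    Cells must be non-negative integers; the offending row/column is named
    otherwise. Every sample in ``groups`` must appear in the header.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric != np.floor(numeric))
        if bad.any():
            gene = vals.index[bad.to_numpy()][0]
            raise FormatError(
                f"{path}: cell (gene {gene!r}, sample {col!r}) is not a "
                f"non-negative integer: {vals.loc[gene]!r}")
    return CountMatrix(df.astype(np.int64), dict(groups))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: set-name <TAB> description <TAB> member genes..."""
    collections: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT rows need name, description and "
                f">=1 member")
        name, members = parts[0], [g for g in parts[2:] if g]
        if name in collections:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        collections[name] = set(members)
    return collections


def write_gmt(collections: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)])
        for name, genes in collections.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_string_edges(path: str | Path, score_min: float = 0.9) -> pd.DataFrame:
    """Read a STRING-style scored edge TSV and filter by combined score.

    The first two columns are node IDs and the last numeric column is the
    combined score. Both score dialects are accepted: 0-1 fractions and
    STRING's 0-1000 integers (auto-detected: any value > 1 implies the
    0-1000 dialect, which is then divided by 1000). Edges are undirected
    and deduplicated (the higher score wins); self-loops are dropped.
    """
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected >= 3 columns (node, node, score)")
    a, b = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)
    score = pd.to_numeric(df.iloc[:, -1], errors="coerce")
    if score.isna().any():
        row = int(np.flatnonzero(score.isna())[0])
        raise FormatError(f"{path}: non-numeric score in data row {row}")
    if (score < 0).any() or (score > 1000).any():
        raise FormatError(
            f"{path}: scores outside both the 0-1 and 0-1000 dialects")
    if (score > 1).any():
        logger.info("read_string_edges: detected 0-1000 score dialect")
        score = score / 1000.0
    else:
        logger.info("read_string_edges: detected 0-1 score dialect")
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    edges = pd.DataFrame({"node1": lo, "node2": hi, "score": score})
    edges = edges[edges.node1 != edges.node2]
    edges = (edges.groupby(["node1", "node2"], as_index=False)["score"].max())
    edges = edges[edges.score >= score_min].reset_index(drop=True)
    return edges.sort_values(["node1", "node2"]).reset_index(drop=True)


def write_string_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False,
                 columns=["node1", "node2", "score"])


_NETWORK_FORMATS = ("tsv", "sif")


def write_network(graph: nx.Graph, path: str | Path, format: str = "sif") -> None:
    """Export a network as SIF or edge-list TSV.

    SIF rows are ``source<TAB>interaction<TAB>target`` using the edge's
    ``interaction`` attribute (default ``pp``); isolated nodes get a
    single-column row so re-import reproduces the node set exactly.
    """
    if format not in _NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {format!r}; expected one of {_NETWORK_FORMATS}")
    if graph.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    lines = []
    for u, v, data in sorted(graph.edges(data=True)):
        kind = data.get("interaction", "pp")
        if format == "sif":
            lines.append(f"{u}\t{kind}\t{v}")
        else:
            lines.append(f"{u}\t{v}\t{kind}")
    for node in sorted(nx.isolates(graph)):
        lines.append(str(node))
    header = [] if format == "sif" else ["source\ttarget\tinteraction"]
    Path(path).write_text("\n".join(header + lines) + "\n")


def read_network(path: str | Path, format: str = "sif") -> nx.Graph:
    if format not in _NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {format!r}; expected one of {_NETWORK_FORMATS}")
    graph = nx.Graph()
    lines = Path(path).read_text().splitlines()
    if format == "tsv":
        lines = lines[1:]
    for line in lines:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            graph.add_node(parts[0])
        elif len(parts) == 3:
            if format == "sif":
                u, kind, v = parts
            else:
                u, v, kind = parts
            graph.add_edge(u, v, interaction=kind)
        else:
            raise FormatError(f"{path}: malformed network row {line!r}")
    return graph
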