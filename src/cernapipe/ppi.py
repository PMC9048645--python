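"""Protein-protein interaction graph, topological ranking, core proteins.

The graph is the undirected simple graph of high-confidence interactions
among DEGs; nodes carry their regulation direction. Per-node centralities
follow the 'without weight' convention: exact degree, unnormalized
betweenness (Brandes accumulation over unweighted shortest paths,
endpoints excluded, halved for undirected graphs) and component-size
adjusted closeness. A core protein ranks in the top-k for all three
metrics simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class PPIGraph:
    """Undirected scored interaction graph with DEG annotations."""

    graph: nx.Graph
    regulation: dict[str, str] = field(default_factory=dict)


def build_ppi(edges: pd.DataFrame, deg_table: pd.DataFrame | None = None,
              config: PipelineConfig | None = None) -> PPIGraph:
    """Assemble the PPI graph from a filtered scored edge table.

    ``edges`` must have node1/node2/score columns (already score-filtered
    by the reader, or filter here via config.ppi_score_min). Nodes are
    annotated up/down from the DEG table; nodes absent from it get
    regulation ``none`` with a warning.
    """
    config = config or PipelineConfig()
    graph = nx.Graph()
    kept = edges[edges.score >= config.ppi_score_min]
    for row in kept.itertuples(index=False):
        if row.node1 != row.node2:
            graph.add_edge(str(row.node1), str(row.node2), score=float(row.score),
                           interaction="pp")
    status = {}
    if deg_table is not None:
        status = dict(zip(deg_table.gene_id.astype(str), deg_table.status))
    regulation = {}
    missing = []
    for node in graph.nodes:
        st = status.get(node)
        if st in ("up", "down"):
            regulation[node] = st
        else:
            regulation[node] = "none"
            if deg_table is not None and node not in status:
                missing.append(node)
    if missing:
        logger.warning("build_ppi: %d node(s) absent from DEG table, "
                       "regulation set to 'none'", len(missing))
    logger.info("build_ppi: %d nodes, %d edges",
                graph.number_of_nodes(), graph.number_of_edges())
    return PPIGraph(graph, regulation)


def centralities(ppi: PPIGraph | nx.Graph,
                 closeness_compat: bool = False) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node.

    Betweenness is the unnormalized shortest-path pair sum (endpoints
    excluded; ordered-pair sum halved on undirected graphs). Closeness
    defaults to the component-size-adjusted form
    ``(reachable/(|V|-1)) * (reachable/sum of distances)``; with
    ``closeness_compat`` it is the plain ``1/sum of distances`` within the
    node's component (0 for isolated nodes).
    """
    graph = ppi.graph if isinstance(ppi, PPIGraph) else ppi
    regulation = ppi.regulation if isinstance(ppi, PPIGraph) else {}
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=False)
    if closeness_compat:
        cls = {}
        for v in graph.nodes:
            dists = nx.single_source_shortest_path_length(graph, v)
            total = sum(dists.values())
            cls[v] = 1.0 / total if total > 0 else 0.0
    else:
        cls = nx.closeness_centrality(graph, wf_improved=True)
    rows = [{"node": v, "degree": degree[v], "betweenness": btw[v],
             "closeness": cls[v], "regulation": regulation.get(v, "none")}
            for v in graph.nodes]
    return (pd.DataFrame(rows)
            .sort_values(["degree", "node"], ascending=[False, True])
            .reset_index(drop=True))


def _top_k(records: pd.DataFrame, metric: str, k: int) -> list[str]:
    ordered = records.sort_values([metric, "node"],
                                  ascending=[False, True])
    top = ordered.head(k)
    if len(ordered) > k:
        boundary = top[metric].iloc[-1]
        n_ties = int((ordered[metric] == boundary).sum())
        n_kept = int((top[metric] == boundary).sum())
        if n_ties > n_kept:
            logger.info("core_proteins: %d-way tie at the %s boundary value "
                        "%.6g truncated by node name", n_ties, metric, boundary)
    return list(top.node)


def core_proteins(records: pd.DataFrame, k: int = 20) -> dict:
    """Top-k tables per metric and their intersection (the core set).

    Ties at the k-th boundary are broken deterministically by node name
    (and logged). The core is every node present in all three top-k
    lists, ranked by degree then name.
    """
    if k > len(records):
        raise ValueError(f"k={k} exceeds the {len(records)} available nodes")
    tops = {m: _top_k(records, m, k)
            for m in ("degree", "betweenness", "closeness")}
    in_all = set(tops["degree"]) & set(tops["betweenness"]) & set(tops["closeness"])
    core = [n for n in tops["degree"] if n in in_all]
    return {"top_degree": tops["degree"],
            "top_betweenness": tops["betweenness"],
            "top_closeness": tops["closeness"],
            "core": core}
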