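"""ceRNA (circRNA-miRNA-mRNA) network assembly and hub-gene ranking.

A circRNA that sponges a miRNA derepresses that miRNA's other targets,
so with the circRNA overexpressed the sponged miRNAs' targets should
rise. The assembly therefore keeps circRNA-miRNA pairs scored in the top
percentile, miRNA targets supported by all six prediction sources,
and of those only target genes that are upregulated DEGs present in the
PPI graph; mRNA nodes additionally pass the stricter FDR/log2FC/P node
filter. Hub genes are the mRNA nodes of highest degree; crucial miRNAs
are those with the most target sites (mRNA-side degree).

Also houses the circRNA annotation utilities (genomic coordinates,
spliced lengths and predicted flanking-region RNA-binding proteins).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .config import PipelineConfig
from .io import FormatError
from .ppi import PPIGraph

logger = logging.getLogger(__name__)

N_TARGET_SOURCES = 6

_POSITION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class CircAnnotation:
    """One circRNA annotation row: position, lengths, host gene, RBPs."""

    chrom: str
    start: int
    end: int
    strand: str
    circ_id: str
    genomic_length: int
    spliced_length: int
    gene_symbol: str
    rbps: frozenset[str]

    @property
    def position(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _parse_annotation_row(row: pd.Series, rownum: int) -> CircAnnotation:
    m = _POSITION_RE.match(str(row.iloc[0]).strip())
    if not m:
        raise FormatError(
            f"row {rownum}: malformed position {row.iloc[0]!r} "
            f"(expected chrN:start-end)")
    chrom, start, end = m["chrom"], int(m["start"]), int(m["end"])
    if start >= end:
        raise FormatError(f"row {rownum}: start {start} >= end {end}")
    strand = str(row.iloc[1]).strip()
    if strand not in ("+", "-"):
        raise FormatError(f"row {rownum}: strand must be + or -, got {strand!r}")
    genomic_length = int(row.iloc[3])
    spliced_length = int(row.iloc[4])
    if genomic_length != end - start:
        raise FormatError(
            f"row {rownum} ({row.iloc[2]}): genomic length column "
            f"{genomic_length} != end - start = {end - start}")
    if spliced_length > genomic_length:
        raise FormatError(
            f"row {rownum} ({row.iloc[2]}): spliced length {spliced_length} "
            f"exceeds genomic length {genomic_length}")
    rbps = frozenset(p.strip() for p in str(row.iloc[6]).split(",") if p.strip())
    return CircAnnotation(chrom=chrom, start=start, end=end, strand=strand,
                          circ_id=str(row.iloc[2]).strip(),
                          genomic_length=genomic_length,
                          spliced_length=spliced_length,
                          gene_symbol=str(row.iloc[5]).strip(), rbps=rbps)


def read_circ_annotation(path: str | Path) -> list[CircAnnotation]:
    """Read a circRNA annotation TSV (position, strand, ID, genomic
    length, spliced length, gene symbol, comma-separated RBPs).

    The genomic-length column is checked against end - start; a mismatch
    is a validation error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 7:
        raise FormatError(f"{path}: expected 7 annotation columns")
    return [_parse_annotation_row(row, i + 1) for i, (_, row) in
            enumerate(df.iterrows())]


def bundled_anril_annotation() -> list[CircAnnotation]:
    """The 13 published ANRIL-derived circRNA annotation rows."""
    ref = resources.files("cernapipe").joinpath(
        "data/anril_circrna_annotation.tsv")
    with resources.as_file(ref) as path:
        return read_circ_annotation(path)


def unique_rbps(annotations: list[CircAnnotation]) -> list[str]:
    """Sorted union of flanking-region RBPs across all annotation rows."""
    if not annotations:
        raise ValueError("no annotation rows")
    out: set[str] = set()
    for ann in annotations:
        out |= ann.rbps
    return sorted(out)


def rbp_differential_check(rbps: list[str],
                           deg_table: pd.DataFrame) -> pd.DataFrame:
    """Per-RBP differential-expression status.

    RBPs absent from the DEG table are reported ``not tested``. The
    frame's ``.attrs['any_differential']`` records whether any RBP is a
    DEG (up or down).
    """
    status = dict(zip(deg_table.gene_id.astype(str), deg_table.status))
    rows = [{"rbp": r, "status": status.get(r, "not tested")} for r in rbps]
    report = pd.DataFrame(rows, columns=["rbp", "status"])
    report.attrs["any_differential"] = bool(
        report.status.isin(["up", "down"]).any())
    return report


@dataclass
class PredictionSet:
    """circRNA-miRNA pairs with percentile scores, plus six per-source
    miRNA -> target-gene mappings."""

    circ_mir: pd.DataFrame  # columns: circ_id, mirna_id, percentile
    per_db_targets: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.per_db_targets) != N_TARGET_SOURCES:
            raise ValueError(
                f"expected {N_TARGET_SOURCES} target-prediction sources, "
                f"got {len(self.per_db_targets)}")
        pct = self.circ_mir["percentile"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("percentile scores must lie in [0, 100]")


def read_circ_mir(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"circ_id": str, "mirna_id": str})
    need = {"circ_id", "mirna_id", "percentile"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(need)}")
    return df


def read_target_db(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"mirna_id", "gene_id"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(need)}")
    out: dict[str, set[str]] = {}
    for mir, genes in df.groupby("mirna_id")["gene_id"]:
        out[mir] = set(genes)
    return out


def filter_circ_mir(pred: PredictionSet,
                    percentile_min: float = 90.0) -> pd.DataFrame:
    """Keep deduplicated circRNA-miRNA pairs scored >= percentile_min.

    The boundary is inclusive ('within the Nth percentile' reads as
    at-or-above).
    """
    kept = pred.circ_mir[pred.circ_mir.percentile >= percentile_min]
    kept = (kept.drop_duplicates(subset=["circ_id", "mirna_id"])
            .reset_index(drop=True))
    if kept.empty:
        logger.warning("filter_circ_mir: no pair reaches the %gth percentile",
                       percentile_min)
    return kept[["circ_id", "mirna_id", "percentile"]]


def intersect_target_dbs(pred: PredictionSet) -> dict[str, set[str]]:
    """Per-miRNA target consensus: genes reported by all six sources.

    miRNAs whose consensus is empty are dropped.
    """
    sources = list(pred.per_db_targets.values())
    mirnas = set().union(*(set(s) for s in sources)) if sources else set()
    consensus: dict[str, set[str]] = {}
    for mir in mirnas:
        sets = [s.get(mir, set()) for s in sources]
        inter = set.intersection(*sets) if sets else set()
        if inter:
            consensus[mir] = inter
    return consensus


def concordance_overlap(consensus: dict[str, set[str]],
                        deg_table: pd.DataFrame,
                        ppi: PPIGraph) -> pd.DataFrame:
    """Keep (miRNA, gene) pairs whose gene is an upregulated DEG that is
    also a node of the PPI graph.

    Rationale: with the sponge overexpressed, genes released from the
    shared miRNAs should move up; targets that are down or outside the
    interaction network are discordant and dropped.
    """
    up = set(deg_table.loc[deg_table.status == "up", "gene_id"].astype(str))
    nodes = set(map(str, ppi.graph.nodes))
    rows = [{"mirna_id": mir, "gene_id": g}
            for mir, genes in sorted(consensus.items())
            for g in sorted(genes) if g in up and g in nodes]
    out = pd.DataFrame(rows, columns=["mirna_id", "gene_id"])
    logger.info("concordance_overlap: %d pairs over %d miRNAs and %d genes",
                len(out), out.mirna_id.nunique() if len(out) else 0,
                out.gene_id.nunique() if len(out) else 0)
    return out


@dataclass
class CeRNANetwork:
    """Tripartite circRNA-miRNA-mRNA network with per-node degrees."""

    graph: nx.Graph

    def nodes_of_type(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("kind") == kind)

    def edges_of_type(self, kind: str) -> list[tuple[str, str]]:
        return sorted((u, v) for u, v, d in self.graph.edges(data=True)
                      if d.get("interaction") == kind)

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_nodes() == 0

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def summary(self) -> dict[str, int]:
        return {
            "n_circ": len(self.nodes_of_type("circRNA")),
            "n_mirna": len(self.nodes_of_type("miRNA")),
            "n_mrna": len(self.nodes_of_type("mRNA")),
            "n_nodes": self.graph.number_of_nodes(),
            "n_circ_mir_edges": len(self.edges_of_type("circ-mir")),
            "n_mir_mrna_edges": len(self.edges_of_type("mir-mrna")),
        }


def assemble_cerna(circ_mir: pd.DataFrame, mir_mrna: pd.DataFrame,
                   deg_table: pd.DataFrame | None = None,
                   config: PipelineConfig | None = None) -> CeRNANetwork:
    """Join the two pair sets into the tripartite regulatory network.

    Only miRNAs present in both pair sets are kept. mRNA nodes must pass
    the node filter (fdr < cerna_fdr_max, |log2FC| > cerna_abs_log2fc_min,
    p < cerna_p_max) when a DEG table is supplied; the filter applies to
    mRNA nodes only (no miRNA expression data exists in this design).
    Isolated nodes are dropped. An empty result is returned as an
    explicit empty network (``is_empty``), with a warning, never an
    exception.
    """
    config = config or PipelineConfig()
    if deg_table is not None:
        stats = deg_table.set_index(deg_table.gene_id.astype(str))
        passing = set(stats.index[
            (stats.fdr < config.cerna_fdr_max)
            & (stats.logFC.abs() > config.cerna_abs_log2fc_min)
            & (stats.p_value < config.cerna_p_max)])
        before = mir_mrna.gene_id.nunique()
        mir_mrna = mir_mrna[mir_mrna.gene_id.astype(str).isin(passing)]
        logger.info("assemble_cerna: mRNA node filter kept %d of %d genes",
                    mir_mrna.gene_id.nunique(), before)
    shared = set(circ_mir.mirna_id) & set(mir_mrna.mirna_id)
    circ_mir = circ_mir[circ_mir.mirna_id.isin(shared)]
    mir_mrna = mir_mrna[mir_mrna.mirna_id.isin(shared)]

    graph = nx.Graph()
    for row in circ_mir.itertuples(index=False):
        graph.add_node(str(row.circ_id), kind="circRNA")
        graph.add_node(str(row.mirna_id), kind="miRNA")
        graph.add_edge(str(row.circ_id), str(row.mirna_id),
                       interaction="circ-mir")
    for row in mir_mrna.itertuples(index=False):
        graph.add_node(str(row.mirna_id), kind="miRNA")
        graph.add_node(str(row.gene_id), kind="mRNA")
        graph.add_edge(str(row.mirna_id), str(row.gene_id),
                       interaction="mir-mrna")
    graph.remove_nodes_from(list(nx.isolates(graph)))
    net = CeRNANetwork(graph)
    if net.is_empty:
        logger.warning("assemble_cerna: empty network after filtering")
    else:
        logger.info("assemble_cerna: %s", net.summary())
    return net


def hub_genes(net: CeRNANetwork, top_n: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank mRNA nodes by degree and miRNAs by target-site count.

    Returns (gene ranking, miRNA ranking); the gene frame's head is the
    ``top_n`` hub genes. Ties are broken by name. Downstream curation of
    hubs by biological function is a manual step outside this ranking.
    """
    if net.is_empty:
        raise ValueError("empty network has no hubs")
    gene_rows = [{"gene_id": g, "degree": net.degree(g)}
                 for g in net.nodes_of_type("mRNA")]
    genes = (pd.DataFrame(gene_rows)
             .sort_values(["degree", "gene_id"], ascending=[False, True])
             .reset_index(drop=True))
    genes["hub"] = genes.index < top_n
    mir_rows = []
    for mir in net.nodes_of_type("miRNA"):
        sites = sum(1 for _, _, d in net.graph.edges(mir, data=True)
                    if d.get("interaction") == "mir-mrna")
        mir_rows.append({"mirna_id": mir, "target_sites": sites})
    mirnas = (pd.DataFrame(mir_rows)
              .sort_values(["target_sites", "mirna_id"],
                           ascending=[False, True])
              .reset_index(drop=True))
    return genes, mirnas
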