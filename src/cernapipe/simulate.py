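"""Synthetic pipeline inputs with known ground truth.

Emulates the study design every stage consumes: a 3-vs-3 RNA-seq count
matrix with a planted fraction of differentially expressed genes, a
scored protein-interaction edge list with planted high-degree hubs, a
circRNA-miRNA prediction table with percentile scores, and six
miRNA-target prediction sources with controlled inter-source agreement.
One integer seed drives every generator through a splittable
SeedSequence stream, so an end-to-end run is reproducible bit for bit.

Counts are negative binomial with variance = mu + phi * mu^2 (gamma-
Poisson mixture; phi = 0 is the Poisson limit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cerna import N_TARGET_SOURCES, PredictionSet
from .io import CountMatrix, write_count_matrix, write_string_edges

TARGET_SOURCE_NAMES = ("db1", "db2", "db3", "db4", "db5", "db6")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults mirror the emulated design: three replicates per group,
    moderate biological dispersion, 5% of genes differentially expressed
    at |log2FC| = 2, 13 circRNA isoforms, and six target-prediction
    sources whose per-source reporting probability for a true target is
    ``db_agreement``.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (150_000, 250_000)
    n_circ: int = 13
    n_mirna: int = 20
    n_targets_per_mirna: int = 8
    db_agreement: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "db_agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("n_genes", "n_per_group", "n_circ", "n_mirna",
                     "n_targets_per_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.lib_size_range
        if lo < 1 or hi < lo:
            raise ValueError("lib_size_range must be positive and ordered")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    planted_ppi_hubs: set[str] = field(default_factory=set)
    planted_top_mirna: str = ""
    planted_hub_genes: set[str] = field(default_factory=set)
    true_targets: dict[str, set[str]] = field(default_factory=dict)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_counts(params: SimulationParams,
                    rng: np.random.Generator | None = None
                    ) -> tuple[CountMatrix, GroundTruth]:
    """Two-group NB count matrix with a planted DE fraction.

    Gene baseline abundances are log-normal; DE genes (half up, half
    down, relative to the treatment group ``OE``) have their treatment
    mean multiplied by 2**(+-de_log2fc). Per-sample expected totals are
    drawn uniformly from ``lib_size_range``.
    """
    if params.n_per_group < 2:
        raise ValueError(
            "n_per_group must be >= 2 (dispersion is not estimable from "
            "a single replicate)")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    genes = [f"G{i:05d}" for i in range(params.n_genes)]
    base = rng.lognormal(mean=0.0, sigma=1.2, size=params.n_genes)

    n_de = int(round(params.n_genes * params.de_fraction))
    de_idx = rng.choice(params.n_genes, size=n_de, replace=False)
    up_idx = de_idx[: n_de // 2 + n_de % 2]
    down_idx = de_idx[n_de // 2 + n_de % 2:]
    mult = np.ones(params.n_genes)
    mult[up_idx] = 2.0 ** params.de_log2fc
    mult[down_idx] = 2.0 ** (-params.de_log2fc)

    rel = {"OE": base * mult, "NC": base}
    samples, data, groups = [], [], {}
    for group in ("OE", "NC"):
        p = rel[group] / rel[group].sum()
        for i in range(params.n_per_group):
            name = f"{group}_{i + 1}"
            lib = rng.integers(params.lib_size_range[0],
                               params.lib_size_range[1] + 1)
            data.append(_nb_draw(rng, p * lib, params.nb_dispersion))
            samples.append(name)
            groups[name] = group
    counts = pd.DataFrame(np.column_stack(data), index=genes,
                          columns=samples).astype(np.int64)
    truth = GroundTruth(
        de_genes_up={genes[i] for i in up_idx},
        de_genes_down={genes[i] for i in down_idx},
    )
    return CountMatrix(counts, groups), truth


def simulate_ppi(n_nodes: int, n_edges: int, planted_hubs: int,
                 seed: int | None = 0, pass_fraction: float = 1.0,
                 node_ids: list[str] | None = None,
                 hub_ids: list[str] | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[pd.DataFrame, GroundTruth]:
    """Scored edge list with planted high-degree hubs.

    Background edges are uniform over node pairs; each planted hub is
    then wired to at least 3x the background median degree. Scores are
    drawn so a ``pass_fraction`` of edges lies at or above 0.9 (the rest
    in [0.5, 0.9)).
    """
    if planted_hubs > n_nodes:
        raise ValueError(f"planted_hubs={planted_hubs} > n_nodes={n_nodes}")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds {max_edges} possible pairs")
    rng = rng if rng is not None else np.random.default_rng(seed)
    nodes = list(node_ids) if node_ids is not None else [
        f"P{i:04d}" for i in range(n_nodes)]
    if len(nodes) != n_nodes:
        raise ValueError("node_ids length must equal n_nodes")
    if hub_ids is not None:
        if len(hub_ids) != planted_hubs or not set(hub_ids) <= set(nodes):
            raise ValueError("hub_ids must be planted_hubs node IDs")
        hubs = list(hub_ids)
    else:
        hubs = [str(h) for h in rng.choice(nodes, size=planted_hubs,
                                           replace=False)]

    pairs: set[tuple[str, str]] = set()
    while len(pairs) < n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            pairs.add((nodes[min(i, j)], nodes[max(i, j)]))
    degree: dict[str, int] = {n: 0 for n in nodes}
    for u, v in pairs:
        degree[u] += 1
        degree[v] += 1
    median_deg = float(np.median(list(degree.values()))) if nodes else 0.0
    target = max(3, int(np.ceil(3 * max(median_deg, 1.0))))
    for hub in hubs:
        others = [n for n in nodes if n != hub]
        while degree[hub] < target:
            partner = others[rng.integers(0, len(others))]
            key = (min(hub, partner), max(hub, partner))
            if key not in pairs:
                pairs.add(key)
                degree[hub] += 1
                degree[partner] += 1

    ordered = sorted(pairs)
    passing = rng.random(len(ordered)) < pass_fraction
    scores = np.where(passing,
                      rng.uniform(0.9, 1.0, len(ordered)),
                      rng.uniform(0.5, 0.9, len(ordered)))
    edges = pd.DataFrame({"node1": [u for u, _ in ordered],
                          "node2": [v for _, v in ordered],
                          "score": np.round(scores, 4)})
    return edges, GroundTruth(planted_ppi_hubs=set(hubs))


def simulate_predictions(params: SimulationParams, truth: GroundTruth,
                         rng: np.random.Generator | None = None,
                         gene_universe: list[str] | None = None
                         ) -> tuple[PredictionSet, GroundTruth]:
    """circRNA-miRNA pairs and six miRNA-target sources.

    True targets are reported by each source independently with
    probability ``db_agreement``; decoy (untrue) pairs are reported at a
    low rate and are always withheld from at least one source, so the
    six-way intersection contains no decoy. Planted hub genes are
    targets of >= 2 miRNAs that also pair with circRNAs at a percentile
    >= 90; the planted top miRNA targets every planted hub gene and
    carries the largest true target set.
    """
    if not truth.planted_top_mirna:
        truth.planted_top_mirna = "miR-0001"
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    mirnas = [f"miR-{i:04d}" for i in range(1, params.n_mirna + 1)]
    if truth.planted_top_mirna not in mirnas:
        mirnas[0] = truth.planted_top_mirna
    circs = [f"circ_{i:02d}" for i in range(1, params.n_circ + 1)]
    if gene_universe is None:
        gene_universe = [f"G{i:05d}" for i in range(params.n_genes)]
    if not truth.planted_hub_genes:
        pool = sorted(truth.de_genes_up) or list(gene_universe)
        k = min(3, len(pool))
        truth.planted_hub_genes = set(
            map(str, rng.choice(pool, size=k, replace=False)))
    hubs = sorted(truth.planted_hub_genes)

    # circRNA-miRNA pairs: every miRNA pairs with >= 1 circRNA; planted
    # pairs (those of the hub-supporting miRNAs) score >= 90.
    support_mirnas = [truth.planted_top_mirna,
                      mirnas[1 % len(mirnas)]] if len(mirnas) > 1 else mirnas
    rows = []
    for mir in mirnas:
        n_partners = int(rng.integers(1, min(4, params.n_circ) + 1))
        partners = rng.choice(circs, size=n_partners, replace=False)
        planted = mir in support_mirnas
        for c in partners:
            pct = (float(rng.uniform(90, 100)) if planted
                   else float(rng.uniform(0, 100)))
            rows.append({"circ_id": c, "mirna_id": mir,
                         "percentile": round(pct, 2)})
    circ_mir = pd.DataFrame(rows).drop_duplicates(
        subset=["circ_id", "mirna_id"]).reset_index(drop=True)

    # true target map: hubs covered by >= 2 supporting miRNAs
    non_hub = [g for g in gene_universe if g not in truth.planted_hub_genes]
    true_targets: dict[str, set[str]] = {}
    for mir in mirnas:
        n_t = params.n_targets_per_mirna
        if mir == truth.planted_top_mirna:
            picks = set(hubs)
            n_extra = max(n_t, len(hubs) + 2) - len(picks)
        elif mir in support_mirnas:
            picks = set(hubs)
            n_extra = max(n_t - len(picks), 0)
        else:
            picks = set()
            n_extra = n_t
        if n_extra > 0 and non_hub:
            picks |= set(rng.choice(non_hub, size=min(n_extra, len(non_hub)),
                                    replace=False))
        true_targets[mir] = picks

    sources: dict[str, dict[str, set[str]]] = {
        name: {} for name in TARGET_SOURCE_NAMES}
    for mir in mirnas:
        for gene in sorted(true_targets[mir]):
            for name in TARGET_SOURCE_NAMES:
                if rng.random() < params.db_agreement:
                    sources[name].setdefault(mir, set()).add(gene)
        # decoys: reported by some sources but never by all six
        n_decoys = int(rng.integers(0, 4))
        decoy_pool = [g for g in non_hub if g not in true_targets[mir]]
        if decoy_pool and n_decoys:
            decoys = rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)),
                                replace=False)
            for gene in decoys:
                withheld = int(rng.integers(0, N_TARGET_SOURCES))
                for si, name in enumerate(TARGET_SOURCE_NAMES):
                    if si != withheld and rng.random() < 0.5:
                        sources[name].setdefault(mir, set()).add(gene)
    truth.true_targets = true_targets
    return PredictionSet(circ_mir=circ_mir, per_db_targets=sources), truth


def simulate_all(params: SimulationParams
                 ) -> tuple[CountMatrix, pd.DataFrame, PredictionSet, GroundTruth]:
    """End-to-end consistent inputs from one seed.

    The planted hub genes are upregulated DE genes; the PPI generator
    plants them (plus extras) as hubs so they survive the concordance
    overlap; the prediction generator wires them under the planted top
    miRNA. Returns (counts, ppi edge table, prediction set, truth).
    """
    ss = np.random.SeedSequence(params.seed)
    rng_counts, rng_ppi, rng_pred = (np.random.default_rng(c)
                                     for c in ss.spawn(3))
    counts, truth = simulate_counts(params, rng=rng_counts)

    up = sorted(truth.de_genes_up)
    if not up:
        raise ValueError("simulate_all needs de_fraction > 0 to plant hubs")
    hub_rng = np.random.default_rng(ss.spawn(1)[0])
    # hubs are detectable transcripts: draw among up-regulated genes of at
    # least median abundance (falling back to all up genes if none qualify)
    mean_counts = counts.counts.mean(axis=1)
    expressed = [g for g in up if mean_counts[g] >= mean_counts.median()]
    pool = expressed or up
    n_hubs = min(3, len(pool))
    truth.planted_hub_genes = set(map(str, hub_rng.choice(pool, size=n_hubs,
                                                          replace=False)))

    n_nodes = min(200, params.n_genes)
    others = [g for g in counts.genes if g not in truth.planted_hub_genes]
    node_ids = sorted(truth.planted_hub_genes) + others[: n_nodes - n_hubs]
    edges, ppi_truth = simulate_ppi(
        n_nodes=n_nodes, n_edges=3 * n_nodes, planted_hubs=n_hubs,
        pass_fraction=1.0, node_ids=node_ids,
        hub_ids=sorted(truth.planted_hub_genes), rng=rng_ppi)
    truth.planted_ppi_hubs = ppi_truth.planted_ppi_hubs

    pred, truth = simulate_predictions(params, truth, rng=rng_pred,
                                       gene_universe=counts.genes)
    return counts, edges, pred, truth


def write_inputs(outdir: str | Path, params: SimulationParams) -> GroundTruth:
    """Emit a self-contained input directory in the pipeline's dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, edges, pred, truth = simulate_all(params)
    write_count_matrix(counts, outdir / "counts.tsv")
    pd.DataFrame(sorted(counts.groups.items())).to_csv(
        outdir / "groups.tsv", sep="\t", header=False, index=False)
    write_string_edges(edges, outdir / "ppi_edges.tsv")
    pred.circ_mir.to_csv(outdir / "circ_mir.tsv", sep="\t", index=False)
    for name, mapping in pred.per_db_targets.items():
        rows = [{"mirna_id": m, "gene_id": g}
                for m, gs in sorted(mapping.items()) for g in sorted(gs)]
        pd.DataFrame(rows, columns=["mirna_id", "gene_id"]).to_csv(
            outdir / f"targets_{name}.tsv", sep="\t", index=False)
    truth_json = {
        "de_genes_up": sorted(truth.de_genes_up),
        "de_genes_down": sorted(truth.de_genes_down),
        "planted_ppi_hubs": sorted(truth.planted_ppi_hubs),
        "planted_top_mirna": truth.planted_top_mirna,
        "planted_hub_genes": sorted(truth.planted_hub_genes),
        "true_targets": {m: sorted(g) for m, g in truth.true_targets.items()},
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth_json, indent=1))
    return truth
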