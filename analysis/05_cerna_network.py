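"""Assemble the ceRNA network and rank hub genes.

Chains the published filters: circRNA-miRNA pairs at percentile >= 90,
six-way target-database consensus, concordance overlap (upregulated DEGs
that are PPI nodes), the strict mRNA node filter (FDR < 1%,
|log2FC| > 2, P < 0.01), then degree-based hub-gene selection. Also
parses the bundled circRNA annotation table and checks its RBPs against
the DEG table.
"""

import json
from pathlib import Path

import pandas as pd

from cernapipe.cerna import (assemble_cerna, bundled_anril_annotation,
                             concordance_overlap, filter_circ_mir, hub_genes,
                             intersect_target_dbs, rbp_differential_check,
                             read_circ_mir, read_target_db, unique_rbps,
                             PredictionSet)
from cernapipe.config import PipelineConfig
from cernapipe.io import read_string_edges, write_network
from cernapipe.ppi import build_ppi

RESULTS = Path(__file__).resolve().parent.parent / "results"
INPUTS = RESULTS / "inputs"
if not (RESULTS / "deg_table.tsv").exists():
    raise SystemExit("run analysis/02_differential_expression.py first")

cfg = PipelineConfig()
degs = pd.read_csv(RESULTS / "deg_table.tsv", sep="\t")
truth = json.loads((INPUTS / "ground_truth.json").read_text())

annots = bundled_anril_annotation()
rbps = unique_rbps(annots)
report = rbp_differential_check(rbps, degs)
print(f"{len(annots)} annotated circRNA isoforms; {len(rbps)} unique "
      f"flanking RBPs: {', '.join(rbps)}")
print(f"any RBP differentially expressed: {report.attrs['any_differential']}")

pred = PredictionSet(
    circ_mir=read_circ_mir(INPUTS / "circ_mir.tsv"),
    per_db_targets={p.stem.removeprefix("targets_"): read_target_db(p)
                    for p in sorted(INPUTS.glob("targets_*.tsv"))})
pairs = filter_circ_mir(pred, cfg.percentile_min)
consensus = intersect_target_dbs(pred)
ppi = build_ppi(read_string_edges(INPUTS / "ppi_edges.tsv",
                                  cfg.ppi_score_min), degs)
mir_mrna = concordance_overlap(consensus, degs, ppi)
net = assemble_cerna(pairs, mir_mrna, degs, cfg)
if net.is_empty:
    raise SystemExit("empty ceRNA network after filtering")

write_network(net.graph, RESULTS / "cerna_network.sif", format="sif")
genes, mirnas = hub_genes(net, top_n=5)
genes.to_csv(RESULTS / "cerna_hub_genes.tsv", sep="\t", index=False)
mirnas.to_csv(RESULTS / "cerna_mirna_sites.tsv", sep="\t", index=False)

s = net.summary()
print(f"network: {s['n_nodes']} nodes ({s['n_circ']} circRNA / "
      f"{s['n_mirna']} miRNA / {s['n_mrna']} mRNA); "
      f"{s['n_circ_mir_edges']} circ-mir + {s['n_mir_mrna_edges']} "
      f"mir-mrna edges")
print(f"top miRNA: {mirnas.mirna_id.iloc[0]} "
      f"({mirnas.target_sites.iloc[0]} target sites; planted "
      f"{truth['planted_top_mirna']})")
hubs = set(truth["planted_hub_genes"])
top = set(genes.loc[genes.hub, "gene_id"])
print(f"planted hub genes {sorted(hubs)} -> {len(hubs & top)}/{len(hubs)} "
      f"recovered in the top-5 degree ranking")
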