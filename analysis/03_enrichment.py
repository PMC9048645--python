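"""Gene-set over-representation of the up- and down-regulated DEGs.

Builds a small synthetic gene-set collection over the tested universe
(two sets deliberately seeded with DE genes, plus background sets drawn
at random) and tests each direction separately with the EASE-style
conservative p-value; significance requires p < 0.05 and fold
enrichment > 5.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cernapipe.enrichment import enrich_degs
from cernapipe.io import write_gmt

RESULTS = Path(__file__).resolve().parent.parent / "results"
if not (RESULTS / "deg_table.tsv").exists():
    raise SystemExit("run analysis/02_differential_expression.py first")

degs = pd.read_csv(RESULTS / "deg_table.tsv", sep="\t")
rng = np.random.default_rng(0)
universe = degs.gene_id.tolist()
up = degs.loc[degs.status == "up", "gene_id"].tolist()
down = degs.loc[degs.status == "down", "gene_id"].tolist()

collections = {
    "seeded_up_process": set(up[:15]) | set(rng.choice(universe, 10)),
    "seeded_down_process": set(down[:15]) | set(rng.choice(universe, 10)),
}
for j in range(8):
    collections[f"background_set_{j}"] = set(
        rng.choice(universe, size=30, replace=False))
write_gmt(collections, RESULTS / "gene_sets.gmt")

for direction in ("up", "down"):
    table = enrich_degs(degs, collections, direction=direction, mode="ease")
    table.to_csv(RESULTS / f"enrichment_{direction}.tsv", sep="\t",
                 index=False)
    hits = table[table.significant]
    print(f"{direction}: {len(hits)} significant of {len(table)} tested sets"
          + (f"; top term {hits.set_id.iloc[0]} "
             f"(p={hits.p_value.iloc[0]:.2e}, "
             f"fold={hits.fold_enrichment.iloc[0]:.1f})" if len(hits) else ""))
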