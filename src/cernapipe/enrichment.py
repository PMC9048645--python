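"""Gene-set over-representation with hypergeometric or EASE p-values.

For a query of n genes drawn from a universe of N, a set covering K
universe genes and k query hits, the standard p-value is the
hypergeometric upper tail P(X >= k). EASE mode is the conservative
variant that discounts one hit, P(X >= k-1), so single-hit sets are never
significant (k = 1 gives p = 1). Fold enrichment is (k/n)/(K/N).
A term is significant when p < enrich_p_max and fold enrichment
> enrich_fold_min.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .config import PipelineConfig

MODES = ("hypergeometric", "ease")


def enrich(query: set[str], universe: set[str],
           collections: dict[str, set[str]], mode: str = "ease",
           config: PipelineConfig | None = None) -> pd.DataFrame:
    """Test every gene set for over-representation of ``query``.

    Sets are intersected with the universe first; sets with an empty
    intersection are skipped. Returns one row per tested set, sorted by
    p-value, with BH-adjusted FDR over all tested sets.

    Raises if the query is not contained in the universe.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    config = config or PipelineConfig()
    offenders = query - universe
    if offenders:
        raise ValueError(
            f"query genes outside the universe: {sorted(offenders)}")
    n_univ = len(universe)
    n_query = len(query)
    rows = []
    for name, members in collections.items():
        in_univ = members & universe
        big_k = len(in_univ)
        if big_k == 0:
            continue
        k = len(query & in_univ)
        if mode == "ease":
            # one-hit discount: P(X >= k-1); k <= 1 is never evidence
            p = 1.0 if k <= 1 else float(hypergeom.sf(k - 2, n_univ, big_k, n_query))
        else:
            p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, n_univ, big_k, n_query))
        fold = 0.0
        if k > 0 and n_query > 0:
            fold = (k / n_query) / (big_k / n_univ)
        rows.append({"set_id": name, "k": k, "K": big_k, "n": n_query,
                     "N": n_univ, "p_value": min(p, 1.0),
                     "fold_enrichment": fold})
    table = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N",
                                        "p_value", "fold_enrichment"])
    if len(table):
        from statsmodels.stats.multitest import multipletests
        table["bh_fdr"] = multipletests(table.p_value, method="fdr_bh")[1]
        table["significant"] = ((table.p_value < config.enrich_p_max)
                                & (table.fold_enrichment > config.enrich_fold_min))
        table = (table.sort_values(["p_value", "set_id"])
                 .reset_index(drop=True))
    else:
        table["bh_fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table


def enrich_degs(deg_table: pd.DataFrame, collections: dict[str, set[str]],
                direction: str = "up", mode: str = "ease",
                config: PipelineConfig | None = None) -> pd.DataFrame:
    """Run :func:`enrich` on the up-, down- or all-regulated DEGs.

    The universe is the full tested-gene list of the DEG table.
    """
    if direction not in ("up", "down", "all"):
        raise ValueError(f"direction must be up/down/all, got {direction!r}")
    universe = set(deg_table.gene_id)
    if direction == "all":
        query = set(deg_table.loc[deg_table.status != "ns", "gene_id"])
    else:
        query = set(deg_table.loc[deg_table.status == direction, "gene_id"])
    return enrich(query, universe, collections, mode=mode, config=config)
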