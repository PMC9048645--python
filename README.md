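# cernapipe

A pipeline for identifying hub genes regulated by a circular RNA through
the competing-endogenous-RNA (ceRNA) mechanism. The motivating system is
circANRIL, the circular isoform of the lncRNA ANRIL (CDKN2B-AS, chr9p21):
when a cell overexpresses a circRNA that sponges a set of miRNAs, the
targets of those miRNAs should be derepressed, so candidate effector
genes can be found by intersecting (i) upregulated differentially
expressed genes, (ii) the protein-interaction neighborhood, and (iii)
multi-database miRNA-target predictions, then ranking the surviving mRNA
nodes by their degree in the assembled circRNA-miRNA-mRNA network.

The pipeline is aimed at analysts who start from an RNA-seq count matrix
(e.g. a 3-vs-3 overexpression-vs-control design) plus exported database
tables (STRING-style scored interaction edges, circRNA-miRNA percentile
predictions, six miRNA-target prediction sources), not from raw reads or
live web services.

## What it computes

1. **Differential expression** (`cernapipe.diffexpr`). TMM scaling
   factors (doubly trimmed, precision-weighted mean of M-values), log2
   CPM, a common negative-binomial dispersion φ estimated by maximizing
   the conditional (qCML) likelihood (variance = μ + φμ²), and a
   conditional NB exact test per gene: the two-sided p-value is the
   probability, given the two-group sum, of splits no more probable than
   the observed one. BH-adjusted FDR; a gene is `up` if FDR < 0.05 and
   log2FC > 1 (symmetrically `down`). Sample QC reports Pearson r
   between samples and PCA variance fractions.
2. **Gene-set over-representation** (`cernapipe.enrichment`).
   Hypergeometric upper-tail p (or the conservative EASE variant that
   discounts one hit); a term is significant when p < 0.05 and fold
   enrichment (k/n)/(K/N) > 5.
3. **PPI centrality** (`cernapipe.ppi`). Interactions at combined score
   ≥ 0.9 form an unweighted graph; per-node degree, unnormalized
   betweenness and component-adjusted closeness are ranked and the
   *core proteins* are the nodes in the top-20 of all three metrics.
4. **ceRNA assembly** (`cernapipe.cerna`). circRNA-miRNA pairs at
   percentile ≥ 90, miRNA targets supported by **all six** prediction
   sources, concordance overlap (targets must be upregulated DEGs that
   are PPI nodes), a strict mRNA node filter (FDR < 1%, |log2FC| > 2,
   P < 0.01), then hub genes by node degree and crucial miRNAs by
   target-site count. The 13-isoform circANRIL annotation table (with
   flanking-region RNA-binding proteins) ships with the package.
5. **Synthetic data** (`cernapipe.simulate`). Every input above can be
   generated with planted ground truth (DE genes, PPI hubs, top miRNA,
   hub genes), which is how the pipeline is tested end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs (2000 genes, 3 vs 3, 5% DE at |log2FC| = 3, NB dispersion 0.1,
full prediction-source agreement, seed 0) and write their tables under
`results/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_differential_expression.py
python analysis/03_enrichment.py
python analysis/04_ppi_centrality.py
python analysis/05_cerna_network.py
```

Output of the run above:

```
53 up / 48 down of 2000 tested genes
recovered 97.0% of planted DE genes; observed FDR 4.0%
sample similarity: median r within groups 0.908, between 0.840
...
planted hubs ['G00419', 'G00544', 'G01602'] -> 3/3 in the core set
...
network: 12 nodes (6 circRNA / 2 miRNA / 4 mRNA); 6 circ-mir + 7 mir-mrna edges
top miRNA: miR-0001 (4 target sites; planted miR-0001)
planted hub genes ['G00419', 'G00544', 'G01602'] -> 3/3 recovered in the top-5 degree ranking
```

Read: the DEG caller flagged 101 genes, recovering 97% of the 100
planted DE genes at an observed FDR of 4% (nominal 5%); the three
planted hub genes were recovered both as PPI core
proteins and as the top-degree mRNA nodes of the ceRNA network, and the
planted top miRNA carries the most target sites — i.e. on data whose
answer is known, every stage returns it.

The same stages are available as a CLI
(`cernapipe simulate|deg|enrich|ppi|cerna|run-all`, see `--help`) for
running on real exported tables.

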