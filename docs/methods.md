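# Methods

## Model and procedure

The pipeline treats a circRNA-overexpression experiment as a chain of
filters over three evidence layers.

**Counts.** Gene counts are modeled as negative binomial with a common
dispersion: for gene g in sample s, y_gs ~ NB(μ_gs, φ) with
Var = μ + φμ². Between-sample composition bias is removed by TMM: the
reference sample is the one whose upper quartile of count/library is
closest to the mean upper quartile; for each other sample the scaling
factor is 2 to the precision-weighted mean of M-values (log2 ratios)
after removing genes with zeros, the most extreme 30% of M-values and
5% of A-values from each tail; weights are inverse approximate binomial
variances of the log-ratio; factors are rescaled to geometric mean 1.
This reproduces the standard TMM definition (it matches
bioconductor-edgeR's `calcNormFactors` to ~1e-5 on random matrices, see
`tests/test_diffexpr.py::TestEdgeRCrossCheck`).

**Exact test.** Counts are first equalized to the geometric-mean
effective library (scaling then rounding to the nearest integer; the
conditional test downstream is exact for the rounded counts). Because a
sum of n iid NB(μ, φ) variables is NB with size n/φ, the distribution
of one group's sum conditional on the two-group total is free of μ, and
the two-sided p-value is the total conditional probability of splits no
more probable than the observed one. φ = 0 reduces to the binomial
split. Both group sums zero returns p = 1. The common φ is estimated by
bounded 1-D maximization (log scale, φ ∈ [1e-6, 10]) of the summed
per-gene conditional log-likelihoods (qCML); identical replicates drive
the estimate to the lower bound. BH adjustment is applied over all
tested genes, and genes are classified `up`/`down`/`ns` at
FDR < `deg_fdr_max` and |log2FC| > `deg_abs_logfc_min`. log2FC is
computed from TMM-adjusted CPM group means with a 0.5 pseudo-count,
positive when higher in the overexpression group. The exact-test
classic variant (common dispersion, no tagwise or trended shrinkage,
no GLM) was chosen as the simplest model consistent with a 3-vs-3
two-group design; tagwise dispersion would change individual p-values
but not the pipeline's structure.

**Low-count filter.** Genes with CPM > 1 in fewer than 2 samples are
removed before testing. This particular rule is a configurable default,
not a claim about any external dataset's preprocessing.

**Enrichment.** Over-representation uses the hypergeometric upper tail;
the default EASE mode discounts one hit (p = P(X ≥ k−1), so k = 1 is
never evidence), mirroring conservative annotation-tool practice. The
"enrichment score" gate is interpreted as per-term fold enrichment
(k/n)/(K/N) > 5 combined with p < 0.05. The universe defaults to the
tested-gene list of the DEG table; up- and down-regulated lists are
tested separately. No GO-DAG propagation is attempted — collections are
flat GMT sets.

**PPI.** Edges at combined score ≥ 0.9 (both the 0–1 and the 0–1000
STRING export dialects are auto-detected) form an undirected simple
graph. Centralities follow the unweighted convention: exact degree;
betweenness as the unnormalized Brandes pair-path sum (endpoints
excluded, halved for undirected graphs), delegated to networkx and
verified in tests against a naive all-pairs BFS path-counting oracle;
closeness in the component-size-adjusted form
(reachable/(|V|−1))·(reachable/Σd), with a compat flag for plain 1/Σd
within the component. Published closeness values from other tools on
disconnected graphs are not exactly recoverable without that tool's
formula, so the supported contract is the *ranking*, not the raw
closeness value. Core proteins are nodes in the top-k (default 20) of
all three metrics; boundary ties are included then truncated
deterministically by node name, with a log message when triggered.

**ceRNA assembly.** circRNA-miRNA pairs are kept at percentile ≥ 90
(inclusive boundary: "within the Nth percentile" is read as
at-or-above). A miRNA's consensus targets are the genes reported by all
six prediction sources — a strict intersection, so one missing source
vetoes a gene. The concordance overlap keeps (miRNA, gene) pairs whose
gene is an upregulated DEG *and* a PPI node — the sponge logic: if the
circRNA is up, genes released from its miRNAs should be up. mRNA nodes
must additionally pass FDR < 1%, |log2FC| > 2 and P < 0.01; this node
filter is applied to mRNAs only, because the design has no miRNA
expression data (a miRNA DEG table, if ever available, could extend it).
Only miRNAs present in both pair sets survive; isolated nodes are
dropped; an empty result is reported explicitly (`is_empty`), not
raised, so callers can distinguish "nothing survives the filters" from
a malformed input. Hub genes are mRNA nodes ranked by degree (ties by
name); crucial miRNAs by mRNA-side degree (target sites). Any further
curation of hubs by biological function is a manual step outside the
ranking.

**circRNA annotation.** The bundled 13-row annotation of ANRIL-derived
circRNA isoforms stores positions as printed (`chrN:start-end`, no
re-basing); genomic length is defined as end − start and validated
row-wise on parse, since all 13 rows satisfy it exactly. Flanking-region
RBP sets are unioned by `unique_rbps` and cross-checked against the DEG
table by `rbp_differential_check`.

## Synthetic data: what it emulates, what it does not

`simulate.py` generates all inputs from one seed through a splittable
SeedSequence, so every run is bitwise reproducible. Counts: gene
baselines are log-normal (σ = 1.2), per-sample expected totals uniform
in 150k–250k, NB sampling via the gamma-Poisson mixture; DE genes (half
up, half down relative to the `OE` group) have their treatment mean
multiplied by 2^(±de_log2fc). PPI: uniform background edges plus
planted hubs wired to ≥3× the median background degree, scores drawn so
a configurable fraction passes 0.9. Predictions: true targets reported
per-source with probability `db_agreement`; decoy pairs at a low rate
and always withheld from at least one source, so the six-way
intersection is decoy-free by construction at full agreement; planted
hub genes are targeted by ≥2 circRNA-paired miRNAs, and the planted top
miRNA carries the largest target set. Hub genes are drawn from the
upregulated DE genes of at least median abundance — hubs are expressed
transcripts — so they are detectable by the DEG stage.

Defaults: 2000 genes, 3 replicates per group, 5% DE, φ = 0.1, 13
circRNAs, 20 miRNAs, 8 targets per miRNA. The benchmark regime for DEG
recovery plants |log2FC| = 2 against the |log2FC| > 1 calling threshold;
the end-to-end network demonstrations plant |log2FC| = 3 so that planted
genes sit clearly inside the stricter |log2FC| > 2 ceRNA node filter
rather than on its boundary.

What the generator does **not** emulate: gene-length effects, GC bias,
batch structure, correlated genes, tagwise dispersion variation,
compositionally realistic miRNA target structure, or annotation-version
drift in the prediction databases. Passing recovery tests therefore
demonstrates the pipeline's internal correctness and calibration under
its own model, not performance on any particular real dataset.

## Numerical choices

- Conditional pmfs are computed in log space (`gammaln`, `logsumexp`);
  the "no more probable" comparison uses a 1e-10 relative tolerance so
  ties at the observed probability are included.
- The dispersion search uses `minimize_scalar(bounded)` with
  xatol = 1e-4 on the log scale.
- TMM trim boundaries replicate rank-based double trimming
  (floor(n·trim)+1 … n+1−that) on both M and A.
- PCA variance fractions come from the SVD of the gene-centered
  sample × gene logCPM matrix; with s samples at most s−1 components are
  nonzero.
- Library equalization rounds to integers; tests compare against
  oracles *post-rounding*, and the edgeR cross-check tolerance (0.02 on
  p-values) reflects the difference between rounding-based and
  quantile-adjusted pseudo-counts.
- Degenerate inputs raise with the offending row/column/sample named:
  all-zero samples, non-integer cells, constant matrices (undefined
  correlation), empty graphs and empty networks.

## Problem sizes

Recovery statistics are measured at 2000 genes × 6 samples over 10–20
seeds, null calibration over ≥4 seeds (≥8000 p-values), oracle
equivalence on totals ≤ 50, universes ≤ 12 and graphs ≤ 8 nodes (100
random graphs) — sizes at which exhaustive enumeration is exact and the
whole suite stays fast.

## Known limitations

- Only the classic common-dispersion exact test is implemented; designs
  beyond two groups must be contrasted pairwise.
- EASE/hypergeometric enrichment ignores gene length and expression
  biases (no permutation or GSEA-style alternative).
- Centrality values (not rankings) depend on closeness conventions
  across tools; only the ranking is contract-stable.
- The six-source intersection rule is strict by design and brittle to a
  single silent source failure; `intersect_target_dbs` drops miRNAs with
  empty consensus rather than imputing.
- The published supplementary tables of the motivating study are
  journal download files; where they are absent the corresponding counts
  cannot be recomputed (see `tests/test_acceptance.py`), and the
  pipeline validates against planted synthetic truth instead.
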