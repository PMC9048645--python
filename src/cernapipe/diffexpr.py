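"""Differential expression from raw counts, classic count-based workflow.

Stages: TMM (trimmed mean of M-values) scaling factors, log2 CPM,
library equalization, qCML-style common negative-binomial dispersion,
conditional NB exact test, Benjamini-Hochberg FDR and threshold
classification, plus sample-level QC (Pearson correlation and PCA).

The NB parameterization throughout is variance = mu + phi * mu^2, i.e.
``phi`` is the dispersion and 1/phi the NB size parameter; phi = 0 is the
Poisson limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import CountMatrix

logger = logging.getLogger(__name__)

_PHI_MIN = 1e-6
_PHI_MAX = 10.0


def _lib_sizes(cm: CountMatrix) -> pd.Series:
    libs = cm.counts.sum(axis=0)
    zero = libs[libs == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return libs.astype(float)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean rescaled to 1.

    The reference sample is the column whose upper-quartile (of counts
    scaled by library size) is closest to the mean upper-quartile. For
    each sample, genes with a zero count in either the sample or the
    reference are excluded; M-values (log2 ratio) and A-values (log2
    abundance) are doubly trimmed (``trim_m`` and ``trim_a`` from each
    tail), and the factor is 2 to the precision-weighted mean of the
    surviving M-values, with weights from the approximate binomial
    variance of each log-ratio.
    """
    counts = cm.counts.to_numpy(dtype=float)
    libs = _lib_sizes(cm).to_numpy()
    uq = np.array([np.quantile(counts[:, j] / libs[j], 0.75)
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, nr = counts[:, ref], libs[ref]

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ys, ns = counts[:, j], libs[j]
        keep = (ys > 0) & (yr > 0)
        if keep.sum() == 0:
            continue
        ps, pr = ys[keep] / ns, yr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # approximate binomial variance of the log-ratio; weight = 1/var
        var = ((ns - ys[keep]) / (ns * ys[keep])
               + (nr - yr[keep]) / (nr * yr[keep]))
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        trimmed = ((rank_m >= lo_m) & (rank_m <= hi_m)
                   & (rank_a >= lo_a) & (rank_a <= hi_a))
        if trimmed.sum() == 0 or not np.isfinite(m[trimmed]).any():
            continue
        f = np.sum(m[trimmed] / var[trimmed]) / np.sum(1.0 / var[trimmed])
        if np.isfinite(f) and abs(f) > 1e-10:
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="tmm_factor")


def log_cpm(cm: CountMatrix, factors: pd.Series | None = None,
            prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes.

    value = log2((count + prior) / (library * factor / 1e6)).
    """
    if factors is None:
        factors = tmm_factors(cm)
    libs = _lib_sizes(cm)
    eff = libs * factors.reindex(libs.index)
    if (eff <= 0).any():
        bad = list(eff[eff <= 0].index)
        raise ValueError(f"non-positive effective library for sample(s) {bad}")
    return np.log2((cm.counts + prior).div(eff / 1e6, axis=1))


def equalize_libraries(cm: CountMatrix,
                       factors: pd.Series | None = None) -> CountMatrix:
    """Rescale counts to the geometric-mean effective library.

    Each sample's counts are multiplied by (common library / its effective
    library) and rounded to the nearest integer, giving pseudo-counts on
    which equal-library conditional tests are exact post-rounding.
    """
    if factors is None:
        factors = tmm_factors(cm)
    libs = _lib_sizes(cm)
    eff = libs * factors.reindex(libs.index)
    common = np.exp(np.mean(np.log(eff)))
    adj = np.rint(cm.counts * (common / eff)).astype(np.int64)
    return CountMatrix(adj, dict(cm.groups))


def _cond_log_pmf(total: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """Log pmf of the group-1 sum conditional on the two-group total.

    Each count is NB(mu, phi) with a mean shared across samples; the sum
    of n iid such counts is NB with size n/phi, so conditioning on the
    total leaves a distribution free of both mu and the NB probability
    parameter. phi = 0 gives the binomial split n1/(n1+n2).
    """
    a = np.arange(total + 1)
    if phi <= 0:
        logp = (gammaln(total + 1) - gammaln(a + 1) - gammaln(total - a + 1)
                + a * np.log(n1 / (n1 + n2))
                + (total - a) * np.log(n2 / (n1 + n2)))
        return logp
    r1, r2 = n1 / phi, n2 / phi
    logp = (gammaln(a + r1) - gammaln(a + 1)
            + gammaln(total - a + r2) - gammaln(total - a + 1))
    return logp - logsumexp(logp)


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray,
                  dispersion: float) -> float:
    """Two-sided conditional NB exact test on two groups of counts.

    Assumes counts are on a common effective library (see
    :func:`equalize_libraries`). The p-value is the total conditional
    probability, given the two-group sum, of splits no more probable than
    the observed one. Both group sums zero returns p = 1 (no evidence).
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    sa, sb = int(counts_a.sum()), int(counts_b.sum())
    total = sa + sb
    if total == 0:
        return 1.0
    logp = _cond_log_pmf(total, len(counts_a), len(counts_b), dispersion)
    logp = logp - logsumexp(logp)
    obs = logp[sa]
    return float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))


def estimate_common_dispersion(cm: CountMatrix) -> float:
    """Common NB dispersion maximizing the conditional (qCML) likelihood.

    Works on library-equalized counts; every group must have >= 2
    replicates. The likelihood conditions each gene's group counts on
    their sum, which removes the gene means, leaving phi the only free
    parameter; the search is bounded on a log scale.
    """
    from scipy.optimize import minimize_scalar

    groups = cm.group_names
    members = {g: cm.group_samples(g) for g in groups}
    for g, ss in members.items():
        if len(ss) < 2:
            raise ValueError(
                f"group {g!r} has {len(ss)} sample(s); need >= 2 for "
                f"dispersion estimation")
    blocks = [cm.counts[ss].to_numpy(dtype=float) for g, ss in members.items()]

    def neg_cond_loglik(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        r = 1.0 / phi
        total = 0.0
        for y in blocks:
            n = y.shape[1]
            s = y.sum(axis=1)
            keep = s > 0
            if not keep.any():
                continue
            yk, sk = y[keep], s[keep]
            ll = (gammaln(yk + r).sum(axis=1) - y.shape[1] * gammaln(r)
                  - gammaln(sk + n * r) + gammaln(n * r)
                  + gammaln(sk + 1) - gammaln(yk + 1).sum(axis=1))
            total += ll.sum()
        return -total

    res = minimize_scalar(neg_cond_loglik,
                          bounds=(np.log(_PHI_MIN), np.log(_PHI_MAX)),
                          method="bounded",
                          options={"xatol": 1e-4})
    return float(np.exp(res.x))


def filter_low_counts(cm: CountMatrix, min_cpm: float = 1.0,
                      min_samples: int = 2) -> CountMatrix:
    """Drop genes below ``min_cpm`` CPM in fewer than ``min_samples`` samples."""
    libs = _lib_sizes(cm)
    cpm = cm.counts.div(libs / 1e6, axis=1)
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts[keep].copy(), dict(cm.groups))


def call_degs(cm: CountMatrix, config: PipelineConfig | None = None,
              contrast: tuple[str, str] | None = None,
              low_count_filter: bool = True) -> pd.DataFrame:
    """Full DEG table: logFC, logCPM, exact-test p, BH FDR and status.

    ``contrast`` is (treatment, control); the default contrasts the first
    two group labels in sample order. logFC is positive when the gene is
    higher in the treatment group. Status is ``up`` iff
    fdr < deg_fdr_max and logFC > deg_abs_logfc_min, symmetrically
    ``down``, else ``ns``.
    """
    config = config or PipelineConfig()
    if contrast is None:
        names = cm.group_names
        if len(names) < 2:
            raise ValueError("need >= 2 groups")
        contrast = (names[0], names[1])
    treat, ctrl = contrast
    sub = cm.subset_groups([treat, ctrl])
    if low_count_filter:
        sub = filter_low_counts(sub)

    factors = tmm_factors(sub)
    eq = equalize_libraries(sub, factors)
    phi = estimate_common_dispersion(eq)
    logger.info("call_degs: common dispersion %.4g on %d genes", phi,
                len(sub.genes))

    ya = eq.counts[eq.group_samples(treat)].to_numpy()
    yb = eq.counts[eq.group_samples(ctrl)].to_numpy()
    pvals = np.array([nb_exact_test(ya[i], yb[i], phi)
                      for i in range(ya.shape[0])])

    libs = _lib_sizes(sub)
    eff = libs * factors
    cpm = (sub.counts + 0.5).div(eff / 1e6, axis=1)
    mean_t = cpm[sub.group_samples(treat)].mean(axis=1)
    mean_c = cpm[sub.group_samples(ctrl)].mean(axis=1)
    logfc = np.log2(mean_t / mean_c)
    logcpm_mean = log_cpm(sub, factors).mean(axis=1)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame({
        "gene_id": sub.genes,
        "logFC": logfc.to_numpy(),
        "logCPM": logcpm_mean.to_numpy(),
        "p_value": pvals,
        "fdr": fdr,
    })
    up = (table.fdr < config.deg_fdr_max) & (table.logFC > config.deg_abs_logfc_min)
    down = (table.fdr < config.deg_fdr_max) & (table.logFC < -config.deg_abs_logfc_min)
    table["status"] = np.where(up, "up", np.where(down, "down", "ns"))
    logger.info("call_degs: %d up, %d down of %d genes",
                int(up.sum()), int(down.sum()), len(table))
    return table


@dataclass
class SampleQC:
    """Sample-level QC: correlation structure and principal components."""

    pearson_r: pd.DataFrame
    pc_variance: np.ndarray
    within_group_median_r: float
    between_group_median_r: float


def sample_qc(cm: CountMatrix) -> SampleQC:
    """Pearson correlations and PCA of samples on log2 CPM.

    PCA is the singular value decomposition of the gene-centered logCPM
    matrix with samples as observations; ``pc_variance`` holds each
    component's fraction of total variance (non-increasing, sums to 1).
    """
    if len(cm.samples) < 3:
        raise ValueError("sample QC needs >= 3 samples")
    lcpm = log_cpm(cm)
    if np.allclose(lcpm.to_numpy().std(axis=0), 0):
        raise ValueError("constant expression matrix: correlation undefined")
    r = lcpm.corr(method="pearson")

    x = lcpm.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(x, compute_uv=False)
    pc_var = sv ** 2 / np.sum(sv ** 2)

    within, between = [], []
    samples = cm.samples
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            gi, gj = cm.groups.get(samples[i]), cm.groups.get(samples[j])
            val = r.iloc[i, j]
            if gi is not None and gi == gj:
                within.append(val)
            elif gi is not None and gj is not None:
                between.append(val)
    return SampleQC(
        pearson_r=r,
        pc_variance=pc_var,
        within_group_median_r=float(np.median(within)) if within else float("nan"),
        between_group_median_r=float(np.median(between)) if between else float("nan"),
    )
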