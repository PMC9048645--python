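import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernapipe.config import PipelineConfig
from cernapipe.diffexpr import (call_degs, equalize_libraries,
                                estimate_common_dispersion, filter_low_counts,
                                log_cpm, nb_exact_test, sample_qc, tmm_factors)
from cernapipe.io import CountMatrix
from cernapipe.simulate import SimulationParams, simulate_counts


def _cm(array, groups=None, genes=None):
    arr = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    groups = groups or {s: ("A" if j < arr.shape[1] // 2 else "B")
                        for j, s in enumerate(samples)}
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples,
                                    dtype=np.int64), groups)


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm(np.tile([[10], [50], [200], [5], [80]], (1, 2)))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), [1.0, 1.0])

    def test_pure_depth_change_gives_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80])
        cm = _cm(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), [1.0, 1.0],
                                   atol=1e-12)

    def test_toy_matrix_matches_direct_formula(self):
        # 5 genes, one inflated in sample 1; oracle evaluates the weighted
        # trimmed mean of M-values directly from its definition.
        y = np.array([[100, 100], [200, 210], [300, 290],
                      [400, 410], [50, 2000]])
        cm = _cm(y)
        n0, n1 = y[:, 0].sum(), y[:, 1].sum()
        # upper-quartile reference selection
        uq = [np.quantile(y[:, 0] / n0, 0.75), np.quantile(y[:, 1] / n1, 0.75)]
        ref = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
        other = 1 - ref
        ps, pr = y[:, other] / [n0, n1][other], y[:, ref] / [n0, n1][ref]
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = 1.0 / ((([n0, n1][other] - y[:, other]) / ([n0, n1][other] * y[:, other]))
                   + (([n0, n1][ref] - y[:, ref]) / ([n0, n1][ref] * y[:, ref])))
        # double trim on 5 genes: M keeps ranks 2..4, A keeps all
        keep = np.argsort(np.argsort(m)) + 1
        mask = (keep >= 2) & (keep <= 4)
        f_other = 2.0 ** (np.sum(m[mask] * w[mask]) / np.sum(w[mask]))
        expected = np.ones(2)
        expected[other] = f_other
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), expected,
                                   rtol=1e-10)

    def test_geometric_mean_is_one_and_gene_order_invariant(self, medium_counts):
        f = tmm_factors(medium_counts)
        assert np.prod(f) == pytest.approx(1.0, abs=1e-12)
        shuffled = CountMatrix(
            medium_counts.counts.sample(frac=1, random_state=0),
            medium_counts.groups)
        np.testing.assert_allclose(tmm_factors(shuffled).to_numpy(),
                                   f.to_numpy())

    def test_all_zero_sample_named(self):
        cm = _cm([[5, 0], [3, 0]])
        with pytest.raises(ValueError, match="s1"):
            tmm_factors(cm)


class TestLogCpm:
    def test_zero_count_million_library(self):
        # one gene at count 0 in a sample whose library is ~1e6
        mat = pd.DataFrame([[0, 5], [10 ** 6, 10 ** 6]], index=["g0", "g1"],
                           columns=["s0", "s1"])
        cm = CountMatrix(mat.astype(np.int64), {"s0": "A", "s1": "B"})
        factors = pd.Series([1.0, 1.0], index=["s0", "s1"])
        lcpm = log_cpm(cm, factors, prior=0.5)
        # library ~ 1e6 (the second gene dominates), value = log2(0.5/1.000005)
        assert lcpm.loc["g0", "s0"] == pytest.approx(np.log2(0.5), abs=0.01)

    def test_joint_scaling_invariance_at_zero_prior(self):
        base = np.array([[10, 20], [30, 40], [60, 80]])
        cm1 = _cm(base, groups={"s0": "A", "s1": "B"})
        cm2 = _cm(2 * base, groups={"s0": "A", "s1": "B"})
        f = pd.Series([1.0, 1.0], index=["s0", "s1"])
        pd.testing.assert_frame_equal(log_cpm(cm1, f, prior=0),
                                      log_cpm(cm2, f, prior=0))

    def test_matches_direct_formula(self):
        mat = np.array([[3, 10], [7, 0], [20, 5]])
        cm = _cm(mat, groups={"s0": "A", "s1": "B"})
        factors = pd.Series([1.1, 0.9], index=["s0", "s1"])
        libs = mat.sum(axis=0)
        expected = np.log2((mat + 0.5) / (libs * np.array([1.1, 0.9]) / 1e6))
        np.testing.assert_allclose(log_cpm(cm, factors).to_numpy(), expected)

    def test_nonpositive_effective_library_rejected(self):
        cm = _cm([[3, 10]], groups={"s0": "A", "s1": "B"})
        factors = pd.Series([0.0, 1.0], index=["s0", "s1"])
        with pytest.raises(ValueError, match="effective library"):
            log_cpm(cm, factors)


class TestNbExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert nb_exact_test([5, 5, 5], [5, 5, 5], 0.1) == pytest.approx(1.0)

    def test_poisson_limit_equals_binomial_two_sided(self):
        # groups of equal size and library: conditional law is Binomial(s, 1/2)
        a, b = np.array([7, 3]), np.array([0, 0])
        s = int(a.sum() + b.sum())
        pmf = stats.binom.pmf(np.arange(s + 1), s, 0.5)
        obs = pmf[int(a.sum())]
        expected = pmf[pmf <= obs * (1 + 1e-12)].sum()
        assert nb_exact_test(a, b, 0.0) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("a,b,phi", [
        ([3, 1], [9, 8], 0.2),
        ([10, 5, 2], [1, 0, 4], 0.05),
        ([0, 0], [6, 7], 0.5),
        ([12, 13], [11, 14], 0.0),
    ])
    def test_matches_independent_conditional_enumeration(self, a, b, phi):
        # oracle: scipy nbinom pmf products at an arbitrary mean, normalized
        # over all splits of the total (the mean cancels by conditioning)
        a, b = np.array(a), np.array(b)
        s = int(a.sum() + b.sum())
        splits = np.arange(s + 1)
        if phi == 0:
            probs = stats.poisson.pmf(splits, 5.0 * len(a)) * \
                stats.poisson.pmf(s - splits, 5.0 * len(b))
        else:
            r1, r2 = len(a) / phi, len(b) / phi
            mu1, mu2 = 5.0 * len(a), 5.0 * len(b)
            probs = stats.nbinom.pmf(splits, r1, r1 / (r1 + mu1)) * \
                stats.nbinom.pmf(s - splits, r2, r2 / (r2 + mu2))
        probs = probs / probs.sum()
        obs = probs[int(a.sum())]
        expected = probs[probs <= obs * (1 + 1e-9)].sum()
        assert nb_exact_test(a, b, phi) == pytest.approx(expected, rel=1e-8)

    def test_both_groups_zero_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], 0.1) == 1.0


class TestCommonDispersion:
    def test_poisson_data_estimates_near_zero(self):
        ests = []
        for seed in range(5):
            cm, _ = simulate_counts(SimulationParams(
                n_genes=1000, nb_dispersion=0.0, de_fraction=0.0, seed=seed))
            ests.append(estimate_common_dispersion(equalize_libraries(cm)))
        assert np.mean(ests) < 0.01

    def test_recovers_planted_dispersion(self):
        ests = []
        for seed in range(5):
            cm, _ = simulate_counts(SimulationParams(
                n_genes=1000, nb_dispersion=0.2, de_fraction=0.0, seed=seed))
            ests.append(estimate_common_dispersion(equalize_libraries(cm)))
        assert 0.1 <= np.mean(ests) <= 0.3

    def test_identical_replicates_drive_to_lower_bound(self):
        col = np.array([10, 50, 200, 5, 80, 33])
        cm = _cm(np.tile(col[:, None], (1, 4)))
        assert estimate_common_dispersion(cm) < 1e-4

    def test_single_replicate_group_rejected(self):
        cm = _cm([[1, 2, 3], [4, 5, 6]],
                 groups={"s0": "A", "s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="B"):
            estimate_common_dispersion(cm)


class TestCallDegs:
    def test_status_thresholds_hold_row_wise(self):
        cm, _ = simulate_counts(SimulationParams(n_genes=600, seed=2))
        table = call_degs(cm)
        cfg = PipelineConfig()
        up = (table.fdr < cfg.deg_fdr_max) & (table.logFC > cfg.deg_abs_logfc_min)
        down = (table.fdr < cfg.deg_fdr_max) & (table.logFC < -cfg.deg_abs_logfc_min)
        assert ((table.status == "up") == up).all()
        assert ((table.status == "down") == down).all()
        assert set(table.status) <= {"up", "down", "ns"}

    def test_sample_order_permutation_invariant(self):
        cm, _ = simulate_counts(SimulationParams(n_genes=300, seed=4))
        perm = ["NC_2", "OE_1", "NC_1", "OE_3", "NC_3", "OE_2"]
        cm_perm = CountMatrix(cm.counts[perm], cm.groups)
        t1 = call_degs(cm, contrast=("OE", "NC"))
        t2 = call_degs(cm_perm, contrast=("OE", "NC"))
        pd.testing.assert_frame_equal(t1, t2)

    def test_bh_fdr_is_monotone_in_p_rank(self):
        cm, _ = simulate_counts(SimulationParams(n_genes=400, seed=5))
        table = call_degs(cm).sort_values("p_value")
        assert (np.diff(table.fdr.to_numpy()) >= -1e-12).all()
        assert table.fdr.max() <= 1.0
        assert (table.fdr.to_numpy() >= table.p_value.to_numpy() - 1e-12).all()

    def test_low_count_filter_drops_weak_genes(self):
        cm, _ = simulate_counts(SimulationParams(n_genes=300, seed=1))
        filtered = filter_low_counts(cm, min_cpm=1.0, min_samples=2)
        assert 0 < len(filtered.genes) <= len(cm.genes)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript unavailable")
class TestEdgeRCrossCheck:
    """Independent oracle: bioconductor-edgeR on the same small matrix."""

    def test_factors_dispersion_and_pvalues_agree(self, medium_counts, tmp_path):
        counts_path = tmp_path / "counts.tsv"
        medium_counts.counts.to_csv(counts_path, sep="\t")
        out = tmp_path / "edger.csv"
        script = f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.delim("{counts_path}", row.names=1))
        y <- DGEList(counts=x, group=factor(rep(c("A","B"), each=3)))
        y <- calcNormFactors(y, method="TMM")
        y <- estimateCommonDisp(y)
        et <- exactTest(y)
        res <- data.frame(factor=rep(y$common.dispersion, nrow(x)),
                          pval=et$table$PValue)
        res$tmm <- rep(y$samples$norm.factors, length.out=nrow(x))[1:nrow(x)]
        write.csv(data.frame(pval=et$table$PValue), "{out}")
        cat(y$samples$norm.factors, "\n")
        cat(y$common.dispersion, "\n")
        """
        proc = subprocess.run(["Rscript", "-"], input=script, text=True,
                              capture_output=True, check=True)
        lines = [l for l in proc.stdout.strip().splitlines() if l.strip()]
        r_factors = np.array(lines[-2].split(), dtype=float)
        r_phi = float(lines[-1])

        f = tmm_factors(medium_counts)
        np.testing.assert_allclose(f.to_numpy(), r_factors, rtol=1e-4)
        eq = equalize_libraries(medium_counts, f)
        phi = estimate_common_dispersion(eq)
        assert phi == pytest.approx(r_phi, rel=0.05)
        ya = eq.counts.iloc[:, :3].to_numpy()
        yb = eq.counts.iloc[:, 3:].to_numpy()
        p_mine = np.array([nb_exact_test(ya[i], yb[i], phi)
                           for i in range(len(ya))])
        p_edger = pd.read_csv(out).pval.to_numpy()
        assert np.max(np.abs(p_mine - p_edger)) < 0.02


class TestSampleQc:
    def test_duplicate_samples_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 500, size=100)
        arr = np.column_stack([col, col, rng.integers(1, 500, size=100)])
        cm = _cm(arr, groups={"s0": "A", "s1": "A", "s2": "B"})
        qc = sample_qc(cm)
        assert qc.pearson_r.iloc[0, 1] == pytest.approx(1.0)
        assert qc.pearson_r.equals(qc.pearson_r.T)
        np.testing.assert_allclose(np.diag(qc.pearson_r), 1.0)

    def test_rank_two_data_explained_by_two_components(self):
        rng = np.random.default_rng(4)
        # four samples confined to a plane in gene space
        b1, b2 = rng.normal(size=50), rng.normal(size=50)
        coeffs = rng.normal(size=(4, 2))
        lcpm_like = np.exp(coeffs @ np.vstack([b1, b2]) / 4)
        counts = np.rint(50 * lcpm_like.T + 50).astype(int)
        cm = _cm(counts, groups={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        qc = sample_qc(cm)
        # 4 centered samples have rank <= 3; just check the invariants
        assert qc.pc_variance.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(qc.pc_variance) <= 1e-12).all()

    def test_variance_fractions_match_eigendecomposition(self, medium_counts):
        qc = sample_qc(medium_counts)
        lcpm = log_cpm(medium_counts)
        x = lcpm.to_numpy().T
        x = x - x.mean(axis=0)
        eig = np.linalg.eigvalsh(x @ x.T)[::-1]
        eig = np.clip(eig, 0, None)
        np.testing.assert_allclose(qc.pc_variance[: len(eig)],
                                   eig / eig.sum(), atol=1e-8)

    def test_exact_rank_two_geometry(self):
        # three samples: centered data has rank <= 2, so PC1+PC2 = 100%
        rng = np.random.default_rng(5)
        arr = rng.integers(10, 300, size=(60, 3))
        cm = _cm(arr, groups={"s0": "A", "s1": "A", "s2": "B"})
        qc = sample_qc(cm)
        assert qc.pc_variance[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_three_samples_rejected(self):
        cm = _cm([[1, 2], [3, 4]], groups={"s0": "A", "s1": "B"})
        with pytest.raises(ValueError, match="3 samples"):
            sample_qc(cm)
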