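"""Partitioned-heritability estimator: LD scores, WLS/GLS fits, enrichment."""

import numpy as np
import pytest
from scipy import stats

from ocrpipe.h2 import (
    GwasSummary,
    SnpPanel,
    annotate_snps,
    bonferroni_threshold,
    fit_partitioned,
    fit_partitioned_gls,
    fold_enrichment,
    fold_from_proportions,
    ld_scores,
    read_panel_tsv,
)
from ocrpipe.intervals import GenomeModel, GenomicInterval, PeakSet
from ocrpipe.synth import simulate_gwas


def _panel_no_ld(n_snps, n_ind=60, seed=0, block=10):
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 3, size=(n_ind, n_snps)).astype(np.int8)
    for j in range(n_snps):  # ensure polymorphic
        while G[:, j].std() == 0:
            G[:, j] = rng.integers(0, 3, size=n_ind)
    bounds = [(i, min(i + block, n_snps)) for i in range(0, n_snps, block)]
    block_R = [np.eye(hi - lo) for lo, hi in bounds]
    return SnpPanel(
        snp_ids=[f"rs{j}" for j in range(n_snps)],
        chrom=np.array(["chr1"] * n_snps, dtype=object),
        pos=np.arange(1, n_snps + 1) * 100,
        block_bounds=bounds,
        genotypes=G,
        block_R=block_R,
    )


class TestAnnotateSnps:
    GENOME = GenomeModel({"chr1": 100_000})

    def _panel(self, positions):
        n = len(positions)
        return SnpPanel(
            snp_ids=[f"rs{j}" for j in range(n)],
            chrom=np.array(["chr1"] * n, dtype=object),
            pos=np.array(positions),
            block_bounds=[(0, n)],
            block_R=[np.eye(n)],
        )

    def test_flank_boundary_convention(self):
        # peak [1500,2000) extended by 500 -> [1000,2500); a SNP's 0-based
        # coordinate is pos-1, so 1-based 1001 (0-based 1000) is the first
        # position inside and 1000 (0-based 999) is just outside
        panel = self._panel([1000, 1001, 2500, 2501])
        got = annotate_snps(panel, PeakSet([GenomicInterval("chr1", 1500, 2000)]),
                            flank=500, genome=self.GENOME)
        assert got.tolist() == [0, 1, 1, 0]

    def test_no_peaks_all_zero(self):
        panel = self._panel([10, 20])
        assert annotate_snps(panel, PeakSet(), 500, self.GENOME).tolist() == [0, 0]

    def test_whole_genome_all_one(self):
        panel = self._panel([1, 50_000, 100_000])
        peaks = PeakSet([GenomicInterval("chr1", 0, 100_000)])
        assert annotate_snps(panel, peaks, 0, self.GENOME).tolist() == [1, 1, 1]


class TestLdScores:
    def test_no_ld_base_score_is_one(self):
        panel = _panel_no_ld(10)
        panel.genotypes = None  # force use of the identity block_R
        ell = ld_scores(panel, np.ones((10, 1)))
        assert np.allclose(ell, 1.0)

    def test_perfectly_correlated_pair(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        panel = SnpPanel(
            snp_ids=["a", "b"],
            chrom=np.array(["chr1", "chr1"], dtype=object),
            pos=np.array([100, 200]),
            block_bounds=[(0, 2)],
            block_R=[R],
        )
        ell = ld_scores(panel, np.ones((2, 1)))
        assert np.allclose(ell, 2.0)

    def test_brute_force_all_pairs_oracle(self):
        """Genotype-derived scores equal the naive all-pairs r^2 sum on a
        single-block 50-SNP panel."""
        rng = np.random.default_rng(5)
        n_snps, n_ind = 50, 80
        G = rng.integers(0, 3, size=(n_ind, n_snps)).astype(np.int8)
        panel = SnpPanel(
            snp_ids=[f"rs{j}" for j in range(n_snps)],
            chrom=np.array(["chr1"] * n_snps, dtype=object),
            pos=np.arange(1, n_snps + 1) * 10,
            block_bounds=[(0, n_snps)],
            genotypes=G,
        )
        A = np.column_stack([np.ones(n_snps), rng.integers(0, 2, n_snps)])
        got = ld_scores(panel, A, window_bp=10_000)
        expected = np.zeros_like(got)
        for j in range(n_snps):
            for k in range(n_snps):
                r = np.corrcoef(G[:, j].astype(float), G[:, k].astype(float))[0, 1]
                r2 = r * r
                r2 = max(0.0, r2 - (1 - r2) / (n_ind - 2)) if j != k else 1.0
                for c in range(2):
                    if A[k, c]:
                        expected[j, c] += r2
        assert np.allclose(got, expected, atol=1e-10)

    def test_window_limits_pairs(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        panel = SnpPanel(
            snp_ids=["a", "b", "c"],
            chrom=np.array(["chr1"] * 3, dtype=object),
            pos=np.array([100, 200, 10_000]),
            block_bounds=[(0, 3)],
            block_R=[R],
        )
        ell = ld_scores(panel, np.ones((3, 1)), window_bp=500)
        assert np.allclose(ell[:, 0], [1.25, 1.25, 1.0])


class TestFitPartitioned:
    def test_exact_recovery_without_noise(self):
        # chi2 = N*tau + 1 exactly, single base category, no LD
        n, N, tau = 200, 1000.0, 3e-4
        ell = np.ones((n, 1))
        gwas = GwasSummary(np.full(n, N * tau + 1.0), N)
        fit = fit_partitioned(gwas, ell, n_blocks=10)
        assert fit.tau[0] == pytest.approx(tau, rel=1e-12)
        assert fit.tau_se[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_wls_closed_form(self, rng):
        n = 300
        ell = np.column_stack([rng.uniform(1, 20, n), rng.uniform(0, 5, n)])
        chisq = rng.chisquare(1, n) * 2
        gwas = GwasSummary(chisq, 500.0)
        fit = fit_partitioned(gwas, ell, n_blocks=5)
        X = 500.0 * ell
        w = 1.0 / np.maximum(ell[:, 0], 1.0)
        beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ (chisq - 1))
        assert np.allclose(fit.tau, beta, rtol=1e-10)

    def test_singular_design_names_categories(self):
        n = 100
        base = np.ones(n)
        ell = np.column_stack([base, base * 2])  # collinear
        with pytest.raises(ValueError, match="collinear"):
            fit_partitioned(GwasSummary(np.ones(n), 100.0), ell,
                            n_blocks=5, category_names=["base", "dup"])

    def test_free_intercept_recovers_inflation(self):
        n, N, tau, a = 2000, 1000.0, 2e-4, 1.3
        rng = np.random.default_rng(8)
        ell = np.column_stack([rng.uniform(1, 10, n)])
        mean = N * tau * ell[:, 0] + a
        gwas = GwasSummary(mean * rng.chisquare(1, n), N)
        fit = fit_partitioned(gwas, ell, n_blocks=20, free_intercept=True)
        assert fit.intercept == pytest.approx(a, rel=0.2)

    def test_tau_recovery_within_jackknife_se(self, bundle):
        ell = ld_scores(bundle.panel, bundle.annotations)
        rng = np.random.default_rng(77)
        gwas, _, _ = simulate_gwas(
            bundle.panel, bundle.annotations, bundle.truth.tau, bundle.config.n_gwas, rng
        )
        fit = fit_partitioned(gwas, ell, n_blocks=20, category_names=bundle.category_names)
        for c in range(len(fit.tau)):
            assert abs(fit.tau[c] - bundle.truth.tau[c]) < 4 * fit.tau_se[c] + 1e-12


class TestFoldEnrichment:
    def test_paper_style_proportions(self):
        assert fold_from_proportions(0.239, 0.033) == pytest.approx(7.24, abs=0.01)

    def test_all_snps_annotation_fold_one(self):
        n = 100
        ell = np.ones((n, 2))
        gwas = GwasSummary(np.full(n, 1.5), 100.0)
        A = np.ones((n, 2))
        with pytest.raises(ValueError, match="collinear"):
            # the duplicated all-SNPs column is degenerate by construction
            fit_partitioned(gwas, ell, n_blocks=5)
        # with a single base category the annotation IS all SNPs: fold == 1
        fit = fit_partitioned(gwas, ell[:, :1], n_blocks=5)
        res = fold_enrichment(fit, A[:, :1], 0)
        assert res.fold == pytest.approx(1.0)
        assert res.prop_snps == 1.0

    def test_uniform_tau_uniform_coverage_fold_one(self):
        rng = np.random.default_rng(1)
        n = 400
        A = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        tau = np.array([2e-4, 0.0])  # equal per-SNP h2 everywhere
        from ocrpipe.h2 import PartitionedFit

        fit = PartitionedFit(
            tau=tau,
            tau_cov=np.eye(2) * 1e-12,
            delete_tau=np.tile(tau, (5, 1)),
            category_names=["base", "c"],
            intercept=1.0,
            n_snps=n,
            N=100.0,
        )
        assert fold_enrichment(fit, A, "c").fold == pytest.approx(1.0)

    def test_h2_shares_partition_to_one(self):
        """Across disjoint categories covering all SNPs, prop_h2 sums to 1."""
        rng = np.random.default_rng(9)
        n = 600
        groups = rng.integers(0, 3, n)
        A = np.column_stack([np.ones(n)] + [(groups == k).astype(float) for k in range(3)])
        tau = np.array([1e-4, 5e-5, 0.0, 2e-4])
        from ocrpipe.h2 import PartitionedFit

        fit = PartitionedFit(
            tau=tau,
            tau_cov=np.eye(4) * 1e-12,
            delete_tau=np.tile(tau, (5, 1)),
            category_names=["base", "g0", "g1", "g2"],
            intercept=1.0,
            n_snps=n,
            N=100.0,
        )
        total = sum(fold_enrichment(fit, A, f"g{k}").prop_h2 for k in range(3))
        assert total == pytest.approx(1.0)

    def test_gls_matches_wls_closely_on_no_ld_panel(self):
        panel = _panel_no_ld(200, block=20)
        panel.genotypes = None
        rng = np.random.default_rng(12)
        A = np.column_stack([np.ones(200), rng.integers(0, 2, 200)])
        tau = np.array([2e-4, 2e-4])
        gwas, _, _ = simulate_gwas(panel, A, tau, 500.0, rng)
        ell = ld_scores(panel, A)
        wls = fit_partitioned(gwas, ell, n_blocks=10)
        gls = fit_partitioned_gls(gwas, ell, panel, A, n_blocks=10)
        # without LD both estimators solve nearly the same problem
        assert np.allclose(wls.tau, gls.tau, atol=5e-4)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 7, 0.0071), (0.05, 1, 0.05), (0.01, 5, 0.002)]
    )
    def test_threshold_examples(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 3)


class TestPanelIO:
    def test_panel_tsv_round_trip(self, tmp_path, bundle):
        from ocrpipe.synth import write_study

        manifest = write_study(bundle, tmp_path)
        panel = read_panel_tsv(manifest["panel"])
        assert panel.n_snps == bundle.panel.n_snps
        assert panel.block_bounds == bundle.panel.block_bounds
        assert np.array_equal(panel.genotypes, bundle.panel.genotypes)
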