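"""GRM construction, HE regression, liability conversion, comparisons."""

import numpy as np
import pytest
from scipy import stats

from phenoharmon.exceptions import EstimationError
from phenoharmon.heritability import (
    H2Estimate,
    build_grm,
    compare_h2,
    estimate_h2_observed,
    grm_snps_qc,
    he_regression,
    hwe_pvalues,
    ld_prune,
    liability_factor,
    liability_transform,
    reml_h2,
)


def simulate_quantitative(rng, n, m, h2):
    f = rng.uniform(0.1, 0.5, m)
    G = rng.binomial(2, f, size=(n, m))
    X = (G - 2 * f) / np.sqrt(2 * f * (1 - f))
    b = rng.standard_normal(m) * np.sqrt(h2 / m)
    y = X @ b + rng.standard_normal(n) * np.sqrt(1 - h2)
    return G, y


class TestQC:
    def test_low_maf_removed(self, rng):
        G = rng.binomial(2, [0.05, 0.3, 0.4], size=(500, 3)).astype(float)
        _, snp_keep = grm_snps_qc(G, prune_r2=1.1)
        assert not snp_keep[0] and snp_keep[1] and snp_keep[2]

    def test_duplicated_snp_pruned(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        G = np.column_stack([g, g, rng.binomial(2, 0.4, 300)])
        _, snp_keep = grm_snps_qc(G)
        assert snp_keep.sum() == 2
        assert not (snp_keep[0] and snp_keep[1])  # one copy of the pair dropped

    def test_independent_snps_barely_pruned(self, rng):
        G = rng.binomial(2, rng.uniform(0.15, 0.5, 150), size=(800, 150)).astype(float)
        _, snp_keep = grm_snps_qc(G)
        assert snp_keep.sum() >= 145

    def test_hwe_violating_snp_removed(self, rng):
        # all-heterozygote SNP grossly violates HWE
        G = np.column_stack(
            [np.ones(500), rng.binomial(2, 0.4, 500)]
        ).astype(float)
        p = hwe_pvalues(G)
        assert p[0] < 1e-10 and p[1] > 0.001
        _, snp_keep = grm_snps_qc(G, prune_r2=1.1)
        assert not snp_keep[0] and snp_keep[1]

    def test_high_missingness_sample_removed(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 50)).astype(float)
        G[0, :40] = np.nan
        sample_keep, _ = grm_snps_qc(G)
        assert not sample_keep[0] and sample_keep[1:].all()

    def test_all_removed_raises(self):
        G = np.ones((50, 2))  # monomorphic -> MAF 0 everywhere
        with pytest.raises(EstimationError):
            grm_snps_qc(G)

    def test_region_exclusion(self, rng):
        import pandas as pd

        G = rng.binomial(2, 0.3, size=(200, 4)).astype(float)
        meta = pd.DataFrame({"CHR": [1, 1, 2, 2], "BP": [100, 5000, 100, 5000]})
        _, snp_keep = grm_snps_qc(G, meta, exclude_regions=[(1, 0, 1000)], prune_r2=1.1)
        assert not snp_keep[0] and snp_keep[1:].all()


class TestGRM:
    def test_matches_brute_force(self, rng):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 50), size=(20, 50))
        A = build_grm(G)
        f = G.mean(0) / 2
        X = (G - 2 * f) / np.sqrt(2 * f * (1 - f))
        oracle = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                oracle[i, j] = np.mean(X[i] * X[j])
        assert np.allclose(A, oracle, atol=1e-12)

    def test_duplicated_sample_relationship(self, rng):
        G = rng.binomial(2, 0.3, size=(30, 200))
        G[1] = G[0]
        A = build_grm(G)
        assert A[0, 1] == pytest.approx(A[0, 0])

    def test_unrelated_off_diagonals_near_centering_constant(self, rng):
        # with sample-frequency centering, off-diagonals sum to -trace
        # exactly, so their mean for unrelated samples is ~ -1/(n-1)
        n = 100
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 500), size=(n, 500))
        A = build_grm(G)
        off = A[np.triu_indices(n, 1)]
        assert off.mean() == pytest.approx(-A.trace() / (n * (n - 1)), abs=1e-12)
        assert abs(off.mean()) < 0.02
        assert A.diagonal().mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_excluded(self, rng):
        G = np.column_stack([np.zeros(50), rng.binomial(2, 0.4, 50)])
        A = build_grm(G)  # must not produce NaN
        assert np.isfinite(A).all()


class TestHERegression:
    def test_slope_equals_least_squares_oracle(self, rng):
        n = 30
        A = rng.standard_normal((n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        slope, _ = he_regression(y, A, n_blocks=5)
        xs, ys = [], []
        for i in range(n):
            for j in range(i + 1, n):
                xs.append(A[i, j])
                ys.append(y[i] * y[j])
        # the estimator is the through-origin least-squares slope
        xs, ys = np.array(xs), np.array(ys)
        oracle0 = (xs @ ys) / (xs @ xs)
        assert slope == pytest.approx(oracle0, abs=1e-12)

    def test_null_phenotype_near_zero(self, rng):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 400), size=(800, 400))
        A = build_grm(G)
        y = rng.standard_normal(800)
        est = estimate_h2_observed(y, A)
        assert abs(est.h2) < 2 * est.se + 0.02

    def test_parameter_recovery(self, rng):
        vals = []
        for _ in range(10):
            G, y = simulate_quantitative(rng, 1200, 400, 0.3)
            est = estimate_h2_observed(y, build_grm(G))
            vals.append(est.h2)
        assert 0.24 < np.mean(vals) < 0.36

    def test_reml_agrees_with_he(self, rng):
        G, y = simulate_quantitative(rng, 1000, 300, 0.4)
        A = build_grm(G)
        he = estimate_h2_observed(y, A, estimator="he")
        reml = estimate_h2_observed(y, A, estimator="reml")
        assert abs(he.h2 - reml.h2) < 2 * np.hypot(he.se, reml.se)

    def test_zero_variance_rejected(self, rng):
        A = np.eye(10)
        with pytest.raises(EstimationError):
            estimate_h2_observed(np.ones(10), A)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(EstimationError):
            he_regression(np.zeros(5), np.eye(4))


class TestLiabilityConversion:
    def test_closed_form_half(self):
        # K = P = 0.5: t = 0, phi(0)^2 = 1/(2 pi), factor = pi/2
        assert liability_factor(0.5, 0.5) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_numeric_oracle(self):
        K, P = 0.01, 0.05
        t = stats.norm.isf(K)
        oracle = K**2 * (1 - K) ** 2 / (P * (1 - P) * stats.norm.pdf(t) ** 2)
        assert liability_factor(K, P) == pytest.approx(oracle, abs=1e-6)

    def test_zero_h2_maps_to_zero(self):
        est = H2Estimate("d", "observed", 0.0, 0.01, None, 0.3, 100, 50)
        for K in (0.01, 0.2, 0.5):
            assert liability_transform(est, K).h2 == 0.0

    def test_linear_in_h2_and_se(self):
        a = H2Estimate("d", "observed", 0.10, 0.02, None, 0.3, 100, 50)
        b = H2Estimate("d", "observed", 0.20, 0.04, None, 0.3, 100, 50)
        ta, tb = liability_transform(a, 0.05), liability_transform(b, 0.05)
        assert tb.h2 == pytest.approx(2 * ta.h2)
        assert tb.se == pytest.approx(2 * ta.se)

    def test_domain_errors(self):
        with pytest.raises(EstimationError):
            liability_factor(0.0, 0.5)
        with pytest.raises(EstimationError):
            liability_factor(0.5, 1.0)


class TestCompareH2:
    def mk(self, h2, se):
        return H2Estimate("d", "liability", h2, se, 0.01, 0.3, 100, 50)

    def test_identical_estimates_p_one(self):
        a = self.mk(0.2, 0.05)
        stat, p = compare_h2(a, self.mk(0.2, 0.05))
        assert stat == 0.0 and p == 1.0

    def test_published_style_difference_significant(self):
        # 0.275 +/- 0.017 vs 0.139 +/- 0.009 is overwhelmingly different
        stat, p = compare_h2(self.mk(0.275, 0.017), self.mk(0.139, 0.009))
        assert p < 3.6e-3

    def test_symmetry(self):
        a, b = self.mk(0.3, 0.02), self.mk(0.25, 0.03)
        s1, p1 = compare_h2(a, b)
        s2, p2 = compare_h2(b, a)
        assert s1 == -s2 and p1 == p2

    def test_scale_mismatch_rejected(self):
        obs = H2Estimate("d", "observed", 0.1, 0.02, None, 0.3, 100, 50)
        with pytest.raises(EstimationError):
            compare_h2(self.mk(0.2, 0.05), obs)


def test_ld_prune_keeps_representative(rng):
    g = rng.binomial(2, 0.3, 500).astype(float)
    noisy = np.clip(g + rng.binomial(1, 0.05, 500), 0, 2)  # r2 ~ 0.9
    indep = rng.binomial(2, 0.3, 500).astype(float)
    G = np.column_stack([g, noisy, indep])
    maf = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
    keep = ld_prune(G, maf, window=10, step=5, r2_max=0.2)
    assert keep.sum() == 2 and keep[2]
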