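"""Synthetic-cohort generator: LD structure, liability model, classifiers."""

import numpy as np
import pytest
from scipy import stats

from phenoharmon.exceptions import CalibrationError, ConfigurationError, SimulationError
from phenoharmon.phenodef import cohens_kappa
from phenoharmon.simdata import (
    SimConfig,
    calibrate_confusion,
    expected_kappa,
    simulate_classifiers,
    simulate_cohort,
    simulate_genotypes,
    symmetric_confusion,
)


class TestGenotypes:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_snps=100, seed=7)
        g1, m1 = simulate_genotypes(cfg, 200)
        g2, m2 = simulate_genotypes(cfg, 200)
        assert np.array_equal(g1, g2)
        assert m1.equals(m2)

    def test_different_seed_differs(self):
        g1, _ = simulate_genotypes(SimConfig(n_snps=100, seed=1), 200)
        g2, _ = simulate_genotypes(SimConfig(n_snps=100, seed=2), 200)
        assert not np.array_equal(g1, g2)

    def test_dosage_domain_and_frequency(self):
        cfg = SimConfig(n_snps=200, maf_range=(0.2, 0.4), seed=3)
        g, meta = simulate_genotypes(cfg, 3000)
        assert set(np.unique(g)) <= {0, 1, 2}
        sample_f = g.mean(axis=0) / 2
        # sample frequency tracks the generating frequency within ~4 SE
        se = np.sqrt(meta["FREQ1"] * (1 - meta["FREQ1"]) / (2 * 3000))
        assert np.all(np.abs(sample_f - meta["FREQ1"]) < 4.5 * se)

    def test_independent_snps_uncorrelated(self):
        cfg = SimConfig(n_snps=80, ld_rho=0.0, seed=5, n_causal_per_subtype=5)
        g, _ = simulate_genotypes(cfg, 1500)
        gc = g - g.mean(axis=0)
        corr = np.corrcoef(gc.T)
        off = corr[np.triu_indices(80, 1)]
        assert np.mean(np.abs(off)) < 3 / np.sqrt(1500)

    def test_high_ld_adjacent_r2_matches_monte_carlo_oracle(self):
        """Adjacent-SNP genotype r2 under latent rho=0.9 matches a direct
        bivariate-normal Monte-Carlo oracle at the same allele
        frequencies (thresholding attenuates r2 well below rho^2)."""
        cfg = SimConfig(
            n_snps=100, ld_rho=0.9, ld_block_size=10, seed=11,
            n_chromosomes=1, n_causal_per_subtype=10,
        )
        g, meta = simulate_genotypes(cfg, 2000)
        freq = meta["FREQ1"].to_numpy()

        def oracle_r2(rho, f1, f2, n=100_000):
            orng = np.random.default_rng(99)
            z1 = orng.standard_normal((2, n))
            z2 = rho * z1 + np.sqrt(1 - rho**2) * orng.standard_normal((2, n))
            a = (z1 < stats.norm.ppf(f1)).sum(axis=0)
            b = (z2 < stats.norm.ppf(f2)).sum(axis=0)
            return np.corrcoef(a, b)[0, 1] ** 2

        obs, exp = [], []
        for j in range(0, 99, 7):
            if (j + 1) % 10 == 0:  # block boundary
                continue
            obs.append(np.corrcoef(g[:, j], g[:, j + 1])[0, 1] ** 2)
            exp.append(oracle_r2(0.9, freq[j], freq[j + 1]))
        assert np.mean(obs) == pytest.approx(np.mean(exp), abs=0.08)
        assert np.mean(obs) > 0.2  # strong LD regime

    def test_ld_resets_at_block_boundary(self):
        cfg = SimConfig(n_snps=100, ld_rho=0.9, ld_block_size=10, seed=13, n_chromosomes=1)
        g, _ = simulate_genotypes(cfg, 2000)
        cross = [np.corrcoef(g[:, j], g[:, j + 1])[0, 1] ** 2 for j in range(9, 99, 10)]
        assert np.mean(cross) < 0.1

    def test_positions_increase_within_chromosome(self):
        _, meta = simulate_genotypes(SimConfig(n_snps=100, n_chromosomes=3, seed=1), 10)
        for _, sub in meta.groupby("CHR"):
            assert np.all(np.diff(sub["BP"]) > 0)

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_snps=0)
        with pytest.raises(ConfigurationError):
            simulate_genotypes(SimConfig(n_snps=10), 0)


class TestLiabilityModel:
    def test_null_h2_cases_independent_of_genotype(self):
        cfg = SimConfig(
            n_cases_per_subtype=120, n_controls=300, n_snps=100,
            h2_liability=0.0, n_causal_per_subtype=5, ld_rho=0.0, seed=2,
        )
        cohort = simulate_cohort(cfg)
        # at the nominally causal SNPs, case/control frequencies agree
        causal = cohort.effects.causal_idx["SVS"]
        is_case = (cohort.samples["TRUE_SUBTYPE"] == "SVS").to_numpy()
        is_ctl = (cohort.samples["STATUS"] == "control").to_numpy()
        f_case = cohort.genotypes[is_case][:, causal].mean() / 2
        f_ctl = cohort.genotypes[is_ctl][:, causal].mean() / 2
        assert abs(f_case - f_ctl) < 0.05

    def test_causal_snps_enriched_in_cases(self):
        cfg = SimConfig(
            n_cases_per_subtype=300, n_controls=600, n_snps=60,
            h2_liability=0.5, n_causal_per_subtype=2, ld_rho=0.0,
            prevalence=0.10, seed=21,
        )
        cohort = simulate_cohort(cfg)
        idx = cohort.effects.causal_idx["SVS"]
        beta = cohort.effects.beta["SVS"]
        is_case = (cohort.samples["TRUE_SUBTYPE"] == "SVS").to_numpy()
        is_ctl = (cohort.samples["STATUS"] == "control").to_numpy()
        # frequency shift agrees in sign with the effect for the big effects
        j = idx[np.argmax(np.abs(beta))]
        shift = cohort.genotypes[is_case, j].mean() - cohort.genotypes[is_ctl, j].mean()
        assert np.sign(shift) == np.sign(beta[np.argmax(np.abs(beta))])

    def test_effect_scale_matches_h2(self):
        from phenoharmon.simdata import draw_effects

        cfg = SimConfig(n_snps=500, h2_liability=0.37, seed=4)
        eff = draw_effects(cfg, np.random.default_rng(4))
        for s in cfg.subtypes:
            assert np.sum(eff.beta[s] ** 2) == pytest.approx(0.37)

    def test_disjoint_causal_sets(self):
        from phenoharmon.simdata import draw_effects

        cfg = SimConfig(n_snps=200, n_causal_per_subtype=40, seed=9)
        eff = draw_effects(cfg, np.random.default_rng(9))
        all_idx = np.concatenate([eff.causal_idx[s] for s in cfg.subtypes])
        assert len(all_idx) == len(set(all_idx))

    def test_infeasible_ascertainment_raises(self):
        cfg = SimConfig(
            n_cases_per_subtype=500, n_controls=100, n_snps=50,
            prevalence=0.01, max_pool=2000, seed=1, n_causal_per_subtype=5,
        )
        with pytest.raises(SimulationError, match="max_pool"):
            simulate_cohort(cfg)

    def test_cohort_reproducible(self):
        cfg = SimConfig(n_cases_per_subtype=50, n_controls=120, n_snps=80, seed=33, n_causal_per_subtype=5)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert c1.samples.equals(c2.samples)

    def test_controls_have_no_subtype(self, small_cohort):
        ctl = small_cohort.samples[small_cohort.samples["STATUS"] == "control"]
        assert (ctl["TRUE_SUBTYPE"] == ".").all()
        assert (ctl["CCSC"] == ".").all()


class TestClassifiers:
    def test_identity_confusion_kappa_one(self, rng):
        cfg = SimConfig(seed=0)
        ident = np.hstack([np.eye(3), np.zeros((3, 1))])
        true = rng.choice(cfg.subtypes, 500)
        out = simulate_classifiers(true, {s: ident for s in cfg.systems}, cfg, rng)
        k = cohens_kappa(out["CCSC"], out["TOAST"])
        assert k.kappa == 1.0

    def test_uniform_confusion_kappa_near_zero(self, rng):
        cfg = SimConfig(seed=0, multilabel_system=None)
        uniform = np.full((3, 4), 0.25)
        true = rng.choice(cfg.subtypes, 4000)
        out = simulate_classifiers(true, {s: uniform for s in cfg.systems}, cfg, rng)
        k = cohens_kappa(out["CCSC"], out["TOAST"])
        assert abs(k.kappa) < 3 * k.se

    def test_bad_confusion_row_rejected(self, rng):
        cfg = SimConfig(seed=0)
        bad = np.full((3, 4), 0.25)
        bad[0, 0] = 0.30  # row sums to 1.05
        with pytest.raises(ConfigurationError, match="sum to 1"):
            simulate_classifiers(
                np.array(["CES"]), {s: bad for s in cfg.systems}, cfg, rng
            )

    def test_multilabel_system_emits_secondary(self, rng):
        cfg = SimConfig(seed=0, secondary_label_prob=1.0)
        ident = np.hstack([np.eye(3), np.zeros((3, 1))])
        true = np.array(["SVS"] * 50, dtype=object)
        out = simulate_classifiers(true, {s: ident for s in cfg.systems}, cfg, rng)
        assert all(";" in lab for lab in out["CCSP"])
        assert all(";" not in lab for lab in out["CCSC"])

    def test_high_undetermined_regime_achievable(self, rng):
        cfg = SimConfig(seed=0, multilabel_system=None)
        mat = symmetric_confusion(0.4, 3, undetermined_share=0.65)
        true = rng.choice(cfg.subtypes, 3000)
        out = simulate_classifiers(true, {s: mat for s in cfg.systems}, cfg, rng)
        assert (out["TOAST"] == "undetermined").mean() > 1 / 3


class TestKappaCalibration:
    def test_target_one_gives_identity(self):
        mat = calibrate_confusion(1.0, 3)
        assert np.allclose(mat[:, :3], np.eye(3))
        assert np.allclose(mat[:, 3], 0.0)

    def test_closed_form_kappa_of_construction(self):
        # analytic kappa of the calibrated joint distribution hits 0.50
        mat = calibrate_confusion(0.5, 3, undetermined_share=0.35)
        k = expected_kappa(mat, mat, np.ones(3) / 3)
        assert k == pytest.approx(0.50, abs=0.01)

    @pytest.mark.parametrize("target,lo,hi", [(0.71, 0.66, 0.76), (0.56, 0.51, 0.61)])
    def test_empirical_kappa_matches_target(self, target, lo, hi, rng):
        cfg = SimConfig(seed=0, multilabel_system=None)
        mat = calibrate_confusion(target, 3)
        true = rng.choice(cfg.subtypes, 5000)
        out = simulate_classifiers(true, {s: mat for s in cfg.systems}, cfg, rng)
        k = cohens_kappa(out["CCSC"], out["TOAST"])
        assert lo < k.kappa < hi

    def test_unattainable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_confusion(-0.2, 3)
        with pytest.raises(CalibrationError):
            calibrate_confusion(1.5, 3)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigurationError):
        SimConfig(ld_rho=1.0)
    with pytest.raises(ConfigurationError):
        SimConfig(h2_liability=1.5)
    with pytest.raises(ConfigurationError):
        SimConfig(prevalence=0.0)
    with pytest.raises(ConfigurationError):
        SimConfig(n_snps=50, n_causal_per_subtype=20)  # 3*20 > 50
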