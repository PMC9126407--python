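"""Generator properties: determinism, allele frequencies, LD structure,
heritability control and outcome calibration."""

import numpy as np
import pytest
from scipy import stats

from omicschain.simdata import (
    ConfigError,
    SimConfig,
    make_split,
    make_truth,
    make_two_sample_split,
    simulate_genotypes,
    simulate_omics,
    simulate_outcome,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.3, 0.2)},
            {"ld_decay": 1.0},
            {"ld_decay": -0.1},
            {"n_variants_per_region": 1},
            {"mediation_fraction": 1.5},
            {"prevalence": 0.0},
            {"architectures": ("shared",), "n_regions": 2},
            {"architectures": "weird"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)


class TestGenotypes:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_samples=200, n_variants_per_region=10, n_regions=2, seed=5)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_dosages_in_range_and_positions_increasing(self):
        cfg = SimConfig(n_samples=300, n_variants_per_region=15, n_regions=2, seed=1)
        g = simulate_genotypes(cfg)
        assert g.dosages.min() >= 0 and g.dosages.max() <= 2
        for r in range(2):
            pos = g.variants.loc[g.variants["region"] == r, "pos"].to_numpy()
            assert np.all(np.diff(pos) > 0)

    def test_allele_frequency_conservation(self):
        """Empirical MAF within 3 binomial SDs of the declared target."""
        cfg = SimConfig(n_samples=4000, n_variants_per_region=40, n_regions=1, seed=2)
        g = simulate_genotypes(cfg)
        target = g.variants["maf"].to_numpy()
        emp = g.empirical_eaf()
        sd = np.sqrt(target * (1 - target) / (2 * cfg.n_samples))
        assert np.all(np.abs(emp - target) < 3.5 * sd)

    def test_zero_ld_decay_gives_independence(self):
        cfg = SimConfig(
            n_samples=5000, n_variants_per_region=10, n_regions=1,
            ld_decay=0.0, maf_range=(0.2, 0.5), seed=3,
        )
        g = simulate_genotypes(cfg)
        corr = np.corrcoef(g.dosages, rowvar=False)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_adjacent_r2_matches_latent_gaussian_oracle(self):
        """Mean adjacent-pair dosage r² agrees with an independent
        Monte-Carlo oracle that simulates correlated latent pairs directly."""
        rho, maf_lo, maf_hi = 0.9, 0.2, 0.5
        cfg = SimConfig(
            n_samples=5000, n_variants_per_region=60, n_regions=1,
            ld_decay=rho, maf_range=(maf_lo, maf_hi), seed=4,
        )
        g = simulate_genotypes(cfg)
        D = g.dosages
        r2 = np.array(
            [np.corrcoef(D[:, j], D[:, j + 1])[0, 1] ** 2 for j in range(59)]
        )
        # oracle: 1e5 haplotype pairs per MAF pair, thresholded bivariate normals
        rng = np.random.default_rng(12345)
        n_mc = 100_000
        oracle_vals = []
        for _ in range(40):
            m1, m2 = rng.uniform(maf_lo, maf_hi, 2)
            z1 = rng.standard_normal(2 * n_mc)
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(2 * n_mc)
            a1 = (z1 < stats.norm.ppf(m1)).astype(float)
            a2 = (z2 < stats.norm.ppf(m2)).astype(float)
            d1 = a1[:n_mc] + a1[n_mc:]
            d2 = a2[:n_mc] + a2[n_mc:]
            oracle_vals.append(np.corrcoef(d1, d2)[0, 1] ** 2)
        assert abs(r2.mean() - np.mean(oracle_vals)) < 0.02

    def test_duplicated_column_has_r2_one(self):
        from omicschain.hfdr_ld import ld_r2

        cfg = SimConfig(n_samples=500, n_variants_per_region=5, n_regions=1, seed=6)
        g = simulate_genotypes(cfg)
        g.dosages[:, 1] = g.dosages[:, 0]
        assert ld_r2(g.dosages, 0, 1) == pytest.approx(1.0)


class TestTruthAndOmics:
    def test_architecture_constraints(self, small_cohort):
        cfg, geno, truth, _ = small_cohort
        shared, independent, null = truth.regions
        assert shared.ge_causal == shared.pe_causal
        assert independent.ge_causal != independent.pe_causal
        r2 = np.corrcoef(
            geno.dosages[:, independent.ge_causal],
            geno.dosages[:, independent.pe_causal],
        )[0, 1] ** 2
        assert r2 < cfg.independent_r2_cap
        assert null.ge_causal is None and np.all(null.beta_ge == 0)

    def test_null_regions_are_pure_noise(self):
        """Per-SNP type-I error of a scan on a null region is ~nominal."""
        from omicschain.qtlscan import scan_region

        cfg = SimConfig(
            n_samples=800, n_variants_per_region=1000, n_regions=1,
            architectures="null", ld_decay=0.0, seed=11,
        )
        geno = simulate_genotypes(cfg)
        truth = make_truth(geno, cfg)
        om = simulate_omics(geno, truth, cfg)
        st = scan_region(geno, om.pe[0])
        frac = (st["p"] < 0.05).mean()
        assert 0.025 < frac < 0.08  # binomial tolerance around 0.05

    def test_discordant_sign_pattern_flips_pe(self, small_cohort):
        cfg, geno, truth, om = small_cohort
        rt = truth.regions[0]  # shared + discordant
        g = geno.dosages[:, rt.ge_causal]
        assert np.corrcoef(g, om.ge[0, 0])[0, 1] > 0
        assert np.corrcoef(g, om.pe[0])[0, 1] < 0

    def test_cis_heritability_recovered(self):
        """Variance explained by the causal variant matches the target."""
        r2s = []
        for seed in (13, 14, 15, 16, 17):
            cfg = SimConfig(
                n_samples=2000, n_variants_per_region=10, n_regions=1,
                ge_h2=0.1, age_effect_pe=0.0, sex_effect_pe=0.0, seed=seed,
            )
            geno = simulate_genotypes(cfg)
            truth = make_truth(geno, cfg)
            om = simulate_omics(geno, truth, cfg)
            g = geno.dosages[:, truth.regions[0].ge_causal]
            r2s.append(np.corrcoef(g, om.ge[0, 0])[0, 1] ** 2)
        # closed form: variance explained = beta^2 var(G) / total = h2
        assert abs(np.mean(r2s) - 0.1) < 0.02

    def test_sex_interaction_scales_male_effects(self):
        cfg = SimConfig(
            n_samples=6000, n_variants_per_region=6, n_regions=1,
            ge_h2=0.2, sex_interaction=2.0, seed=14,
        )
        geno = simulate_genotypes(cfg)
        truth = make_truth(geno, cfg)
        om = simulate_omics(geno, truth, cfg)
        g = geno.dosages[:, truth.regions[0].ge_causal]
        sex = om.sex
        slope_f = np.polyfit(g[sex == 0], om.ge[0, 0][sex == 0], 1)[0]
        slope_m = np.polyfit(g[sex == 1], om.ge[0, 0][sex == 1], 1)[0]
        assert slope_m / slope_f == pytest.approx(2.0, abs=0.35)


class TestOutcome:
    def test_prevalence_calibrated(self):
        cfg = SimConfig(
            n_samples=20000, n_variants_per_region=6, n_regions=1,
            prevalence=0.3, theta_pe=0.5, seed=15,
        )
        geno = simulate_genotypes(cfg)
        truth = make_truth(geno, cfg)
        om = simulate_omics(geno, truth, cfg)
        y = simulate_outcome(om.pe, om.ge, truth, cfg)
        assert abs(y.mean() - 0.3) < 0.02

    def test_logistic_refit_recovers_theta_pe(self):
        """Refit oracle: logistic regression recovers the PE log-odds."""
        import statsmodels.api as sm

        cfg = SimConfig(
            n_samples=20000, n_variants_per_region=6, n_regions=1,
            prevalence=0.3, theta_pe=0.5, mediation_fraction=1.0, seed=16,
        )
        geno = simulate_genotypes(cfg)
        truth = make_truth(geno, cfg)
        om = simulate_omics(geno, truth, cfg)
        y = simulate_outcome(om.pe, om.ge, truth, cfg)
        X = sm.add_constant(om.pe[0])
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert abs(fit.params[1] - 0.5) < 0.05

    def test_full_mediation_means_no_direct_effect(self):
        cfg = SimConfig(mediation_fraction=1.0, pathway_coupling=0.5)
        # the direct genetic term vanishes; total equals indirect
        geno = simulate_genotypes(
            SimConfig(n_samples=100, n_variants_per_region=4, n_regions=1, seed=1)
        )
        truth = make_truth(geno, SimConfig(
            n_samples=100, n_variants_per_region=4, n_regions=1,
            mediation_fraction=1.0, pathway_coupling=0.5, seed=1,
        ))
        assert truth.theta_ge_direct == 0.0
        assert truth.true_total_effect(0) == truth.true_indirect_effect(0)


class TestSplits:
    def test_even_split_disjoint(self):
        a, b = make_two_sample_split(2000, seed=3)
        assert len(a) == len(b) == 1000
        assert len(np.intersect1d(a, b)) == 0

    def test_split_deterministic(self):
        assert all(
            np.array_equal(x, y)
            for x, y in zip(make_split(100, [30, 30], seed=9), make_split(100, [30, 30], seed=9))
        )

    def test_oversized_split_rejected(self):
        with pytest.raises(ConfigError):
            make_two_sample_split(100, 60, 60)
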