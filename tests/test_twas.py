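"""Predicted-expression association: identities, closed forms and the
summary/individual-level equivalence."""

import numpy as np
import pandas as pd
import pytest

from omicschain.simdata import SimConfig, make_truth, simulate_genotypes, simulate_omics
from omicschain.twas import (
    WeightModel,
    hierarchical_fdr_tissues,
    predict_expression,
    results_frame,
    summary_twas,
)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(
        n_samples=1200, n_variants_per_region=20, n_regions=1,
        ld_decay=0.7, maf_range=(0.15, 0.5), ge_h2=0.15, pe_h2=0.15,
        age_effect_pe=0.0, sex_effect_pe=0.0, seed=31,
    )
    geno = simulate_genotypes(cfg)
    truth = make_truth(geno, cfg)
    om = simulate_omics(geno, truth, cfg)
    return cfg, geno, truth, om


def _model(geno, idx, weights, gene="g", tissue="t0"):
    return WeightModel(
        gene, tissue,
        pd.DataFrame(
            {
                "variant_id": geno.variants["variant_id"].iloc[idx].to_numpy(),
                "effect_allele": "A",
                "weight": weights,
            }
        ),
    )


class TestPredictExpression:
    def test_single_unit_weight_is_identity(self, cohort):
        _, geno, _, _ = cohort
        gge = predict_expression(geno, _model(geno, [4], [1.0]))
        np.testing.assert_allclose(gge, geno.dosages[:, 4])

    def test_negative_weight_anticorrelates(self, cohort):
        _, geno, _, _ = cohort
        gge = predict_expression(geno, _model(geno, [4], [-0.5]))
        assert np.corrcoef(gge, geno.dosages[:, 4])[0, 1] == pytest.approx(-1.0)

    def test_true_weight_model_tracks_genetic_value(self, cohort):
        _, geno, truth, _ = cohort
        rt = truth.regions[0]
        model = _model(geno, [rt.ge_causal], [rt.beta_ge[0]])
        gge = predict_expression(geno, model)
        true_gv = rt.beta_ge[0] * geno.dosages[:, rt.ge_causal]
        assert np.corrcoef(gge, true_gv)[0, 1] > 0.99

    def test_no_usable_variant_rejected(self, cohort):
        _, geno, _, _ = cohort
        model = WeightModel(
            "g", "t0",
            pd.DataFrame(
                {"variant_id": ["nope"], "effect_allele": ["A"], "weight": [1.0]}
            ),
        )
        with pytest.raises(ValueError):
            predict_expression(geno, model)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightModel(
                "g", "t0",
                pd.DataFrame(
                    {"variant_id": ["v"], "effect_allele": ["A"], "weight": [0.0]}
                ),
            )


class TestSummaryTwas:
    def test_single_variant_z_equals_variant_z(self, cohort):
        """One-variant model with unit weight: z_gene == beta/se of that
        variant (sigma_l == sigma_g)."""
        from omicschain.qtlscan import scan_region

        _, geno, _, om = cohort
        stats = scan_region(geno, om.pe[0])
        model = _model(geno, [7], [1.0])
        res = summary_twas(stats, model, geno)
        row = stats.loc[stats["variant_id"] == geno.variants["variant_id"][7]].iloc[0]
        assert res.z == pytest.approx(row["beta"] / row["se"], rel=1e-12)
        assert res.n_variants_used == 1

    def test_duplicated_variant_no_double_counting(self, cohort):
        """Two perfectly correlated variants with equal weights give the
        same z as the single-variant model (rank-1 LD)."""
        from omicschain.qtlscan import scan_region
        from omicschain.simdata import GenotypeMatrix

        _, geno, _, om = cohort
        dup = GenotypeMatrix(
            np.column_stack([geno.dosages[:, 7], geno.dosages[:, 7]]),
            pd.DataFrame(
                {
                    "variant_id": ["a", "b"], "chrom": "chr1", "pos": [1, 2],
                    "region": 0, "effect_allele": "A", "other_allele": "G",
                    "maf": 0.3,
                }
            ),
        )
        stats = scan_region(dup, om.pe[0])
        single = summary_twas(stats, _model(dup, [0], [1.0]), dup)
        double = summary_twas(stats, _model(dup, [0, 1], [0.5, 0.5]), dup)
        assert double.z == pytest.approx(single.z, rel=1e-9)

    def test_allele_flip_invariance(self, cohort):
        """Re-orienting a variant's stats (negate beta, complement EAF)
        leaves z_gene unchanged."""
        from omicschain.qtlscan import scan_region

        _, geno, _, om = cohort
        stats = scan_region(geno, om.pe[0])
        model = _model(geno, [3, 7], [0.4, -0.2])
        base = summary_twas(stats, model, geno)
        flipped = stats.copy()
        vid = geno.variants["variant_id"][3]
        sel = flipped["variant_id"] == vid
        flipped.loc[sel, "beta"] *= -1
        flipped.loc[sel, "eaf"] = 1 - flipped.loc[sel, "eaf"]
        flipped.loc[sel, "effect_allele"] = "G"
        res = summary_twas(flipped, model, geno)
        assert res.z == pytest.approx(base.z, rel=1e-12)

    def test_matches_individual_level_regression(self):
        """Summary-level z tracks the individual-level oracle closely."""
        from omicschain.validation import twas_equivalence_experiment

        out = twas_equivalence_experiment(seed=3, n_genes=10, n=2000)
        assert out["max_abs_delta_z"] < 0.1

    def test_p_consistent_with_z(self, cohort):
        from scipy import stats as sps

        from omicschain.qtlscan import scan_region

        _, geno, _, om = cohort
        stats = scan_region(geno, om.pe[0])
        res = summary_twas(stats, _model(geno, [2, 5], [0.3, 0.1]), geno)
        assert res.p == pytest.approx(2 * sps.norm.sf(abs(res.z)), rel=1e-9)


class TestHierarchicalTissues:
    def test_single_strong_pair_significant(self):
        from omicschain.twas import TwasResult

        results = [TwasResult("g1", "t0", 8.0, 1.0, 1e-10, 1)]
        sig, hres = hierarchical_fdr_tissues(results)
        assert len(sig) == 1 and hres.k == 1

    def test_threshold_scales_with_selected_families(self):
        from omicschain.twas import TwasResult

        results = [
            TwasResult("g1", "t0", 9.0, 1.0, 1e-15, 1),
            TwasResult("g1", "t1", 2.4, 1.0, 0.016, 1),
            TwasResult("g2", "t0", 0.1, 0.0, 0.9, 1),
        ]
        sig, hres = hierarchical_fdr_tissues(results, alpha1=0.05)
        # one of two families selected -> within-family threshold 0.025
        assert hres.k == 1 and hres.alpha2 == pytest.approx(0.025)
        pairs = {(r["gene_id"], r["tissue"]) for _, r in sig.iterrows()}
        assert ("g1", "t0") in pairs and ("g1", "t1") in pairs

    def test_null_families_controlled(self):
        """Uniform-null p over 64 x 35 gene-tissue grid: families with a
        false discovery stay rare across replicates."""
        from omicschain.twas import TwasResult

        rng = np.random.default_rng(6)
        false_family_props = []
        for _ in range(30):
            results = [
                TwasResult(f"g{i}", f"t{j}", 0.0, 0.0, float(p), 1)
                for i in range(64)
                for j, p in enumerate(rng.uniform(size=35))
            ]
            _, hres = hierarchical_fdr_tissues(results, alpha1=0.05)
            false_family_props.append(hres.k / 64)
        assert np.mean(false_family_props) <= 0.05
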