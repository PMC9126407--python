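"""Multiplicity correction and LD pruning against independent references."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from omicschain.hfdr_ld import (
    bh_adjust,
    hierarchical_fdr,
    ld_r2,
    priority_prune,
    simes_p,
)
from omicschain.simdata import SimConfig, simulate_genotypes

pvec = st.lists(
    st.floats(min_value=1e-12, max_value=1.0, allow_nan=False), min_size=1, max_size=8
)


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_identity(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_empty_input_empty_output(self):
        assert bh_adjust([]).size == 0

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    @given(pvec)
    def test_matches_statsmodels(self, p):
        """Property sweep: equality with the statsmodels step-up on all
        short vectors."""
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    @given(pvec)
    def test_monotone_in_rank_and_bounded(self, p):
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSimes:
    def test_min_of_bh_example(self):
        assert simes_p([0.01, 0.02, 0.03]) == pytest.approx(0.03)

    def test_enumeration_example(self):
        # min(m*p_(i)/i) over {2*1e-10/1, 2*0.9/2} = 2e-10
        assert simes_p([1e-10, 0.9]) == pytest.approx(2e-10)

    def test_single_variant(self):
        assert simes_p([0.2]) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            simes_p([])


class TestHierarchicalFDR:
    def test_single_strong_region_among_nulls(self):
        """One overwhelming region among 91 uniform nulls: k=1 and the
        second-level threshold is alpha/92."""
        rng = np.random.default_rng(0)
        regions = {f"r{i}": rng.uniform(0.2, 1.0, 50) for i in range(91)}
        strong = np.full(50, 0.9)
        strong[7] = 1e-300
        regions["hit"] = strong
        res = hierarchical_fdr(regions, alpha1=0.05)
        assert res.selected == ["hit"]
        assert res.k == 1
        assert res.alpha2 == pytest.approx(0.05 / 92)
        assert list(res.significant["hit"]) == [7]
        assert all(len(res.significant[f"r{i}"]) == 0 for i in range(91))

    def test_null_regions_rarely_selected(self):
        rng = np.random.default_rng(1)
        n_sel = 0
        for _ in range(20):
            regions = {f"r{i}": rng.uniform(size=200) for i in range(92)}
            n_sel += hierarchical_fdr(regions).k
        assert n_sel <= 20  # mostly zero selections under the global null

    def test_m1_degenerates_to_plain_bh(self):
        p = np.array([0.001, 0.2, 0.04, 0.5])
        res = hierarchical_fdr({"only": p}, alpha1=0.05)
        adj = bh_adjust(p)
        if adj.min() <= 0.05:
            assert res.k == 1 and res.alpha2 == pytest.approx(0.05)
            np.testing.assert_array_equal(
                res.significant["only"], np.flatnonzero(adj <= 0.05)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_fdr({})


class TestLDr2:
    def test_identical_columns(self):
        d = np.random.default_rng(2).integers(0, 3, size=(100, 2)).astype(float)
        d[:, 1] = d[:, 0]
        assert ld_r2(d, 0, 1) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, size=(100_000, 2)).astype(float)
        assert ld_r2(d, 0, 1) < 1e-3

    def test_ar1_matches_latent_oracle(self):
        """Adjacent-pair r² under ld_decay=0.9 matches an independent
        latent-Gaussian Monte-Carlo within 0.02 (shared oracle logic)."""
        from scipy import stats as sps

        rho = 0.9
        cfg = SimConfig(
            n_samples=20000, n_variants_per_region=2, n_regions=1,
            ld_decay=rho, maf_range=(0.3, 0.3001), seed=8,
        )
        g = simulate_genotypes(cfg)
        observed = ld_r2(g, 0, 1)
        rng = np.random.default_rng(77)
        n_mc = 100_000
        z1 = rng.standard_normal(2 * n_mc)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(2 * n_mc)
        thr = sps.norm.ppf(0.3)
        a1, a2 = (z1 < thr).astype(float), (z2 < thr).astype(float)
        oracle = np.corrcoef(a1[:n_mc] + a1[n_mc:], a2[:n_mc] + a2[n_mc:])[0, 1] ** 2
        assert observed == pytest.approx(oracle, abs=0.02)

    def test_zero_variance_rejected(self):
        d = np.zeros((50, 2))
        d[:, 1] = np.arange(50.0)
        with pytest.raises(ValueError):
            ld_r2(d, 0, 1)


class TestPriorityPrune:
    def _geno(self, seed=30, m=10, rho=0.9):
        cfg = SimConfig(
            n_samples=2000, n_variants_per_region=m, n_regions=1,
            ld_decay=rho, maf_range=(0.2, 0.5), seed=seed,
        )
        return simulate_genotypes(cfg)

    def test_duplicate_keeps_best_p(self, stats_factory):
        g = self._geno(m=2, rho=0.0)
        g.dosages[:, 1] = g.dosages[:, 0]
        st = stats_factory([1e-9, 1e-8], ids=list(g.variants["variant_id"]))
        kept = priority_prune(st, g)
        assert list(kept["variant_id"]) == [g.variants["variant_id"][0]]

    def test_all_independent_all_kept(self, stats_factory):
        g = self._geno(m=6, rho=0.0)
        st = stats_factory(
            np.linspace(0.001, 0.01, 6), ids=list(g.variants["variant_id"])
        )
        kept = priority_prune(st, g)
        assert len(kept) == 6

    def test_matches_bruteforce_greedy_oracle(self, stats_factory):
        """AR(1) block: output equals an explicit greedy walk."""
        g = self._geno(m=10, rho=0.9)
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-10, 1e-3, 10)
        st = stats_factory(p, ids=list(g.variants["variant_id"]))
        kept = priority_prune(st, g, r2_max=0.1)
        # oracle: independent greedy implementation
        order = np.argsort(p, kind="mergesort")
        chosen = []
        for j in order:
            if all(
                np.corrcoef(g.dosages[:, j], g.dosages[:, k])[0, 1] ** 2 < 0.1
                for k in chosen
            ):
                chosen.append(j)
        expected = [g.variants["variant_id"][j] for j in chosen]
        assert list(kept["variant_id"]) == expected

    def test_output_pairwise_below_cap(self, stats_factory):
        g = self._geno(m=12, rho=0.95)
        p = np.random.default_rng(10).uniform(1e-8, 1e-2, 12)
        st = stats_factory(p, ids=list(g.variants["variant_id"]))
        kept = priority_prune(st, g, r2_max=0.1)
        ids = list(kept["variant_id"])
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                assert ld_r2(g, g.index_of(ids[a]), g.index_of(ids[b])) < 0.1
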