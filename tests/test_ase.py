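"""ASE: site filters, binomial LRT vs direct-likelihood oracle, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rnaqtl import ase, duplicates, eqtl, normalize as nm
from rnaqtl.dataio import AllelicCountTable
from rnaqtl.synthetic_data import (
    SimConfig,
    simulate_all,
    simulate_allelic_counts,
    simulate_genotypes,
)

from conftest import make_genotype_table


def counts_table(rows):
    """rows: list of (variant_id, sample_id, ref, alt[, mapp, excl])."""
    recs = []
    for r in rows:
        v, s, ref, alt = r[:4]
        mapp = r[4] if len(r) > 4 else 1.0
        excl = r[5] if len(r) > 5 else False
        recs.append(
            dict(variant_id=v, sample_id=s, chrom="1", pos=100,
                 ref_count=ref, alt_count=alt,
                 in_excluded_region=excl, mappability=mapp)
        )
    return AllelicCountTable(data=pd.DataFrame(recs))


def het_gt(variants, samples, gq=99.0):
    calls = np.ones((len(variants), len(samples)), dtype=np.int8)
    gt = make_genotype_table(calls, maf=np.full(len(variants), 0.3),
                             gq=gq, samples=list(samples))
    gt.variants.index = pd.Index(variants, name="variant_id")
    gt.calls.index = gt.variants.index
    gt.gq.index = gt.variants.index
    gt.dosage.index = gt.variants.index
    return gt


class TestFilterSites:
    def test_minimum_het_samples(self):
        samples = [f"s{j}" for j in range(5)]
        gt = het_gt(["v1", "v2"], samples)
        rows = [("v1", s, 50, 50) for s in samples[:4]]  # only 4 samples
        rows += [("v2", s, 50, 50) for s in samples]     # 5 samples
        out = ase.filter_sites(counts_table(rows), gt)
        assert list(out["variant_id"]) == ["v2"]

    def test_reads_per_allele_threshold(self):
        samples = [f"s{j}" for j in range(5)]
        gt = het_gt(["v1"], samples)
        rows = [("v1", s, 200, 1) for s in samples]  # pooled alt = 5 < 10
        out = ase.filter_sites(counts_table(rows), gt)
        assert len(out) == 0

    def test_two_percent_boundary_inclusive(self):
        samples = [f"s{j}" for j in range(5)]
        gt = het_gt(["v1", "v2"], samples)
        rows = [("v1", s, 196, 4) for s in samples]   # alt frac exactly 2%
        rows += [("v2", s, 197, 3) for s in samples]  # 1.5% -> fails
        out = ase.filter_sites(counts_table(rows), gt)
        assert list(out["variant_id"]) == ["v1"]
        assert out["pooled_alt"].iloc[0] == 20

    def test_gq_strictly_above_30(self):
        samples = [f"s{j}" for j in range(5)]
        gt = het_gt(["v1"], samples, gq=30.0)  # exactly 30 fails "above 30"
        rows = [("v1", s, 50, 50) for s in samples]
        out = ase.filter_sites(counts_table(rows), gt)
        assert len(out) == 0

    def test_mappability_and_exclusion(self):
        samples = [f"s{j}" for j in range(5)]
        gt = het_gt(["v1", "v2", "v3"], samples)
        rows = [("v1", s, 50, 50, 0.5, False) for s in samples]
        rows += [("v2", s, 50, 50, 1.0, True) for s in samples]
        rows += [("v3", s, 50, 50, 1.0, False) for s in samples]
        out = ase.filter_sites(counts_table(rows), gt)
        assert list(out["variant_id"]) == ["v3"]

    def test_non_het_rows_not_counted(self):
        samples = [f"s{j}" for j in range(6)]
        gt = het_gt(["v1"], samples)
        gt.calls.iloc[0, 0] = 0  # one sample actually hom_ref
        rows = [("v1", s, 50, 50) for s in samples]
        out = ase.filter_sites(counts_table(rows), gt, min_het_samples=6)
        assert len(out) == 0

    def test_per_sample_semantics(self):
        samples = [f"s{j}" for j in range(6)]
        gt = het_gt(["v1"], samples)
        rows = [("v1", s, 50, 9) for s in samples[:5]]  # alt < 10 per sample
        rows += [("v1", samples[5], 50, 50)]
        pooled = ase.filter_sites(counts_table(rows), gt)
        per_sample = ase.filter_sites(counts_table(rows), gt, per_sample=True)
        assert len(pooled) == 1       # pooled alt = 95 passes
        assert len(per_sample) == 0   # only 1 qualifying sample


class TestBinomialLRT:
    def test_balanced_null(self):
        p_hat, lrt, p = ase.binomial_lrt([50], [50])
        assert p_hat[0] == 0.5 and lrt[0] == 0.0 and p[0] == 1.0

    def test_known_value_30_of_100(self):
        # direct formula: 2(30 ln .3 + 70 ln .7 - 100 ln .5)
        p_hat, lrt, p = ase.binomial_lrt([70], [30])
        expected = 2 * (30 * np.log(0.3) + 70 * np.log(0.7) - 100 * np.log(0.5))
        assert lrt[0] == pytest.approx(expected, abs=1e-12)
        assert lrt[0] == pytest.approx(16.4566, abs=1e-4)

    def test_pooling_equivalence_exact(self):
        # any partition of the same pooled counts yields the identical lrt:
        # run two partitions through the site filter and the test
        samples = [f"s{j}" for j in range(6)]
        gt = het_gt(["v1"], samples)
        split = [("v1", samples[j], r, a) for j, (r, a) in
                 enumerate([(7, 3), (6, 4), (10, 5), (11, 2), (9, 6), (200, 100)])]
        merged = [("v1", samples[j], r, a) for j, (r, a) in
                  enumerate([(243, 120), (0, 0), (0, 0), (0, 0), (0, 0), (0, 0)])]
        r1 = ase.run_ase(ase.filter_sites(counts_table(split), gt, min_het_samples=1))
        r2 = ase.run_ase(ase.filter_sites(counts_table(merged), gt, min_het_samples=1))
        assert r1.sites["lrt"].iloc[0] == r2.sites["lrt"].iloc[0]
        assert r1.sites["p_hat"].iloc[0] == r2.sites["p_hat"].iloc[0]

    def test_matches_independent_direct_likelihood(self):
        # oracle via scipy's binomial log-pmf (combinatorial terms cancel in
        # the ratio)
        rng = np.random.default_rng(23)
        tot = rng.integers(1, 2000, size=1000)
        alt = rng.binomial(tot, rng.uniform(0.0, 1.0, size=1000))
        ref = tot - alt
        p_hat, lrt, _ = ase.binomial_lrt(ref, alt)
        ll_hat = stats.binom.logpmf(alt, tot, np.clip(p_hat, 1e-300, 1.0))
        ll_null = stats.binom.logpmf(alt, tot, 0.5)
        expected = 2 * (ll_hat - ll_null)
        np.testing.assert_allclose(lrt, expected, atol=1e-9)

    def test_extremes_zero_and_all_alt(self):
        p_hat, lrt, p = ase.binomial_lrt([10, 0], [0, 10])
        assert p_hat.tolist() == [0.0, 1.0]
        expected = 2 * 10 * np.log(2.0)
        np.testing.assert_allclose(lrt, expected, atol=1e-12)

    def test_zero_total_error(self):
        with pytest.raises(ValueError, match="positive"):
            ase.binomial_lrt([0], [0])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_lrt_nonnegative_zero_iff_balanced(self, ref, alt):
        if ref + alt == 0:
            return
        _, lrt, _ = ase.binomial_lrt([ref], [alt])
        assert lrt[0] >= 0.0
        if ref == alt:
            assert lrt[0] == 0.0
        else:
            assert lrt[0] > 0.0


class TestBHFdr:
    def test_single_p(self):
        assert ase.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            ase.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_allclose(ase.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ase.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            ase.bh_fdr([0.5, 1.5])

    def test_matches_brute_force_and_statsmodels(self):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                val = min(prev, p[i] * m / rank_from_top)
                adj[i] = val
                prev = val
            return adj

        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(29)
        for _ in range(10):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            mine = ase.bh_fdr(p)
            np.testing.assert_allclose(mine, oracle(p), atol=1e-12)
            np.testing.assert_allclose(
                mine, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )


class TestDirectionConcordance:
    def _fake_results(self, meta_z, p_hat):
        sites = pd.DataFrame(
            {
                "variant_id": ["v1"],
                "n_het_samples": [10],
                "pooled_ref": [100],
                "pooled_alt": [150],
                "p_hat": [p_hat],
                "lrt": [10.0],
                "p_value": [1e-3],
                "fdr": [1e-3],
                "direction": [ase.DIR_ALT if p_hat > 0.5 else ase.DIR_REF],
            }
        )
        assoc = pd.DataFrame(
            {"variant_id": ["v1"], "gene_id": ["g1"], "distance": [0],
             "meta_z": [meta_z], "p_value": [1e-4]}
        )
        genes = pd.DataFrame({"gene_id": ["g1"], "fdr": [0.01]})
        return ase.ASEResult(sites=sites), assoc, genes

    def test_single_matching_pair(self):
        res, assoc, genes = self._fake_results(meta_z=3.0, p_hat=0.6)
        out = ase.direction_concordance(res, assoc, genes)
        assert out["concordance"] == 1.0

    def test_single_discordant_pair(self):
        res, assoc, genes = self._fake_results(meta_z=-3.0, p_hat=0.6)
        out = ase.direction_concordance(res, assoc, genes)
        assert out["concordance"] == 0.0

    def test_empty_intersection_error(self):
        res, assoc, genes = self._fake_results(meta_z=3.0, p_hat=0.6)
        genes["fdr"] = 1.0  # no significant eQTL genes
        with pytest.raises(ValueError, match="no shared"):
            ase.direction_concordance(res, assoc, genes)


class TestClassDirectionSummary:
    def _result_from_ratios(self, ratios, rng):
        n = len(ratios)
        tot = rng.poisson(800, size=n) + 50
        alt = rng.binomial(tot, ratios)
        sites = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(n)],
             "n_het_samples": 10, "pooled_ref": tot - alt, "pooled_alt": alt}
        )
        return ase.run_ase(sites)

    def test_shifted_category_detected(self):
        rng = np.random.default_rng(31)
        ratios = np.array([0.3] * 100 + [0.5] * 100)
        res = self._result_from_ratios(ratios, rng)
        labels = pd.Series(
            ["nonsense"] * 100 + ["other"] * 100,
            index=[f"v{i}" for i in range(200)],
        )
        out = ase.class_direction_summary(res, labels).set_index("category")
        assert out.loc["nonsense", "rank_sum_p"] < 0.01
        assert out.loc["nonsense", "mean_p_hat"] < out.loc["other", "mean_p_hat"]

    def test_single_category_no_comparison(self):
        rng = np.random.default_rng(32)
        res = self._result_from_ratios(np.full(10, 0.5), rng)
        labels = pd.Series(["x"] * 10, index=[f"v{i}" for i in range(10)])
        out = ase.class_direction_summary(res, labels)
        assert np.isnan(out["rank_sum_p"].iloc[0])

    def test_null_categories_uniformish_p(self):
        rng = np.random.default_rng(33)
        ps = []
        for _ in range(20):
            res = self._result_from_ratios(np.full(60, 0.5), rng)
            labels = pd.Series(["a"] * 30 + ["b"] * 30,
                               index=[f"v{i}" for i in range(60)])
            out = ase.class_direction_summary(res, labels).set_index("category")
            ps.append(out.loc["a", "rank_sum_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_joint_simulation_ase_eqtl_direction_agree():
    """Planted imbalance at eQTL variants drives concordant directions."""
    cfg = SimConfig(
        n_samples={"EUR": 80, "AFR": 40}, n_studies=2, n_genes=80, n_variants=200,
        depth=80, eqtl_frac=0.3, eqtl_beta=1.5, ase_frac=0.0,
        dup_pairs=0, contaminated=0, imputation_dr2=0.95, seed=37,
    )
    g = simulate_genotypes(cfg)
    from rnaqtl.synthetic_data import simulate_expression

    e = simulate_expression(cfg, g)
    # plant ASE at the eQTL variants with matching direction (alt up)
    a = simulate_allelic_counts(cfg, g)
    d = a.counts.data
    eff_variants = set(e.eqtl_effects["variant_id"])
    rng = np.random.default_rng(0)
    mask = d["variant_id"].isin(eff_variants)
    tot = (d.loc[mask, "ref_count"] + d.loc[mask, "alt_count"]).to_numpy()
    alt = rng.binomial(tot, 0.65)
    d.loc[mask, "alt_count"] = alt
    d.loc[mask, "ref_count"] = tot - alt

    sites = ase.filter_sites(a.counts, g.genotypes)
    ares = ase.run_ase(sites)
    gpcs = duplicates.genotype_pca(g.genotypes, n_components=2)
    cov = gpcs.copy()
    cov["lr"] = np.log10(e.expression.total_mapped_reads.reindex(gpcs.index) + 1)
    resid, _ = nm.NormalizationRecipe(n_expression_pcs=5).run(
        e.expression, covariates=cov
    )
    pairs = eqtl.build_cis_pairs(g.genotypes, resid)
    eres = eqtl.permutation_fdr(pairs, g.genotypes, resid, g.sheet,
                                n_perm=5, seed=2, min_n=20)
    out = ase.direction_concordance(ares, eres.associations, eres.genes)
    assert out["n_shared_pairs"] >= 5
    assert out["concordance"] >= 0.8
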