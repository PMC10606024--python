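"""Genomic-inflation calibration, q-values, and the three genome scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import seapop as sp

from conftest import hwe_genotypes, make_genotypes


class TestGenomicInflationFactor:
    def test_calibrated_null_lambda_one(self):
        rng = np.random.default_rng(0)
        stats = rng.chisquare(1, size=100_000)
        lam, _, _ = sp.genomic_inflation_factor(stats, df=1)
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_scaled_stats_lambda_two_and_reuniform(self):
        rng = np.random.default_rng(1)
        stats = 2.0 * rng.chisquare(1, size=50_000)
        lam, adj, p = sp.genomic_inflation_factor(stats, df=1)
        assert lam == pytest.approx(2.0, abs=0.05)
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_chi2_df1_median_constant(self):
        assert sps.chi2.median(1) == pytest.approx(0.4549, abs=1e-4)

    def test_negative_stats_rejected(self):
        with pytest.raises(sp.DataError):
            sp.genomic_inflation_factor(np.array([-1.0, 2.0]), df=1)


class TestQvalues:
    def test_bh_hand_computed_case(self):
        q = sp.qvalues(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        q = sp.qvalues(np.ones(10), method="bh")
        np.testing.assert_allclose(q, 1.0)

    def test_monotone_in_p_ordering(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        for method in ("bh", "storey"):
            q = sp.qvalues(p, method=method)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_pi0_near_one_under_null(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=10_000)
        q_storey = sp.qvalues(p, method="storey")
        q_bh = sp.qvalues(p, method="bh")
        ratio = np.median(q_storey[q_bh > 0] / q_bh[q_bh > 0])
        assert ratio == pytest.approx(1.0, abs=0.1)


@pytest.fixture(scope="module")
def power_scenario():
    """Two basins (one dominant structure axis), clinal selection on the
    secondary gradient, n=200, 10k loci, 100 planted."""
    cfg = sp.SimConfig(n_pops=10, n_per_pop=20, n_loci=10_000, frac_adaptive=0.01,
                       frac_duplicated=0, frac_cnv=0, fst_within_group=0.0,
                       divergent_pop=None, adaptive_predictors=("FE",), seed=42)
    g, samples, truth = sp.simulate_metapopulation(cfg)
    g_imp = sp.impute_most_common(g)
    summary = sp.summarize_env(sp.simulate_environment(samples, cfg, n_years=5))
    scores, _, _, n_ret = sp.env_pca(summary)
    X = scores.iloc[:, :max(n_ret, 2)].loc[
        samples["population"].to_numpy()].reset_index(drop=True)
    return cfg, g_imp, samples, truth, X, summary


@pytest.fixture(scope="module")
def confounded_null():
    """Ten differentiated populations, environment collinear with
    structure, no true associations."""
    cfg = sp.SimConfig(n_pops=10, n_per_pop=20, n_loci=5000, frac_adaptive=0,
                       frac_duplicated=0, frac_cnv=0, divergent_pop=None, seed=9)
    g, samples, truth = sp.simulate_metapopulation(cfg)
    g_imp = sp.impute_most_common(g)
    summary = sp.summarize_env(sp.simulate_environment(samples, cfg, n_years=5))
    scores, _, _, n_ret = sp.env_pca(summary)
    X = scores.iloc[:, :max(n_ret, 2)].loc[
        samples["population"].to_numpy()].reset_index(drop=True)
    return cfg, g_imp, samples, X


class TestLfmmRidgeScan:
    def test_k_zero_reduces_to_ordinary_regression(self, confounded_null):
        import statsmodels.api as sm

        _, g_imp, _, X = confounded_null
        res, _ = sp.lfmm_ridge_scan(g_imp, X.iloc[:, :2], k=0)
        sub = res[res["predictor"] == X.columns[0]].head(50)
        Xc = X.iloc[:, :2].to_numpy()
        for _, row in sub.iterrows():
            j = int(row["locus"])
            y = g_imp.calls[:, j].astype(float)
            if y.std() == 0:
                continue
            fit = sm.OLS(y, sm.add_constant(Xc)).fit()
            assert row["raw_p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_confounded_null_calibration_at_correct_k(self, confounded_null):
        cfg, g_imp, _, X = confounded_null
        k_true = cfg.n_pops - 1           # ten drifted demes span 9 axes
        res, info = sp.lfmm_ridge_scan(g_imp, X, k=k_true, cfg=sp.GeaConfig(seed=2))
        for lam in info["gif"].values():
            assert 0.8 <= lam <= 1.3
        false_frac = res.groupby("locus")["candidate"].any().mean()
        assert false_frac <= 0.07

    def test_no_latent_factors_inflates_under_confounding(self, confounded_null):
        _, g_imp, _, X = confounded_null
        _, info0 = sp.lfmm_ridge_scan(g_imp, X, k=0, cfg=sp.GeaConfig(seed=2))
        assert info0["gif"][X.columns[0]] > 1.3

    def test_power_on_planted_clinal_loci(self, power_scenario):
        _, g_imp, _, truth, X, _ = power_scenario
        res, _ = sp.lfmm_ridge_scan(g_imp, X, k=1, cfg=sp.GeaConfig(seed=1))
        cand = set(res.loc[res["candidate"], "locus"])
        planted = set(truth.class_indices("adaptive"))
        assert len(cand & planted) / len(planted) >= 0.8

    def test_invalid_k_rejected(self, confounded_null):
        _, g_imp, _, X = confounded_null
        with pytest.raises(sp.DataError):
            sp.lfmm_ridge_scan(g_imp, X, k=g_imp.n_samples)


class TestRdaScan:
    def test_power_and_predictor_assignment(self, power_scenario):
        _, g_imp, _, truth, X, summary = power_scenario
        res, info = sp.rda_scan(g_imp, X, cfg=sp.GeaConfig(seed=1))
        cand = set(res.loc[res["candidate"], "locus"])
        planted = set(truth.class_indices("adaptive"))
        assert len(cand & planted) / len(planted) >= 0.8

    def test_predictor_assignment_names_true_driver(self, power_scenario):
        _, g_imp, samples, truth, _, summary = power_scenario
        raw = summary[["SST_OM", "FE_OM"]].loc[
            samples["population"].to_numpy()].reset_index(drop=True)
        res, _ = sp.rda_scan(g_imp, raw, cfg=sp.GeaConfig(seed=1))
        planted = set(truth.class_indices("adaptive"))
        hits = res[res["candidate"] & res["locus"].isin(planted)]
        if len(hits):
            frac_fe = (hits["predictor"] == "FE_OM").mean()
            assert frac_fe >= 0.8          # planted driver is the FE gradient

    def test_conditioning_on_structure_controls_null(self, confounded_null):
        cfg, g_imp, samples, X = confounded_null
        xy = sp.geo_to_cartesian(samples.drop_duplicates("population"))
        from seapop.spatial import euclidean_distance_matrix

        mems = sp.dbmem(euclidean_distance_matrix(xy))
        sites = list(samples["population"].drop_duplicates())
        Z = mems.vectors.set_index(pd.Index(sites)).loc[
            samples["population"].to_numpy()].reset_index(drop=True)
        res, info = sp.rda_scan(g_imp, X, cfg=sp.GeaConfig(seed=2), condition_on=Z)
        if info["k_used"] > 0:
            assert 0.8 <= info["gif"] <= 1.3
            assert res["candidate"].mean() <= 0.07

    def test_conditioning_on_causal_predictor_removes_signal(self, power_scenario):
        _, g_imp, _, truth, X, summary = power_scenario
        # partial out the whole predictor set, keep it as response predictors:
        # planted loci must vanish
        res, info = sp.rda_scan(g_imp, X, cfg=sp.GeaConfig(seed=3), condition_on=X)
        planted = set(truth.class_indices("adaptive"))
        cand = set(res.loc[res["candidate"], "locus"])
        assert len(cand & planted) / len(planted) < 0.1


class TestPcaScan:
    def test_panmictic_null_fdr_controlled(self):
        rng = np.random.default_rng(5)
        calls = hwe_genotypes(rng, 100, 5000)
        g = make_genotypes(calls)
        res, info = sp.pca_scan(g, k=2, cfg=sp.GeaConfig(seed=5))
        assert res["candidate"].mean() <= 0.05

    def test_two_group_planted_divergence_recovered(self):
        rng = np.random.default_rng(6)
        calls = hwe_genotypes(rng, 100, 5000)
        calls[:50, :50] = rng.binomial(2, 0.05, size=(50, 50))
        calls[50:, :50] = rng.binomial(2, 0.95, size=(50, 50))
        g = make_genotypes(calls)
        res, info = sp.pca_scan(g, k=2, cfg=sp.GeaConfig(seed=6))
        cand = set(res.loc[res["candidate"], "locus"])
        assert len(cand & set(range(50))) >= 45

    def test_k1_statistic_tracks_pc_loading(self):
        rng = np.random.default_rng(7)
        calls = hwe_genotypes(rng, 60, 300)
        calls[:30, :20] = rng.binomial(2, 0.1, size=(30, 20))
        calls[30:, :20] = rng.binomial(2, 0.9, size=(30, 20))
        g = make_genotypes(calls)
        res, _ = sp.pca_scan(g, k=1, cfg=sp.GeaConfig(seed=7))
        # with one axis, D^2 equals the standardised squared z-score of an
        # ordinary per-locus regression on PC1 (independent oracle)
        import statsmodels.api as sm

        G = g.calls.astype(float)
        Gc = (G - G.mean(0)) / np.where(G.std(0) == 0, 1, G.std(0))
        U, s, _ = np.linalg.svd(Gc, full_matrices=False)
        pc1 = (U[:, 0] * s[0])
        t = np.array([
            sm.OLS(Gc[:, j], sm.add_constant(pc1)).fit().tvalues[1]
            for j in range(300)
        ])
        np.testing.assert_allclose(res["statistic"], ((t - t.mean()) ** 2)
                                   / t.var(ddof=1), rtol=1e-6)

    def test_k_out_of_range(self):
        rng = np.random.default_rng(8)
        g = make_genotypes(hwe_genotypes(rng, 10, 20))
        with pytest.raises(sp.DataError):
            sp.pca_scan(g, k=10)


class TestNeutralSetAndOverlap:
    def _scan_frame(self, loci, candidates):
        return pd.DataFrame({
            "locus": loci,
            "candidate": [l in candidates for l in loci],
        })

    def test_no_candidates_identity(self):
        rng = np.random.default_rng(9)
        g = make_genotypes(hwe_genotypes(rng, 10, 30))
        res = self._scan_frame(range(30), set())
        assert sp.derive_neutral_set(g, res).n_loci == 30

    def test_union_semantics(self):
        rng = np.random.default_rng(10)
        g = make_genotypes(hwe_genotypes(rng, 10, 30))
        r1 = self._scan_frame(range(30), set(range(10)))
        r2 = self._scan_frame(range(30), set(range(5, 15)))
        out = sp.derive_neutral_set(g, r1, r2)
        assert out.n_loci == 15

    def test_all_outliers_rejected(self):
        rng = np.random.default_rng(11)
        g = make_genotypes(hwe_genotypes(rng, 10, 5))
        r = self._scan_frame(range(5), set(range(5)))
        with pytest.raises(sp.DataError):
            sp.derive_neutral_set(g, r)

    def test_overlap_counts_match_brute_force(self):
        r1 = self._scan_frame(range(40), set(range(0, 20)))
        r2 = self._scan_frame(range(40), set(range(10, 30)))
        members, counts = sp.candidate_overlap({"a": r1, "b": r2})
        assert counts["union"] == 30
        assert counts["intersection"] == 10
        assert counts["per_method"] == {"a": 20, "b": 20}
        assert members.shape == (30, 2)

    def test_rad_locus_grouping(self):
        r1 = self._scan_frame(range(6), {0, 1, 4})
        radlocus = pd.Series(["R0", "R0", "R1", "R1", "R2", "R2"],
                             index=range(6))
        _, counts = sp.candidate_overlap({"a": r1}, radlocus_of=radlocus)
        assert counts["unique_rad_loci"]["a"] == 2


class TestScanAgreement:
    def test_rda_and_pca_scan_agree_when_predictors_are_pcs(self):
        rng = np.random.default_rng(12)
        calls = hwe_genotypes(rng, 80, 400)
        calls[:40, :15] = rng.binomial(2, 0.1, size=(40, 15))
        calls[40:, :15] = rng.binomial(2, 0.9, size=(40, 15))
        g = make_genotypes(calls)
        G = g.calls.astype(float)
        Gc = (G - G.mean(0)) / np.where(G.std(0) == 0, 1, G.std(0))
        U, s, _ = np.linalg.svd(Gc, full_matrices=False)
        pcs = pd.DataFrame(U[:, :2] * s[:2], columns=["PC1", "PC2"])
        res_rda, _ = sp.rda_scan(g, pcs, cfg=sp.GeaConfig(seed=12))
        res_pca, _ = sp.pca_scan(g, k=2, cfg=sp.GeaConfig(seed=12))
        rho = sps.spearmanr(res_rda["statistic"], res_pca["statistic"]).statistic
        assert rho > 0.9
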