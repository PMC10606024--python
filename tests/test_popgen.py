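"""Differentiation and diversity statistics against independent oracles:
a scalar-loop WC84 transcription, brute-force rarefaction enumeration,
hand-evaluated distances, and scikit-bio's PCoA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import seapop as sp
from seapop.datatypes import MISSING

from conftest import hwe_genotypes, make_genotypes, make_samples
from wc_oracle import wc_theta_oracle


class TestWeirCockerham:
    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_pops = rng.integers(2, 6)
            n_per = rng.integers(3, 10)
            L = rng.integers(5, 51)
            n = n_pops * n_per
            pop_of = np.repeat(np.arange(n_pops), n_per)
            p_pop = rng.uniform(0.05, 0.95, size=(n_pops, L))
            calls = rng.binomial(2, p_pop[pop_of]).astype(np.int8)
            calls[rng.random(calls.shape) < 0.1] = MISSING
            g = make_genotypes(calls)
            samples = make_samples([f"p{k}" for k in pop_of])
            theta = sp.multilocus_fst_wc(g, samples)
            theta_oracle, _ = wc_theta_oracle(calls, pop_of)
            assert theta == pytest.approx(theta_oracle, abs=1e-12)

    def test_complete_fixation_theta_one(self):
        calls = np.array([[0] * 4, [0] * 4, [2] * 4, [2] * 4], dtype=np.int8)
        g = make_genotypes(calls)
        samples = make_samples(["A", "A", "B", "B"])
        m = sp.pairwise_fst_wc(g, samples, n_boot=0)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_identical_frequencies_theta_near_zero(self):
        rng = np.random.default_rng(1)
        calls = hwe_genotypes(rng, 200, 3000)
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 100 + ["B"] * 100)
        m = sp.pairwise_fst_wc(g, samples, n_boot=0)
        assert abs(m.values[0, 1]) < 0.01

    def test_bootstrap_ci_brackets_point(self, classified_sim):
        _, g, samples, _, _, _ = classified_sim
        m = sp.pairwise_fst_wc(g, samples, n_boot=200, seed=3)
        k = len(m.labels)
        iu = np.triu_indices(k, 1)
        assert (m.ci_lo[iu] <= m.values[iu] + 1e-9).all()
        assert (m.ci_hi[iu] >= m.values[iu] - 1e-9).all()

    def test_per_locus_theta_matches_oracle_components(self):
        rng = np.random.default_rng(4)
        pop_of = np.repeat([0, 1, 2], 8)
        p_pop = rng.uniform(0.1, 0.9, size=(3, 30))
        calls = rng.binomial(2, p_pop[pop_of]).astype(np.int8)
        g = make_genotypes(calls)
        samples = make_samples([f"p{k}" for k in pop_of])
        theta = sp.per_locus_fst_wc(g, samples)
        _, per_locus = wc_theta_oracle(calls, pop_of)
        for j, abc in enumerate(per_locus):
            if abc is None:
                assert np.isnan(theta[j])
            else:
                a, b, c = abc
                assert theta[j] == pytest.approx(a / (a + b + c), abs=1e-12)


class TestDiversityStats:
    def test_all_heterozygotes(self):
        calls = np.ones((8, 20), dtype=np.int8)
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 4 + ["B"] * 4)
        out = sp.diversity_stats(g, samples, n_boot=0)
        assert (out["h_o"] == 1.0).all()
        assert (out["f_is"] < 0).all()

    def test_monomorphic_population(self):
        calls = np.zeros((8, 20), dtype=np.int8)
        calls[4:] = 2                      # pop B fixed alt, pop A fixed ref
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 4 + ["B"] * 4)
        out = sp.diversity_stats(g, samples, n_boot=0)
        assert (out["h_o"] == 0.0).all()
        assert out["f_is"].isna().all()

    def test_hwe_fis_ci_covers_zero(self):
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(100 + s)
            calls = hwe_genotypes(rng, 50, 500, p=np.full(500, 0.5))
            g = make_genotypes(calls)
            samples = make_samples(["A"] * 25 + ["B"] * 25)
            out = sp.diversity_stats(g, samples, n_boot=200, seed=s)
            row = out.iloc[0]
            if row["f_is_lo"] <= 0 <= row["f_is_hi"]:
                hits += 1
        assert hits >= int(0.9 * n_seeds) - 1


class TestAllelicRichness:
    def test_monomorphic_gives_one(self):
        calls = np.zeros((8, 10), dtype=np.int8)
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 4 + ["B"] * 4)
        ar = sp.allelic_richness(g, samples)
        np.testing.assert_allclose(ar.to_numpy(), 1.0)

    def test_balanced_alleles_large_n_approaches_two(self):
        calls = np.tile([0, 2], (50, 25)).astype(np.int8)[:, :50]
        calls[::2] = 2 - calls[::2]
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 25 + ["B"] * 25)
        ar = sp.allelic_richness(g, samples, rarefaction_size=40)
        assert (ar > 1.99).all()

    def test_matches_exhaustive_enumeration_small_case(self):
        # one population, 3 individuals, allele copies 5 ref / 1 alt, rarefy to 4
        calls = np.array([[0], [0], [1], [0], [0], [0]], dtype=np.int8)[:3]
        g = make_genotypes(calls)
        samples = make_samples(["A", "A", "A"])
        ar = sp.allelic_richness(g, samples, rarefaction_size=4)

        copies = [0, 0, 0, 0, 0, 1]       # 5 ref, 1 alt gene copies
        n_expected = []
        for combo in itertools.combinations(range(6), 4):
            n_expected.append(len({copies[i] for i in combo}))
        assert ar["A"] == pytest.approx(np.mean(n_expected), abs=1e-12)


class TestPrivateAlleles:
    def test_shared_allele_not_private(self):
        calls = np.array([[1], [1]], dtype=np.int8)
        g = make_genotypes(calls)
        samples = make_samples(["A", "B"])
        ap = sp.private_alleles(g, samples)
        assert (ap == 0).all()

    def test_exclusive_alt_counts(self):
        calls = np.array([[1, 1, 1, 0], [0, 0, 0, 0]], dtype=np.int8)
        g = make_genotypes(calls)
        samples = make_samples(["A", "B"])
        ap = sp.private_alleles(g, samples)
        assert ap["A"] == 3 and ap["B"] == 0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = MISSING
        pops = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        g = make_genotypes(calls)
        samples = make_samples(pops)
        ap = sp.private_alleles(g, samples)

        brute = {"A": 0, "B": 0, "C": 0}
        for j in range(200):
            for allele in ("ref", "alt"):
                present = []
                for pop in ("A", "B", "C"):
                    rows = [i for i in range(30) if pops[i] == pop]
                    gt = [calls[i, j] for i in rows if calls[i, j] != MISSING]
                    if allele == "alt":
                        has = any(x > 0 for x in gt)
                    else:
                        has = any(x < 2 for x in gt)
                    if has:
                        present.append(pop)
                if len(present) == 1:
                    brute[present[0]] += 1
        for pop in brute:
            assert ap[pop] == brute[pop]


class TestBetaWT:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(8)
        calls = hwe_genotypes(rng, 120, 2000)
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 40 + ["B"] * 40 + ["C"] * 40)
        out = sp.beta_wt(g, samples, n_boot=0)
        pops = out[out["population"] != "overall"]
        assert np.abs(pops["beta_wt"]).max() < 0.01

    def test_exchangeable_island_model_betas_equal(self):
        cfg = sp.SimConfig(n_pops=5, n_per_pop=25, n_loci=3000, n_groups=1,
                           frac_adaptive=0, frac_duplicated=0, frac_cnv=0,
                           fst_within_group=0.05, divergent_pop=None, seed=9)
        g, samples, _ = sp.simulate_metapopulation(cfg)
        out = sp.beta_wt(g, samples, n_boot=0)
        pops = out[out["population"] != "overall"]["beta_wt"].to_numpy()
        assert pops.std() < 0.015
        assert pops.mean() == pytest.approx(0.05, abs=0.02)

    def test_divergent_population_has_largest_beta(self, default_sim):
        cfg, g, samples, _, _, _ = default_sim
        out = sp.beta_wt(g, samples, n_boot=0)
        pops = out[out["population"] != "overall"]
        top = pops.loc[pops["beta_wt"].idxmax(), "population"]
        assert top == f"pop{cfg.divergent_pop:02d}"


class TestNeiDa:
    def test_identical_populations_zero(self):
        calls = np.tile(np.array([[0], [1], [2]], dtype=np.int8), (2, 5))
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 3 + ["B"] * 3)
        da = sp.nei_da(g, samples)
        assert da.values[0, 1] == pytest.approx(0.0)

    def test_opposite_fixation_one(self):
        calls = np.array([[0] * 4, [0] * 4, [2] * 4, [2] * 4], dtype=np.int8)
        g = make_genotypes(calls)
        samples = make_samples(["A", "A", "B", "B"])
        da = sp.nei_da(g, samples)
        assert da.values[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_case(self):
        # both loci: pop A freq 0.5, pop B fixed ref -> per-locus term
        # sqrt(0.5*0) + sqrt(0.5*1) = 0.7071; D_A = 1 - 0.7071
        calls = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        g = make_genotypes(calls)
        samples = make_samples(["A", "A", "B", "B"])
        da = sp.nei_da(g, samples)
        assert da.values[0, 1] == pytest.approx(1.0 - np.sqrt(0.5), abs=1e-12)


class TestPcoa:
    def test_recovers_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [-1.0, 1.0]])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, evals, frac = sp.pcoa(D)
        D2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_zero_matrix_zero_coordinates(self):
        coords, evals, frac = sp.pcoa(np.zeros((4, 4)))
        assert coords.shape[1] == 0 or np.allclose(coords, 0)

    def test_eigenvalue_sum_identity(self, default_sim):
        _, g, samples, _, _, _ = default_sim
        da = sp.nei_da(g, samples)
        coords, evals, _ = sp.pcoa(da)
        D = da.values
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        assert evals.sum() == pytest.approx(np.trace(B), abs=1e-10)

    def test_matches_scikit_bio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours, evals, _ = sp.pcoa(D)
        theirs = skbio_pcoa(D, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.sort(evals[evals > 1e-9])[::-1],
            np.sort(theirs.eigvals.to_numpy()[:3])[::-1], atol=1e-8,
        )
        for k in range(3):
            r = np.corrcoef(ours[:, k], theirs.samples.iloc[:, k])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_non_symmetric_rejected(self):
        with pytest.raises(sp.DataError):
            sp.pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestTopFstSubset:
    def test_exact_count(self, default_sim):
        _, g, samples, _, _, _ = default_sim
        sub = sp.top_fst_subset(g, samples, n_top=150)
        assert sub.n_loci == 150

    def test_zero_top_empty(self, default_sim):
        _, g, samples, _, _, _ = default_sim
        assert sp.top_fst_subset(g, samples, n_top=0).n_loci == 0

    def test_planted_divergent_loci_rank_first(self):
        rng = np.random.default_rng(12)
        calls = hwe_genotypes(rng, 60, 500)
        # plant 10 strongly differentiated loci
        calls[:30, :10] = rng.binomial(2, 0.05, size=(30, 10))
        calls[30:, :10] = rng.binomial(2, 0.95, size=(30, 10))
        g = make_genotypes(calls)
        samples = make_samples(["A"] * 30 + ["B"] * 30)
        sub = sp.top_fst_subset(g, samples, n_top=10)
        assert set(sub.loci["pos"]) == set(g.loci["pos"][:10])
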