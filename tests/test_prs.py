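"""PRS arithmetic, allele orientation, clumping and P+T selection."""

import numpy as np
import pytest

import lpsprs as lp
from lpsprs.prs import DEFAULT_P_THRESHOLDS


def _weights(site_ids, weight, p_value, effect_allele=None):
    n = len(site_ids)
    return lp.GWASWeights(
        site_id=np.array(site_ids, dtype=object),
        effect_allele=np.array(effect_allele or ["alt"] * n, dtype=object),
        weight=np.asarray(weight, dtype=float),
        p_value=np.asarray(p_value, dtype=float),
        is_causal=np.zeros(n, dtype=bool),
        true_beta=np.zeros(n),
    )


SITES = np.array(["a", "b"], dtype=object)


class TestComputePrs:
    def test_weighted_sum(self):
        w = _weights(["a", "b"], [0.2, -0.1], [0.01, 0.02])
        res = lp.compute_prs(np.array([[2.0, 1.0]]), SITES, w, ["a", "b"])
        assert res.raw[0] == pytest.approx(0.3)

    def test_zero_weights_zero_scores(self):
        w = _weights(["a", "b"], [0.0, 0.0], [0.5, 0.5])
        res = lp.compute_prs(np.array([[1.0, 2.0], [0.0, 1.0]]), SITES, w, ["a", "b"])
        assert (res.raw == 0).all()

    def test_reference_effect_allele_flips_dosage(self):
        """Effect allele = ref with DS = 0.5 contributes w * 1.5."""
        w = _weights(["a"], [0.4], [0.01], effect_allele=["ref"])
        res = lp.compute_prs(np.array([[0.5]]), np.array(["a"], dtype=object), w, ["a"])
        assert res.raw[0] == pytest.approx(0.4 * 1.5)

    def test_missing_snps_skipped_and_logged(self):
        w = _weights(["a", "b", "zzz"], [0.2, 0.1, 9.0], [0.01, 0.02, 0.03])
        res = lp.compute_prs(np.array([[1.0, 1.0]]), SITES, w, ["a", "b", "zzz"])
        assert res.snps_skipped == ["zzz"]
        assert res.raw[0] == pytest.approx(0.3)

    def test_empty_subset_raises(self):
        w = _weights(["a"], [0.2], [0.01])
        with pytest.raises(ValueError, match="no scorable SNPs"):
            lp.compute_prs(np.array([[1.0, 1.0]]), SITES, w, ["zzz"])

    def test_linearity_over_disjoint_subsets(self):
        rng = np.random.default_rng(50)
        ids = np.array([f"s{i}" for i in range(10)], dtype=object)
        w = _weights(ids, rng.normal(0, 0.2, 10), rng.uniform(0.001, 1, 10))
        X = rng.uniform(0, 2, (6, 10))
        full = lp.compute_prs(X, ids, w, list(ids)).raw
        part1 = lp.compute_prs(X, ids, w, list(ids[:4])).raw
        part2 = lp.compute_prs(X, ids, w, list(ids[4:])).raw
        np.testing.assert_allclose(full, part1 + part2, atol=1e-12)

    def test_allele_flip_involution(self):
        """Flipping effect allele, negating w and complementing X preserves scores
        up to the per-SNP constant, hence exactly after mean-centering."""
        rng = np.random.default_rng(51)
        ids = np.array([f"s{i}" for i in range(6)], dtype=object)
        wts = rng.normal(0, 0.3, 6)
        X = rng.uniform(0, 2, (8, 6))
        w_alt = _weights(ids, wts, np.full(6, 0.5))
        w_ref = _weights(ids, -wts, np.full(6, 0.5), effect_allele=["ref"] * 6)
        a = lp.normalize_scores(lp.compute_prs(X, ids, w_alt, list(ids))).normalized
        b = lp.normalize_scores(lp.compute_prs(X, ids, w_ref, list(ids))).normalized
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestNormalizeScores:
    def test_mean_zero(self):
        w = _weights(["a"], [1.0], [0.5])
        res = lp.compute_prs(np.array([[1.0], [2.0], [3.0]]),
                             np.array(["a"], dtype=object), w, ["a"])
        norm = lp.normalize_scores(res)
        np.testing.assert_allclose(norm.normalized, [-1, 0, 1])
        assert abs(norm.normalized.sum()) < 1e-9

    def test_single_individual_degenerates_to_zero(self):
        w = _weights(["a"], [1.0], [0.5])
        res = lp.compute_prs(np.array([[1.5]]), np.array(["a"], dtype=object), w, ["a"])
        assert lp.normalize_scores(res).normalized[0] == 0.0


class TestLdClump:
    def test_correlated_pair_keeps_most_significant(self):
        rng = np.random.default_rng(52)
        g = rng.integers(0, 3, (40, 1)).astype(float)
        G = np.hstack([g, g])  # perfectly correlated pair
        ids = SITES
        w = _weights(ids, [0.1, 0.2], [1e-10, 1e-4])
        assert lp.ld_clump(G, ids, w) == ["a"]

    def test_uncorrelated_snps_all_retained(self):
        rng = np.random.default_rng(53)
        G = rng.integers(0, 3, (200, 5)).astype(float)
        ids = np.array([f"s{i}" for i in range(5)], dtype=object)
        w = _weights(ids, np.ones(5), [0.5, 0.1, 0.3, 0.2, 0.4])
        assert sorted(lp.ld_clump(G, ids, w)) == sorted(ids)

    def test_single_snp_retained(self):
        w = _weights(["a"], [0.5], [0.01])
        got = lp.ld_clump(np.array([[0.0], [1.0], [2.0]]),
                          np.array(["a"], dtype=object), w)
        assert got == ["a"]


class TestPlatformScoreCorrelation:
    def test_array_and_lowpass_scores_strongly_correlated_at_1x(self):
        """Scores from the array route and GL-imputed 1x sequencing agree
        strongly on the same fixed significant-SNP model (averaged over
        synthetic cohorts under default generator conditions)."""
        corrs = []
        for seed0 in (500, 510, 520):
            population = lp.simulate_panel(300, 300, seed=seed0)
            panel = lp.subsample_panel(population, 150, seed=seed0 + 1)
            cohort = lp.simulate_cohort(population, 60, seed=seed0 + 100)
            afs = population.population_af
            src = lp.simulate_reads(cohort, 30.0, seed=seed0 + 200)
            gl = lp.compute_gl(lp.downsample_reads(src, 1.0, seed=seed0 + 300))
            d_gl = lp.impute_gl(gl, panel, dtype=np.float32)
            d_ar = lp.impute_hardcall(
                lp.simulate_array(cohort, seed=seed0 + 400, afs=afs),
                panel, dtype=np.float32,
            )
            w = lp.assign_effects(afs, 15, 0.2, seed=seed0 + 500,
                                  site_ids=population.site_ids)
            sig = list(w.site_id[w.p_value < 5e-8])
            s_ar = lp.normalize_scores(
                lp.compute_prs(d_ar.dosage, panel.site_ids, w, sig)).scores
            s_gl = lp.normalize_scores(
                lp.compute_prs(d_gl.dosage, panel.site_ids, w, sig)).scores
            corrs.append(lp.score_correlation(s_ar, s_gl)[0])
        assert np.mean(corrs) > 0.9


class TestPPlusT:
    def test_single_threshold_matches_unadjusted_on_clumped_set(self):
        rng = np.random.default_rng(54)
        ids = np.array([f"s{i}" for i in range(6)], dtype=object)
        G = rng.integers(0, 3, (60, 6)).astype(float)
        w = _weights(ids, rng.normal(0, 0.2, 6), rng.uniform(1e-6, 1e-3, 6))
        labels = rng.integers(0, 2, 60)
        labels[:5] = 1
        labels[-5:] = 0
        best, table = lp.p_plus_t(G, ids, w, labels, thresholds=[5e-2])
        clumped = lp.ld_clump(G, ids, w)
        direct = lp.normalize_scores(lp.compute_prs(G, ids, w, clumped))
        np.testing.assert_allclose(best.scores, direct.scores, atol=1e-12)
        assert table.shape[0] == 1

    def test_default_grid_spans_5e2_to_1e20(self):
        assert max(DEFAULT_P_THRESHOLDS) == 5e-2
        assert min(DEFAULT_P_THRESHOLDS) == 1e-20

    def test_empty_threshold_recorded_as_null_not_error(self):
        ids = SITES
        w = _weights(ids, [0.1, 0.2], [0.04, 0.03])
        G = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0], [1.0, 1.0]])
        labels = np.array([1, 0, 1, 0])
        _, table = lp.p_plus_t(G, ids, w, labels, thresholds=[1e-20, 5e-2])
        null_row = table[table["p_threshold"] == 1e-20].iloc[0]
        assert null_row["n_snps"] == 0 and np.isnan(null_row["auc"])

    def test_best_threshold_recovers_planted_causal_snp(self):
        """Only the causal SNP is significant; P+T should isolate it and win."""
        rng = np.random.default_rng(55)
        n = 300
        ids = np.array([f"s{i}" for i in range(8)], dtype=object)
        G = rng.integers(0, 3, (n, 8)).astype(float)
        liability = 1.2 * G[:, 0] + rng.normal(0, 1, n)
        labels = (liability > np.quantile(liability, 0.5)).astype(int)
        pvals = np.concatenate([[1e-12], rng.uniform(0.2, 1.0, 7)])
        w = _weights(ids, np.concatenate([[1.2], rng.normal(0, 0.05, 7)]), pvals)
        best, table = lp.p_plus_t(G, ids, w, labels,
                                  thresholds=[5e-2, 1e-5, 1e-10])
        assert best.snps_used == ["s0"]
        all_snp_auc = table[table["p_threshold"] == 5e-2]["auc"].iloc[0]
        assert table["auc"].max() >= all_snp_auc
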