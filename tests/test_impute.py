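"""Li–Stephens imputation HMM against an exhaustive path-enumeration oracle."""

import itertools

import numpy as np
import pytest

import lpsprs as lp
from lpsprs.impute import _miscopy_matrix
from conftest import tiny_panel


def _oracle_gp(L, panel, params):
    """Genotype posteriors by brute-force summation over every state path.

    States are ordered haplotype pairs; transitions factorize per haplotype
    as (1 - rho) * I + rho / K; emissions mix the copied genotype through the
    per-allele miscopy matrix. Only feasible for tiny instances.
    """
    K = panel.n_haplotypes
    M = panel.n_sites
    mu = params.resolve_miscopy(K)
    C = _miscopy_matrix(mu)
    rho = 1.0 - np.exp(-params.switch_rate * np.diff(panel.positions.astype(float)))

    def t_hap(a, b, r):
        return (1.0 - r) * (a == b) + r / K

    states = list(itertools.product(range(K), repeat=2))
    em = np.empty((M, len(states)))
    pg = np.empty((M, len(states)), dtype=int)
    for m in range(M):
        for s, (i, j) in enumerate(states):
            g = panel.alleles[i, m] + panel.alleles[j, m]
            pg[m, s] = g
            em[m, s] = sum(C[g, gp] * L[m, gp] for gp in range(3))

    gp_post = np.zeros((M, 3))
    for path in itertools.product(range(len(states)), repeat=M):
        w = 1.0 / (K * K)
        for m in range(1, M):
            (i0, j0), (i1, j1) = states[path[m - 1]], states[path[m]]
            w *= t_hap(i0, i1, rho[m - 1]) * t_hap(j0, j1, rho[m - 1])
        full = w * np.prod([em[m, path[m]] for m in range(M)])
        for m in range(M):
            g = pg[m, path[m]]
            base = full / em[m, path[m]]
            for gprime in range(3):
                gp_post[m, gprime] += base * C[g, gprime] * L[m, gprime]
    return gp_post / gp_post.sum(axis=1, keepdims=True)


def _gl_from_L(L, panel):
    """Wrap linear likelihood triples as a GenotypeLikelihoods object."""
    L = np.asarray(L, dtype=float)
    return lp.GenotypeLikelihoods(
        log_gl=np.log(L)[None, :, :],
        depth=np.ones(L.shape[0], dtype=int)[None, :],
        positions=panel.positions,
        site_ids=panel.site_ids,
    )


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_sites,n_haps,seed", [
        (1, 2, 0), (2, 2, 1), (2, 3, 2), (3, 2, 3), (3, 3, 4),
    ])
    def test_gl_mode_matches_path_enumeration(self, n_sites, n_haps, seed):
        rng = np.random.default_rng(seed)
        panel = tiny_panel(rng.integers(0, 2, (n_haps, n_sites)),
                           positions=np.cumsum(rng.integers(500, 50_000, n_sites)))
        L = rng.random((n_sites, 3)) + 0.05
        params = lp.HmmParams(switch_rate=2e-5, miscopy=0.05)
        got = lp.impute_gl(_gl_from_L(L, panel), panel, params).gp[0]
        want = _oracle_gp(L / L.sum(1, keepdims=True), panel, params)
        np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_hardcall_mode_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        panel = tiny_panel(rng.integers(0, 2, (3, 3)),
                           positions=[1_000, 20_000, 90_000])
        calls = lp.CalledGenotypes(
            calls=np.array([[rng.integers(0, 3), lp.MISSING, rng.integers(0, 3)]],
                           dtype=np.int8),
            positions=panel.positions,
            site_ids=panel.site_ids,
        )
        params = lp.HmmParams(switch_rate=1e-5, miscopy=0.1, call_error=0.02)
        got = lp.impute_hardcall(calls, panel, params).gp[0]
        theta = params.call_error
        L = np.full((3, 3), theta / 2)
        for m in range(3):
            c = calls.calls[0, m]
            if c == lp.MISSING:
                L[m] = 1 / 3
            else:
                L[m, c] = 1 - theta
        want = _oracle_gp(L / L.sum(1, keepdims=True), panel, params)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestLimits:
    def test_monomorphic_ref_panel_prior_drives_dosage_to_zero(self):
        """No reads + all-ref panel + tiny miscopy -> dosage ~ 0."""
        panel = tiny_panel(np.zeros((4, 3)))
        L = np.ones((3, 3)) / 3
        params = lp.HmmParams(miscopy=1e-6)
        dos = lp.impute_gl(_gl_from_L(L, panel), panel, params)
        assert dos.dosage.max() < 1e-4

    def test_all_missing_calls_equal_flat_gl(self):
        """Uninformative emissions agree between the two modes exactly."""
        rng = np.random.default_rng(7)
        panel = tiny_panel(rng.integers(0, 2, (6, 8)))
        params = lp.HmmParams(miscopy=0.02)
        calls = lp.CalledGenotypes(
            calls=np.full((2, 8), lp.MISSING, dtype=np.int8),
            positions=panel.positions, site_ids=panel.site_ids,
        )
        gl = lp.GenotypeLikelihoods(
            log_gl=np.zeros((2, 8, 3)), depth=np.zeros((2, 8), dtype=int),
            positions=panel.positions, site_ids=panel.site_ids,
        )
        np.testing.assert_allclose(
            lp.impute_hardcall(calls, panel, params).gp,
            lp.impute_gl(gl, panel, params).gp,
            atol=1e-12,
        )

    def test_certain_gl_equals_matching_hardcall(self):
        """Degenerate GLs and theta = 0 calls produce identical posteriors."""
        rng = np.random.default_rng(8)
        panel = tiny_panel(rng.integers(0, 2, (5, 6)))
        truth = rng.integers(0, 3, (1, 6))
        L = np.full((1, 6, 3), 1e-12)
        for m in range(6):
            L[0, m, truth[0, m]] = 1.0
        gl = lp.GenotypeLikelihoods(
            log_gl=np.log(L), depth=np.full((1, 6), 30),
            positions=panel.positions, site_ids=panel.site_ids,
        )
        calls = lp.CalledGenotypes(calls=truth.astype(np.int8),
                                   positions=panel.positions, site_ids=panel.site_ids)
        p_gl = lp.HmmParams(miscopy=0.05)
        p_hc = lp.HmmParams(miscopy=0.05, call_error=2e-12)
        np.testing.assert_allclose(
            lp.impute_gl(gl, panel, p_gl).gp,
            lp.impute_hardcall(calls, panel, p_hc).gp,
            atol=1e-6,
        )

    def test_deep_reads_recover_truth(self, small_panel, small_cohort, deep_gl):
        dos = lp.impute_gl(deep_gl, small_panel)
        close = np.abs(dos.dosage - small_cohort.genotypes) < 0.05
        assert close.mean() >= 0.99

    def test_gp_rows_normalized(self, small_panel, lowpass_gl):
        dos = lp.impute_gl(lowpass_gl, small_panel)
        np.testing.assert_allclose(dos.gp.sum(-1), 1.0, atol=1e-9)
        assert (dos.dosage >= 0).all() and (dos.dosage <= 2).all()

    def test_float32_matches_float64(self, small_panel, lowpass_gl):
        d64 = lp.impute_gl(lowpass_gl, small_panel, dtype=np.float64)
        d32 = lp.impute_gl(lowpass_gl, small_panel, dtype=np.float32)
        assert np.abs(d64.dosage - d32.dosage).max() < 1e-4

    def test_degenerate_panel_rejected(self):
        panel = tiny_panel(np.zeros((1, 3)))
        L = np.ones((3, 3)) / 3
        with pytest.raises(ValueError, match="2 haplotypes"):
            lp.impute_gl(_gl_from_L(L, panel), panel)

    def test_unknown_sites_rejected(self, small_panel):
        gl = lp.GenotypeLikelihoods(
            log_gl=np.zeros((1, 2, 3)), depth=np.zeros((1, 2), dtype=int),
            positions=np.array([1, 2]),
            site_ids=np.array(["nope1", "nope2"], dtype=object),
        )
        with pytest.raises(ValueError, match="absent from panel"):
            lp.impute_gl(gl, small_panel)


class TestModeContrast:
    def test_gl_beats_hardcall_at_low_depth(self, small_panel, small_cohort, lowpass_gl):
        """The central low-pass result: GL emissions outperform fixed calls at 0.5x."""
        d_gl = lp.impute_gl(lowpass_gl, small_panel)
        d_hc = lp.impute_hardcall(lp.hard_call(lowpass_gl), small_panel)
        truth = small_cohort.genotypes
        assert lp.pearson_r2(truth, d_gl.dosage) > lp.pearson_r2(truth, d_hc.dosage)
        assert lp.ndr(truth, d_gl.best_guess) < lp.ndr(truth, d_hc.best_guess)

    def test_gl_accuracy_increases_with_depth(self, small_panel, small_cohort):
        r2 = []
        reads = lp.simulate_reads(small_cohort, 8.0, seed=77)
        for d in (0.5, 2.0, 8.0):
            gl = lp.compute_gl(lp.downsample_reads(reads, d, seed=78))
            dos = lp.impute_gl(gl, small_panel)
            r2.append(lp.pearson_r2(small_cohort.genotypes, dos.dosage))
        assert r2[0] < r2[1] < r2[2]


class TestInfoScore:
    def test_monomorphic_dosages_zero(self):
        assert lp.info_score(np.zeros((5, 1)))[0] == 0.0

    def test_hardy_weinberg_hard_genotypes_give_one(self):
        ds = np.array([[0.0], [1.0], [1.0], [2.0]])
        assert lp.info_score(ds)[0] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """[0.5, 0.5, 0.5, 1.5]: var 0.1875 over 2 p (1-p) = 0.46875 -> 0.4."""
        ds = np.array([[0.5], [0.5], [0.5], [1.5]])
        assert lp.info_score(ds)[0] == pytest.approx(0.4)

    def test_clipped_to_unit_interval(self):
        ds = np.array([[0.0], [2.0], [0.0], [2.0]])  # var > binomial variance
        assert lp.info_score(ds)[0] == 1.0


class TestFilterByInfo:
    def test_boundary_site_retained(self):
        dos = lp.ImputedDosages(
            gp=np.zeros((2, 2, 3)), positions=np.array([1, 2]),
            site_ids=np.array(["a", "b"], dtype=object),
            info=np.array([0.3, 0.29999]),
        )
        keep = lp.filter_by_info(dos, 0.3)
        assert keep.tolist() == [True, False]

    def test_zero_threshold_keeps_all(self):
        dos = lp.ImputedDosages(
            gp=np.zeros((2, 5, 3)), positions=np.arange(5),
            site_ids=np.array(list("abcde"), dtype=object),
            info=np.array([0.0, 0.1, 0.5, 0.9, 1.0]),
        )
        assert lp.filter_by_info(dos, 0.0).all()

    def test_hand_fixture(self):
        info = np.array([0.05, 0.35, 0.2, 0.9, 0.3])
        dos = lp.ImputedDosages(
            gp=np.zeros((2, 5, 3)), positions=np.arange(5),
            site_ids=np.array(list("abcde"), dtype=object), info=info,
        )
        assert lp.filter_by_info(dos, 0.3).tolist() == [False, True, False, True, True]
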