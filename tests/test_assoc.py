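"""Null LMM fitting and the LS / QLS score tests."""

import numpy as np
import pytest
from scipy import stats

import pedscore as ps
from pedscore.assoc import CohortSolver, NullFit, UndefinedTestError


def _iid_data(n=400, seed=0):
    rng = np.random.default_rng(seed)
    W = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    beta = np.array([1.0, 0.5, 0.8])
    Y = W @ beta + rng.normal(scale=1.2, size=n)
    return Y, W


class TestFitNull:
    def test_independent_data_recovers_ols_limit(self, cohort_phi):
        """Data with no polygenic component: the fitted ratio collapses
        toward zero and the GLS coefficients approach OLS.  (With
        Phi = I the split sigma_e^2/sigma_a^2 would be unidentifiable,
        so the check uses the structured cohort kinship.)"""
        rng = np.random.default_rng(0)
        n = 100
        W = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        Y = W @ np.array([1.0, 0.5, 0.8]) + rng.normal(scale=1.2, size=n)
        fit = ps.fit_null(Y, W, phi=cohort_phi)
        ols = np.linalg.lstsq(W, Y, rcond=None)[0]
        assert np.allclose(fit.beta0_hat, ols, atol=0.05)
        assert fit.sigma_a2_hat < 0.5 * fit.sigma_e2_hat

    def test_gls_residual_orthogonality(self, cohort, cohort_phi):
        rng = np.random.default_rng(3)
        W = np.column_stack([np.ones(100), rng.normal(size=100), rng.integers(0, 2, 100)])
        L = np.linalg.cholesky(1.5 * np.eye(100) + 2.5 * cohort_phi)
        Y = W @ np.array([1.0, 0.5, 0.8]) + L @ rng.normal(size=100)
        fit = ps.fit_null(Y, W, phi=cohort_phi)
        assert np.max(np.abs(W.T @ fit.residual_R)) < 1e-8 * np.abs(Y).max()

    def test_fixed_variance_ratio(self):
        Y, W = _iid_data(n=100, seed=5)
        fit = ps.fit_null(Y, W, phi=np.eye(100), var_ratio=0.0)
        assert fit.sigma_a2_hat == 0.0

    def test_rank_deficient_W_rejected(self):
        Y, W = _iid_data(n=50, seed=2)
        W2 = np.column_stack([W, W[:, 1]])
        with pytest.raises(ValueError):
            ps.fit_null(Y, W2, phi=np.eye(50))

    def test_parameter_recovery_mean(self, cohort, cohort_phi):
        """ML estimates of (sigma_e^2, sigma_a^2) are close to the
        generating (1.5, 2.5) on average over replicate cohorts."""
        solver = None
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(1.5 * np.eye(100) + 2.5 * cohort_phi)
        est = []
        for _ in range(60):
            W = np.column_stack(
                [np.ones(100), rng.uniform(18, 80, 100), rng.random(100) < 0.7]
            )
            Y = W @ np.array([1.0, 0.5, 0.8]) + L @ rng.normal(size=100)
            fit = ps.fit_null(Y, W, phi=cohort_phi)
            est.append([fit.sigma_e2_hat, fit.sigma_a2_hat])
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - 1.5) < 0.25
        assert abs(mean[1] - 2.5) < 0.4


class TestLSTest:
    def test_reduces_to_ols_score_when_independent(self):
        """With Phi = I and the variance ratio pinned at 0, the LS
        statistic equals the textbook score statistic for adding X."""
        Y, W = _iid_data(n=300, seed=9)
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, size=300).astype(float)
        fit = ps.fit_null(Y, W, phi=np.eye(300), var_ratio=0.0)
        res = ps.ls_test(X, fit)
        # oracle by direct regression algebra
        H = W @ np.linalg.solve(W.T @ W, W.T)
        r = Y - H @ Y
        sigma2 = (r @ r) / 300  # ML error variance
        M = np.eye(300) - H
        s_oracle = (X @ r) ** 2 / (sigma2 * (X @ M @ X))
        assert res.s_stat == pytest.approx(s_oracle, rel=1e-8)

    def test_orthogonal_snp_gives_zero(self, small_dataset, cohort_phi):
        fit = ps.fit_null(
            small_dataset.traits[0], small_dataset.covariates, phi=cohort_phi
        )
        # project a pseudo-genotype onto the orthocomplement of R
        R = fit.residual_R
        v = np.random.default_rng(0).normal(size=100)
        X = v - (v @ R) / (R @ R) * R
        res = ps.ls_test(X, fit)
        assert res.s_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_snp_rejected(self, small_dataset, cohort_phi):
        fit = ps.fit_null(
            small_dataset.traits[0], small_dataset.covariates, phi=cohort_phi
        )
        with pytest.raises(UndefinedTestError):
            ps.ls_test(np.zeros(100), fit)


class TestQLSTest:
    def test_hand_computed_example(self):
        """n = 4 unrelated, R = (1,-1,1,-1), X = (2,0,2,0): the BLUE is
        0.5, sigma_X^2 = 0.5, R'X = 4 and S = 16 / (4 * 0.5) = 8."""
        fit = NullFit(
            beta0_hat=np.zeros(1),
            sigma_e2_hat=1.0,
            sigma_a2_hat=0.0,
            residual_R=np.array([1.0, -1.0, 1.0, -1.0]),
            loglik=0.0,
        )
        res = ps.qls_test(np.array([2.0, 0.0, 2.0, 0.0]), fit, phi=np.eye(4))
        assert res.s_stat == pytest.approx(8.0, abs=1e-12)
        assert res.z_stat == pytest.approx(np.sqrt(8.0))

    def test_fixed_af_snp_rejected(self, small_dataset, cohort_phi):
        fit = ps.fit_null(
            small_dataset.traits[0], small_dataset.covariates, phi=cohort_phi
        )
        with pytest.raises(UndefinedTestError):
            ps.qls_test(np.full(100, 2.0), fit)


class TestInvariances:
    def test_allele_flip_preserves_s_and_flips_z(self, small_dataset, cohort_phi):
        fit = ps.fit_null(
            small_dataset.traits[3], small_dataset.covariates, phi=cohort_phi
        )
        X = small_dataset.genotypes[3].astype(float)
        for test in (ps.ls_test, ps.qls_test):
            a = test(X, fit)
            b = test(2.0 - X, fit)
            assert b.s_stat == pytest.approx(a.s_stat, rel=1e-8)
            assert b.z_stat == pytest.approx(-a.z_stat, rel=1e-8)

    def test_trait_scale_invariance(self, small_dataset, cohort_phi):
        Y = small_dataset.traits[5]
        W = small_dataset.covariates
        X = small_dataset.genotypes[5].astype(float)
        fa = ps.fit_null(Y, W, phi=cohort_phi)
        fb = ps.fit_null(3.7 * Y, W, phi=cohort_phi)
        assert ps.ls_test(X, fa).s_stat == pytest.approx(
            ps.ls_test(X, fb).s_stat, rel=1e-5
        )
        assert ps.qls_test(X, fa).s_stat == pytest.approx(
            ps.qls_test(X, fb).s_stat, rel=1e-5
        )


class TestGenomeScan:
    def test_complete_table(self, small_scan):
        t = small_scan.table
        assert len(t) == 60
        assert t["p_ls"].notna().all()
        assert t["p_qls"].notna().all()
        assert set(["xtr", "p_f_hat", "p_d_hat"]) <= set(t.columns)

    def test_order_invariance(self, small_dataset, cohort, cohort_phi):
        """Reversing SNP order permutes but does not change results."""
        import copy

        ds2 = copy.deepcopy(small_dataset)
        ds2.genotypes = ds2.genotypes[::-1].copy()
        ds2.traits = ds2.traits[::-1].copy()
        ds2.snp_ids = ds2.snp_ids[::-1]
        scan2 = ps.genome_scan(ds2, phi=cohort_phi, ped=cohort)
        ref = ps.genome_scan(small_dataset, phi=cohort_phi, ped=cohort)
        a = ref.table.set_index("snp_id")["s_ls"]
        b = scan2.table.set_index("snp_id")["s_ls"]
        assert np.allclose(a.sort_index(), b.sort_index())

    def test_shared_trait_mode_finds_causal_snp(self, cohort, cohort_phi):
        """With one strongly causal SNP and a shared trait, that SNP
        attains the smallest LS p-value."""
        params = ps.SimParams(n_snps=40, seed=21)
        ds = ps.simulate_dataset(cohort, params, phi=cohort_phi)
        causal = 7
        y = ds.traits[0] + 2.5 * ds.genotypes[causal]
        scan = ps.genome_scan(ds, phi=cohort_phi, ped=cohort, shared_trait=y)
        assert scan.table["p_ls"].idxmin() == causal

    def test_monomorphic_snp_flagged_not_fatal(self, cohort, cohort_phi):
        params = ps.SimParams(n_snps=5, seed=2)
        ds = ps.simulate_dataset(cohort, params, phi=cohort_phi)
        ds.genotypes[2] = 0
        scan = ps.genome_scan(ds, phi=cohort_phi, ped=cohort)
        row = scan.table.iloc[2]
        assert row["flag"] == "skipped"
        assert np.isnan(row["p_ls"])
        assert scan.table["p_ls"].notna().sum() == 4

    def test_ls_qls_z_strongly_correlated(self, small_scan):
        t = small_scan.table
        r = np.corrcoef(t["z_ls"], t["z_qls"])[0, 1]
        assert r > 0.9
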