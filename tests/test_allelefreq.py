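"""Naive and BLUE allele-frequency estimators and the analytic
covariance oracle for subset estimators on pedigrees."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedscore as ps
from pedscore.allelefreq import af_var_analytic, blue_var_analytic


@pytest.fixture(scope="module")
def sets(cohort):
    f_idx, d_idx = ps.partition(cohort)
    return np.arange(cohort.n), f_idx, d_idx


class TestNaiveAF:
    def test_hand_counts(self):
        idx = np.arange(4)
        assert ps.naive_af(np.zeros(4), idx).value == 0.0
        assert ps.naive_af(np.array([2, 1, 1, 0]), idx).value == 0.5

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            ps.naive_af(np.array([1, 2]), np.array([], dtype=int))

    @given(st.integers(0, 3**10 - 1))
    @settings(max_examples=30, deadline=None)
    def test_weighted_decomposition(self, cohort, code):
        """n * p_all == nf * p_f + nd * p_d exactly, for any genotypes."""
        x = np.array([(code // 3**i) % 3 for i in range(10)] * 10, dtype=float)
        all_idx, f_idx, d_idx = (
            np.arange(100),
            *ps.partition(cohort),
        )
        pa = ps.naive_af(x, all_idx).value
        pf = ps.naive_af(x, f_idx).value
        pd_ = ps.naive_af(x, d_idx).value
        assert 100 * pa == pytest.approx(40 * pf + 60 * pd_, abs=1e-12)


class TestBlueAF:
    def test_identity_kinship_equals_naive(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=20).astype(float)
        blue = ps.blue_af(x, np.eye(20))
        assert blue.value == pytest.approx(x.sum() / 40.0, abs=1e-12)

    def test_boundary_unbiasedness(self, cohort_phi):
        assert ps.blue_af(np.full(100, 2.0), cohort_phi).value == pytest.approx(1.0)

    def test_matches_gls_solve(self, cohort_phi):
        """BLUE equals the generalized-least-squares fit of X on a
        constant mean 2c with covariance proportional to Phi."""
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=100).astype(float)
        ones = np.ones(100)
        phi_inv = np.linalg.inv(cohort_phi)
        c_gls = (ones @ phi_inv @ x) / (2.0 * ones @ phi_inv @ ones)
        assert ps.blue_af(x, cohort_phi).value == pytest.approx(c_gls, abs=1e-10)

    def test_out_of_range_clipped_with_warning(self):
        # the middle individual gets a negative BLUE weight here, so a
        # genotype concentrated on it pushes the raw estimate below 0
        phi = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.6], [0.0, 0.6, 1.0]])
        with pytest.warns(UserWarning):
            est = ps.blue_af(np.array([0.0, 2.0, 0.0]), phi)
        assert est.value == 0.0
        assert est.raw_value < 0.0


class TestAnalyticCovariance:
    P = 0.3

    def test_founder_variance_is_binomial(self, cohort_phi, sets):
        _, f_idx, _ = sets
        sigma2 = 2 * self.P * (1 - self.P)
        assert af_var_analytic(cohort_phi, f_idx, self.P) == pytest.approx(
            sigma2 / (4 * 40), abs=1e-15
        )

    def test_printed_identities(self, cohort_phi, sets):
        """The three classical covariance identities follow exactly from
        the bilinear form on the canonical cohort."""
        all_idx, f_idx, d_idx = sets
        sigma2 = 2 * self.P * (1 - self.P)
        nf, nd, n = 40, 60, 100
        cov_fd = ps.af_cov_analytic(cohort_phi, f_idx, d_idx, self.P)
        cov_af = ps.af_cov_analytic(cohort_phi, all_idx, f_idx, self.P)
        cov_ad = ps.af_cov_analytic(cohort_phi, all_idx, d_idx, self.P)
        assert cov_fd == pytest.approx(sigma2 / (4 * nf), rel=1e-12)
        assert cov_af == pytest.approx(sigma2 / (4 * nf), rel=1e-12)
        quad = cohort_phi.sum() / n - 1.0
        assert cov_ad == pytest.approx(sigma2 / (4 * nd) * quad, rel=1e-12)
        assert cov_ad > cov_fd and cov_ad > cov_af

    def test_variance_ordering(self, cohort_phi, sets):
        all_idx, f_idx, d_idx = sets
        vf = af_var_analytic(cohort_phi, f_idx, self.P)
        va = af_var_analytic(cohort_phi, all_idx, self.P)
        vd = af_var_analytic(cohort_phi, d_idx, self.P)
        assert vf <= va <= vd

    def test_founder_optimal_in_mixture_family(self, cohort_phi, sets):
        """var((1-w) p_f + w p_d) over w in [0,1] is minimized at w = 0."""
        _, f_idx, d_idx = sets
        vf = af_var_analytic(cohort_phi, f_idx, self.P)
        vd = af_var_analytic(cohort_phi, d_idx, self.P)
        cfd = ps.af_cov_analytic(cohort_phi, f_idx, d_idx, self.P)

        def var_w(w):
            return (1 - w) ** 2 * vf + w**2 * vd + 2 * w * (1 - w) * cfd

        grid = np.linspace(0, 1, 101)
        vals = var_w(grid)
        assert np.argmin(vals) == 0
        # stationary point of the quadratic lies at or below zero
        w_star = (vf - cfd) / (vf + vd - 2 * cfd)
        assert w_star <= 1e-12 or var_w(w_star) >= vf

    def test_blue_beats_naive_estimators(self, cohort_phi, sets):
        all_idx, f_idx, d_idx = sets
        vb = blue_var_analytic(cohort_phi, self.P)
        for s in sets:
            assert vb <= af_var_analytic(cohort_phi, s, self.P) + 1e-15

    def test_argument_errors(self, cohort_phi, sets):
        all_idx, f_idx, _ = sets
        with pytest.raises(ValueError):
            ps.af_cov_analytic(cohort_phi, np.array([], dtype=int), f_idx, 0.3)
        with pytest.raises(ValueError):
            ps.af_cov_analytic(cohort_phi, all_idx, f_idx, 0.0)


class TestMonteCarloAgreement:
    def test_estimators_unbiased_and_covariances_match(self, cohort, cohort_phi):
        """Gene-dropped replicate SNPs reproduce the analytic means and
        covariances of (p_all, p_f, p_d) within Monte-Carlo error."""
        p = 0.3
        m = 100_000
        rng = np.random.default_rng(12)
        g = ps.gene_drop(cohort, p, rng, size=m).astype(float)
        all_idx, f_idx, d_idx = np.arange(100), *ps.partition(cohort)
        ests = np.column_stack(
            [
                g[:, s].sum(axis=1) / (2.0 * len(s))
                for s in (all_idx, f_idx, d_idx)
            ]
        )
        # unbiasedness within 3 standard errors
        for col, s in zip(ests.T, (all_idx, f_idx, d_idx)):
            se = np.sqrt(af_var_analytic(cohort_phi, s, p) / m)
            assert abs(col.mean() - p) < 3 * se
        emp = np.cov(ests.T)
        pairs = {
            (0, 1): (all_idx, f_idx),
            (0, 2): (all_idx, d_idx),
            (1, 2): (f_idx, d_idx),
        }
        for (i, j), (S, T) in pairs.items():
            analytic = ps.af_cov_analytic(cohort_phi, S, T, p)
            prod = (ests[:, i] - p) * (ests[:, j] - p)
            se = prod.std(ddof=1) / np.sqrt(m)
            assert abs(emp[i, j] - analytic) < 3 * se
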