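"""Null mixed-model fitting and the LS / QLS association score tests.

The null trait model is Y = W beta0 + eps with eps ~ N(0, Sigma0),
Sigma0 = sigma_e^2 I + sigma_a^2 Phi.  Both tests are built on the
transformed phenotypic residual R = Sigma0_hat^-1 (Y - W beta0_hat):

* prospective likelihood score (LS):
    S_LS = (X'R)^2 / X'[S - S W (W'S W)^-1 W'S] X,  S = Sigma0_hat^-1
* retrospective quasi-likelihood score (QLS, the MASTOR statistic):
    S_QLS = (R'X)^2 / (R' Phi R * sigma_X^2),
  with sigma_X^2 = 2 p_hat (1 - p_hat) from the BLUE allele frequency.

Both statistics are chi-square(1) under the null; the signed form
Z = sign(X'R) * sqrt(S) is used for emulation and reporting.

The likelihood is maximized by eigendecomposing Phi once per cohort and
profiling beta0 and the overall scale, leaving a one-dimensional search
over the variance ratio sigma_a^2 / sigma_e^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .allelefreq import blue_af
from .pedigree import Pedigree, kinship_matrix, partition

__all__ = [
    "CohortSolver",
    "NullFit",
    "TestResult",
    "UndefinedTestError",
    "fit_null",
    "ls_test",
    "qls_test",
    "genome_scan",
    "ScanResult",
]

_LOG_RATIO_BOUNDS = (-12.0, 12.0)
_XATOL = 1e-8


class UndefinedTestError(ValueError):
    """The test statistic is undefined (monomorphic SNP, zero variance)."""


@dataclass
class CohortSolver:
    """Per-cohort precomputations shared across SNPs.

    Holds the eigendecomposition Phi = U diag(lam) U' and the rotated
    design U'W, so that each per-SNP null fit reduces to a scalar search.
    """

    phi: np.ndarray
    U: np.ndarray
    lam: np.ndarray
    W: np.ndarray
    Wt: np.ndarray  # U' W
    phi_inv_one: np.ndarray
    one_phi_one: float

    @classmethod
    def from_phi(cls, phi: np.ndarray, W: np.ndarray) -> "CohortSolver":
        lam, U = np.linalg.eigh(phi)
        if lam[0] <= 0:
            raise np.linalg.LinAlgError("kinship matrix is not positive definite")
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise ValueError("covariate matrix W is rank-deficient")
        pio = np.linalg.solve(phi, np.ones(phi.shape[0]))
        return cls(phi, U, lam, W, U.T @ W, pio, float(pio.sum()))


@dataclass
class NullFit:
    """Fitted null LMM and the transformed residual R = Sigma0^-1 (Y - W b)."""

    beta0_hat: np.ndarray
    sigma_e2_hat: float
    sigma_a2_hat: float
    residual_R: np.ndarray
    loglik: float
    boundary: bool = False  # variance-ratio optimum at the search boundary
    solver: CohortSolver | None = None
    _Rt: np.ndarray | None = None  # U'R, cached for the tests

    @property
    def r_phi_r(self) -> float:
        if self.solver is not None and self._Rt is not None:
            return float(self._Rt @ (self.solver.lam * self._Rt))
        raise ValueError("fit has no attached solver")


@dataclass(frozen=True)
class TestResult:
    s_stat: float
    z_stat: float
    p_value: float
    xtr: float
    test_kind: str


def _profile_negloglik(
    log_delta: float, Yt: np.ndarray, Wt: np.ndarray, lam: np.ndarray
) -> float:
    # delta = sigma_a^2 / sigma_e^2; beta and sigma_e^2 are profiled out
    n = Yt.size
    d = 1.0 + np.exp(log_delta) * lam
    wd = Wt / d[:, None]
    beta = np.linalg.solve(Wt.T @ wd, wd.T @ Yt)
    resid = Yt - Wt @ beta
    rss = float(resid @ (resid / d))
    return 0.5 * (n * np.log(rss / n) + np.log(d).sum())


def fit_null(
    Y: np.ndarray,
    W: np.ndarray,
    phi: np.ndarray | None = None,
    solver: CohortSolver | None = None,
    var_ratio: float | None = None,
) -> NullFit:
    """ML fit of the null LMM by profiled 1-D search over the variance ratio.

    ``var_ratio`` pins sigma_a^2 / sigma_e^2 instead of estimating it
    (var_ratio=0 gives the ordinary-regression limit).
    """
    if solver is None:
        if phi is None:
            raise ValueError("need phi or a CohortSolver")
        solver = CohortSolver.from_phi(np.asarray(phi, float), np.asarray(W, float))
    n, q = solver.W.shape
    if n <= q:
        raise ValueError("need n > q")
    Yt = solver.U.T @ np.asarray(Y, float)

    boundary = False
    if var_ratio is not None:
        delta = float(var_ratio)
    else:
        res = optimize.minimize_scalar(
            _profile_negloglik,
            bounds=_LOG_RATIO_BOUNDS,
            args=(Yt, solver.Wt, solver.lam),
            method="bounded",
            options={"xatol": _XATOL},
        )
        delta = float(np.exp(res.x))
        boundary = min(res.x - _LOG_RATIO_BOUNDS[0], _LOG_RATIO_BOUNDS[1] - res.x) < 1e-3

    d = 1.0 + delta * solver.lam
    wd = solver.Wt / d[:, None]
    beta = np.linalg.solve(solver.Wt.T @ wd, wd.T @ Yt)
    resid_t = Yt - solver.Wt @ beta
    rss = float(resid_t @ (resid_t / d))
    sigma_e2 = rss / n
    sigma_a2 = delta * sigma_e2
    loglik = -0.5 * (
        n * np.log(2.0 * np.pi * sigma_e2) + np.log(d).sum() + rss / sigma_e2
    )
    Rt = resid_t / (d * sigma_e2)
    R = solver.U @ Rt
    return NullFit(beta, sigma_e2, sigma_a2, R, loglik, boundary, solver, Rt)


def _chi2_sf(s: float) -> float:
    return float(stats.chi2.sf(s, df=1))


def ls_test(X: np.ndarray, null_fit: NullFit, W: np.ndarray | None = None) -> TestResult:
    """Prospective likelihood score test of the SNP effect."""
    sv = null_fit.solver
    if sv is None:
        raise ValueError("null fit has no attached solver")
    X = np.asarray(X, float)
    Xt = sv.U.T @ X
    delta_d = 1.0 + (null_fit.sigma_a2_hat / null_fit.sigma_e2_hat) * sv.lam
    se2 = null_fit.sigma_e2_hat
    xdx = float(Xt @ (Xt / delta_d)) / se2
    xdw = (Xt / delta_d) @ sv.Wt / se2
    wdw = sv.Wt.T @ (sv.Wt / delta_d[:, None]) / se2
    denom = xdx - float(xdw @ np.linalg.solve(wdw, xdw))
    xtr = float(X @ null_fit.residual_R)
    if denom <= 0:
        raise UndefinedTestError("LS variance is zero (monomorphic or degenerate SNP)")
    s = xtr * xtr / denom
    z = float(np.sign(xtr) * np.sqrt(s))
    return TestResult(s, z, _chi2_sf(s), xtr, "LS")


def qls_test(X: np.ndarray, null_fit: NullFit, phi: np.ndarray | None = None) -> TestResult:
    """Retrospective quasi-likelihood score (MASTOR) test."""
    sv = null_fit.solver
    X = np.asarray(X, float)
    if sv is not None:
        n = X.size
        raw = float(sv.phi_inv_one @ X / (2.0 * sv.one_phi_one))
        p_hat = min(max(raw, 0.0), 1.0)
        rpr = null_fit.r_phi_r
    else:
        if phi is None:
            raise ValueError("need phi when the fit has no solver")
        p_hat = blue_af(X, phi).value
        R = null_fit.residual_R
        rpr = float(R @ phi @ R)
    sigma_x2 = 2.0 * p_hat * (1.0 - p_hat)
    if sigma_x2 <= 0:
        raise UndefinedTestError("estimated allele frequency is 0 or 1")
    xtr = float(X @ null_fit.residual_R)
    s = xtr * xtr / (rpr * sigma_x2)
    z = float(np.sign(xtr) * np.sqrt(s))
    return TestResult(s, z, _chi2_sf(s), xtr, "QLS")


@dataclass
class ScanResult:
    """Per-SNP test results plus the residual matrix used as DNN input."""

    table: pd.DataFrame
    residuals: np.ndarray  # (n_snps, n) transformed phenotypic residuals

    def __len__(self) -> int:
        return len(self.table)


def genome_scan(
    dataset,
    phi: np.ndarray | None = None,
    ped: Pedigree | None = None,
    test_kind: str = "both",
    shared_trait: np.ndarray | None = None,
) -> ScanResult:
    """Run LS and/or QLS across all SNPs of a dataset.

    In the default per-SNP-trait mode each SNP has its own simulated
    trait and the null model is refitted per SNP.  In shared-trait mode
    a single phenotype vector is used and the null model is fitted once.
    """
    if phi is None:
        if ped is None:
            raise ValueError("need phi or ped")
        phi = kinship_matrix(ped)
    geno = dataset.genotypes
    W = dataset.covariates
    n_snps, n = geno.shape
    if ped is not None:
        f_idx, d_idx = partition(ped)
    else:
        f_idx = d_idx = None

    solver = CohortSolver.from_phi(phi, W)
    shared_fit = None
    if shared_trait is not None:
        shared_fit = fit_null(shared_trait, W, solver=solver)

    snp_ids = dataset.snp_ids or [f"snp{j+1}" for j in range(n_snps)]
    rows = []
    residuals = np.empty((n_snps, n))
    nan = float("nan")
    for j in range(n_snps):
        x = geno[j].astype(float)
        fit = shared_fit if shared_fit is not None else fit_null(
            dataset.traits[j], W, solver=solver
        )
        residuals[j] = fit.residual_R
        rec = {
            "snp_id": snp_ids[j],
            "xtr": float(x @ fit.residual_R),
            "sigma_e2_hat": fit.sigma_e2_hat,
            "sigma_a2_hat": fit.sigma_a2_hat,
            "flag": "",
        }
        if f_idx is not None:
            rec["p_f_hat"] = float(x[f_idx].sum() / (2.0 * f_idx.size))
            rec["p_d_hat"] = float(x[d_idx].sum() / (2.0 * d_idx.size))
        try:
            if test_kind in ("ls", "both"):
                r = ls_test(x, fit)
                rec.update(z_ls=r.z_stat, s_ls=r.s_stat, p_ls=r.p_value)
            if test_kind in ("qls", "both"):
                r = qls_test(x, fit)
                rec.update(z_qls=r.z_stat, s_qls=r.s_stat, p_qls=r.p_value)
        except UndefinedTestError as exc:
            rec["flag"] = "skipped"
            for col in ("z_ls", "s_ls", "p_ls", "z_qls", "s_qls", "p_qls"):
                rec.setdefault(col, nan)
        rows.append(rec)
    return ScanResult(pd.DataFrame(rows), residuals)
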