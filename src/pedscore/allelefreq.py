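"""Allele-frequency estimation on pedigrees.

Naive counting estimators restricted to a subset of individuals (all,
founders, descendants), the best linear unbiased estimator (BLUE) that
weights individuals by the inverse kinship matrix, and the analytic
covariance of any two naive subset estimators.  For subsets S and T of
an outbred pedigree with kinship matrix Phi,

    cov(p_S, p_T) = sigma_X^2 * (1_S' Phi 1_T) / (4 |S| |T|),

with sigma_X^2 = 2 p (1 - p) the marginal genotype variance under
Hardy-Weinberg equilibrium.  The familiar founder/descendant identities
are special cases of this bilinear form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AFEstimate",
    "naive_af",
    "blue_af",
    "af_cov_analytic",
    "af_var_analytic",
]


@dataclass(frozen=True)
class AFEstimate:
    value: float  # clipped to [0, 1]
    estimator_kind: str  # all | founders | descendants | blue
    n_used: int
    raw_value: float | None = None  # unclipped BLUE, for diagnostics

    @property
    def sigma_x2(self) -> float:
        """HWE genotype variance 2 p (1 - p) at the estimated frequency."""
        return 2.0 * self.value * (1.0 - self.value)


def naive_af(X: np.ndarray, subset: np.ndarray, kind: str = "all") -> AFEstimate:
    """Allele-counting estimate over a subset: sum(X_subset) / (2 |subset|)."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    x = np.asarray(X, dtype=float)[subset]
    return AFEstimate(float(x.sum() / (2.0 * x.size)), kind, int(x.size))


def blue_af(X: np.ndarray, phi: np.ndarray) -> AFEstimate:
    """Best linear unbiased allele-frequency estimator.

    p_hat = (1' Phi^-1 1)^-1 (1' Phi^-1 X) / 2 — generalized least
    squares of the genotype on a constant with covariance proportional
    to Phi.  Values outside [0, 1] (possible in finite samples) are
    clipped with a warning; the raw value is retained.
    """
    X = np.asarray(X, dtype=float)
    n = X.size
    w = np.linalg.solve(phi, np.ones(n))
    raw = float(w @ X / (2.0 * w.sum()))
    val = raw
    if not (0.0 <= raw <= 1.0):
        warnings.warn(f"BLUE allele frequency {raw:.4g} outside [0,1]; clipped")
        val = min(max(raw, 0.0), 1.0)
    return AFEstimate(val, "blue", n, raw_value=raw)


def af_cov_analytic(
    phi: np.ndarray,
    setS: np.ndarray,
    setT: np.ndarray,
    p: float,
) -> float:
    """Analytic covariance of two naive subset estimators at true frequency p."""
    setS = np.asarray(setS)
    setT = np.asarray(setT)
    if setS.size == 0 or setT.size == 0:
        raise ValueError("subsets must be non-empty")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    sigma_x2 = 2.0 * p * (1.0 - p)
    quad = float(phi[np.ix_(setS, setT)].sum())
    return sigma_x2 * quad / (4.0 * setS.size * setT.size)


def af_var_analytic(phi: np.ndarray, subset: np.ndarray, p: float) -> float:
    """Analytic variance of a naive subset estimator (S = T case)."""
    return af_cov_analytic(phi, subset, subset, p)


def blue_var_analytic(phi: np.ndarray, p: float) -> float:
    """Analytic variance of the BLUE: sigma_X^2 / (4 * 1' Phi^-1 1)."""
    n = phi.shape[0]
    denom = float(np.ones(n) @ np.linalg.solve(phi, np.ones(n)))
    return 2.0 * p * (1.0 - p) / (4.0 * denom)
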