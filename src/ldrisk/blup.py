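"""Best linear unbiased prediction (BLUP) from a linear mixed model.

Model: y = 1·mu + Z u + eps with u ~ N(0, sigma_u^2 I_p) and
eps ~ N(0, sigma_e^2 I_n). Variance components are estimated by REML,
profiled over the ratio gamma = sigma_u^2 / sigma_e^2 on the spectrum of
the genomic relationship matrix K = Z Z^T, which makes each likelihood
evaluation O(n) after a single eigendecomposition. Given the components,
the BLUP of the random effects is

    u_hat = Z^T (Z Z^T + lambda I)^{-1} (y - mu),   lambda = sigma_e^2 / sigma_u^2,

identical (via the Woodbury identity) to ridge regression with penalty
lambda, and predictions are mu + Z_new u_hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import minimize_scalar

__all__ = ["VarianceComponents", "estimate_variance_components", "blup_predict"]


@dataclass(frozen=True)
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float

    def __post_init__(self):
        if self.sigma_u2 < 0 or self.sigma_e2 < 0 or \
                (self.sigma_u2 == 0 and self.sigma_e2 == 0):
            raise ValueError("variance components must be >= 0 and not both 0")

    @property
    def ridge_penalty(self) -> float:
        if self.sigma_u2 == 0:
            return np.inf
        return self.sigma_e2 / self.sigma_u2


def _reml_neg_loglik(log_gamma, d, yt2, n):
    """-2 REML log-likelihood (up to a constant), intercept projected out.

    ``d``/``yt2`` are eigenvalues of K and squared rotated centred
    responses on the (n-1)-dim complement of the intercept.
    """
    gamma = np.exp(log_gamma)
    h = gamma * d + 1.0
    quad = np.sum(yt2 / h)
    sigma_e2 = quad / (n - 1)
    return (n - 1) * np.log(sigma_e2) + np.sum(np.log(h))


def estimate_variance_components(Z: np.ndarray, y: np.ndarray,
                                 ) -> VarianceComponents:
    """REML estimates of (sigma_u^2, sigma_e^2) via the spectrum of Z Z^T.

    The intercept (the only fixed effect) is handled by restricting the
    likelihood to contrasts orthogonal to 1. Falls back to a
    Haseman–Elston-style method-of-moments fit with a warning if the
    profile optimisation does not converge.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    n = y.size
    if n < 2 or Z.shape[0] != n:
        raise ValueError("need n >= 2 samples with matching genotype rows")
    K = Z @ Z.T
    # orthonormal basis of the contrast space orthogonal to the intercept
    C = null_space(np.ones((1, n)))
    Cy = C.T @ y
    CKC = C.T @ K @ C
    d, U = np.linalg.eigh((CKC + CKC.T) / 2.0)
    d = np.clip(d, 0.0, None)
    yt2 = (U.T @ Cy) ** 2
    res = minimize_scalar(_reml_neg_loglik, bounds=(-12.0, 12.0),
                          args=(d, yt2, n), method="bounded",
                          options={"xatol": 1e-8})
    if res.success:
        gamma = float(np.exp(res.x))
        h = gamma * d + 1.0
        sigma_e2 = float(np.sum(yt2 / h) / (n - 1))
        return VarianceComponents(gamma * sigma_e2, sigma_e2)
    warnings.warn("REML profile optimisation failed; falling back to "
                  "method-of-moments estimates", RuntimeWarning)
    yc = y - y.mean()
    # regress y_i y_j on K_ij over off-diagonal pairs
    off = ~np.eye(n, dtype=bool)
    num = float((np.outer(yc, yc)[off] * K[off]).sum())
    den = float((K[off] ** 2).sum())
    sigma_u2 = max(num / den, 0.0)
    sigma_e2 = max(float(yc @ yc / (n - 1)) - sigma_u2 * float(np.trace(K)) / n, 1e-12)
    return VarianceComponents(sigma_u2, sigma_e2)


def blup_predict(Z_train: np.ndarray, y_train: np.ndarray, Z_test: np.ndarray,
                 vc: VarianceComponents) -> np.ndarray:
    """Predictions mu + Z_test u_hat with the training mean as intercept."""
    Z_train = np.asarray(Z_train, dtype=np.float64)
    Z_test = np.asarray(Z_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64).reshape(-1)
    if Z_train.shape[0] != y_train.size or Z_train.shape[1] != Z_test.shape[1]:
        raise ValueError("inconsistent dimensions between genotypes and phenotypes")
    mu = y_train.mean()
    if vc.sigma_u2 == 0.0:
        return np.full(Z_test.shape[0], mu)
    lam = vc.ridge_penalty
    n = y_train.size
    K = Z_train @ Z_train.T
    u_hat = Z_train.T @ np.linalg.solve(K + lam * np.eye(n), y_train - mu)
    return mu + Z_test @ u_hat
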