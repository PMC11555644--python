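"""Minimal Newton/IRLS logistic regression used across the pipeline.

A small dedicated fitter keeps the per-SNP association scans fast (thousands
of fits per run) and gives one consistent numerical path for betas, Wald
standard errors and score statistics. Agreement with statsmodels is asserted
in the test suite.
"""

from __future__ import annotations

import numpy as np


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (typically quasi-complete separation)."""


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                 tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Fit logit P(y=1) = X beta by Newton-Raphson.

    Returns (beta, cov) where cov is the inverse observed information
    (Wald covariance). Raises :class:`SeparationError` on non-convergence or
    diverging coefficients.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # log-likelihood for convergence check
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.abs(beta).max() > 1e3:
            raise SeparationError("diverging coefficients (separation?)")
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    else:
        raise SeparationError("IRLS did not converge")
    if np.abs(beta).max() > 15:
        # a log-odds beyond +-15 on (standardized) predictors is numerically
        # a perfectly separating direction, not a finite MLE
        raise SeparationError("coefficient escaping to infinity (separation)")
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("singular information at optimum") from exc
    return beta, cov


def null_model(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the covariate-only null model; return (beta, mu, w)."""
    beta, _ = fit_logistic(X, y)
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return beta, mu, mu * (1.0 - mu)


def design_matrix(samples, covariates: tuple[str, ...] = ("sex", "age"),
                  pcs: np.ndarray | None = None) -> np.ndarray:
    """Build [1 | covariates | PCs] from a sample table.

    sex enters as an indicator (female=1); age is standardized to keep the
    Newton steps well-scaled. Requesting age with missing values raises.
    """
    cols = [np.ones(len(samples))]
    if "sex" in covariates:
        cols.append((samples["sex"] == "female").to_numpy(float))
    if "age" in covariates:
        age = samples["age"].to_numpy(float)
        if np.isnan(age).any():
            raise ValueError("age covariate requested but ages are missing")
        sd = age.std()
        cols.append((age - age.mean()) / (sd if sd > 0 else 1.0))
    X = np.column_stack(cols)
    if pcs is not None and pcs.size:
        X = np.column_stack([X, pcs])
    return X
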