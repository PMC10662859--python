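"""Quasi-Poisson log-linear regression fitted by IRLS.

The mean model is Poisson with a log link; the variance is phi * mu with the
dispersion phi estimated from the Pearson statistic, so standard errors are
robust to overdispersion in daily counts.  Each IRLS step solves the
weighted least-squares problem through a QR decomposition of the weighted
design rather than the normal equations — the calendar-time spline
contributes ~78 columns and the cross-basis 15 more, and squaring the
condition number there is avoidable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

__all__ = [
    "FitResult",
    "SingularDesignError",
    "QuasiPoissonGLM",
    "fit_quasipoisson",
    "pearson_dispersion",
]


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; carries the offending column labels."""

    def __init__(self, columns: list):
        self.columns = columns
        super().__init__(f"singular design: redundant columns {columns}")


@dataclass
class FitResult:
    """Coefficients, covariance and dispersion of a quasi-Poisson fit."""

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    deviance: float
    n_obs: int
    n_params: int
    column_labels: list[str]
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        p = self.coefficients.size
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape does not match coefficients")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance not symmetric")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_obs <= self.n_params:
            raise ValueError("need n_obs > n_params")

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "dispersion": float(self.dispersion),
            "deviance": float(self.deviance),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "column_labels": list(self.column_labels),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            coefficients=np.asarray(d["coefficients"], float),
            covariance=np.asarray(d["covariance"], float),
            dispersion=float(d["dispersion"]),
            deviance=float(d["deviance"]),
            n_obs=int(d["n_obs"]),
            n_params=int(d["n_params"]),
            column_labels=list(d["column_labels"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
        )


def pearson_dispersion(
    y: Sequence[float] | np.ndarray,
    mu: Sequence[float] | np.ndarray,
    n_params: int,
) -> float:
    """Pearson chi-square divided by residual degrees of freedom."""
    yv = np.asarray(y, float)
    mv = np.asarray(mu, float)
    if np.any(mv <= 0):
        raise ValueError("mu must be strictly positive")
    n = yv.size
    if n <= n_params:
        raise ValueError(f"n={n} must exceed n_params={n_params}")
    return float(np.sum((yv - mv) ** 2 / mv) / (n - n_params))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(ylogy - (y - mu)))


class QuasiPoissonGLM(BaseEstimator):
    """Quasi-Poisson regression estimator (log link, IRLS).

    Parameters
    ----------
    tol : float
        Convergence threshold on the relative deviance change.
    max_iter : int
        IRLS iteration cap; if reached the result is flagged unconverged.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) coefficient vector (first entry is the intercept when the
        design's first column is constant — the estimator adds no column).
    cov_ : (p, p) covariance, phi * (X' W X)^-1 with W = diag(mu_hat).
    dispersion_ : Pearson dispersion phi.
    deviance_, converged_, n_iter_, result_ (a :class:`FitResult`).
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100) -> None:
        self.tol = tol
        self.max_iter = max_iter

    def fit(
        self,
        X: np.ndarray,
        y: Sequence[float] | np.ndarray,
        row_mask: np.ndarray | None = None,
        column_labels: Sequence[str] | None = None,
    ) -> "QuasiPoissonGLM":
        Xf = np.asarray(X, dtype=float)
        yf = np.asarray(y, dtype=float)
        if Xf.ndim != 2 or yf.ndim != 1 or Xf.shape[0] != yf.size:
            raise ValueError("X must be 2-D and align with 1-D y")
        if np.any(yf < 0) or np.any(yf != np.round(yf)):
            raise ValueError("y must contain non-negative integer counts")
        if row_mask is not None:
            row_mask = np.asarray(row_mask, dtype=bool)
            Xf, yf = Xf[row_mask], yf[row_mask]
        if not np.all(np.isfinite(Xf)):
            raise ValueError("design matrix has non-finite entries on fitted rows")
        n, p = Xf.shape
        labels = (
            list(column_labels)
            if column_labels is not None
            else [f"x{i}" for i in range(p)]
        )
        if len(labels) != p:
            raise ValueError("column_labels length mismatch")

        # rank check with column pivoting so offenders can be named
        _, Rp, piv = scipy.linalg.qr(Xf, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rp))
        rank_tol = diag.max() * max(n, p) * np.finfo(float).eps
        rank = int(np.sum(diag > rank_tol))
        if rank < p:
            raise SingularDesignError([labels[i] for i in piv[rank:]])

        mu = yf + 0.5  # guards log(0) with many zero-count days
        eta = np.log(mu)
        dev = _poisson_deviance(yf, mu)
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            w = np.sqrt(mu)
            z = eta + (yf - mu) / mu
            Q, R = np.linalg.qr(w[:, None] * Xf)
            beta = scipy.linalg.solve_triangular(R, Q.T @ (w * z))
            eta = Xf @ beta
            mu = np.exp(eta)
            new_dev = _poisson_deviance(yf, mu)
            if abs(new_dev - dev) <= self.tol * (abs(dev) + 0.1):
                dev = new_dev
                converged = True
                break
            dev = new_dev

        phi = pearson_dispersion(yf, mu, p)
        Rinv = scipy.linalg.solve_triangular(R, np.eye(p))
        cov = phi * (Rinv @ Rinv.T)
        cov = (cov + cov.T) / 2.0

        self.coef_ = beta
        self.cov_ = cov
        self.dispersion_ = phi
        self.deviance_ = dev
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.column_labels_ = labels
        self.result_ = FitResult(
            coefficients=beta,
            covariance=cov,
            dispersion=phi,
            deviance=dev,
            n_obs=n,
            n_params=p,
            column_labels=labels,
            converged=converged,
            n_iter=n_iter,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Expected counts exp(X beta)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")
        return np.exp(np.asarray(X, float) @ self.coef_)


def fit_quasipoisson(
    y: Sequence[float] | np.ndarray,
    X: np.ndarray,
    row_mask: np.ndarray | None = None,
    column_labels: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FitResult:
    """Functional wrapper over :class:`QuasiPoissonGLM`."""
    est = QuasiPoissonGLM(tol=tol, max_iter=max_iter)
    est.fit(X, y, row_mask=row_mask, column_labels=column_labels)
    return est.result_
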