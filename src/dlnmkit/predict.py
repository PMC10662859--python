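"""Relative-risk prediction from a fitted cross-basis model.

Effects are expressed relative to a centering exposure value (here the
fitted minimum-risk value): for grid value x and lag l the contrast vector
over cross-basis columns is

    z(x, l)_{(j,k)} = (R_j(x) - R_j(center)) * C_k(l)

so log RR = z' beta and Var = z' Sigma z (delta method on the linear
predictor scale).  Cumulative effects over lags 0..L' use the summed
contrast Z(x, L') = sum_{l<=L'} z(x, l), which also yields the correct
covariance between lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .basis import evaluate_basis
from .crossbasis import CrossBasis
from .glm import FitResult

__all__ = ["RRSurface", "predict_rr", "find_min_risk", "rr_table"]


@dataclass
class RRSurface:
    """Log-RR and SE on an exposure x lag grid, plus lag-cumulative summaries.

    ``cum_log_rr[g, L']`` is the cumulative effect over lags 0..L'.  At the
    centering value every entry is exactly zero with zero SE.
    """

    exposure_grid: np.ndarray
    lags: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    cum_log_rr: np.ndarray
    cum_se: np.ndarray
    center: float
    level: float = 0.95

    def __post_init__(self) -> None:
        G, L = self.exposure_grid.size, self.lags.size
        for name in ("log_rr", "se", "cum_log_rr", "cum_se"):
            if getattr(self, name).shape != (G, L):
                raise ValueError(f"{name} must have shape {(G, L)}")
        if np.any(self.se < 0) or np.any(self.cum_se < 0):
            raise ValueError("standard errors must be non-negative")

    @property
    def z_crit(self) -> float:
        return float(norm.ppf(0.5 + self.level / 2.0))

    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    def rr_ci(self) -> tuple[np.ndarray, np.ndarray]:
        h = self.z_crit * self.se
        return np.exp(self.log_rr - h), np.exp(self.log_rr + h)

    def cum_rr(self) -> np.ndarray:
        return np.exp(self.cum_log_rr)

    def cum_rr_ci(self) -> tuple[np.ndarray, np.ndarray]:
        h = self.z_crit * self.cum_se
        return np.exp(self.cum_log_rr - h), np.exp(self.cum_log_rr + h)

    def overall(self) -> tuple[np.ndarray, np.ndarray]:
        """Overall cumulative (lag 0..L) log RR curve and its SE."""
        return self.cum_log_rr[:, -1], self.cum_se[:, -1]


def _cb_indices(fit: FitResult, labels: Sequence[str]) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(fit.column_labels)}
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise ValueError(f"cross-basis columns not found in fit: {missing}")
    return np.array([pos[lab] for lab in labels], dtype=int)


def _contrast_tensors(cb: CrossBasis, grid: np.ndarray, center: float):
    R = evaluate_basis(grid, cb.var_spec_)
    Rc = evaluate_basis(np.array([center]), cb.var_spec_)
    D = R - Rc  # (G, vj)
    C = cb.lag_basis_  # (L+1, vk)
    G, vj = D.shape
    vk = C.shape[1]
    z = np.einsum("gj,lk->gljk", D, C).reshape(G, C.shape[0], vj * vk)
    return z


def predict_rr(
    fit: FitResult,
    cb: CrossBasis,
    exposure_grid: Sequence[float] | np.ndarray,
    center: float,
    level: float = 0.95,
    labels: Sequence[str] | None = None,
) -> RRSurface:
    """Lag-specific and lag-cumulative RR surface centered at ``center``.

    ``labels`` names the cross-basis columns inside ``fit`` (defaults to the
    transformer's own ``cb_j_k`` names); they must all be present in the fit.
    """
    grid = np.atleast_1d(np.asarray(exposure_grid, float))
    if labels is None:
        labels = cb.column_names()
    idx = _cb_indices(fit, labels)
    beta = fit.coefficients[idx]
    sigma = fit.covariance[np.ix_(idx, idx)]

    z = _contrast_tensors(cb, grid, center)  # (G, L+1, p)
    log_rr = z @ beta
    var = np.einsum("glp,pq,glq->gl", z, sigma, z)
    se = np.sqrt(np.clip(var, 0.0, None))

    zc = np.cumsum(z, axis=1)
    cum_log_rr = zc @ beta
    cum_var = np.einsum("glp,pq,glq->gl", zc, sigma, zc)
    cum_se = np.sqrt(np.clip(cum_var, 0.0, None))

    return RRSurface(
        exposure_grid=grid,
        lags=np.arange(cb.maxlag + 1),
        log_rr=log_rr,
        se=se,
        cum_log_rr=cum_log_rr,
        cum_se=cum_se,
        center=float(center),
        level=level,
    )


def find_min_risk(
    fit: FitResult,
    cb: CrossBasis,
    search_grid: Sequence[float] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> float:
    """Exposure value minimising the overall cumulative risk curve.

    Two passes: the curve is first predicted with a provisional center (the
    grid median — the argmin of the curve does not depend on the centering,
    which only shifts the curve by a constant on the log scale), then the
    grid argmin is returned.  A flat curve (range < 1e-12) triggers a
    warning and returns the provisional median.
    """
    grid = np.atleast_1d(np.asarray(search_grid, float))
    provisional = float(np.median(grid))
    surf = predict_rr(fit, cb, grid, center=provisional, labels=labels)
    curve, _ = surf.overall()
    if np.ptp(curve) < 1e-12:
        warnings.warn(
            "overall cumulative curve is flat; returning the grid median",
            RuntimeWarning,
        )
        return provisional
    return float(grid[int(np.argmin(curve))])


def rr_table(
    surface: RRSurface,
    at: Mapping[str, float],
    level: float | None = None,
) -> pd.DataFrame:
    """Tidy RR table at named exposure values (min, deciles, max, mode...).

    One row per (exposure value, lag) for lag-specific effects
    (``kind="lag"``) and per (exposure value, lag window 0..L') for
    cumulative effects (``kind="cumulative"``).  ``significant`` flags a
    two-sided Wald CI excluding RR = 1.
    """
    if level is None:
        level = surface.level
    zq = float(norm.ppf(0.5 + level / 2.0))
    rows = []
    for name, value in at.items():
        hits = np.nonzero(np.isclose(surface.exposure_grid, value, atol=1e-9))[0]
        if hits.size == 0:
            raise ValueError(
                f"requested value {value!r} ({name}) is not on the surface grid"
            )
        g = int(hits[0])
        for kind, lrr, se in (
            ("lag", surface.log_rr[g], surface.se[g]),
            ("cumulative", surface.cum_log_rr[g], surface.cum_se[g]),
        ):
            lo = np.exp(lrr - zq * se)
            hi = np.exp(lrr + zq * se)
            for li, lag in enumerate(surface.lags):
                rows.append(
                    {
                        "value_label": name,
                        "factor_value": float(value),
                        "kind": kind,
                        "lag": int(lag),
                        "lag_range": f"0-{int(lag)}" if kind == "cumulative" else str(int(lag)),
                        "rr": float(np.exp(lrr[li])),
                        "ci_lo": float(lo[li]),
                        "ci_hi": float(hi[li]),
                        "significant": bool(lo[li] > 1.0 or hi[li] < 1.0),
                    }
                )
    return pd.DataFrame(rows)
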