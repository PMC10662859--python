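"""Cross-basis construction: the exposure-lag-response design sub-matrix.

The cross-basis encodes a smooth bidimensional surface f(x, lag) as a tensor
combination of an exposure basis R (columns j) and a lag basis C (columns k),
summed over the lag window:

    cb[t, (j, k)] = sum_{lag=0..L} R_j(x_{t-lag}) * C_k(lag)

Rows with incomplete lag history (the first ``maxlag`` days) are flagged and
excluded from fitting rather than imputed.  Column order is j-major:
``cb_0_0, cb_0_1, ..., cb_0_{vk-1}, cb_1_0, ...``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .basis import BasisSpec, evaluate_basis

__all__ = ["LagMatrix", "lag_matrix", "CrossBasis", "build_crossbasis"]


@dataclass
class LagMatrix:
    """T x (L+1) matrix of lagged exposures; column lag is the value lag days ago.

    Entries with t < lag have no history and are NaN; ``valid_from`` is the
    first row (0-based) with a complete history, i.e. ``maxlag`` itself.
    """

    values: np.ndarray
    maxlag: int

    @property
    def valid_from(self) -> int:
        return self.maxlag

    @property
    def complete_rows(self) -> np.ndarray:
        mask = np.zeros(self.values.shape[0], dtype=bool)
        mask[self.maxlag:] = True
        return mask


def lag_matrix(series: Sequence[float] | np.ndarray, maxlag: int) -> LagMatrix:
    """Build the lagged exposure matrix; lag 0 is the same-day value."""
    x = np.asarray(series, dtype=float)
    if maxlag < 0:
        raise ValueError("maxlag must be >= 0")
    if x.size <= maxlag:
        raise ValueError(f"series length {x.size} must exceed maxlag {maxlag}")
    T = x.size
    out = np.full((T, maxlag + 1), np.nan)
    for lag in range(maxlag + 1):
        out[lag:, lag] = x[: T - lag]
    return LagMatrix(values=out, maxlag=maxlag)


class CrossBasis(BaseEstimator, TransformerMixin):
    """Cross-basis transformer for one exposure series.

    ``fit`` places knots from the observed exposure distribution (exposure
    dimension) and from the integer lag sequence 0..maxlag (lag dimension);
    ``transform`` builds the T x (var_df * lag_df) design sub-matrix.  The
    lag basis is evaluated only at integer lags; exposure values outside the
    observed range follow the basis extrapolation contract.

    Parameters
    ----------
    maxlag : int
        Longest lag (days) of the exposure window.
    var_df, var_degree : int
        Dimension and degree of the (B-spline) exposure basis.
    lag_df : int
        Dimension of the (natural cubic) lag basis.
    var_kind, lag_kind : str
        Spline family per dimension.
    var_intercept, lag_intercept : bool
        Intercept conventions; defaults (False, True) are the standard
        identifiable cross-basis parameterisation next to a model intercept.
    """

    def __init__(
        self,
        maxlag: int = 14,
        var_df: int = 3,
        var_degree: int = 2,
        lag_df: int = 5,
        var_kind: str = "bspline",
        lag_kind: str = "natural_cubic",
        var_intercept: bool = False,
        lag_intercept: bool = True,
    ) -> None:
        self.maxlag = maxlag
        self.var_df = var_df
        self.var_degree = var_degree
        self.lag_df = lag_df
        self.var_kind = var_kind
        self.lag_kind = lag_kind
        self.var_intercept = var_intercept
        self.lag_intercept = lag_intercept

    # -- sklearn API ---------------------------------------------------
    def fit(self, X: Sequence[float] | np.ndarray, y=None) -> "CrossBasis":
        x = np.asarray(X, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError("exposure series contains non-finite values")
        self.var_spec_ = BasisSpec.from_data(
            x,
            df=self.var_df,
            kind=self.var_kind,
            degree=self.var_degree,
            intercept=self.var_intercept,
        )
        self.lag_spec_ = BasisSpec.from_data(
            np.arange(self.maxlag + 1, dtype=float),
            df=self.lag_df,
            kind=self.lag_kind,
            degree=3,
            intercept=self.lag_intercept,
        )
        # lag basis evaluated once at the integer lags
        self.lag_basis_ = evaluate_basis(
            np.arange(self.maxlag + 1, dtype=float), self.lag_spec_
        )
        self.column_labels_ = [
            (j, k) for j in range(self.var_spec_.df) for k in range(self.lag_spec_.df)
        ]
        return self

    def transform(self, X: Sequence[float] | np.ndarray) -> np.ndarray:
        if not hasattr(self, "var_spec_"):
            raise RuntimeError("CrossBasis must be fitted before transform")
        x = np.asarray(X, dtype=float).ravel()
        L = self.maxlag
        R = evaluate_basis(x, self.var_spec_)  # (T, vj)
        C = self.lag_basis_  # (L+1, vk)
        T, vj = R.shape
        vk = C.shape[1]
        out = np.full((T, vj * vk), np.nan)
        # lagged stack of each exposure-basis column, contracted against C
        for j in range(vj):
            lagged = np.full((T, L + 1), np.nan)
            for lag in range(L + 1):
                lagged[lag:, lag] = R[: T - lag, j]
            block = lagged[L:] @ C
            out[L:, j * vk : (j + 1) * vk] = block
        return out

    # -- conveniences ---------------------------------------------------
    @property
    def n_columns_(self) -> int:
        return self.var_spec_.df * self.lag_spec_.df

    def complete_rows(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        mask[self.maxlag:] = True
        return mask

    def column_names(self) -> list[str]:
        return [f"cb_{j}_{k}" for j, k in self.column_labels_]

    def to_frame(self, X: Sequence[float] | np.ndarray) -> pd.DataFrame:
        """Labeled CSV-ready export for debugging and parity checks."""
        return pd.DataFrame(self.transform(X), columns=self.column_names())


def build_crossbasis(
    series: Sequence[float] | np.ndarray,
    maxlag: int,
    var_spec: BasisSpec | None = None,
    lag_spec: BasisSpec | None = None,
    **kwargs,
) -> tuple[np.ndarray, CrossBasis]:
    """Fit-and-transform convenience; returns (matrix, fitted CrossBasis).

    If explicit specs are given their df/degree/kind/intercept are used for
    knot placement on the observed data.
    """
    params = dict(maxlag=maxlag, **kwargs)
    if var_spec is not None:
        params.update(
            var_df=var_spec.df,
            var_degree=var_spec.degree,
            var_kind=var_spec.kind,
            var_intercept=var_spec.intercept,
        )
    if lag_spec is not None:
        params.update(
            lag_df=lag_spec.df,
            lag_kind=lag_spec.kind,
            lag_intercept=lag_spec.intercept,
        )
    cb = CrossBasis(**params).fit(series)
    return cb.transform(series), cb
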