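"""One-dimensional spline bases for exposure, lag and calendar-time dimensions.

Two spline families are provided, matching standard practice in distributed
lag non-linear modelling:

* **B-splines** (default quadratic, ``degree=2``) for the exposure-response
  dimension, evaluated from the Cox-de Boor knot representation with
  polynomial extrapolation of the terminal pieces beyond the boundary knots.
* **Natural cubic splines** for the lag-response dimension and for the
  long-term/seasonal calendar-time trend: cubic splines constrained to have
  zero second derivative at the boundary knots and extended linearly beyond
  them.

Knot counts follow the convention that a basis of dimension ``df`` needs
``df - degree - intercept`` internal knots for a B-spline and
``df - 1 - intercept`` internal knots for a natural cubic spline; internal
knots are placed at equally spaced quantiles of the observed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "KnotSet",
    "InfeasibleBasisError",
    "DegenerateRangeError",
    "place_knots",
    "bspline_basis",
    "natural_cubic_basis",
    "evaluate_basis",
    "time_spline",
    "dow_indicators",
    "DOW_LABELS",
]


class InfeasibleBasisError(ValueError):
    """Requested df is too small for the spline kind/degree/intercept."""


class DegenerateRangeError(ValueError):
    """The values from which knots are placed have zero range."""


class KnotSet(NamedTuple):
    internal: tuple[float, ...]
    boundary: tuple[float, float]


def _n_internal_knots(kind: str, df: int, degree: int, intercept: bool) -> int:
    if kind == "bspline":
        n = df - degree - int(intercept)
    elif kind == "natural_cubic":
        n = df - 1 - int(intercept)
    else:
        raise ValueError(f"unknown basis kind {kind!r}")
    return n


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of a one-dimensional spline basis.

    Parameters
    ----------
    kind : {"bspline", "natural_cubic"}
    df : int
        Dimension (number of columns) of the basis.
    degree : int
        Polynomial degree; only meaningful for ``kind="bspline"`` (natural
        cubic splines are cubic by definition).
    intercept : bool
        Whether the basis spans the constant function on its own.  When
        False the constant direction is removed so the basis can sit next to
        a model intercept without collinearity.
    internal_knots : tuple of float
        Strictly inside the boundary interval, non-decreasing.
    boundary_knots : (lo, hi)
    """

    kind: Literal["bspline", "natural_cubic"]
    df: int
    degree: int
    intercept: bool
    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        if self.df < 1:
            raise InfeasibleBasisError(f"df must be >= 1, got {self.df}")
        if self.kind == "bspline" and self.degree < 1:
            raise InfeasibleBasisError(f"degree must be >= 1, got {self.degree}")
        lo, hi = self.boundary_knots
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise DegenerateRangeError(
                f"boundary knots must satisfy lo < hi, got ({lo}, {hi})"
            )
        ik = np.asarray(self.internal_knots, dtype=float)
        if ik.size and (np.any(np.diff(ik) < 0) or ik.min() <= lo or ik.max() >= hi):
            raise ValueError(
                "internal knots must be non-decreasing and strictly inside "
                f"({lo}, {hi}); got {self.internal_knots}"
            )
        expected = _n_internal_knots(self.kind, self.df, self.degree, self.intercept)
        if expected < 0:
            raise InfeasibleBasisError(
                f"df={self.df} infeasible for kind={self.kind}, "
                f"degree={self.degree}, intercept={self.intercept}"
            )
        if len(self.internal_knots) != expected:
            raise ValueError(
                f"{self.kind} with df={self.df}, degree={self.degree}, "
                f"intercept={self.intercept} needs {expected} internal knots, "
                f"got {len(self.internal_knots)}"
            )

    @classmethod
    def from_data(
        cls,
        values: Sequence[float] | np.ndarray,
        df: int,
        kind: Literal["bspline", "natural_cubic"] = "bspline",
        degree: int = 2,
        intercept: bool = False,
    ) -> "BasisSpec":
        """Build a spec with knots placed from observed values."""
        knots = place_knots(values, df, kind, degree=degree, intercept=intercept)
        return cls(
            kind=kind,
            df=df,
            degree=degree,
            intercept=intercept,
            internal_knots=knots.internal,
            boundary_knots=knots.boundary,
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "df": self.df,
            "degree": self.degree,
            "intercept": self.intercept,
            "internal_knots": [float(k) for k in self.internal_knots],
            "boundary_knots": [float(k) for k in self.boundary_knots],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            kind=d["kind"],
            df=int(d["df"]),
            degree=int(d["degree"]),
            intercept=bool(d["intercept"]),
            internal_knots=tuple(float(k) for k in d["internal_knots"]),
            boundary_knots=(float(d["boundary_knots"][0]), float(d["boundary_knots"][1])),
        )


@dataclass
class BasisMatrix:
    """Evaluated basis: an (n_points, df) matrix plus its provenance."""

    values: np.ndarray
    spec: BasisSpec
    eval_points: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.eval_points = np.asarray(self.eval_points, dtype=float)
        if self.values.shape != (self.eval_points.size, self.spec.df):
            raise ValueError(
                f"basis matrix shape {self.values.shape} inconsistent with "
                f"{self.eval_points.size} points x df={self.spec.df}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("basis matrix contains non-finite entries")


def place_knots(
    values: Sequence[float] | np.ndarray,
    df: int,
    kind: Literal["bspline", "natural_cubic"],
    degree: int = 2,
    intercept: bool = False,
) -> KnotSet:
    """Place boundary and internal knots from observed values.

    Boundary knots are the observed min and max.  The number of internal
    knots is ``df - degree - intercept`` (B-spline) or ``df - 1 - intercept``
    (natural cubic); they sit at equally spaced quantiles of ``values``
    (one knot -> median, three knots -> quartiles, ...).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot place knots on empty values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values contain non-finite entries")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise DegenerateRangeError("degenerate range: all values are equal")
    n_int = _n_internal_knots(kind, df, degree, intercept)
    if n_int < 0:
        raise InfeasibleBasisError(
            f"infeasible basis: df={df}, kind={kind}, degree={degree}, "
            f"intercept={intercept} implies {n_int} internal knots"
        )
    if n_int:
        probs = np.linspace(0.0, 1.0, n_int + 2)[1:-1]
        internal = tuple(float(q) for q in np.quantile(v, probs))
    else:
        internal = ()
    return KnotSet(internal=internal, boundary=(lo, hi))


def _bspline_knot_vector(spec: BasisSpec) -> np.ndarray:
    lo, hi = spec.boundary_knots
    k = spec.degree
    return np.concatenate(
        [np.full(k + 1, lo), np.asarray(spec.internal_knots, float), np.full(k + 1, hi)]
    )


def _bspline_full_design(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """All Cox-de Boor basis columns (including the leading one)."""
    t = _bspline_knot_vector(spec)
    return BSpline.design_matrix(x, t, spec.degree, extrapolate=True).toarray()


def bspline_basis(x: Sequence[float] | np.ndarray, spec: BasisSpec) -> BasisMatrix:
    """Evaluate a B-spline basis.

    The basis is built on the padded knot sequence (boundary knots repeated
    ``degree + 1`` times).  With ``intercept=True`` all columns are kept and
    rows sum to one inside the boundary (partition of unity); with
    ``intercept=False`` the first column is dropped.  Points beyond the
    boundary knots are evaluated by polynomial extrapolation of the terminal
    spans, so prediction grids may touch or slightly exceed the observed
    range deterministically.
    """
    if spec.kind != "bspline":
        raise ValueError(f"spec.kind must be 'bspline', got {spec.kind!r}")
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(xv)):
        raise ValueError("x contains non-finite entries")
    full = _bspline_full_design(xv, spec)
    mat = full if spec.intercept else full[:, 1:]
    return BasisMatrix(values=mat, spec=spec, eval_points=xv)


def _natural_transform(spec: BasisSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (knot_vector, Z) where the natural basis is B(x) @ Z.

    Z spans the null space of the boundary second-derivative constraints of
    the full cubic B-spline basis; for intercept=False the constant
    direction is additionally removed (coordinates of the constant function
    are Z.T @ 1 by partition of unity).
    """
    lo, hi = spec.boundary_knots
    t = np.concatenate(
        [np.full(4, lo), np.asarray(spec.internal_knots, float), np.full(4, hi)]
    )
    n_b = len(t) - 4  # number of cubic B-spline basis functions
    constraints = BSpline(t, np.eye(n_b), 3).derivative(2)(np.array([lo, hi]))
    Z = null_space(constraints)  # (n_b, n_b - 2), orthonormal columns
    if not spec.intercept:
        u = Z.T @ np.ones(n_b)
        u /= np.linalg.norm(u)
        Z = Z @ null_space(u[None, :])
    return t, Z


def natural_cubic_basis(
    x: Sequence[float] | np.ndarray, spec: BasisSpec
) -> BasisMatrix:
    """Evaluate a natural cubic spline basis.

    Cubic spline constrained to zero second derivative at both boundary
    knots; beyond the boundaries every basis function is continued linearly
    (first-order Taylor expansion at the boundary), so the span is affine
    outside the observed range.
    """
    if spec.kind != "natural_cubic":
        raise ValueError(f"spec.kind must be 'natural_cubic', got {spec.kind!r}")
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(xv)):
        raise ValueError("x contains non-finite entries")
    t, Z = _natural_transform(spec)
    lo, hi = spec.boundary_knots
    inside = np.clip(xv, lo, hi)
    base = BSpline.design_matrix(inside, t, 3, extrapolate=False).toarray() @ Z
    below = xv < lo
    above = xv > hi
    if below.any() or above.any():
        n_b = Z.shape[0]
        deriv = BSpline(t, np.eye(n_b), 3).derivative(1)(np.array([lo, hi])) @ Z
        if below.any():
            base[below] += np.outer(xv[below] - lo, deriv[0])
        if above.any():
            base[above] += np.outer(xv[above] - hi, deriv[1])
    return BasisMatrix(values=base, spec=spec, eval_points=xv)


def evaluate_basis(x: Sequence[float] | np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Evaluate whichever basis family ``spec`` describes; returns the matrix."""
    if spec.kind == "bspline":
        return bspline_basis(x, spec).values
    return natural_cubic_basis(x, spec).values


def time_spline(
    day_index: Sequence[int] | np.ndarray,
    df_per_year: int,
    days_per_year: float = 365.25,
    total_df: int | None = None,
) -> BasisMatrix:
    """Natural cubic spline of the day index for seasonal/long-term trends.

    Total dimension is ``round(df_per_year * n_days / days_per_year)`` unless
    ``total_df`` is given explicitly (some analyses fix the total instead of
    the per-year rate).  The basis excludes the constant so it can accompany
    a model intercept.
    """
    idx = np.asarray(day_index, dtype=float)
    if idx.size < 2 or not np.all(np.diff(idx) == 1):
        raise ValueError("day_index must be consecutive integers")
    if total_df is None:
        if df_per_year < 1:
            raise ValueError("df_per_year must be >= 1")
        total_df = int(round(df_per_year * idx.size / days_per_year))
    if total_df < 1:
        raise ValueError(f"total time-spline df must be >= 1, got {total_df}")
    spec = BasisSpec.from_data(
        idx, df=total_df, kind="natural_cubic", intercept=False
    )
    return natural_cubic_basis(idx, spec)


DOW_LABELS = ("dow_tue", "dow_wed", "dow_thu", "dow_fri", "dow_sat", "dow_sun")


def dow_indicators(dates: Sequence | pd.DatetimeIndex) -> np.ndarray:
    """Day-of-week dummy matrix with Monday as the reference level.

    Returns an (n, 6) 0/1 matrix with columns Tuesday..Sunday; a Monday row
    is all zeros.  Relative risks downstream are invariant to the reference
    choice.
    """
    dt = pd.DatetimeIndex(dates)
    wd = dt.weekday.to_numpy()  # Monday = 0
    out = np.zeros((len(dt), 6), dtype=float)
    nonref = wd > 0
    out[np.nonzero(nonref)[0], wd[nonref] - 1] = 1.0
    return out
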