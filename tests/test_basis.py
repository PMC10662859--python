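"""Spline basis construction: knot rules, Cox-de Boor oracle, natural
boundary behaviour, calendar-time and day-of-week designs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlnmkit.basis import (
    BasisSpec,
    DegenerateRangeError,
    InfeasibleBasisError,
    bspline_basis,
    dow_indicators,
    natural_cubic_basis,
    place_knots,
    time_spline,
)


# --- independent naive Cox-de Boor recursion (oracle) -----------------

def naive_bspline_value(x: float, t: np.ndarray, k: int, i: int) -> float:
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + k] != t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * naive_bspline_value(x, t, k - 1, i)
    right = 0.0
    if t[i + k + 1] != t[i + 1]:
        right = (
            (t[i + k + 1] - x)
            / (t[i + k + 1] - t[i + 1])
            * naive_bspline_value(x, t, k - 1, i + 1)
        )
    return left + right


def naive_bspline_design(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    lo, hi = spec.boundary_knots
    k = spec.degree
    t = np.concatenate(
        [np.full(k + 1, lo), np.asarray(spec.internal_knots), np.full(k + 1, hi)]
    )
    n_basis = len(t) - k - 1
    out = np.array(
        [[naive_bspline_value(xi, t, k, i) for i in range(n_basis)] for xi in x]
    )
    return out if spec.intercept else out[:, 1:]


# --- knot placement ----------------------------------------------------

def test_knot_placement_examples():
    ks = place_knots(np.linspace(0, 100, 101), df=3, kind="bspline", degree=2,
                     intercept=False)
    assert ks.internal == (50.0,)
    assert ks.boundary == (0.0, 100.0)

    ks = place_knots(np.arange(15.0), df=5, kind="natural_cubic", intercept=True)
    assert ks.internal == (3.5, 7.0, 10.5)
    assert ks.boundary == (0.0, 14.0)


def test_knot_placement_errors():
    with pytest.raises(InfeasibleBasisError):
        place_knots(np.arange(10.0), df=1, kind="bspline", degree=2, intercept=True)
    with pytest.raises(DegenerateRangeError):
        place_knots(np.full(5, 3.0), df=3, kind="bspline", degree=2)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    kind=st.sampled_from(["bspline", "natural_cubic"]),
    df=st.integers(1, 12),
    degree=st.integers(1, 4),
    intercept=st.booleans(),
)
def test_knot_count_rule_property(kind, df, degree, intercept):
    """Internal knot count is df-degree-intercept (bs) / df-1-intercept (ns)
    whenever feasible, and an explicit error otherwise."""
    values = np.linspace(-2.0, 5.0, 200)
    expected = (df - degree - intercept) if kind == "bspline" else (df - 1 - intercept)
    if expected < 0:
        with pytest.raises(InfeasibleBasisError):
            place_knots(values, df=df, kind=kind, degree=degree, intercept=intercept)
    else:
        ks = place_knots(values, df=df, kind=kind, degree=degree, intercept=intercept)
        assert len(ks.internal) == expected
        assert all(-2.0 < k < 5.0 for k in ks.internal)


# --- B-splines ---------------------------------------------------------

def test_bspline_matches_naive_recursion(rng):
    """1,000 random (point, spec) evaluations agree with the naive
    Cox-de Boor oracle to 1e-10."""
    checked = 0
    while checked < 1000:
        df = int(rng.integers(2, 7))
        degree = int(rng.integers(1, 4))
        intercept = bool(rng.integers(0, 2))
        if df - degree - intercept < 0:
            continue
        vals = rng.uniform(0.0, 1.0, size=60)
        spec = BasisSpec.from_data(vals, df=df, kind="bspline", degree=degree,
                                   intercept=intercept)
        x = rng.uniform(vals.min(), vals.max(), size=25)
        ours = bspline_basis(x, spec).values
        oracle = naive_bspline_design(x, spec)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)
        checked += x.size


def test_bspline_partition_of_unity(rng):
    x = rng.uniform(0.0, 10.0, 300)
    spec = BasisSpec.from_data(x, df=4, kind="bspline", degree=2, intercept=True)
    mat = bspline_basis(x, spec).values
    np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)


def test_bspline_shape_and_intercept_drop(rng):
    x = rng.uniform(0.0, 1.0, 50)
    spec = BasisSpec.from_data(x, df=3, kind="bspline", degree=2, intercept=False)
    assert bspline_basis(x, spec).values.shape == (50, 3)
    with pytest.raises(ValueError):
        bspline_basis([np.nan], spec)


def test_bspline_extrapolation_is_polynomial():
    """Beyond the boundary the terminal quadratic piece continues smoothly:
    second differences are constant (quadratic), third differences vanish."""
    x = np.linspace(0.0, 1.0, 50)
    spec = BasisSpec.from_data(x, df=3, kind="bspline", degree=2, intercept=False)
    xo = np.array([1.0, 1.1, 1.2, 1.3, 1.4])
    mat = bspline_basis(xo, spec).values
    third = np.diff(mat, n=3, axis=0)
    np.testing.assert_allclose(third, 0.0, atol=1e-9)


# --- natural cubic splines --------------------------------------------

@pytest.fixture(scope="module")
def lag_spec():
    return BasisSpec.from_data(np.arange(15.0), df=5, kind="natural_cubic",
                               intercept=True)


def test_natural_second_derivative_zero_at_boundaries(lag_spec, rng):
    """One-sided 4-point second-derivative formula (exact on the terminal
    cubic piece) vanishes at both boundary knots."""
    coef = rng.normal(size=5)
    h = 1e-3
    for b, sgn in ((0.0, +1), (14.0, -1)):
        pts = b + sgn * h * np.arange(4)
        f = natural_cubic_basis(pts, lag_spec).values @ coef
        d2 = (2 * f[0] - 5 * f[1] + 4 * f[2] - f[3]) / h**2
        assert abs(d2) <= 1e-6


def test_natural_linear_beyond_boundary(lag_spec, rng):
    coef = rng.normal(size=5)
    h = 0.37
    for base in (14.0, -1.0):
        pts = np.array([base, base + h, base + 2 * h]) if base > 0 else np.array(
            [base - 2 * h, base - h, base]
        )
        f = natural_cubic_basis(pts, lag_spec).values @ coef
        assert abs(f[0] - 2 * f[1] + f[2]) <= 1e-8


def test_natural_rank_and_shape(lag_spec):
    mat = natural_cubic_basis(np.arange(15.0), lag_spec).values
    assert mat.shape == (15, 5)
    assert np.linalg.matrix_rank(mat) == 5


def test_natural_spans_constant_and_linear(lag_spec):
    """Projection residuals of 1 and x onto the (intercept) basis vanish."""
    x = np.linspace(0.0, 14.0, 200)
    B = natural_cubic_basis(x, lag_spec).values
    for target in (np.ones_like(x), x):
        coef, *_ = np.linalg.lstsq(B, target, rcond=None)
        assert np.max(np.abs(B @ coef - target)) <= 1e-8


def test_natural_no_intercept_plus_constant_spans_linear():
    spec = BasisSpec.from_data(np.arange(15.0), df=4, kind="natural_cubic",
                               intercept=False)
    x = np.linspace(0.0, 14.0, 120)
    B = np.column_stack([np.ones_like(x), natural_cubic_basis(x, spec).values])
    assert B.shape[1] == 5
    coef, *_ = np.linalg.lstsq(B, x, rcond=None)
    assert np.max(np.abs(B @ coef - x)) <= 1e-8


# --- calendar-time spline and day-of-week ------------------------------

@pytest.mark.parametrize(
    "n_days,dfy,expected",
    [(4078, 7, 78), (365, 7, 7), (731, 5, 10)],
)
def test_time_spline_total_df(n_days, dfy, expected):
    assert round(dfy * n_days / 365.25) == expected  # arithmetic sanity
    mat = time_spline(np.arange(n_days), df_per_year=dfy)
    assert mat.values.shape == (n_days, expected)


def test_time_spline_explicit_total_df():
    mat = time_spline(np.arange(1000), df_per_year=7, total_df=84)
    assert mat.values.shape[1] == 84


def test_dow_indicators():
    dates = pd.date_range("2009-01-05", periods=14)  # starts on a Monday
    mat = dow_indicators(dates)
    assert mat.shape == (14, 6)
    assert np.all(mat[0] == 0)  # Monday = reference
    assert mat[6].sum() == 1  # Sunday: exactly one indicator
    np.testing.assert_array_equal(mat.sum(axis=0), np.full(6, 2.0))
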