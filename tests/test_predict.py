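"""RR prediction: centering and cumulative identities, delta-method
variance oracles, minimum-risk search, and the reporting table."""

import numpy as np
import pytest

from dlnmkit.crossbasis import CrossBasis
from dlnmkit.glm import fit_quasipoisson
from dlnmkit.predict import find_min_risk, predict_rr, rr_table


@pytest.fixture(scope="module")
def small_fit():
    """Cross-basis-only fit on a short simulated series."""
    rng = np.random.default_rng(3)
    n = 600
    x = rng.uniform(5, 30, n)
    cb = CrossBasis(maxlag=14).fit(x)
    M = cb.transform(x)
    X = np.column_stack([np.ones(n), M])
    labels = ["intercept"] + cb.column_names()
    beta_true = np.concatenate([[0.3], rng.normal(0, 0.05, 15)])
    mask = cb.complete_rows(n)
    mu = np.exp(np.where(mask, X @ np.nan_to_num(beta_true), 0.3))
    y = rng.poisson(mu)
    fit = fit_quasipoisson(y, np.nan_to_num(X), row_mask=mask, column_labels=labels)
    return fit, cb, x


def test_rr_is_one_at_center(small_fit):
    fit, cb, x = small_fit
    center = 18.0
    grid = np.array([10.0, center, 25.0])
    surf = predict_rr(fit, cb, grid, center=center)
    assert np.all(surf.log_rr[1] == 0.0)
    assert np.all(surf.se[1] == 0.0)
    assert np.all(surf.cum_log_rr[1] == 0.0)
    assert np.all(surf.cum_se[1] == 0.0)


def test_cumulative_is_sum_of_lag_specific(small_fit):
    fit, cb, x = small_fit
    surf = predict_rr(fit, cb, np.linspace(6, 29, 7), center=18.0)
    np.testing.assert_allclose(
        surf.cum_log_rr, np.cumsum(surf.log_rr, axis=1), atol=1e-12
    )


def test_variance_matches_explicit_loop_oracle(small_fit):
    """Cumulative variance equals the brute-force double loop over the
    lag-pair covariance quadratic form."""
    fit, cb, x = small_fit
    from dlnmkit.basis import evaluate_basis

    grid = np.array([8.0, 22.0])
    center = 18.0
    surf = predict_rr(fit, cb, grid, center=center)

    idx = [fit.column_labels.index(c) for c in cb.column_names()]
    sigma = fit.covariance[np.ix_(idx, idx)]
    R = evaluate_basis(grid, cb.var_spec_)
    Rc = evaluate_basis(np.array([center]), cb.var_spec_)
    C = cb.lag_basis_
    vk = C.shape[1]
    for g in range(grid.size):
        for Lp in (0, 7, 14):
            zs = []
            for lag in range(Lp + 1):
                z = np.zeros(15)
                for j in range(cb.var_spec_.df):
                    for k in range(vk):
                        z[j * vk + k] = (R[g, j] - Rc[0, j]) * C[lag, k]
                zs.append(z)
            var = 0.0
            for za in zs:
                for zb in zs:
                    var += za @ sigma @ zb
            assert surf.cum_se[g, Lp] ** 2 == pytest.approx(var, abs=1e-12)


def test_lag_variance_matches_loop(small_fit):
    fit, cb, x = small_fit
    from dlnmkit.basis import evaluate_basis

    grid = np.array([12.0])
    surf = predict_rr(fit, cb, grid, center=18.0)
    idx = [fit.column_labels.index(c) for c in cb.column_names()]
    sigma = fit.covariance[np.ix_(idx, idx)]
    R = evaluate_basis(grid, cb.var_spec_)
    Rc = evaluate_basis(np.array([18.0]), cb.var_spec_)
    C = cb.lag_basis_
    vk = C.shape[1]
    for lag in (0, 5, 14):
        z = np.array(
            [
                (R[0, j] - Rc[0, j]) * C[lag, k]
                for j in range(cb.var_spec_.df)
                for k in range(vk)
            ]
        )
        assert surf.se[0, lag] ** 2 == pytest.approx(z @ sigma @ z, abs=1e-12)


def test_find_min_risk_recovers_argmin(recovery_fit):
    """On data simulated with a risk minimum at 27, the fitted center lands
    within one search-grid step of 27."""
    series_center = recovery_fit.center_
    x_grid = recovery_fit.surface_.exposure_grid
    step = (x_grid.max() - x_grid.min()) / 99
    assert abs(series_center - 27.0) <= step + 1e-9


def test_argmin_invariant_to_provisional_center(recovery_fit):
    """Centering only shifts the overall curve by a constant on the log
    scale, so the argmin must not depend on the provisional center."""
    cb = recovery_fit.crossbasis_
    fit = recovery_fit.fit_result_
    labels = [f"mean_temperature:{c}" for c in cb.column_names()]
    lo, hi = cb.var_spec_.boundary_knots
    grid = np.linspace(lo, hi, 100)
    argmins = []
    for provisional in (lo, float(np.median(grid)), hi):
        curve, _ = predict_rr(fit, cb, grid, center=provisional,
                              labels=labels).overall()
        argmins.append(grid[int(np.argmin(curve))])
    assert np.ptp(argmins) <= (hi - lo) / 99 + 1e-9


def test_find_min_risk_flat_curve_warns(small_fit):
    fit, cb, x = small_fit
    import copy

    flat = copy.deepcopy(fit)
    idx = [fit.column_labels.index(c) for c in cb.column_names()]
    flat.coefficients[idx] = 0.0
    with pytest.warns(RuntimeWarning):
        center = find_min_risk(flat, cb, np.linspace(6, 29, 50))
    assert np.isfinite(center)


def test_label_mismatch_raises(small_fit):
    fit, cb, x = small_fit
    with pytest.raises(ValueError, match="not found"):
        predict_rr(fit, cb, [10.0], center=18.0, labels=["nope_0_0"] * 15)


def test_rr_table_layout_and_wald_ci(small_fit):
    fit, cb, x = small_fit
    named = {"min": float(x.min()), "P50": float(np.quantile(x, 0.5)),
             "max": float(x.max()), "center": 18.0}
    grid = np.unique(np.array(list(named.values())))
    surf = predict_rr(fit, cb, grid, center=18.0)
    table = rr_table(surf, named)
    # 4 values x 15 lags x {lag, cumulative}
    assert len(table) == 4 * 15 * 2
    row = table[(table.value_label == "P50") & (table.kind == "lag") &
                (table.lag == 3)].iloc[0]
    g = int(np.nonzero(np.isclose(grid, named["P50"]))[0][0])
    lrr, se = surf.log_rr[g, 3], surf.se[g, 3]
    assert row.ci_lo == pytest.approx(np.exp(lrr - 1.959964 * se), rel=1e-6)
    assert row.ci_hi == pytest.approx(np.exp(lrr + 1.959964 * se), rel=1e-6)
    # the centering value is RR 1 and never significant
    center_rows = table[table.value_label == "center"]
    assert np.allclose(center_rows.rr, 1.0)
    assert not center_rows.significant.any()


def test_rr_table_value_off_grid_raises(small_fit):
    fit, cb, x = small_fit
    surf = predict_rr(fit, cb, np.array([10.0, 20.0]), center=20.0)
    with pytest.raises(ValueError, match="not on the surface grid"):
        rr_table(surf, {"odd": 11.111})
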