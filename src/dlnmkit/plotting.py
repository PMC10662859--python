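"""Plots of exposure-lag-response surfaces: lag curves, overall curves,
contour and 3-D views.  Styling is intentionally plain; every function
accepts/returns matplotlib objects so callers can restyle."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .predict import RRSurface  # noqa: E402

__all__ = ["plot_lag_response", "plot_overall", "plot_contour", "plot_surface3d"]


def _grid_index(surface: RRSurface, value: float) -> int:
    hits = np.nonzero(np.isclose(surface.exposure_grid, value, atol=1e-9))[0]
    if hits.size == 0:
        raise ValueError(f"value {value} not on the surface grid")
    return int(hits[0])


def plot_lag_response(surface: RRSurface, value: float, ax=None):
    """RR against lag at one exposure value, with the Wald CI band."""
    if ax is None:
        _, ax = plt.subplots()
    g = _grid_index(surface, value)
    lo, hi = surface.rr_ci()
    ax.fill_between(surface.lags, lo[g], hi[g], alpha=0.25, color="tab:red")
    ax.plot(surface.lags, surface.rr()[g], color="tab:red")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("RR")
    ax.set_title(f"lag-response at exposure {value:g} (center {surface.center:g})")
    return ax


def plot_overall(surface: RRSurface, ax=None):
    """Overall cumulative (lag 0..L) RR against exposure."""
    if ax is None:
        _, ax = plt.subplots()
    lrr, se = surface.overall()
    z = surface.z_crit
    ax.fill_between(
        surface.exposure_grid,
        np.exp(lrr - z * se),
        np.exp(lrr + z * se),
        alpha=0.25,
        color="tab:blue",
    )
    ax.plot(surface.exposure_grid, np.exp(lrr), color="tab:blue")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.axvline(surface.center, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("exposure")
    ax.set_ylabel("cumulative RR")
    return ax


def plot_contour(surface: RRSurface, ax=None):
    """Filled contours of lag-specific RR over the exposure x lag plane."""
    if ax is None:
        _, ax = plt.subplots()
    cs = ax.contourf(surface.lags, surface.exposure_grid, surface.rr(), levels=20)
    plt.colorbar(cs, ax=ax, label="RR")
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("exposure")
    return ax


def plot_surface3d(surface: RRSurface, ax=None):
    """3-D view of the RR surface."""
    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    L, X = np.meshgrid(surface.lags, surface.exposure_grid)
    ax.plot_surface(X, L, surface.rr(), cmap="viridis", linewidth=0)
    ax.set_xlabel("exposure")
    ax.set_ylabel("lag (days)")
    ax.set_zlabel("RR")
    return ax
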