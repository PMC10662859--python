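"""End-to-end analysis orchestration: CSV in, RR tables out.

Design matrix per factor (single-factor mode, the default):

    [ intercept | cross-basis (var_df x lag_df cols) | time spline | dow ]

With ``joint_model=True`` every configured factor contributes its own
cross-basis to one mutually-adjusted model; predictions are still made and
centered per factor.  Counts are regressed by quasi-Poisson; the centering
value is the fitted minimum-risk exposure from the overall cumulative
curve; RR tables are emitted at the observed minimum, the nine deciles,
the maximum and the mode (at recording precision).

Significance labelling is "95% CI excludes 1" with no multiple-testing
correction across factors, lags and exposure values — a deliberate mirror
of common practice in this literature; treat isolated flags accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .basis import DOW_LABELS, dow_indicators, time_spline
from .crossbasis import CrossBasis
from .glm import FitResult, QuasiPoissonGLM
from .predict import RRSurface, find_min_risk, predict_rr, rr_table

__all__ = [
    "DailySeries",
    "AnalysisConfig",
    "load_daily_csv",
    "descriptive_table",
    "DLNMAnalysis",
    "run_factor_analysis",
    "sensitivity_analysis",
]

DECILE_PROBS = tuple(np.arange(0.1, 1.0, 0.1))


@dataclass
class DailySeries:
    """Validated daily table: consecutive dates, counts, exposure columns."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("date", "count"):
            if col not in df.columns:
                raise ValueError(f"missing required column '{col}'")
        dates = pd.to_datetime(df["date"])
        gaps = np.flatnonzero(np.diff(dates.to_numpy()) != np.timedelta64(1, "D"))
        if gaps.size:
            examples = ", ".join(
                f"{dates.iloc[g].date()} -> {dates.iloc[g + 1].date()}"
                for g in gaps[:5]
            )
            raise ValueError(f"dates are not consecutive; gaps after: {examples}")
        counts = df["count"].to_numpy()
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
            raise ValueError("count must be non-negative")
        self.frame = df.assign(date=dates).reset_index(drop=True)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["date"])

    @property
    def counts(self) -> np.ndarray:
        return self.frame["count"].to_numpy()

    @property
    def factors(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("date", "count")]

    def exposure(self, name: str) -> np.ndarray:
        if name not in self.factors:
            raise KeyError(f"factor column '{name}' not in table")
        col = self.frame[name]
        if col.isna().all():
            raise ValueError(f"factor column '{name}' is entirely missing")
        return col.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def load_daily_csv(path) -> DailySeries:
    return DailySeries(pd.read_csv(path))


@dataclass
class AnalysisConfig:
    """Tunable analysis settings; defaults follow the reference analysis."""

    factors: tuple[str, ...] = ()
    maxlag: int = 14
    var_df: int = 3
    var_degree: int = 2
    lag_df: int = 5
    time_df_per_year: int = 7
    time_total_df: int | None = None  # overrides the per-year rule when set
    dow: bool = True
    joint_model: bool = False
    ci_level: float = 0.95
    seed: int = 0
    n_search_grid: int = 100
    mode_precision: dict = field(default_factory=dict)  # factor -> step
    sensitivity_df_per_year: tuple[int, ...] = (5, 6, 7)

    def precision_for(self, factor: str) -> float:
        return float(self.mode_precision.get(factor, 0.1))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("factors", "sensitivity_df_per_year"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _mode_at_precision(values: np.ndarray, precision: float) -> float:
    """Most frequent value after rounding to the recording step; ties -> smallest."""
    rounded = np.round(np.asarray(values, float) / precision) * precision
    uniq, counts = np.unique(rounded, return_counts=True)
    return float(uniq[np.argmax(counts)])  # np.unique sorts, argmax takes first


def descriptive_table(
    series: DailySeries, precision: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Per-factor mean, SD (n-1), min, quartiles, max and mode."""
    precision = dict(precision or {})
    rows = []
    for name in series.factors:
        x = series.exposure(name)
        step = float(precision.get(name, 0.1))
        rows.append(
            {
                "factor": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "min": float(np.min(x)),
                "p25": float(np.quantile(x, 0.25)),
                "p50": float(np.quantile(x, 0.50)),
                "p75": float(np.quantile(x, 0.75)),
                "max": float(np.max(x)),
                "mode": _mode_at_precision(x, step),
            }
        )
    return pd.DataFrame(rows)


def named_exposure_values(
    x: np.ndarray, precision: float = 0.1
) -> dict[str, float]:
    """The reporting grid: min, deciles P10..P90, max, mode."""
    out = {"min": float(np.min(x))}
    for p in DECILE_PROBS:
        out[f"P{int(round(p * 100))}"] = float(np.quantile(x, p))
    out["max"] = float(np.max(x))
    out["mode"] = _mode_at_precision(x, precision)
    return out


class DLNMAnalysis(BaseEstimator):
    """One-factor (optionally mutually adjusted) DLNM analysis.

    ``fit(series, factor)`` builds the design, fits the quasi-Poisson
    model, locates the minimum-risk centering value and computes the RR
    surface and reporting tables.

    Attributes after fit: ``crossbasis_`` (the target factor's transformer),
    ``fit_result_``, ``center_``, ``surface_``, ``named_values_``,
    ``table_`` (tidy RR table), ``time_df_``.
    """

    def __init__(self, config: AnalysisConfig | None = None) -> None:
        self.config = config

    def _design(self, series: DailySeries, factor: str, cfg: AnalysisConfig):
        n = len(series)
        blocks = [np.ones((n, 1))]
        labels = ["intercept"]
        crossbases: dict[str, CrossBasis] = {}
        cb_factors = (
            [factor]
            if not cfg.joint_model
            else list(dict.fromkeys([factor, *cfg.factors]))
        )
        for name in cb_factors:
            cb = CrossBasis(
                maxlag=cfg.maxlag,
                var_df=cfg.var_df,
                var_degree=cfg.var_degree,
                lag_df=cfg.lag_df,
            ).fit(series.exposure(name))
            blocks.append(cb.transform(series.exposure(name)))
            labels += [f"{name}:{c}" for c in cb.column_names()]
            crossbases[name] = cb
        tspl = time_spline(
            np.arange(n),
            df_per_year=cfg.time_df_per_year,
            total_df=cfg.time_total_df,
        )
        blocks.append(tspl.values)
        labels += [f"time_{i}" for i in range(tspl.values.shape[1])]
        if cfg.dow:
            blocks.append(dow_indicators(series.dates))
            labels += list(DOW_LABELS)
        X = np.hstack(blocks)
        mask = np.zeros(n, dtype=bool)
        mask[cfg.maxlag:] = True
        return X, labels, mask, crossbases, tspl.values.shape[1]

    def fit(self, series: DailySeries, factor: str) -> "DLNMAnalysis":
        cfg = self.config or AnalysisConfig()
        if factor not in series.factors:
            raise KeyError(f"factor column '{factor}' not in table")
        if len(series) < 2 * 365:
            raise ValueError("need at least two years of daily data")
        X, labels, mask, crossbases, time_df = self._design(series, factor, cfg)
        glm = QuasiPoissonGLM().fit(
            X, series.counts, row_mask=mask, column_labels=labels
        )
        cb = crossbases[factor]
        x = series.exposure(factor)
        cb_labels = [f"{factor}:{c}" for c in cb.column_names()]
        search = np.linspace(x.min(), x.max(), cfg.n_search_grid)
        center = find_min_risk(glm.result_, cb, search, labels=cb_labels)
        named = named_exposure_values(x, cfg.precision_for(factor))
        grid = np.unique(np.concatenate([search, list(named.values()), [center]]))
        surface = predict_rr(
            glm.result_, cb, grid, center=center, level=cfg.ci_level,
            labels=cb_labels,
        )
        self.factor_ = factor
        self.config_ = cfg
        self.crossbasis_ = cb
        self.crossbases_ = crossbases
        self.glm_ = glm
        self.fit_result_ = glm.result_
        self.center_ = center
        self.named_values_ = named
        self.surface_ = surface
        self.table_ = rr_table(surface, named, level=cfg.ci_level)
        self.time_df_ = time_df
        return self

    # reporting conveniences -------------------------------------------
    def lag_specific_table(self) -> pd.DataFrame:
        t = self.table_[self.table_["kind"] == "lag"].copy()
        return t.drop(columns=["kind", "lag_range"])

    def cumulative_table(self) -> pd.DataFrame:
        t = self.table_[self.table_["kind"] == "cumulative"].copy()
        return t.drop(columns=["kind", "lag"])


def run_factor_analysis(
    series: DailySeries, factor: str, config: AnalysisConfig | None = None
) -> DLNMAnalysis:
    """Fit the full single-factor analysis; returns the fitted estimator."""
    return DLNMAnalysis(config=config).fit(series, factor)


def sensitivity_analysis(
    series: DailySeries, factor: str, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Refit while varying the calendar-time df/year; report the mode-value
    overall cumulative RR per setting and flag any sign change in log RR."""
    cfg = config or AnalysisConfig()
    rows = []
    for dfy in cfg.sensitivity_df_per_year:
        alt = AnalysisConfig(**{**asdict(cfg), "time_df_per_year": dfy,
                                "time_total_df": None})
        res = DLNMAnalysis(config=alt).fit(series, factor)
        mode_val = res.named_values_["mode"]
        g = int(np.nonzero(np.isclose(res.surface_.exposure_grid, mode_val))[0][0])
        lrr = float(res.surface_.cum_log_rr[g, -1])
        se = float(res.surface_.cum_se[g, -1])
        zq = res.surface_.z_crit
        rows.append(
            {
                "factor": factor,
                "time_df_per_year": dfy,
                "mode_value": mode_val,
                "center": res.center_,
                "cum_log_rr": lrr,
                "cum_se": se,
                "cum_rr": float(np.exp(lrr)),
                "ci_lo": float(np.exp(lrr - zq * se)),
                "ci_hi": float(np.exp(lrr + zq * se)),
            }
        )
    out = pd.DataFrame(rows)
    signs = np.sign(out["cum_log_rr"].to_numpy())
    out["sign_change"] = bool(signs.size and np.any(signs != signs[0]))
    return out
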