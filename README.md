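# dlnmkit

Distributed lag non-linear models (DLNM) for daily count time series in
environmental epidemiology: how does an exposure such as temperature or
humidity, acting today and over the previous two weeks, change the risk of
a health event recorded as sparse daily counts?

The package implements the standard single-city analysis chain used in
weather-and-health studies (the motivating application is daily hospital
admissions for severe Bell's palsy against nine meteorological factors over
an ~11-year window):

* **Cross-basis construction.** The effect of exposure `x` at lag `ℓ` is a
  smooth surface `f(x, ℓ)` represented by the tensor product of a quadratic
  B-spline over exposure (df = 3) and a natural cubic spline over lags
  0..14 (df = 5), summed over the lag window:

  `cb[t,(j,k)] = Σ_{ℓ=0}^{L} R_j(x_{t−ℓ}) · C_k(ℓ)`

* **Quasi-Poisson regression.** Daily counts follow
  `log E(Y_t) = α + cb_t β + ns(t, 7 df/year) + dow_t`, fitted by IRLS with
  QR-decomposed weighted least squares; the dispersion `φ` is estimated by
  the Pearson statistic so standard errors respect overdispersion.

* **Relative-risk prediction.** Lag-specific and lag-cumulative RRs with
  delta-method Wald intervals, centered at the *minimum-risk* exposure
  value — the argmin of the fitted overall cumulative curve — and reported
  at the observed minimum, each decile, the maximum and the mode.

* **Synthetic data.** A generator producing seasonal, autocorrelated
  weather factors calibrated to the published descriptive statistics of
  the Shenzhen 2009–2020 study window, and overdispersed daily counts
  driven by a configurable *known* exposure-lag-response surface, so the
  whole chain is testable end to end without restricted hospital data.

Everything is exposed both as scikit-learn-style estimators
(`CrossBasis`, `QuasiPoissonGLM`, `DLNMAnalysis`) and as thin functional
wrappers (`build_crossbasis`, `fit_quasipoisson`, `run_factor_analysis`).

## Worked example

Simulate an 11-year study in which cold and hot days raise risk
quadratically around a minimum at 27 °C with an exponentially decaying lag
effect, then recover that structure:

```python
from dlnmkit import (simulate_dataset, TrueSurface, BaselineSpec,
                     DailySeries, AnalysisConfig, run_factor_analysis)

surface = TrueSurface(x_ref=27.0, gamma=0.1, scale=5.5, tau=3.0)
baseline = BaselineSpec(mean_daily_count=2.0)
table, truth = simulate_dataset(
    n_days=4078, factors=["mean_temperature"],
    surfaces={"mean_temperature": surface}, baseline=baseline, seed=1,
)
series = DailySeries(table)
config = AnalysisConfig(factors=("mean_temperature",))
result = run_factor_analysis(series, "mean_temperature", config)

print(f"minimum-risk temperature: {result.center_:.2f} degC")
print(f"Pearson dispersion:       {result.fit_result_.dispersion:.3f}")
cum = result.cumulative_table()
row = cum[(cum.value_label == "P10") & (cum.lag_range == "0-14")].iloc[0]
print(f"cumulative RR at P10 ({row.factor_value:.1f} degC), lag 0-14: "
      f"{row.rr:.3f} (95% CI {row.ci_lo:.3f}-{row.ci_hi:.3f})")
```

prints

```
minimum-risk temperature: 27.13 degC
Pearson dispersion:       1.056
cumulative RR at P10 (16.0 degC), lag 0-14: 4.060 (95% CI 3.507-4.700)
```

The fitted centering value lands on the true risk minimum (27 °C) to
within the search-grid resolution; the dispersion is ~1 because the counts
were generated as Poisson; and the cumulative RR at the 10th temperature
percentile matches the injected truth
(`exp(0.1·((16−27)/5.5)²·Σℓ e^{−ℓ/3}) ≈ 4.1`).

The same analysis runs from a shell:

```sh
dlnmkit simulate --days 4078 --seed 1 --effect-factor mean_temperature \
    --baseline-mean 2.0 --factors mean_temperature --out data.csv
dlnmkit describe data.csv
dlnmkit analyze data.csv --factor mean_temperature --out-dir results/
dlnmkit sensitivity data.csv --factor mean_temperature --out-dir results/
dlnmkit plot data.csv --factor mean_temperature --out-dir plots/
```

`analyze` writes `lag_specific_<factor>.csv` and `cumulative_<factor>.csv`
(one row per exposure value × lag / lag window, with RR, 95% CI and a
significance flag), `sensitivity` refits under calendar-time df of 5, 6
and 7 per year, and `plot` renders lag-response, overall-cumulative,
contour and 3-D surface views.

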