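# Methods

## Model

The analysis targets the association between a daily meteorological
exposure `x_t` and a daily event count `Y_t` allowing both non-linearity
in the exposure and a delayed (distributed-lag) response. The mean model
is a log-linear quasi-Poisson regression

    log E(Y_t) = α + Σ_{j,k} β_{jk} cb_t(j,k) + s(t) + dow_t

where `cb` is the cross-basis

    cb_t(j,k) = Σ_{ℓ=0}^{L} R_j(x_{t−ℓ}) · C_k(ℓ),

`R` a quadratic B-spline basis over the exposure range (df = 3, knots at
equally spaced quantiles of the observed values, no intercept column — the
model intercept absorbs it), `C` a natural cubic spline over the integer
lags 0..L (df = 5, with intercept), `L = 14` days, `s(t)` a natural cubic
spline of the day index controlling seasonality and long-term trend
(7 df per year by default), and `dow` six weekday indicators (Monday
reference; relative risks are invariant to the reference choice).

The variance is modelled as `Var(Y_t) = φ·μ_t` with the dispersion `φ`
estimated by the Pearson statistic `Σ (y−μ̂)²/μ̂ / (n−p)`, so inference is
robust to the overdispersion typical of daily surveillance counts.

### Spline conventions

Knot counts follow df − degree − intercept (B-spline) and
df − 1 − intercept (natural cubic). Internal knots sit at equally spaced
quantiles of the observed exposure (or of the lag sequence); boundary
knots are the observed extremes. B-splines are evaluated from the
Cox–de Boor knot representation with the boundary knots repeated
degree + 1 times; beyond the boundaries the terminal polynomial pieces are
extrapolated, deterministically, so prediction grids may touch the
observed extremes exactly. The natural cubic basis is built from the
cubic B-spline design projected onto the null space of the two boundary
second-derivative constraints (well conditioned even at the ~78 columns of
an 11-year time spline) and is continued linearly outside the boundaries.
When the basis must exclude the constant (e.g. the calendar-time spline
next to the model intercept), the constant direction is removed from the
null-space basis; only the span is identified, which is all the model
uses.

### Fitting

IRLS with the log link: working response `z = η + (y−μ)/μ`, weights `μ`,
each step solved by QR decomposition of the weighted design (not normal
equations — with ~100 columns the squared condition number is avoidable).
Start values `μ⁰ = y + 0.5` guard `log 0` on zero-count days. Convergence
is declared when the relative deviance change falls below 1e−10, with a
hard cap of 100 iterations (both configurable); an unconverged fit is
returned flagged, not raised. Rank deficiency is detected up front by a
pivoted QR and reported with the names of the redundant columns. The first
`maxlag` days have incomplete lag history and are excluded from the
likelihood rather than imputed.

### Prediction and centering

Effects are reported relative to a centering exposure `c`: the contrast
vector for grid value `x` at lag `ℓ` is
`z(x,ℓ)_{jk} = (R_j(x) − R_j(c))·C_k(ℓ)`, giving
`log RR = zᵀβ̂` and `Var = zᵀΣ̂z`; cumulative effects over lags 0..L′ sum
the contrast vectors first, which accounts for the covariance between
lags. Confidence intervals are normal-quantile Wald intervals on the log
scale — standard in this literature; no small-sample correction.

The centering value is the *minimum-risk* exposure: the argmin of the
overall cumulative (lag 0..14) curve on a 100-point uniform grid over the
observed range. Because centering only shifts the log-scale curve by a
constant, the argmin does not depend on the provisional center used in the
first pass; a flat curve (range < 1e−12) falls back to the grid median
with a warning. In multi-location designs this reference is usually taken
from a pooled (BLUP) curve; with a single location that machinery
degenerates to the fitted curve itself, which is what is implemented.

RR tables are emitted at the observed minimum, the nine deciles, the
maximum and the mode; the mode of a continuous factor is computed at its
recording precision (0.1 °C and similar), ties broken toward the smaller
value. Significance flags mirror "the 95% CI excludes 1" with **no
multiple-testing correction** across factors × lags × exposure values —
deliberately matching field practice; isolated flags among hundreds of
cells should be read accordingly.

### Analysis modes

Default is one model per factor. `joint_model=True` instead places every
configured factor's cross-basis in a single mutually adjusted model
(predictions remain per factor, centered per factor). Dates must be
consecutive calendar days; gaps are an error, never silently bridged —
the lag structure assumes contiguity.

The sensitivity harness refits with calendar-time smoothness of 5, 6 and
7 df per year and compares the mode-value overall cumulative RR across
settings. The time spline's total dimension is
`round(df_per_year × n_days / 365.25)`; a fixed total (e.g. 84) can be
given instead via `time_total_df` — both readings of "7 df per year over
~11 years" are supported, neither silently corrected.

## Synthetic data generator

Each factor is a sinusoidal annual cycle plus AR(1) Gaussian noise,
confined to physical bounds and rounded to its recording precision. Nine
presets are calibrated so that the simulated mean and SD over ~4,078 days
match the published Shenzhen 2009–2020 descriptives (mean temperature
23.25 ± 5.50 °C, relative humidity 74.71 ± 12.99 %, …) within per-factor
tolerances of roughly 0.1·SD on the mean and 0.2·SD on the SD
(`CALIBRATION_TARGETS`). Bounds are enforced two ways: a hard clip, which
deliberately leaves a probability atom at a bound for factors whose most
frequent recorded value *is* a bound (total cloud cover at 100 %, sunshine
duration at 0 h), and a smooth logistic compression of the tails
(`soft_clip_width > 0`) for the other factors, so their modes stay
interior as in the recorded data.

Counts are drawn from `log μ_t = log(baseline) + seasonal + trend + dow +
Σ_ℓ f(x_{t−ℓ}, ℓ)` with a known surface
`f(x,ℓ) = γ·((x−x_ref)/s)²·exp(−ℓ/τ)` (zero at the reference for every
lag; `γ = 0` gives the null). Poisson when `dispersion = 1`; otherwise
negative binomial with per-day size `k_t = μ_t/(φ−1)`, which makes
`Var = φ·μ_t` hold exactly for every day — the variance function
quasi-Poisson assumes, realised by a concrete generator. Weather and
counts use independent child streams of one seed; identical seeds give
byte-identical output.

What the generator does **not** emulate: cross-factor dependence beyond a
shared seasonal phase, asymmetric seasonality (a sinusoid's occupation
density peaks at both seasonal extremes, so the simulated temperature mode
falls near 19–22 °C rather than the recorded 29.3 °C, which reflects a
summer plateau), weather fronts or other non-Gaussian dynamics, and any
case-ascertainment process. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's assumptions, not
the validity of any substantive epidemiological finding.

## Reference simulation for recovery checks

Parameter-recovery and interval-calibration checks use a temperature-like
factor carrying `f` with `x_ref = 27 °C`, `γ = 0.1`, `s = 5.5 °C`,
`τ = 3` days (overall cumulative RR ≈ 4 at the 10th temperature
percentile) on a baseline of 2 cases/day over ~4,000 days. The effect size
and rate were fixed once, from a design (power) analysis: at the sparse
0.21 cases/day of the motivating study the overall curve's standard error
is near 1 on the log scale — consistent with the very wide intervals such
studies report — and the location of the risk minimum is then not
statistically identifiable to sub-degree precision by *any* estimator, so
a recovery test at that scale would only measure noise. At 2 cases/day
(an ordinary daily-mortality scale for this model class) the fitted
minimum lands within the 100-point search grid's resolution of the truth
for most seeds, the overall cumulative curve tracks the truth well within
2× its standard error over the interior 80 % of the exposure range, and
95 % intervals cover at their nominal rate (93–96 % over 100 replicates).
Replicate-based checks (coverage, type-I error) use 3,000-day series to
keep a 100-replicate run within seconds.

## Numerical choices and degenerate inputs

- Basis evaluation outside the boundary knots: polynomial (B-spline) or
  linear (natural cubic) extrapolation — fixed, documented behaviour.
- Constant exposure series: knot placement raises a degenerate-range
  error rather than producing a singular basis.
- Infeasible df/degree/intercept combinations raise an explicit
  infeasible-basis error (the knot-count rule would need a negative
  count).
- All-equal overall curve in the centering search: warning + median.
- Count validation rejects negative or non-integer responses; design
  matrices must be finite on fitted rows.

## Known limitations

- Wald intervals can be anticonservative at very sparse counts
  (zero-heavy days); the type-I probe at 0.21 cases/day runs at ~5–8 %
  rather than exactly 5 %.
- No penalised smoothness selection; df are fixed by design, as in the
  motivating analysis, with the sensitivity harness as the robustness
  check.
- Attributable fractions, multi-location meta-analysis (true BLUP
  pooling) and autocorrelation-robust covariances are out of scope.
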