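# Methods

`seascord` implements a complete study protocol for *binary seasonality
classification* of monthly health time series: the construction of
persons-per-thousand proportion series from monthly count tables, eight
alternative seasonality tests, and the concordance analytics that quantify
how much — or how little — the methods agree.

## Series construction

The input is a long-format table of monthly counts per series: the number
of distinct persons with the event in a calendar month (numerator) and the
number of persons under observation that month (denominator).  The monthly
value is `1000 * event_persons / denominator_persons` — a proportion per
thousand persons observed.  A series is eligible once it contains at least
four complete calendar years (12 months each); leading and trailing partial
years are trimmed rather than causing rejection, and rejection occurs only
when fewer than four complete years survive.  Months with zero events are
valid zero values; an *absent* month row is missing data and breaks the run
of complete years (a gap is indistinguishable from lost observation, so it
is never imputed as zero).

## Shared preprocessing

Seven of the eight methods remove any linear-in-time trend first.  The
default is ordinary least-squares residuals of `value_t = a + b·t + e_t`
with `t = 1..n`; residuals are orthogonal to the intercept and the time
index to within 1e-8 of the series scale.  First differencing is available
as an alternative trend-removal mode for sensitivity analysis (some
reference time-series libraries difference internally), but it shortens the
series by one month and breaks calendar-year alignment, so the rank/ANOVA
methods always use OLS residuals regardless of the configured mode.

One numerical guard matters: when the input *is* a straight line, the OLS
residuals are pure floating-point rounding residue whose systematic pattern
masquerades as structure to rank-based tests.  Residuals are therefore
snapped to exact zero when their largest magnitude is below 1e-10 of the
input scale, which routes genuinely constant series into the degenerate
branches of each test (tied ranks, zero-variance errors) instead of
producing spurious seasonal calls.

The sample autocorrelation is the biased (n-denominator) estimator
`rho_k = sum(e_t - m)(e_{t+k} - m) / sum(e_t - m)^2`.  Note its maximum on
an exactly periodic series is `(n - k)/n`, not 1 — at 8 years and lag 12
that is 0.875.

## The eight methods

All p-valued methods use the strict decision rule *seasonal ⇔ p < α*, with
α ∈ {0.01, 0.05, 0.1} by default and no multiple-testing correction (each
test is its own fixed-level decision).

**ED (Edwards harmonic test).**  A Poisson GLM (log link) of pseudo-counts
on `cos(2πM/12)` and `sin(2πM/12)` with `M` the calendar month; the
statistic is the deviance drop against the intercept-only model, referred
to chi-square with 2 df.  It runs on the *raw* series: the harmonic basis
is orthogonal to a linear trend over complete years, so trend removal is
unnecessary.  Because the Poisson family needs counts while the pipeline
carries real-valued proportions, pseudo-counts `round(scale × value)` are
used with `scale` = 1000 by default: with a one-million-person denominator
this reproduces the true monthly event counts exactly, and the test then
operates at its nominal dispersion.  For series from much smaller
denominators the pseudo-counts overstate the information and the test
becomes anticonservative; `scale` is configurable for that reason.

**FR (Friedman) / KW (Kruskal–Wallis) / WE (Welch ANOVA).**  The detrended
series is folded into a years × 12 matrix.  FR ranks the 12 months within
each year and uses the tie-corrected Friedman chi-square (11 df); KW ranks
all observations jointly and uses the tie-corrected H statistic (11 df);
WE computes the heteroscedastic one-way ANOVA F* with Welch's
degrees-of-freedom across the 12 month groups.  Fully tied inputs yield
statistic 0 and p = 1 for the rank tests; a month group with zero variance
makes Welch's weights undefined and is reported as a degenerate-input
failure naming the month.

**QS.**  Ljung–Box-weighted *positive parts* of the detrended series'
autocorrelations at lags 12 and 24,
`QS = n(n+2)·Σ max(0, ρ̂_{12i})²/(n−12i)`, chi-square with 2 df.  Negative
seasonal autocorrelations count as zero, so the statistic is exactly 0 (p=1)
whenever both are non-positive.  Requires n > 24.

**ET (ETS likelihood-ratio test).**  The best additive-error
exponential-smoothing state-space model *with* additive period-12
seasonality and the best *without* are each selected by AICc over the
candidate trend structures and compared by `max(0, 2Δℓ)` against chi-square
with df equal to the difference in free parameters.  One of the 12 initial
seasonal states is redundant with the level, so with matching trend
structures df = 12 (one seasonal smoothing weight + 11 free initial
states).  The candidate trends default to {none, additive}; damped-trend
candidates can be enabled (symmetrically in both arms) but are off by
default — they rarely change the verdict on 4–8-year series and double the
fit cost.  Likelihoods come from statsmodels' ETS machinery with estimated
initial states and deterministic initialization, so results are
bit-reproducible.

**AR (seasonal ARIMA likelihood-ratio test).**  A non-seasonal order
(p,d,q) is selected by stepwise AICc search with seasonal terms disabled
(d by sequential KPSS tests).  The seasonal augmentations
(p,d,q)×(P,0,Q)₁₂ for (P,Q) ∈ {(1,0),(0,1),(1,1)} are then fit to the same
data; the best by AICc is compared to the base by a chi-square LRT with
df = P+Q.  Seasonal differencing is held at D = 0 so the two models are fit
to identical observations and the LRT is nested and valid.  The statistic
clamps at 0 when optimizer noise leaves the larger model below the base.

**AA (auto-ARIMA selection).**  A Hyndman–Khandakar stepwise AICc search
over seasonal and non-seasonal ARIMA models at period 12; the series is
seasonal iff the selected (P,D,Q) ≠ (0,0,0).  There is no p-value and the
verdict is identical at every α.  D ∈ {0,1} is fixed before the search by a
seasonal-strength heuristic (threshold 0.64).  Strength is computed from a
*periodic* decomposition — linear trend removed, seasonal component = the
calendar-month means — rather than STL: with only 4–8 cycles STL's local
seasonal smoothing tracks noise year-to-year and estimates strengths around
0.6 on pure white noise, while the periodic decomposition absorbs only
~(11/n) of null variance and never crossed the 0.64 threshold in a
300-series null experiment.  Search bounds default to p,q ≤ 3 and
P,Q ≤ 1; the stepwise neighbourhood moves each order component by ±1 and
toggles the constant.  All fits use the SARIMAX Kalman filter with
concentrated innovation variance and L-BFGS from deterministic starts.

**Degenerate inputs.**  A detrended series with numerically zero variance
short-circuits ET, AR and AA to a non-seasonal verdict (statistic 0): a
constant series is trivially non-seasonal and the likelihood comparison is
degenerate there.  QS and WE instead report degenerate-input failures, as
their statistics are undefined without variance.  Failures are carried as
annotated results — never silently dropped or coerced.

## Concordance analytics

For S series and the 8 methods at one α, the classification matrix holds
boolean calls plus a failure mask.  Concordance is *unanimous* agreement:
positive (all seasonal), negative (all non-seasonal); the concordance rate
is `(M(0) + M(8)) / S` where `M(k)` counts series with exactly k seasonal
votes.  The pattern count `N` maps each exact subset of seasonal-voting
methods to its frequency; there are 2⁸ − 1 = 255 possible nonempty subsets.
Series with any failed cell are excluded from agreement statistics and
tallied separately (coercing a failure to either verdict would bias the
concordance rate).  Per-method proportions are kept as fractions
internally; percentages appear only in report tables.  The within-database
*spread* is max − min of the per-method proportions; across databases the
median spread uses the midpoint convention on even counts.

## Synthetic corpora

The generator produces the structure the analysis assumes:

    value_t = baseline + trend_slope·t
              + amplitude·(1 − decay)^year(t) · s(2π(M_t − peak − J_y)/12)
              + ε_t

with per-year phase jitter `J_y ~ N(0, jitter²)` (peak *consistency*),
geometric amplitude decay (peak *persistence*), white noise ε, and a shape
function `s(θ) = 2·((1+cos θ)/2)^κ − 1` with sharpness κ ≥ 1.  κ = 1 is a
pure cosine; larger κ concentrates the excess into a short spiky peak while
keeping the peak-trough distance at `2·amplitude`.  Gaussian-family values
truncate at 0 (a mild distortion at low baselines); the Poisson family
draws monthly event counts with mean `population·value/1000` and emits both
the count table and derived proportions.  A master seed splits into
per-series seeds through a counter-based seed sequence, so corpora are
reproducible and extendable.

Scenario defaults (`scenarios.yaml`) and their rationale:

* **white-noise-null** — baseline 5/thousand, noise sd 0.07, 4 years.
  0.07 per-thousand is the binomial sampling noise of a one-million-person
  denominator (`sqrt(5000)/1000`), i.e. the pure-sampling regime of a large
  claims database; it also puts ED's pseudo-counts at nominal dispersion.
* **strong-harmonic** — amplitude 2 on baseline 5, sharpness 3, no jitter
  or decay, noise sd 0.2, 6 years.  The positive-concordance regime:
  persistent, consistent, *spiky* peaks.  The sharpness matters for a
  structural reason: a pure cosine is itself an ARMA(2,2) process (complex
  AR roots at the annual frequency), so the AR test's non-seasonal base
  model absorbs it entirely and the seasonal augmentation adds nothing —
  smooth sinusoids are a genuine blind spot of nested-ARIMA seasonality
  testing, at every noise level.  Spiky peaks are not ARMA-representable
  with few parameters and are what strongly seasonal diagnosis series look
  like.
* **near-constant-null** — zero noise, tiny trend (0.002/month).  The
  negative-concordance regime.  It is deterministic on purpose: rank tests
  are distribution-free, so *any* continuous iid noise gives them uniform
  p-values and ~5% of a corpus would be called seasonal no matter how small
  the noise; unanimous non-seasonal classification across a corpus is only
  guaranteed in the effectively-degenerate limit, which matches the
  near-zero variances reported for negatively concordant series.
* **damped-peaks / jittered-peaks / high-variance-aperiodic** — the
  intermediate regimes where methods disagree: decaying peak amplitude
  (persistence loss), 2-month phase jitter (consistency loss), and
  trendless high-variance noise.

What the generator does *not* emulate: serially correlated non-seasonal
noise (e.g. epidemic outbreaks, coding-practice drift), denominator drift
within a series, multiplicative seasonality, and calendar artefacts
(month length, weekday composition).  Passing tests on these corpora
demonstrate correctness and calibration of the machinery, not performance
on any particular real database.

## Numerical choices

* AICc is `−2ℓ + 2k + 2k(k+1)/(n−k−1)` with k counting every estimated
  quantity including the innovation variance; n is the undifferenced
  length, held common across candidate orders for comparability.
* Tie handling in both rank tests: average ranks plus the standard
  `Σ(t³−t)` correction factors; a correction factor of 0 (everything tied)
  yields statistic 0, p = 1.
* Pattern ordering in report tables: by N descending, ties broken by
  pattern cardinality, then by membership bitstring in the fixed method
  order (ED, FR, AR, QS, ET, KW, WE, AA) — fully deterministic.
* LRT statistics clamp at zero; p-values are upper-tail chi-square (or F
  for WE).
* Zero-variance tolerances: residual snap at 1e-10 relative, state-space
  short-circuit at 1e-14 relative variance.

## Problem sizes

The shipped verification suite uses 200-series null corpora for
calibration (the binomial 3σ band around a true 5% rate stays below the
10% acceptance bound), 50-series corpora for the concordance regimes, and
4–8-year series throughout — the eligibility floor and the typical lengths
the construction yields.  The ten-database protocol arithmetic (61,467
series; 184,401 series × α evaluations) is reproduced through the grid
manifest on declared corpus cardinalities, since the underlying commercial
databases are not redistributable.

## Known limitations

* ED's pseudo-count scale ties its calibration to the assumed denominator
  size; it is exact only when `scale × value` reproduces true counts.
* The AR augmentation menu {(1,0),(0,1),(1,1)} at D = 0 is one defensible
  reading of "the same model with a seasonal component"; richer seasonal
  structures are deliberately out of its search space.
* ETS likelihood-ratio df counting treats estimated initial states as free
  parameters (less one redundancy); the chi-square reference is asymptotic
  and approximate at 48–96 observations, which the null-calibration suite
  bounds empirically rather than proves.
* The stepwise searches are greedy; they find good, not provably optimal,
  AICc models — the standard trade-off of the stepwise algorithm.
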