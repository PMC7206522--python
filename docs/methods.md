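# Methods

## Data model and alignment convention

Each patient contributes three daily variables: time in bed (TIB, minutes,
derived as the clock distance from go-to-bed to the next get-up, 24-hour
wrap across midnight), total sleep time (TST, self-reported minutes), and a
depression core-symptom score (mean of two 0–10 visual-analogue items; if
either item is missing the score is missing — there is no single-item
fallback).

The alignment is lag-0 contemporaneous: the sleep episode that *ends on the
morning of day t* shares index *t* with the *evening* depression rating of
day t. Under this convention a lag-1 VAR coefficient is "last night's sleep
predicting today's rating" in one equation and "yesterday evening's rating
predicting last night's sleep" in the other, which is the natural reading of
day-following-night effects. Days whose reported sleep minutes exceed the
derived bed interval are internally inconsistent; both sleep variables are
set missing for that day rather than truncated, because there is no way to
tell which entry is wrong. Calendar gaps become all-missing days so the
index is strictly consecutive.

Inclusion mirrors a feasibility-cohort rule: at least 130 consecutive days
of recording and at most 30% missingness, assessed **per variable** (a
morning-only day counts against the evening variables only). The continuous
period is the full first-to-last span; no best-window search is attempted.

## Imputation

Missing entries are filled by the Kalman smoother of a univariate ARIMA
model selected by AIC on the observed series over a small grid (AR 0–3,
differencing 0–1, MA 0–1, each with a constant — which becomes a drift under
differencing). The model is cast to state-space form; the smoothed
expectation of the observation process at the missing positions is the
imputed value. statsmodels' SARIMAX provides the state-space machinery; the
grid, selection and extraction are this package's.

Two properties matter and are enforced: observed values are never altered,
and the model for one series never sees the other series, so imputation
cannot manufacture cross-series correlation (which would contaminate the
Granger tests downstream). Degenerate inputs: fewer than 30 observed values
is an error; a flat observed series falls back to a constant fill with a
warning. A noiseless linear ramp is imputed exactly (the (0,1,0)+drift
candidate wins and its smoother is linear continuation); this is the
reference case pinning the implementation.

## Stationarity filtering

Each (imputed) series is differenced to the smallest order d ∈ {0, 1, 2} at
which an ADF test rejects a unit root **and** a KPSS test fails to reject
level stationarity, both at 5%. Requiring agreement protects against both
error directions: ADF alone under-rejects on trend-stationary series, KPSS
alone over-differences. An optional linear OLS detrend can be tried before
first differencing (off by default). Series still non-stationary at d = 2
raise an error naming the variable.

The two series of one patient are decided independently but differenced to
the **maximum** d of the pair before VAR fitting so both equations share a
time index. Effects are therefore reported on the filtered scale, and the
filter specification (d per variable) travels with every result so that
minutes and scale units stay interpretable.

## VAR estimation, lag order, Granger tests

Estimation is equationwise OLS of each variable on an intercept and lags
1..p of both variables; the residual covariance uses the 1/n_eff
denominator, and the information criterion is ln|Σ̂| + 2·k·(kp+1)/n_eff.
Lag order is selected by AIC over p ∈ {1..7} (seven days of memory at most),
with every candidate fitted on the common sample that drops the first seven
observations so the criteria are comparable. AIC retains its well-known
positive over-selection probability; the test suite asserts no
under-selection and exact recovery above the asymptotic floor rather than a
rate AIC cannot deliver. One p is selected per patient-model and reused for
both causal directions; the TST and TIB models may select different p.

Granger causality uses the single-equation F-form (better behaved at
n ≈ 170 than the asymptotic χ²): with RSS_r from the effect's own-lags-only
regression and RSS_u from the full regression,

    F = [(RSS_r − RSS_u)/p] / [RSS_u/(n_eff − 2p − 1)] ,

referred to F(p, n_eff − 2p − 1). Tests run at α = 0.05 in both directions
with no multiplicity correction across patients, models or directions (a
correction flag exists but defaults off). The **association sign** is the
sign of the cumulative orthogonalized impulse response of the effect to a
cause shock at horizon 10 — an operationalization of "more X was followed by
more/less Y" that remains well-defined when individual lag coefficients
disagree in sign.

## Impulse responses and variance decomposition

The MA representation Φ_0 = I, Φ_h = Σ_{k≤min(h,p)} Φ_{h−k} A_k feeds both
analyses. Identification is recursive (Cholesky). For an IRF the impulse
variable is ordered first by default, so its orthogonal shock carries the
variable's full innovation variance — the cleanest reading of "a change in
X"; for FEVD the default ordering is the pipeline's variable order, sleep
first, consistent with the alignment convention in which the night's sleep
physically precedes the same-index evening rating. Both choices are
overridable, and with near-diagonal residual covariance the ordering is
immaterial (tested). The shock size defaults to **1 SD of the (filtered)
impulse series** — the conventional definition of a clinically meaningful
change in this literature — rather than 1 residual SD; a flag restores the
textbook residual-SD unit. Horizon is fixed at 10 days; FEVD is reported
from horizon 1.

Confidence bands are a residual-resampling bootstrap (500 runs, percentile
method, 95%): centered fitted residuals are resampled with replacement, the
series rebuilt from the estimated coefficients and the observed initial
values, refitted at the same p, and the IRF recomputed with the shock
re-standardized to the replicate's series SD. Non-stationary refits are kept
(the horizon is finite) but counted; a completion rate under 90% warns.
Percentile intervals are widened minimally to contain the plug-in point
estimate so reported bands are always self-consistent. Under the null the
horizon-1 band covers zero in ≈ 94% of replicates at n = 170 — the usual
slight small-sample undercoverage of percentile bootstraps.

## Cohort aggregation

Significant results are counted by model × direction × sign, with a patient
significant in both directions of one model counted once as "mutual".
Cohort mean rows over per-patient IRF/FEVD entries average **magnitudes**
(mean of absolute values, half-up rounding to two decimals, exact decimal
arithmetic so printed two-decimal inputs round as on paper): signed averages
would let opposite-signed patients cancel and understate typical effect
size. The signed mean is emitted alongside, labelled as such. The bundled
reference tables (per-patient demographics, cumulative IRFs and FEVD shares
from the motivating published cohort) are the worked-example inputs for
these conventions; the published FEVD table prints horizons 1–6 and 8–10
only, and the bundled file mirrors exactly the printed columns, while the
pipeline's own output emits all horizons 1–10.

## Synthetic cohort

The generator draws a stationary bivariate VAR(p) (Gaussian innovations,
burn-in from the unconditional mean), adds an optional per-day linear
drift, clips to instrument bounds (0–1440 minutes, 0–10 score) and rounds
to instrument resolution (whole minutes; two decimals on the score). The
latent sleep value is rendered as TIB by drawing a go-to-bed time uniformly
in a 21:00–00:59 window and back-computing the get-up time, so ingestion
recovers the latent series exactly; TST is a per-day efficiency fraction
(0.85–0.97) of TIB; the depression score is split into two items whose mean
reproduces it exactly. Morning and evening logs go missing as independent
Bernoulli events (MCAR), mirroring the two-log app structure; the
missingness probability is capped at 0.30, the cohort exclusion bound.

Cohort defaults emulate the study conditions: 143–205 diary days, TIB
around 7–8.5 h with innovation SD 30–60 min, mid-scale depression with
innovation SD ≈ 1, daily autocorrelation 0.2–0.5, small drifts, ~10%
missing days. Cross-coupling is specified on the standardized scale (a
coefficient of 0.3 moves the other variable by 0.3 of its innovation SD per
1-SD shock) and defaults to zero, so coupled patients are always planted
deliberately with known direction. Defaults keep clipping at zero, so
linear-VAR theory holds for the closed-form checks.

What the generator does **not** emulate: non-MCAR missingness (real missed
logs correlate with symptom severity), the bounded/ordinal character of the
0–10 scale beyond clipping, naps or split sleep, weekly rhythms, and
measurement reactivity. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generating process, not
robustness to these real-data features.

## Monte-Carlo problem sizes

Calibration experiments run at the study's own scale, n = 170 days: Granger
size on 2000 independent-AR(1) replicates (observed ≈ 0.05), power on 500
replicates at standardized coupling 0.8 (≈ 1.0), coefficient recovery on a
single n = 10⁵ draw (max error ≈ 0.004), FEVD simplex deviation and
IRF-vs-shock-simulation deviation on 200 and 50 random stable systems
(machine precision), bootstrap coverage on 200 outer × 500 inner replicates,
and an end-to-end cohort of 20 coupled (standardized coupling 0.3) plus 20
null patients pushed through the full diary pipeline. In the end-to-end
experiment the per-test false-positive rate runs slightly above the nominal
5% (typically 8–12%) because the lag order is data-selected before testing —
ordinary post-selection inflation, shared by any pipeline that picks p by
AIC and then tests at p; the acceptance check therefore evaluates
consistency with α by an exact binomial test at the 1% level rather than a
point match.

## Known limitations

* Linear, homoscedastic, two-variable dynamics; no exogenous covariates
  (medication changes, weekday effects), no regime switching.
* Recursive identification only; generalized or structural IRFs are out of
  scope, though both orderings can be reported.
* Differencing is the only stationarity transform applied by default;
  series that are stationary around a breakpoint will be over-differenced.
* Imputation uncertainty is not propagated into the VAR standard errors
  (single imputation, as in the pipeline this package re-implements).
* The 0–10 scale is treated as continuous; floor/ceiling effects in
  severely or minimally symptomatic patients will attenuate estimates.
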