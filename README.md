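# idiovar

Idiographic (N-of-1) time-series analysis of the day-to-day interplay between
sleep and depression. Given a patient's daily diary — a morning log with
go-to-bed time, get-up time and self-reported sleep minutes, and an evening
log with two 0–10 depression items — the package derives time in bed (TIB),
total sleep time (TST) and a depression core-symptom score (mean of the two
items), and asks, *for that single patient*: do changes in sleep precede
changes in depressive symptoms, or the other way round, and by how much?

It is aimed at researchers working with experience-sampling / daily-diary
data in psychiatry who want within-person (rather than cohort-average)
temporal inference, and it ships a synthetic diary generator with known
ground truth so the whole pipeline is testable without patient data.

## The model

For each patient and each sleep variable (model 1: TST, model 2: TIB), a
bivariate vector autoregression is fitted to the stationarity-filtered daily
pair y_t = (sleep_t, depression_t)′:

    y_t = c + A_1 y_{t-1} + … + A_p y_{t-p} + ε_t,  ε_t ~ N(0, Σ)

* **Preprocessing.** Missing diary days are imputed per series by the Kalman
  smoother of an AIC-selected ARIMA model (strictly univariate, so imputation
  cannot manufacture cross-series correlation); each series is then
  differenced to the smallest order d at which an ADF/KPSS test pair agrees
  on stationarity.
* **Lag order.** p minimizes the AIC over 1..7 days, all candidates fitted on
  a common sample.
* **Granger causality.** Sleep "Granger-causes" depression (and vice versa)
  when its p lags significantly reduce the residual sum of squares of the
  other equation — an F-test at the 5% level, run in both directions.
* **Impulse responses.** Orthogonalized IRFs trace the effect of a one-time
  1-SD shock in one series on the other over a 10-day horizon, with
  residual-bootstrap 95% bands and cumulative totals; the association sign
  (more sleep → more vs. less depression) is the sign of the cumulative
  response at day 10.
* **Variance decomposition.** FEVD reports the share of each variable's
  forecast-error variance attributable to the other, horizons 1–10.
* **Cohort report.** Per-patient results are aggregated into count tables
  (direction × sign of significant associations) and magnitude-mean rows.

## Worked example

Simulate one patient whose sleep truly drives next-day depression
(standardized lag-1 cross effect 0.3), with 10% missing diary days, then run
the full pipeline:

```python
import numpy as np
from idiovar import synthetic, align_series, analyze_patient

truth = synthetic.default_truth(patient_id="demo", n_days=170,
                                missing_prob=0.10, seed=3, cross_std=(0.3, 0.0))
sim = synthetic.generate_patient(truth)
series = align_series(sim.logs)
analysis = analyze_patient(series, model="tib")

res = analysis.var_results
print(f"included: {analysis.inclusion.include}, lag order p = {res.p}")
print(analysis.granger.sleep_to_dep)
print(analysis.granger.dep_to_sleep)
print("cumulative IRF (TIB -> depression), days 0-10:")
print(np.round(analysis.cum_irf["sleep_to_dep"], 2))
print("FEVD share of depression variance explained by TIB, days 1-10:")
print(np.round(analysis.fevd_cross["sleep_to_dep"], 3))
```

prints

```
included: True, lag order p = 3
tib → dep: F(3, 160) = 4.229, p = 0.0066* (positive)
dep → tib: F(3, 160) = 0.211, p = 0.8885 (positive)
cumulative IRF (TIB -> depression), days 0-10:
[0.09 0.46 0.61 0.75 0.72 0.67 0.61 0.59 0.6  0.61 0.62]
FEVD share of depression variance explained by TIB, days 1-10:
[0.005 0.076 0.083 0.09  0.09  0.09  0.092 0.092 0.092 0.092]
```

The planted direction is recovered (TIB → depression significant, positive;
the reverse direction is not), a 1-SD night in bed cumulatively raises the
next ten days' depression score by about 0.6 scale units, and TIB ends up
explaining roughly 9% of the depression forecast-error variance — while
depression explains essentially none of TIB's.

The same pipeline is available from the shell:

```sh
idiovar simulate --n-patients 22 --seed 1 --out-dir data/
idiovar analyze --in data/diary.csv --out-dir results/
idiovar report --results-dir results/ --out-dir report/
```

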