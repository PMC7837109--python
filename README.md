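# itsreg

Interrupted time-series (ITS) regression for weekly event counts, built
around the analysis of emergency-department (ED) attendances in England
before and after the spring-2020 SARS-CoV-2 lockdown. It is aimed at
health-services researchers who have a weekly count series, a known
interruption date, and want the two headline quantities that kind of study
reports: the immediate percentage drop in activity and the percentage-per-week
recovery, each with a simulation-based confidence interval.

## The model

Weekly counts `y_w` are indexed on a global week number where week 1 begins
1 January 2019 (so 2020 starts at week 53). A transition window — by default
the four weeks 63–66, i.e. 11 March to 6 April 2020 — is excluded from the
fit, and the retained weeks are modelled by segmented regression

```
y_w = i + t·w + p·I[w ≥ 67] + s·I[w ≥ 67]·(w − 67) + ε_w
```

with `i` the intercept, `t` the pre-period slope, `p` the level step at the
interruption and `s` the post-period slope change; week 67 is the first
post-interruption (reference) week. The primary fit is OLS; a
negative-binomial (NB2, log link) fit is available as a sensitivity model
for overdispersed counts. Two metrics summarise the fit relative to the
counterfactual baseline `B = i + 67t`:

```
step change      = −p / B             (immediate relative drop)
weekly increase  = (t + s) / B        (recovery per week, as a share of B)
```

95% confidence intervals come from Monte Carlo simulation: coefficient
vectors are redrawn (independent normals on each estimate's standard error,
10,000 replications by default), the metric is evaluated per draw, and the
2.5th/97.5th percentiles are reported. A batch mode repeats the whole
pipeline over subgroup levels (sex, age group, arrival mode, ...) and flags
levels whose intervals do not overlap the overall analysis. A synthetic-data
generator reproduces the statistical regime of the national series
(~200,000 attendances/week pre-period, ~51% drop, linear recovery) so the
full pipeline is testable without access to the restricted hospital extract.

## Worked example

```python
import numpy as np
from itsreg import (SegmentedITSRegressor, SyntheticConfig,
                    generate_series, metric_estimate)

series = generate_series(SyntheticConfig(seed=42))   # gaussian sigma=3000 noise
est = SegmentedITSRegressor().fit(series.week.reshape(-1, 1), series.count)
print("coefficients (i, t, p, s):", np.round(est.coef_, 1))
for m in ("step_change", "weekly_increase"):
    e = metric_estimate(est.coef_set_, m, est.interruption_,
                        n_reps=10_000, seed=42)
    point, lo, hi = e.as_percent()
    print(f"{m}: {point}% (95% CI {lo}-{hi}%)")
```

prints

```
coefficients (i, t, p, s): [ 1.98676e+05 -8.25000e+01 -9.99915e+04  6.00830e+03]
step_change: 51.8% (95% CI 50.1-53.4%)
weekly_increase: 3.1% (95% CI 2.9-3.3%)
```

The generator's true parameters are the reference national fit
(i = 198,577.6, t = −82.3, p = −98,616.1, s = 5,883.0), so the refit
recovers a ~51% immediate drop and ~3%-per-week recovery; the intervals are
narrower than the published ones because a single synthetic draw at
σ = 3000 is less noisy than the real series.

The same analysis is available from the shell:

```
itsreg simulate --sigma 3000 --seed 42 -o counts.csv
itsreg fit counts.csv -o coefficients.csv
itsreg metrics coefficients.csv
itsreg pipeline --synthetic --seed 42 -o out/        # end-to-end bundle
```

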