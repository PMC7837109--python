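# Methods

## Model and assumptions

The package fits a two-segment interrupted time-series regression to weekly
event counts. Weeks are consecutive 7-day bins on a global index with week 1
beginning 1 January 2019; ISO week numbering is deliberately not used, so
2019 contributes weeks 1–52 and 2020 starts at week 53. The interruption is
represented as a contiguous transition window (default weeks 63–66,
11 March – 6 April 2020) that belongs to neither segment: those weeks are
excluded from every fit. Exclusion is the standard "phase-in" treatment for
an interruption that takes effect over several weeks; the package treats it
as a modelling choice, configurable through `InterruptionSpec`.

For retained weeks the design is `(1, w, I[w ≥ r], I[w ≥ r]·(w − r))` with
`r` the reference week (first week after the window, default 67). The
interaction term originates at the reference week — it is zero there — so
the fitted level at week `r` is `i + r·t + p` and the step-change formula
`−p/(i + r·t)` attributes the entire immediate drop to `p`. An alternative
origin (1 at the reference week) would mix the slope change into the step
and break that identity, which is why it is not offered.

Assumptions inherited from the design: the pre- and post-period means are
linear in week, errors are independent across weeks (no autocorrelation
correction), and no seasonal adjustment is applied. Seasonality in real
attendance data inflates residual variance and hence widens intervals
rather than biasing the segment slopes, but users with multi-year series
should be aware the model will fold seasonal swings into noise.

## Model families

* **linear** (primary): OLS on the count scale via statsmodels. Standard
  errors use the unbiased residual-variance estimator; p-values are
  two-sided t with n − 4 degrees of freedom. At least 5 retained weeks are
  required (4 identify the coefficients, 1 the residual variance); a
  4-point design interpolates exactly but has no error estimate, so it is
  rejected rather than fitted with zero-variance standard errors.
* **negative_binomial** (sensitivity): NB2 maximum likelihood with log
  link, variance μ + μ²/θ, θ estimated jointly. Optimisation starts from a
  Poisson GLM with a method-of-moments overdispersion start and tries
  Newton, then Nelder–Mead, then L-BFGS; a fit that fails to converge with
  finite coefficients and covariance raises a non-convergence error
  carrying the last iterate. Counts must be non-negative integers; an
  all-zero series is rejected (degenerate likelihood). Near-Poisson data
  drives θ to very large values, which is reported as-is.

## Metrics

Both metrics are dimensionless proportions relative to the counterfactual
baseline at the reference week, `B = i + r·t` (linear) or `exp(i + r·t)`
(NB): step change `−p/B`, weekly increase `(t + s)/B`. A non-positive
baseline makes them undefined and raises an error.

For the NB family the step change from predicted means is `1 − exp(p)`.
The weekly increase needs care: the log-link mean path is convex, so its
instantaneous slope at the reference week understates a linear recovery.
The package therefore reports the *average* per-week rise of the predicted
mean over a post-period horizon K, `exp(p)·(exp(K(t+s)) − 1)/K`, relative
to the counterfactual baseline. K defaults to 11 weeks — the post-period
span of the reference 78-week design — making the NB metric directly
comparable with the linear family's constant slope when the underlying
recovery is near-linear.

## Monte Carlo intervals

Coefficient vectors are redrawn `n_reps` times (default 10,000, minimum
1,000 for any reported interval) and the metric evaluated per draw; the
interval is the equal-tailed 2.5/97.5 percentile pair, deterministic given
the seed. The default sampling law draws each coefficient **independently**
from a normal with its own standard error. This ignores the (typically
negative) intercept–slope covariance and therefore slightly overstates
baseline uncertainty; because the baseline contributes little to either
metric's variance at realistic signal-to-noise, the effect is small, and
independent sampling reproduces the published reference intervals within
Monte Carlo error. Sampling from the full multivariate normal over the
fitted covariance is available with `sampling="multivariate"`. Draws whose
baseline is non-positive are discarded with a warning; more than 1% of
discards aborts with an error rather than reporting a quietly truncated
interval. Percentile intervals converge at the usual n^(−1/2) Monte Carlo
rate; at 10⁶ replications they agree with a first-order delta-method
approximation to within a few hundredths of a percentage point on the
reference inputs.

## Subgroup analysis

`run_subgroup_analysis` repeats the fit-and-metrics pipeline on every level
of every requested grouping column plus the overall (summed) series. The
significance flag compares 95% intervals: a level is "larger"/"faster" only
when its whole interval lies above the overall interval, "smaller"/"slower"
when entirely below. Interval non-overlap is conservative — the published
subgroup table contains levels (e.g. walk-in arrivals) whose intervals
overlap the overall one even though their point estimates differ markedly —
and a less conservative rule (overall point outside the subgroup interval)
is available via `rule="point_outside"`. Missing or failed intervals
default to "not_different", and failed level fits are reported with an
explicit status, never dropped. No multiplicity correction is applied
across subsets, matching the unadjusted one-at-a-time design this mirrors.
Per-level Monte Carlo seeds derive from the master seed plus a CRC32 hash
of "grouping:level", so a full batch run is bit-reproducible from one seed.

## Synthetic data

The generator emulates the weekly regime the analysis was designed for: a
near-flat pre-period around 200,000 events/week (the reference truth is the
national fit i = 198,577.6, t = −82.3, p = −98,616.1, s = 5,883.0 over 78
weeks), an abrupt ~51% drop, and a linear recovery of ~3% of baseline per
week. Window weeks are filled by linear interpolation between the two
segment endpoints purely so plotted series look right; they are excluded
from fitting, so the fill is statistically inert. Noise families: gaussian
(default σ = 3000, a judgement matched to the visible pre-period scatter of
roughly 181,500–209,100 about the trend), poisson, and negative binomial
(gamma–Poisson mixture with shape θ). Configurations implying a negative
mean at any week are rejected before sampling. Subgrouped datasets split
the baseline by share and give each level its own planted step and slope
multipliers; per-level draws are independent with label-derived seeds.

What the generator does **not** emulate: seasonality, holiday spikes,
week-to-week autocorrelation, and patient-level microdata. Tests passing on
synthetic data therefore demonstrate the correctness of the estimation
machinery under the model's own assumptions, not robustness to the ways
real attendance series violate them.

## Numerical and interface choices

* Problem sizes in the test suite are chosen to keep the full run fast:
  recovery/coverage checks use 200 replicate series with 2,000-replication
  intervals per fit; headline-interval checks use the full 10,000.
* Reports round percentages and count-scale coefficients to one decimal;
  NB coefficient tables keep full precision (log scale).
* Input files are comma- or tab-separated with a header; weeks may be
  integers (`week`) or ISO week-start dates (`week_start`). Gaps are
  tolerated with a warning; duplicate weeks are rejected with line numbers.
* The `itsreg` CLI exposes `fit`, `metrics`, `subgroups`, `simulate` and
  `pipeline`; YAML config files override nothing silently — explicit flags
  win, unknown keys are errors — and report bundles are byte-identical
  across reruns with the same config and seed.

## Known limitations

* Independent-normal coefficient sampling is an approximation; use the
  multivariate option when the fitted covariance is available and the
  baseline is noisy.
* The NB weekly-increase metric depends on the chosen horizon K when the
  recovery is strongly curved on the count scale.
* No autocorrelation-robust standard errors, change-point detection of the
  interruption, or multivariable adjustment across groupings; subgroup
  flags are unadjusted pairwise interval comparisons.
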