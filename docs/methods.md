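# Methods

`itscount` implements an interrupted time-series (ITS) counterfactual
analysis of monthly surveillance counts — the design used to ask how an
abrupt population-level disruption (here, the arrival of a pandemic period)
changed the incidence of an outcome such as deliberate-self-harm emergency
department visits, when randomization is impossible and the pre-intervention
history must supply the control.

## Model

For one subgroup, let `y_t` be the event count in month `t` and `x_t` the
0-based month index counted from the first month of the study window.  The
counts are modelled as negative binomial (NB2) with log link and a population
offset:

```
E[y_t] = exp( b0 + b_trend * x_t
              + sum_{k=1..n} [ b1k sin(2 pi k x_t / 12) + b2k cos(2 pi k x_t / 12) ] )
         * population_t
Var[y_t] = mu_t + mu_t^2 / size
```

The sine–cosine pairs are Fourier harmonics at integer multiples of the
annual frequency; degree `n = 0` is the trend-only candidate.  The offset
enters as person-months with its coefficient fixed at 1, so the linear
predictor models a log *rate*.  Dispersion uses the **size** convention
(`size = 1/alpha` in the usual NB2 notation); large size approaches the
Poisson limit.

The model is deliberately **non-segmented**: it is fitted to the
pre-intervention window only and extrapolated, rather than fitting a
level/slope change to all data.  No autocorrelation correction is applied.
Fitting is joint maximum likelihood (coefficients plus dispersion) via
`statsmodels`' discrete NB2 model started at the Poisson-fit coefficients;
if that optimizer stalls, a profiled likelihood over `log10(alpha)` with GLM
inner fits takes over (profiling is equivalent to joint MLE; the route taken
is recorded in the fit summary).  Reported coefficient covariance is
conditional on the estimated dispersion, as in the common `glm.nb` practice.

The harmonic degree is chosen by AIC over `n = 0..3`, with
`AIC = -2 log L + 2 (p + 1)` counting the dispersion parameter, and ties
broken toward the smaller degree.  `n` is capped at 3 by default: 48 monthly
pre-window observations cannot support high harmonics, and at `k = 6` the
sine column vanishes identically on an integer monthly grid (the design
builder rejects rank-deficient matrices outright).

## Incidence ratios

Annual counts are monthly sums; partial intervention years are refused, not
prorated.  With `O_y` the observed annual count of intervention year `y`,
`E_y` the model-extrapolated expected count, and `P` the pre-period average
annual count,

```
oIR_y = O_y / P            (model-free)
aIR_y = (O_y / person-years) / (E_y / person-years) = O_y / E_y
```

The population is treated as constant within a calendar year, so the
person-year denominators cancel; the code asserts this cancellation
numerically whenever an annual population is supplied.

### Uncertainty

The aIR's sampling distribution is not analytic here (it mixes estimation
error of an extrapolated GLM with NB sampling noise), so the package defines
a **parametric bootstrap predictive test**, which is its own design choice:

1. draw coefficient vectors from `N(beta_hat, cov(beta_hat))`;
2. for each draw, form the year's monthly means with the same design and
   offset and simulate NB monthly counts at the fitted dispersion, under the
   null of no intervention effect;
3. sum to replicate annual counts `A*`;
4. two-sided p-value: twice the smaller of `P(A* >= O_y)` and
   `P(A* <= O_y)`, capped at 1; a zero-count tail is displayed as a bound
   (`<0.001` at 1000 replicates);
5. 95% CI for the aIR: the percentile interval of `O_y / A*`.

Using the same replicate counts for the p-value and the CI keeps the two
coherent: p < 0.05 exactly when the CI excludes 1, up to Monte-Carlo
resolution.  The fitted dispersion is plugged in rather than redrawn, which
makes the test mildly anticonservative with short fitting windows; measured
type-I error at the default study conditions is ~0.07–0.09 at nominal 0.05
(recomputed, not assumed, by `scripts/acceptance.py` and the test suite).
Each year uses an independent child seed (via `SeedSequence`) so adding a
year never perturbs another year's draws.

## Descriptive comparison

The before/during characteristics table compares, per attribute: sex, 28-day
death, any co-occurring mental-health diagnosis and public-assistance pay
code by Fisher's exact test on the 2x2 period-by-level table; age (integer
years) and triage category (ordinal codes 1–5, midrank ties) by the
Mann-Whitney U test.  The Fisher two-sided p-value uses the
probability-ordering rule (sum of hypergeometric probabilities of tables no
more probable than the observed one), computed with log-gamma arithmetic so
cohort-scale cells (order 1e4) remain exact; the odds ratio is the
conditional MLE.  Mann-Whitney uses exact enumeration when both samples have
at most 8 untied observations and the tie-corrected normal approximation with
continuity correction otherwise.  Display percentages are rounded half-up to
printed precision while full-precision values are retained; no
multiple-testing correction is applied across rows.

## Population offsets

Yearly census anchors are placed at January 1, mid-year anchors at July 1.
Monthly denominators are piecewise-linear between anchors with constant
extrapolation beyond the outermost anchor; anchor months reproduce anchor
values exactly, and a single anchor falls back to a constant series with a
logged notice.  The fitted offset can be either the interpolated monthly
series (default) or each year's value held constant over its 12 months; the
aIR is invariant to rescaling the offset by any constant.

## Synthetic data

The generator is the exact inverse of the fitted model, so every downstream
stage can be tested against known truth.  Monthly counts are NB draws around
`mu_t = exp(linear predictor) * population_t * theta_year`, where `theta` is
a per-calendar-year multiplicative intervention effect (`theta = 1`
pre-intervention) — one constant per year, matching a per-year incidence
ratio rather than a continuous post-intervention slope.  The true `mu_t`
travels with each simulated series for assertions.

Default study conditions: an 84-month window (48 pre + 36 intervention
months), a constant population of 2.4 million, `b0 = -10` and
`b_trend = 0.002` per month (about 110 visits/month, the scale of the
largest subgroups in territory-wide self-harm surveillance), one annual
harmonic of amplitude ~0.1 on the log scale, and dispersion size 50 (mild
overdispersion: variance ≈ 3x mean at mu = 100).  The episode-level
generator draws visit dates uniformly within each period and attributes
independently from period-specific probabilities shaped like a large ED
cohort (sex ≈ 53/47 shifting to 50/50, fewer 28-day deaths, more
mental-health co-diagnoses, triage drifting toward "urgent").

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: within-patient correlation (repeat attenders
are treated as independent visits), autocorrelated month-to-month shocks,
reporting artifacts or coding changes, partial-year effects, and dependence
between attributes (sex, age and diagnosis are drawn independently).

## Numerical and design notes

- Month index is 0-based from the study-window start; the same convention is
  used in generation, fitting and prediction, and prediction verifies that
  requested months extend the fit's calendar scheme (misalignment is a hard
  error, being the classic ITS defect).
- Zero-filled months are mandatory in aggregation: a count model cannot skip
  months.
- Age bands are inclusive: 12–17, 18–24, 25–64, 65–84; other ages map to an
  explicit `out_of_band` value (excluded from subgroup analyses, retained in
  the overall descriptive table).
- Episode parsing is strict: all malformed rows are collected with line
  numbers and reported at once; nothing is silently dropped.
- All randomness flows from one seed through `numpy.random.SeedSequence`
  children; reruns with the same config and seed are byte-identical,
  including SVG figures (fixed hash salt, no embedded timestamps).
- Simulation-based checks in the test suite use 100–400 replicates per
  condition and 48–480-month series; these sizes give Monte-Carlo standard
  errors comfortably below the asserted margins.

## Limitations

- The bootstrap test conditions on the estimated dispersion and the normal
  approximation to the coefficient sampling distribution; with 48 fitting
  months it is mildly anticonservative (see above).
- Counterfactual extrapolation amplifies trend-estimation error with the
  horizon; three years beyond a four-year fit is near the practical limit,
  and aIR uncertainty grows accordingly in later years.
- Linear interpolation of population anchors is itself an approximation and
  can bias offsets when the population shifts abruptly within a year.
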