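# Methods

## The model

`povdyn` models a cohort moving through two income states — state 1 *below*
and state 2 *above* a poverty threshold (1×, 2× or 3× an official poverty
line) — on a discrete one-year age grid. Four annual probability functions
parameterize everything:

- `s1(x)`, `s2(x)` — probability of surviving from age `x` to `x+1` given
  the current state;
- `t21(x)` — probability, conditional on survival, of exiting the below
  state by `x+1`; `t11 = 1 − t21`;
- `t22(x)` — probability, conditional on survival, of staying above;
  `t12 = 1 − t22`.

Per age these combine into the unconditional 2×2 block

```
Q(x) = [ s1·t11   s2·t12 ]     (column j = state at age x,
        [ s1·t21   s2·t22 ]      row i = state at age x+1)
```

placed on the block subdiagonal of the age-state matrix **L** (202×202 on the
full 0–100 grid). A cohort vector advances as `n(x) = L^x n(0)`; adding a
mortality row `m = 1 − (column sums)` and an absorbing Death state gives the
column-stochastic chain `P`. Because age strictly advances and the terminal
age class maps to nothing, **L** is nilpotent and the fundamental matrix
`N = (I − L)^{-1} = Σ L^k` is a finite sum. Column sums of `N` are remaining
life expectancies (counting the current year); the below-state rows give
expected remaining years below the threshold; the factorial-moment identity
`η₂' = η₁'(2N − I)` gives the variance and hence the CV of remaining life.
The state structure of any projected cohort approaches the dominant right
eigenvector of the cumulative product `Qcum(x) = Q(x)···Q(first)`; the
subdominant/dominant eigenvalue ratio of the conditional (survival-free)
product governs how fast.

The model is Markov in (age, state): no duration dependence, no frailty —
a deliberately "neutral" theory in which all heterogeneity in lifetimes and
poverty histories is generated by stochastic state switching under shared
rates (individual stochasticity). Trajectory simulation samples each year's
fate in the model's event order: survival first, then, conditional on
survival, next year's state.

## Estimation

Rates are estimated from longitudinal panel data by pooled repeated
observations: every pair of consecutive responded interview waves of every
person contributes one row with predictors (age at the first wave, state at
the first wave). Two weighted logistic regressions are fitted per age
segment — survival to the next wave, and being above the threshold at the
next wave among survivors — with the default linear predictor
`β0 + β1·age + β2·above + β3·age·above` (configurable: quadratic age,
interaction on/off). Fits use maximum likelihood (statsmodels GLM, binomial
family, survey weights as variance weights); standard errors are
weighted-likelihood SEs, not design-based replicate-weight variances.

Panels with different wave spacings must not share an interval scale, so
fitting is per segment: ages 22–33 (≈12.4-month waves), 34–50 (≈24.1) and
51–95 (≈23.8), with boundary ages owned by the younger segment. Fitted
per-interval probabilities are converted to annual rates assuming a constant
hazard within the interval — the per-interval "no event" probability raised
to `12/ī`, with `ī` the weighted mean observed interval of the segment. The
conversion is exact for survival; an alternative that takes the `12/ī`-th
root of the joint 2×2 conditional transition matrix is available behind the
`annualization="matrix"` switch (both are identities at 12-month spacing).
Segments are then concatenated over ages 22–95; the seam ages (33, 50) are
recorded and drawn on every age-axis figure. Predictions outside a segment's
fitted range raise rather than extrapolate.

Known caveat, shared with any design that omits alive non-responders while
ascertaining death from records: among usable pairs the died-fraction is
conditionally inflated by roughly `q(1−r)(1−q)/(q+(1−q)r)` (response rate
`r`, interval death probability `q`) — negligible at young ages, up to ~1σ
of the cell SE at ages 90+ under 5% non-response. The non-response
diagnostic (`nonresponse_by_state_age`) reports next-wave non-response by
age and state, with the deceased removed from denominators, to check whether
response depends on income state.

## The synthetic panel generator

Real income-and-mortality panels of this structure are restricted-access, so
the package generates panels with the statistical structure the estimator
assumes, from a known ground truth: per-segment logistic coefficients on the
per-interval scale (the scale the regression estimates before
annualization), from which the generator samples wave-to-wave fates directly
at each person's current integer age and state. Features emulated: the
three-segment wave design; interview intervals drawn from a normal in months
(SD 1.5–2, truncated at 1, rounded); lognormal survey weights normalized to
mean 1 (σ = 0.5, CV ≈ 0.53 — the real weight distribution is not published);
5% per-wave non-response with an optional odds multiplier for the below
state; death always ascertained at the next scheduled wave; ages as baseline
plus cumulative months rounded to years. The youth segments are birth-cohort
panels (everyone enters at the segment's first age); the 50+ segment has
staggered entry (baselines uniform over 51–95, follow-up may pass 95; such
observations fall outside every segment fit, as when survey data are subset
to an age window). Initial states default to the stationary distribution of
the interval transition matrix at the baseline age.

Not emulated: real income distributions (only the binary state process),
oversampled subgroups, design-based weighting, duration dependence, and
non-response correlated with the impending fate. Tests passing on these
panels show the pipeline is correct under its own assumptions; they cannot
show robustness to the ways real panels violate them.

Default ground truths for the three thresholds are anchored, once, to the
qualitative demography of U.S. poverty dynamics: survival disparities that
are small at young ages, widen to ~1–2 percentage points in the 70s and
cross over near age 90; poverty-exit probabilities that decline with age
(≈0.4 at 22 down to ≈0.08 at 95 for the 1× threshold); above-state stasis
that strengthens to mid-age and erodes afterwards, more steeply for higher
thresholds; quasi-stable below-shares near 12% (1×), 23% (2×) and 35% (3×).
Anchors are specified as annual probabilities at each segment's endpoint
ages and converted to interval-scale logit-linear coefficients, so the
implied annual curves pass exactly through them. They are plausibility
choices, not a calibration to any published estimate: downstream magnitudes
(expectancy-gap peaks, residence-time moments) follow from the anchors and
are reported as computed.

## Numerical choices

- `N` is computed by a triangular solve of `I − L` (unit diagonal, lower
  block-triangular), which is an exact back-substitution by age; tests pin
  it to the dense inverse and the truncated power series at 1e-10.
- 2×2 eigenstructure is closed-form; a tie in eigenvalue modulus raises
  `NoDominantEigenvalueError` instead of silently picking a branch; dominant
  eigenvectors are sign-fixed nonnegative and normalized to sum 1.
- Cumulative block products accumulate left-to-right deterministically.
- Ages outside 22–95 on the 0–100 grid clamp to the nearest fitted rates;
  all substantive life-table output uses the restricted grid (first fitted
  age through 100). Cohort-projection diagnostics run from birth on the full
  grid, since the projection equation tracks a cohort from age 0.
- Life-expectancy convention: the current year is counted (column sums of
  `N`); the exclude-current convention is one flag away and differs by
  exactly 1 everywhere; the variance is convention-invariant.
- Degenerate probabilities in test truths are encoded with logit ±500
  (`expit(500) == 1` in float64), keeping coefficient arithmetic finite.
- Perfect separation is detected before fitting (no outcome variation) and
  after (|coef| or SE beyond 50 on these scales) and raised as
  `SeparationError`; rare events at small panel scales (e.g. a handful of
  deaths under age 34) genuinely separate and are reported, not smoothed.
- Simulation draws are age-major across the cohort from one seeded
  generator: bitwise reproducible for fixed seed and cohort size.
- Residence-time accounting: starting below counts as an entry at the start
  age; death while below (including forced death after the terminal age)
  counts as an exit at the age the individual would have reached; the mode
  of years-below uses integer bins with ties to the smaller value.

## Problem sizes

The default panel design yields roughly 10^5 pooled observation pairs per
segment (≈10,100 / 14,000 / 30,000 persons), matching the order of the
survey data sets this design emulates. Parameter-recovery validation uses a
variant of the same plans with constant weights and full response, sized to
~10^5 in-range pairs per segment, so recovery error reflects only estimator
sampling variability; under the 2× threshold (both states well populated at
every age) the recovered annual rates sit within ~0.008 of truth in maximum
absolute error, while under the 1× threshold the rare below-state at old
ages leaves edge-age errors of ~0.01–0.02 at this sample size — a
sample-size statement, not a bias: at ~7×10^5 pairs the same curves are
recovered to ≤0.0035. Simulation-vs-chain consistency checks use 10^5
replicates (3-SE agreement); reported cohort simulations use 10,000
individuals.

## Limitations

- Two states only; no duration dependence, period effects, covariates beyond
  age and state, or intergenerational structure.
- Weighted-likelihood SEs understate design-based uncertainty for complex
  survey weights.
- The constant-hazard annualization treats each probability separately; the
  matrix-root alternative is provided but can fail for non-embeddable
  interval matrices.
- Convergence of cohort state structure to the dominant eigenvector of the
  cumulative product is verified empirically on the fitted rate sets, not
  proven in generality.
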