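# povdyn — age-by-state Markov models of poverty dynamics and mortality

People cross income thresholds throughout life, and which side of a
threshold they are on affects their chance of surviving the year. `povdyn`
is for demographers and population-health researchers who want to turn
longitudinal panel data into a discrete-age, two-state (below/above a
poverty threshold) Markov chain and read off what that transience implies:
age-specific survival disparities, the state structure of an aging cohort,
remaining life expectancy and its variance by state, and the distribution of
total years an individual spends in poverty.

The chain is built from four annual probability functions — state-specific
survival `s1(x)`, `s2(x)` and, conditional on survival, the state-switching
probabilities `t21(x)` (exit poverty) and `t22(x)` (stay above) — combined
per age into the block

```
Q(x) = [ s1·t11  s2·t12 ]
       [ s1·t21  s2·t22 ]
```

on the block subdiagonal of an age-state matrix **L** (202×202 for ages
0–100). Cohorts project as `n(x) = Lˣ n(0)`; appending a mortality row makes
an absorbing chain, whose fundamental matrix `N = (I − L)⁻¹` yields
remaining life expectancy (column sums), expected remaining years below the
threshold (below-state rows), and the variance of remaining life via
`η₂' = η₁'(2N − I)`. The probabilities themselves are estimated from panel
data by pooled repeated observations: weighted logistic regressions of
survival and next-wave state on (age, current state), fitted per interview
segment and converted from the irregular interview interval to annual rates
by a constant-hazard root. Because real panels of this kind are
restricted-access, the package includes a first-class synthetic panel
generator with known logit-scale ground truth, used by the whole test suite.

## Worked example

Parameterize the model directly from coefficient tables (here: the package's
built-in ground truth for the 1× threshold), then query the chain:

```python
from povdyn import PovertyDynamicsModel
from povdyn.estimation import segment_fits_from_truth
from povdyn.simulation import residence_summary
from povdyn.synthetic import default_truth

res = PovertyDynamicsModel.from_coefficients(
    segment_fits_from_truth(default_truth("1x"))).fit()

lt = res.life_table()                      # per (age, state) summary
row = lt[lt.age == 40].set_index("state")
for s, name in ((1, "below"), (2, "above")):
    print(f"age 40, {name}:  e = {row.loc[s,'expectancy']:.2f} y, "
          f"years below = {row.loc[s,'years_below']:.2f} y, "
          f"var = {row.loc[s,'variance']:.1f}")
print(res.state_structure(ages=[30, 50, 80]).to_string(index=False))

traj = res.simulate(n=10_000, seed=1)      # individual trajectories
summ = residence_summary(traj)
print(f"simulated years below 1x poverty (n=10,000): "
      f"mean {summ.mean:.2f}, sd {summ.sd:.2f}, mode {summ.mode}")
```

which prints:

```
age 40, below:  e = 35.40 y, years below = 7.57 y, var = 132.9
age 40, above:  e = 35.56 y, years below = 4.27 y, var = 128.8
 age  proportion_below  damping_ratio
  30          0.100201   1.558410e+02
  50          0.121827   3.031069e+05
  80          0.174638   1.178389e+08
simulated years below 1x poverty (n=10,000): mean 6.39, sd 6.37, mode 0
```

Reading this: a 40-year-old below the 1× threshold expects 35.4 more years
of life, 7.6 of them below the threshold — about 3.3 years more poverty than
an otherwise identical 40-year-old currently above it, whose expectancy is
only ~0.16 years longer (state at one age is transient, so the gap is far
smaller than a permanent-state comparison would suggest). About 12% of the
cohort sits below the threshold at age 50, and the huge damping ratios say
any initial state mix converges onto that quasi-stable structure within a
few years. The most common simulated outcome is never spending a year below
the threshold (mode 0), yet the mean is 6.4 years with an SD as large as
the mean — dynamic heterogeneity generated purely by stochastic switching.

To estimate from a panel instead, pass the person-wave table:

```python
from povdyn.synthetic import default_design, default_truth, generate_panel

panel = generate_panel(default_truth("1x"), default_design(), seed=1)
res = PovertyDynamicsModel(panel).fit()
print(res.summary())                       # coefficient tables + headline numbers
```

A `povdyn` command line wraps the same stages
(`povdyn generate|estimate|analyze|simulate|all --config config.yaml`),
writing CSV tables, JSON coefficient files and PNG figures per threshold.

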