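# Methods

## The score and its conventions

For indicator *k* in DA *i*, the gender inequality score is
`s_ik = p_f / (p_f + p_m)` where `p_f`, `p_m` are the sex-specific values:
`num/den` for proportion indicators, or the per-sex mean employment income
(thousand CAD) for the income indicator. The score is scale-invariant
(`s(cf, cm) = s(f, m)`), antisymmetric under sex swap (`s(f,m) + s(m,f) = 1`),
strictly increasing in the female value, and bounded in [0, 1].

Boundary conventions:

- **Both sex values zero.** There is no gender difference by definition; the
  score is attributed as 0.5 and tagged `both_zero`. This arises naturally
  for rare outcomes (e.g. decision-making government positions) in small DAs.
- **One-sided zero value.** `s = 0` or `s = 1` is a legitimate, maximal
  inequality and is kept.
- **Zero denominator for exactly one sex** (a mixed-sex DA with no eligible
  people of one sex for an age-restricted indicator): that sex's proportion
  is undefined and the cell is emitted as absent rather than forced to a
  boundary. This case is rare and ambiguous; omission keeps the score table
  honest.

Exclusion rules, applied in fixed precedence so counts decompose
deterministically: DAs with any missing required field are removed first,
then DAs with an exclusively single-sex population; DAs with zero labour
force (labour-force-participation numerators summing to zero) are retained
but ineligible for the two labour-force indicators. Age restrictions
(≥15/20/25) are treated as already embodied in the input denominators, as
they are in aggregate census cells.

## Monte Carlo heterogeneity test

Null hypothesis: gender inequality is homogeneous across DAs — every DA
shares the same sex-specific rates, so across-DA score variance is pure
sampling noise. Construction:

- **Pooling.** Proportion indicators: `p̂_sex = Σ num / Σ den` over all
  eligible DAs province-wide (not per area type). Income: the
  population-weighted mean of DA sex means, and the person-level SD implied
  by the model `x_i ~ N(μ, σ²/w_i)`, estimated as
  `σ̂² = Σ w_i (x_i − μ̂)² / (n − 1)` with `w_i` the sex population. This
  makes the income null self-consistent with the replicate law below.
- **Replicates.** For each eligible DA, numerators are drawn
  `Binomial(den, p̂)` per sex (income: sex means `Normal(μ̂, σ̂/√w_i)`,
  truncated at zero since a mean income cannot be negative), scores are
  computed with all conventions including both-zero → 0.5, and the sample
  variance (n − 1 denominator) of the replicate's scores is recorded.
- **P-value.** With r of R null variances at or above the observed variance,
  `p = (r + 1)/(R + 1)`; the add-one rule bounds p in [1/(R+1), 1] and can
  never return zero. Default R = 999.
- **Eligibility is shared.** The same eligible DA set (positive denominators
  for both sexes; labour force present where required) is used for the
  observed and every null variance, so ineligible DAs can neither create nor
  mask heterogeneity.
- **Determinism.** Eligible DAs are sorted by `da_id` before drawing, so the
  p-value is invariant to input row order; `heterogeneity_all` spawns one
  seed substream per indicator, so adding indicators or replicates never
  perturbs the others.

The test statistic is the plain sample variance of DA scores: it is the
quantity of interest itself and the simplest sufficient choice. The null
parameters are plug-in estimates from the observed data (a parametric
bootstrap), which is approximately — not exactly — calibrated; the
acceptance suite verifies type-I error within [0.02, 0.09] at α = 0.05 and
Kolmogorov–Smirnov uniformity of null p-values, and ≥90% power against a
logit-scale between-DA SD of 0.5 at 200 DAs with R = 199.

## Rank-based comparisons

Kruskal–Wallis (tie-corrected, chi-square reference with k − 1 df) compares
score distributions across area types; a degenerate all-equal input yields
H = 0, p = 1. Pairwise Mann–Whitney U tests are gated on the omnibus
rejecting at α = 0.05 (overridable) and use the tie-corrected normal
approximation — appropriate at hundreds-to-thousands of DAs; tests verify it
against exact enumeration at pooled n = 8, where its absolute error can
reach ~0.13, the documented worst case at that size. Bonferroni adjustment
is `min(1, 3p)` for the three area pairs. Spearman correlation is the
Pearson correlation of mid-ranks; a constant vector returns NaN (undefined).
These standard tests are delegated to scipy.stats behind the module surface;
the test suite checks them against independent rank-arithmetic and
enumeration oracles.

The correlation gate reads the published criterion `r ≥ 0.4` as `|r| ≥ 0.4`
(boundary inclusive), because strongly negative correlations — income and
unpaid housework both at r = −0.4 in the motivating analysis — are exactly
the cases the stratification is meant to explore.

## Population-weighted tertiles

DAs are sorted by overall (both-sex) indicator level, ties broken by
`da_id`; cumulative population is accumulated and cuts fall at the first DAs
whose cumulative totals reach 1/3 and 2/3 of the total population, the
straddling DA going to the lower tertile (first-reach rule). Each tertile's
population is then within one DA's population of total/3. Boundaries are
computed once on the pooled DA universe and crossed with area type, giving
one boundary pair per indicator across all three areas. The per-area
Kruskal–Wallis p-values compare the three tertiles *within* each area (the
row-wise reading; comparing areas within a tertile is the other possible
design and is not what this package computes).

The overall income level of a DA is the population-weighted mean of the two
sex mean incomes — "overall income" has no canonical aggregate-census
definition, and the weighted recombination is the one consistent with how
overall proportions pool counts.

## Synthetic census generator

The generator emulates a provincial DA extract so every stage is testable
without external data. Defaults are fixed at the study composition:

| parameter | default | meaning |
|---|---|---|
| `n_das` | 11,612 | DA count of a provincial extract |
| `population_range` | (400, 700) | residents per DA, uniform |
| `area_type_shares` | (0.6, 0.2, 0.2) | metropolitan / mid-sized / rural; most DAs of a largely urban province are metropolitan |
| `sex_rates` | per indicator | female/male rates at published provincial means (e.g. divorce 0.112/0.101, labour force 0.570/0.698) |
| `heterogeneity_sd` | 0.2 | logit-scale between-DA SD of the female rate; 0 = homogeneous null |
| `income_params` | μ 22.0/32.9, person SD 15/25, between-DA SD 3.0 (thousand CAD) | income law per sex |
| `n_missing`, `n_single_sex`, `n_zero_labour` | 12, 36, 15 | planted exclusion pathologies |
| `sampling_fraction_20pct` | 0.2 | denominator shrinkage of long-form items |

Mechanics and deliberate simplifications:

- Sex split is Binomial(pop, 0.5) — the simplest symmetric default.
- Between-DA heterogeneity enters on the logit scale for the **female rate
  only**, keeping the male rate fixed, so the null/alternative contrast is
  one-parameter. A side effect is a mechanical positive coupling between a
  DA's score and its overall level, which is what lets high
  `heterogeneity_sd` configurations drive indicators through the |r| ≥ 0.4
  gate in tests.
- The 20%-sample long-form items are emulated by shrinking denominators by
  the sampling fraction before the binomial draws — this reproduces the
  extra sampling noise the Monte Carlo must absorb without modelling census
  household weights. Divorce and single-headed households are treated as
  100%-sample demographic items.
- Employment rate is modelled on the ≥15-population denominator with rates
  near the published sex-specific means (53.3%/64.3%), which are printed on
  that scale; the zero-labour-force exclusion still applies to it.
- Indicator universes are fixed fractions of the sex population (0.80 /
  0.75 / 0.70 for ages ≥15/≥20/≥25; 0.45 for household reference persons) —
  no age-structure model.
- Income is simulated directly as per-sex DA means (between-DA normal plus
  mean-of-n sampling noise), matching the aggregate null model rather than
  person-level microdata. Income SDs are free parameters, as no published
  values exist for them.
- Missing-data DAs are emitted with genuinely absent fields (empty CSV
  cells), not zeros, so filter logic is truly exercised; single-sex DAs
  carry zero counts for the absent sex.
- No spatial autocorrelation, household structure, or real census
  geography identifiers.

What passing tests therefore show: the scoring, exclusion, testing and
stratification machinery is correct under binomial/normal sampling at
realistic DA sizes and rates. What they do not show: robustness to census
weighting artefacts, spatially correlated heterogeneity, or age-structure
confounding, none of which the generator produces.

## Numerical choices

- Quartiles use the median-unbiased linear-interpolation rule
  (`numpy.quantile(..., method="median_unbiased")`) so interquartile ranges
  are reproducible bit for bit; SDs use the n − 1 denominator.
- Scores are kept at full precision internally; rendered tables round scores
  to 2 dp, percentages to 1 dp, and print p-values with "< 0.01" /
  "< 0.001" thresholds, while machine-readable CSVs keep raw values.
- The pipeline's master seed spawns independent substreams per stage
  (generation, Monte Carlo), recorded in `manifest.json`; the manifest
  suffices to reproduce every number exactly.
- Problem sizes in the test suite (200-DA calibration runs with R = 199 and
  200 repetitions; 2,000-DA recovery checks; an 11,612-DA structural run at
  R = 199) were chosen as the smallest sizes at which the binomial bands in
  the checks are informative.

## Known limitations

- The heterogeneity test is a plug-in parametric bootstrap: calibration is
  approximate, very slightly conservative/liberal depending on the
  indicator's denominators; exact conditional calibration is out of scope.
- The score of means differs from the mean of scores (Jensen): summaries
  report the mean of per-DA scores, which carries O(1/den) small-sample bias
  relative to the score of the underlying rates.
- A DA's undefined cells are dropped rather than imputed; under informative
  missingness the summaries would be biased, as with any complete-case rule.
- The between-area analysis treats DAs as exchangeable within area type; no
  spatial or multilevel structure is modelled.
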