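# Methods

This note documents the models, estimators and calibration choices
behind biofilmkit, the defaults that matter, and what the synthetic
data generator does and does not emulate.

## Plate normalization

Raw crystal-violet absorbance (OD595) is meaningful only relative to a
plate's own baseline: staining intensity drifts between plates. Each
plate must therefore carry plasmid-free (WT) monoculture wells
(default expectation: 8; at least 4 are required so that outlier fences
are defined). The reference statistic is the mean of the WT wells that
survive one pass of the Tukey-fence filter
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; every other well on the plate is
divided by it. Quartiles use linear interpolation between order
statistics (the "type 7" rule, the default of most statistical
environments). The filter is deliberately single-pass and is applied at
exactly two points — the WT reference wells per plate, and the
per-condition biological replicate values before testing — never
iterated to convergence, which would bite arbitrarily deep into a
clean sample.

Uninoculated (BLANK) wells are used only as a sanity gate: blanks are
expected within 0.05–0.07 OD and inoculated wells within 0.10–0.51.
Out-of-envelope wells are logged, not rejected, and no blank
subtraction is performed (the normalization ratio absorbs the additive
background to first order).

Technical wells of one biological replicate are collapsed by their
mean. The data model does not require technical replicates; a single
well passes through unchanged.

## Hypothesis testing

All tests are two-sided at α = 0.05.

* **Omnibus:** Welch's one-way ANOVA. Group variances in biofilm data
  routinely differ several-fold between strains, so the
  heteroscedasticity-robust form is the omnibus everywhere. Groups with
  zero variance are refused rather than patched — with multiplicative
  noise they indicate a degenerate input, not a valid measurement.
* **Post hoc, many-to-one:** Dunnett's test in its classical
  pooled-variance form. Adjusted p-values are
  `p_i = P(max_j |T_j| ≥ |t_i|)` under the equicorrelated
  multivariate-t null. Because the Dunnett correlation matrix
  factorizes (`ρ_ij = λ_i λ_j`, `λ_i = √(n_i/(n_i+n_0))`), the CDF of
  `max|T|` reduces to a double integral over the shared normal factor
  and the pooled scale, which is evaluated with 200-point
  Gauss–Legendre quadrature on the probability scale of each variable.
  Critical values are root-found to 1e-4; adjusted p-values agree with
  an independent implementation to ~5e-5 and with the pooled two-sample
  t-test to < 1e-6 in the single-treatment reduction.
* **Post hoc, all-pairs:** Tukey(–Kramer) with studentized-range
  p-values, pooled variance.
* **Gating:** post hoc tests run only when the omnibus is significant;
  otherwise every comparison is reported non-significant. A switch
  (`gate_on_omnibus=False`) allows ungated post hocs for sensitivity
  analysis. The omnibus/post-hoc split (robust omnibus, classical
  post hocs) is a deliberate compromise: fully heteroscedastic
  multiple-comparison procedures exist but are less standard, and the
  simulator's log-normal noise keeps group variances comparable on the
  scales tested.
* **Two samples:** Welch's t-test with Welch–Satterthwaite df. Two
  identical constant samples give t = 0, p = 1 by convention.
* **Normality:** Shapiro–Wilk (AS R94), 3 ≤ n ≤ 5000.

### Exact r×c test

The Freeman–Halton extension of Fisher's exact test is implemented by
full enumeration: all tables with the observed margins are generated
recursively, each weighted by its multivariate hypergeometric
probability (computed in log-space via log-gamma). The two-sided
p-value sums the probabilities of all tables at most as probable as the
observed one, with the relative comparison tolerance 1e-7 used by
standard implementations; enumerated probabilities sum to 1 within
1e-13 on the table sizes of interest. Enumeration is refused above 500
total observations, where a margin-preserving Monte Carlo estimate
(via `scipy.stats.random_table`) takes over.

## Outcome classification

`pattern_to_outcome` is a pure, total function of the three Tukey
significance flags and the three sample means; exhaustive enumeration
over all 8 × 6 input combinations is part of the test suite. Two
conventions needed fixing where the taxonomy is silent:

* The Highest/Lowest dominance subclass is decided by which
  single-plasmid strain produced more biofilm *on the sample means
  alone* — significance of A vs. B is not required, matching how the
  subclass is named rather than tested.
* Exactly tied single-plasmid means (a measure-zero event) break toward
  Dominance-by-the-Highest and are flagged in the output.

A non-significant omnibus maps to Undetermined: no pairwise difference
is claimed that an omnibus could not support.

## Conjugation and growth

Conjugation efficiency is the end-point ratio T/(D×R) (mL/CFU).
Zero transconjugants return efficiency 0 with an explicit flag so that
downstream log10 transforms can exclude the point deliberately; zero
donors or recipients are refused. Colony counts convert to densities as
`colonies × dilution / plated volume`.

Growth rates use a two-phase "easy linear" fit of ln(OD600) vs. time:
all windows of `min_window = 5` consecutive points (50 min at 10-min
sampling) above the detection floor (0.005 OD) are fitted; the
steepest window seeds the estimate; every window whose slope reaches
95% of the seed slope is pooled; and one regression over the pooled
points gives the rate, accepted when its R² ≥ 0.95. The pooling step
matters: taking the steepest qualifying window outright inflates the
rate by ~3% at 1% multiplicative noise (a max-of-noisy-estimates
bias), while pooling brings the bias below 0.1% yet still confines the
fit to the early exponential phase of a logistic curve (measured −3.3%
on a noiseless logistic rising from 1% of carrying capacity, against a
5% tolerance). Technical replicates failing the R² gate are discarded
before averaging; biological rates are divided by the mean plasmid-free
rate to give relative growth rates.

## Correlation with outlier exclusion

Per-plasmid summary points (e.g. mean relative biofilm vs. log10
efficiency) are screened iteratively: fit y ~ x, compute externally
studentized residuals (via statsmodels), and drop the largest-residual
point if its Bonferroni-corrected two-sided outlier p-value is below
0.05; repeat up to `max_removals = 2`. Survivors get an OLS fit and a
two-sided Pearson test; the report carries slope, intercept, R²,
residual variance SSR/(n−2), ρ, df = n_used − 2 and the excluded
labels. Zero or negative efficiencies are dropped with a warning before
the log10 transform. A constant coordinate among survivors yields
ρ = 0, p = 1 with a warning rather than an error.

## Synthetic data generator

The generator emulates the *measurement layers* of a plate study, not
the biology: per-plate baseline variation, multiplicative condition
effects, counting noise and instrument envelopes.

* **Plates.** Each biological replicate occupies one plate with its own
  WT wells (8) and blanks (4). The per-plate WT baseline is uniform on
  `baseline_range = (0.17, 0.22)`; wells are
  `baseline × effect × exp(N(0, noise_sd))` with `noise_sd = 0.10` on
  the log scale. Noise is multiplicative because OD readings are
  positive and effects act as ratios. Wells are clipped into the
  inoculated envelope [0.10, 0.51] with a warning (a stain readout
  saturates at the top and bottoms out at residual stain), and blanks
  are uniform on [0.05, 0.07]. The baseline band is narrower than the
  0.10–0.35 envelope WT reads may occupy: drawing baselines from the
  full envelope would force heavy clipping for strong enhancer effects
  and distort them.
* **Default panel.** Eleven plasmids: eight enhancers (effects
  1.5–2.2), two reducers (0.6, 0.7), one neutral (1.0) — the
  composition a natural-plasmid screen typically shows. Six default
  pairs cover the dominance, increased, decreased and intermediate
  interaction modes, each represented in both intracellular (`A+B`)
  and intercellular (`A|B`) form; modes are chosen so every implied
  pair mean stays inside the measurable envelope. WT monoculture wells
  are individual biological replicates — grouping them per plate would
  collapse every WT value to exactly 1 by the normalization identity.
* **Pair modes.** `dominant_A/B` pin the pair mean to one single's
  effect; `additive` uses `effect_A + effect_B − 1` (joint effect on
  the relative scale); `increased`/`decreased` place it 20% above the
  larger / 25% below the smaller single effect; `intermediate` at
  their midpoint; `null` at the plasmid-free level. The ground-truth
  category is derived by feeding the exact mean (in)equalities through
  the same pattern map the classifier uses, so truth and pipeline
  share one taxonomy (note that `null` with enhancer singles is
  therefore truthfully a joint *decrease*).
* **Matings.** Donors and recipients settle near half the carrying
  capacity (2×10⁹ CFU/mL overall) with 5% log-normal variation;
  expected transconjugants are γ·D·R; colony counts are
  Poisson-sampled at ten-fold dilutions auto-chosen to land near 100
  colonies per plate. Double-plasmid fractions default to 0.45 for
  pairs involving the high-efficiency plasmid F and 0.13 otherwise
  (log-normal jitter 0.08) — the two regimes such assays show.
* **Growth curves.** Logistic trajectories starting from the overnight
  density diluted 100-fold (2×10⁷ CFU/mL), sampled every 10 min for
  16 h, OD calibrated at 1.0 ≈ 2×10⁹ CFU/mL, multiplicative noise 2%.
  A pure-exponential option exists for exactness checks, since a
  logistic curve's early log-slope is r(1 − N₀/K) ≈ 0.99 r, never
  exactly r. Inoculum bookkeeping follows the two-step biofilm scheme
  (5 µL of each overnight culture into a 200 µL mix, 5 µL transferred:
  2.5×10⁵ CFU per strain) and the 100-fold growth-assay dilution.

Everything is driven by one integer seed through
`numpy.random.default_rng`; identical configurations give bit-identical
outputs.

**What passing tests do and do not show.** The generator reproduces
measurement noise, plate structure and counting statistics, so green
tests demonstrate that the pipeline recovers known effects *under those
noise models*. Real data add layers the generator omits: spatial plate
effects (edge evaporation), non-multiplicative staining artifacts,
day-to-day batch effects beyond a scalar baseline, conjugation dynamics
during the assay itself, and plasmid incompatibility. Results on real
plates therefore still require the raw-envelope sanity gate and visual
inspection of the intermediate tables the pipeline writes.

## Problem sizes

The test suite and the acceptance script use: 500 simulated triplet
datasets per interaction mode (n = 8 replicates, smallest mean
separation five noise SDs); 10⁴ replicates for each family-wise error
simulation (Dunnett k = 11 treatments of n = 6; Tukey k = 3 of n = 8),
run as vectorized max-statistic simulations against critical values
from the same reference distributions the public procedures use, with
spot-check agreement against the procedures themselves; exhaustive 2×2
exact-test comparison up to total 30 (≈ 44,500 tables); 150 seeded
end-to-end effect-call studies; and 200 regression-recovery seeds.

## Known limitations

* Dominance subclass labels on near-tied single-plasmid means are
  noise-sensitive even when the dominance call itself is stable.
* The exact r×c test's full enumeration is exponential in table size;
  beyond ~500 observations only the Monte Carlo path is available.
* Welch's omnibus is paired with classical pooled-variance post hocs
  (see above); severe heteroscedasticity between triplet groups could
  in principle distort post hoc error rates.
* The growth estimator assumes a single exponential phase; diauxic
  curves will yield the steeper phase only.
* The pipeline treats plates as exchangeable given their baseline; it
  does not model or remove within-plate spatial gradients.
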