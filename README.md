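# biofilmkit

Analysis pipeline for microtiter-plate studies of how conjugative
plasmids — singly and in pairs — change *Escherichia coli* biofilm
formation. It takes raw crystal-violet OD595 plate readings, colony
counts from mating assays and OD600 growth curves, and produces
per-plasmid effect calls, a five-category dominance classification of
plasmid pairs, conjugation efficiencies, relative growth rates and the
correlation analyses that tie them together. A calibrated synthetic-data
generator with known ground truth makes every stage testable without
wet-lab data.

Intended users: microbiologists running crystal-violet biofilm screens
and anyone who needs a reproducible, scriptable version of the plate →
statistics → classification workflow.

## The statistics at the core

**Normalization.** Every well on a plate is divided by the
outlier-filtered mean of that plate's plasmid-free (WT) monoculture
wells, so all values are biofilm formation relative to WT. Outliers are
removed by the Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` (type-7
quartiles, single pass).

**Effect calls.** Populations are compared to WT with Welch's
heteroscedasticity-robust one-way ANOVA; when the omnibus is significant
(α = 0.05, two-sided), Dunnett's many-to-one test assigns each
population *increased*, *decreased* or *no change*. Dunnett adjusted
p-values come from the equicorrelated multivariate-t reference
distribution, evaluated by numerical quadrature, so unbalanced designs
are handled exactly.

**Dominance classification.** For a pair (A, B), with B_AB the biofilm
of the two-plasmid population and B_A, B_B the single-plasmid strains
(Welch ANOVA + Tukey all-pairs, ≈ non-significant / ≠ significant):

| pattern | category |
|---|---|
| B_AB ≈ B_A and B_AB ≠ B_B | Dominance (by the Highest if the matching single strain made more biofilm, else by the Lowest) |
| B_AB ≠ both and above both means | Increased |
| B_AB ≠ both and below both means | Decreased |
| B_AB ≠ both, between them — or ≈ both while B_A ≠ B_B | Intermediate |
| no significant differences anywhere | Undetermined |

Category tallies per co-cultivation mode (intracellular: both plasmids
in one cell; intercellular: two co-cultured single-plasmid strains) are
compared with an enumeration-based two-sided Fisher–Freeman–Halton exact
test for r×c tables.

**Conjugation and growth.** End-point conjugation efficiency is
T/(D×R) in mL/CFU (transconjugant over donor-times-recipient CFU/mL
densities). Growth rates are the steepest log-linear stretch of each
OD600 curve (two-phase "easy linear" fit; fits with R² < 0.95 are
discarded) expressed relative to the mean plasmid-free rate. Per-plasmid
summaries are correlated (Pearson, OLS) after Bonferroni-corrected
externally-studentized-residual outlier exclusion (at most two points).

## Worked example

```sh
biofilmkit simulate --seed 7 --out demo
biofilmkit run-all --plates demo/plates.csv --matings demo/matings.csv --out demo/report
```

or from Python (`examples/02_normalize_and_effects.py`):

```
 plasmid  direction     p(adj)  true
    R124  increased   0.00e+00  increased
       F  increased   0.00e+00  increased
     ...
    R388  no_change   1.00e+00  no_change
     RN3  decreased   1.78e-15  decreased
    R16a  decreased   0.00e+00  decreased

8 increased / 2 decreased / 1 unchanged
```

The simulated panel was built with eight biofilm-enhancing plasmids, two
reducers and one neutral plasmid; the effect-call stage recovers exactly
that 8/2/1 split, with Dunnett-adjusted p-values controlling the
family-wise error across the 11 comparisons. The scripts in `examples/`
walk through each capability: simulation, normalization and effect
calls, dominance classification, conjugation efficiency, growth rates,
and correlation.

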