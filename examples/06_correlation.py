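"""Correlate mean relative biofilm with log10 conjugation efficiency.

Per-plasmid summary points are screened with the Bonferroni-corrected
externally studentized residual test (at most two removals), then
ordinary least squares and the two-sided Pearson test run on the
survivors.
"""

import numpy as np

from biofilmkit.regression import PairedSeries, correlate_with_exclusion, log10_positive

rng = np.random.default_rng(8)
labels = [f"p{i:02d}" for i in range(11)]
efficiencies = 10 ** rng.uniform(-13, -9, 11)  # mL/CFU
log_labels, log_eff = log10_positive(labels, efficiencies)
# biofilm rises with conjugation ability, plus one aberrant plasmid
biofilm = 0.25 * np.array(log_eff) + 4.0 + rng.normal(0, 0.15, 11)
biofilm[3] += 2.5

series = PairedSeries(labels=tuple(log_labels), x=tuple(log_eff), y=tuple(biofilm))
r = correlate_with_exclusion(series, max_removals=2)

print(f"y = {r.slope:.2f}x + {r.intercept:.2f}, R^2 = {r.r_squared:.2f}, "
      f"sigma^2 = {r.residual_variance:.2f}")
print(f"Pearson rho = {r.rho:.2f}, d.f. = {r.df}, p = {r.p:.3g}")
print(f"excluded as outliers: {list(r.excluded_labels) or 'none'}")
# A positive slope means better conjugators build more biofilm; df is
# n_used - 2 after the outlier was set aside.
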