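"""Normalize raw OD595 readings and call per-plasmid effects.

Every well is divided by its plate's outlier-filtered plasmid-free mean,
technical wells collapse to biological replicates, and each population
is compared to the plasmid-free reference with Welch's ANOVA followed by
Dunnett's many-to-one test.
"""

from biofilmkit.classify import call_effects
from biofilmkit.plates import REFERENCE_CONDITION, aggregate_replicates, normalize_plate
from biofilmkit.simulate import SimulationConfig, simulate_plate_set

cfg = SimulationConfig(seed=7, pair_modes={})  # 11 single plasmids + WT
readings, truth = simulate_plate_set(cfg)

by_plate: dict = {}
for w in readings:
    by_plate.setdefault(w.plate_id, []).append(w)
normalized = []
for plate in by_plate.values():
    normalized.extend(normalize_plate(plate))
samples = aggregate_replicates(normalized)

reference = next(s for s in samples if s.condition == REFERENCE_CONDITION)
others = [s for s in samples if s.condition != REFERENCE_CONDITION]
calls = call_effects(others, reference, alpha=0.05)

print(f"{'plasmid':>8} {'direction':>10} {'p(adj)':>10}  true")
for c in calls:
    print(f"{c.condition:>8} {c.direction:>10} {c.p_adjusted:>10.2e}  "
          f"{truth.effect_direction[c.condition]}")
n_up = sum(c.direction == "increased" for c in calls)
n_down = sum(c.direction == "decreased" for c in calls)
print(f"\n{n_up} increased / {n_down} decreased / {len(calls) - n_up - n_down} unchanged")
# The adjusted p-values control the family-wise error over the 11
# comparisons; a direction other than no_change means the population's
# biofilm level differs significantly from the plasmid-free strain.
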