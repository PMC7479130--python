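"""Generate a complete synthetic plate study with known ground truth.

The generator emulates the measurement layers of a plasmid/biofilm
screen: per-plate plasmid-free baselines, multiplicative plasmid
effects, log-normal well noise and the raw-read envelopes of a crystal-
violet assay. The ground truth records what each condition was built to
do, so every later stage can be scored against it.
"""

from biofilmkit.simulate import SimulationConfig, simulate_plate_set

cfg = SimulationConfig(seed=42)
readings, truth = simulate_plate_set(cfg)

print(f"{len(readings)} wells across {len({w.plate_id for w in readings})} plates")
print(f"{len({w.condition for w in readings})} conditions "
      f"({len(cfg.plasmid_effects)} single plasmids, {len(cfg.pair_modes)} pairs x 2 modes)")
print("\ntrue effect directions (condition -> direction vs. plasmid-free):")
for cond, direction in sorted(truth.effect_direction.items()):
    if "+" not in cond and "|" not in cond:
        print(f"  {cond:>6}: {direction}")
print("\ntrue pair outcomes (intracellular labels):")
for pid, oc in truth.pair_outcome.items():
    if "+" in pid:
        dom = f" (dominant {oc.dominant_plasmid})" if oc.dominant_plasmid else ""
        print(f"  {pid:>10}: {oc.category.value}{dom}")
# Direction says whether a plasmid raises or lowers biofilm relative to
# the plasmid-free strain; the pair outcome is the category the triplet
# classifier should recover from noisy replicates.
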