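"""Synthetic study generator with known ground truth.

Emulates the measurement layers of a plasmid/biofilm plate study so that
every pipeline stage can be exercised end to end without external data:

* crystal-violet plates: per-plate plasmid-free baseline, multiplicative
  plasmid effects, log-normal well noise, uninoculated blanks in their
  reported 0.05-0.07 envelope, inoculated reads clipped (with a warning)
  at the 0.51 envelope top;
* plasmid-pair triplets with a configurable interaction mode (dominance,
  additive, increased, decreased, intermediate, null);
* end-point matings: donors and recipients near carrying capacity
  (~2e9 CFU/mL), expected transconjugants T = gamma*D*R, Poisson colony
  counts at auto-chosen dilutions;
* logistic OD600 growth curves sampled every 10 minutes.

All randomness flows through ``numpy.random.default_rng(cfg.seed)``; the
same configuration reproduces bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .classify import Category, OutcomeClass, pattern_to_outcome
from .conjugation import CfuCount, MatingCounts
from .growth import GrowthCurve
from .plates import BLANK_CONDITION, REFERENCE_CONDITION, WellReading

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GrowthParams",
    "GroundTruth",
    "DEFAULT_PLASMID_EFFECTS",
    "DEFAULT_PAIR_MODES",
    "simulate_plate_set",
    "simulate_triplet_study",
    "simulate_mating",
    "simulate_double_proportion",
    "simulate_growth_curves",
    "biofilm_inoculum_cfu",
    "growth_assay_inoculum_density",
    "pair_mode_mean",
    "true_outcome",
]

PairMode = Literal[
    "dominant_A", "dominant_B", "additive", "increased", "decreased", "intermediate", "null"
]

# Default single-plasmid multiplicative effects on relative biofilm:
# eight enhancers, two reducers, one neutral — the composition of a
# typical natural-plasmid panel. Labels follow common IncF/IncN/IncW/IncX
# plasmid names.
DEFAULT_PLASMID_EFFECTS: dict[str, float] = {
    "R124": 2.2,
    "F": 2.0,
    "R1": 1.9,
    "R702": 1.8,
    "R57b": 1.7,
    "RP4": 1.6,
    "R64": 1.55,
    "R6K": 1.5,
    "R388": 1.0,
    "RN3": 0.7,
    "R16a": 0.6,
}

# Default pair modes chosen so every implied mean stays inside the
# measurable read envelope at the default baselines (see methods note).
DEFAULT_PAIR_MODES: dict[tuple[str, str], PairMode] = {
    ("F", "R16a"): "dominant_B",
    ("F", "R388"): "dominant_A",
    ("F", "R6K"): "increased",
    ("R16a", "R388"): "intermediate",
    ("R16a", "R6K"): "dominant_A",
    ("R388", "R6K"): "decreased",
}

# mode-specific placement of the pair mean relative to the single effects
_INCREASE_FACTOR = 1.2
_DECREASE_FACTOR = 0.75


@dataclass(frozen=True)
class GrowthParams:
    """Per-strain logistic growth parameters."""

    rate: float = 0.02  # per minute (doubling time ~35 min)
    carrying_capacity: float = 2e9  # CFU/mL
    lag: float = 0.0  # minutes


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_plates: int = 8  # one biological replicate per plate by default
    wells_per_condition: int = 3  # technical wells
    n_biological: int = 8
    n_wt_wells: int = 8
    n_blank_wells: int = 4
    wt_signal_range: tuple[float, float] = (0.10, 0.35)
    baseline_range: tuple[float, float] = (0.17, 0.22)
    blank_range: tuple[float, float] = (0.05, 0.07)
    inoculated_min: float = 0.10
    inoculated_max: float = 0.51
    noise_sd: float = 0.10  # sd of well noise on the log scale
    plasmid_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLASMID_EFFECTS)
    )
    pair_modes: Mapping[tuple[str, str], PairMode] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_MODES)
    )
    conjugation_efficiencies: Mapping[str, float] = field(
        default_factory=lambda: {
            label: gamma
            for label, gamma in zip(
                DEFAULT_PLASMID_EFFECTS,
                (1e-9, 3e-10, 1e-10, 5e-11, 2e-11, 1e-11, 5e-12, 2e-12, 1e-12, 5e-13, 1e-13),
            )
        }
    )
    double_fractions: Mapping[tuple[str, str], float] = field(default_factory=dict)
    growth: Mapping[str, GrowthParams] = field(
        default_factory=lambda: {REFERENCE_CONDITION: GrowthParams()}
    )
    growth_noise_sd: float = 0.02
    growth_duration_min: float = 960.0
    growth_sampling_min: float = 10.0
    growth_model: Literal["logistic", "exponential"] = "logistic"

    def __post_init__(self) -> None:
        for name in ("wt_signal_range", "baseline_range", "blank_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered interval")
        if any(e <= 0 for e in self.plasmid_effects.values()):
            raise ValueError("plasmid effects must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually encoded, for recovery checks."""

    effect_direction: dict[str, str]  # condition -> increased/decreased/no_change
    pair_outcome: dict[str, OutcomeClass]  # pair_id -> true category
    growth_rate: dict[str, float]  # strain -> per-minute rate
    efficiency: dict[str, float]  # plasmid -> mL/CFU


# ---------------------------------------------------------------------------
# dilution arithmetic (the wet-lab bookkeeping the simulator reuses)
# ---------------------------------------------------------------------------

def biofilm_inoculum_cfu(
    overnight_density_cfu_per_ml: float,
    mix_strain_volume_ml: float = 0.005,
    mix_total_volume_ml: float = 0.200,
    transfer_volume_ml: float = 0.005,
) -> float:
    """CFU per strain delivered to a biofilm well.

    Two-step scheme: 5 uL of each overnight culture into a 200 uL mix,
    then 5 uL of the mix transferred to the assay well. At 2e9 CFU/mL
    overnight density this yields 2.5e5 CFU per strain.
    """
    mix_density = overnight_density_cfu_per_ml * mix_strain_volume_ml / mix_total_volume_ml
    return mix_density * transfer_volume_ml


def growth_assay_inoculum_density(
    overnight_density_cfu_per_ml: float, dilution_factor: float = 100.0
) -> float:
    """Starting density of a growth-curve well: overnight culture diluted
    ``dilution_factor``-fold (2e9 -> 2e7 CFU/mL at the default)."""
    return overnight_density_cfu_per_ml / dilution_factor


# ---------------------------------------------------------------------------
# pair interaction modes
# ---------------------------------------------------------------------------

def pair_mode_mean(effect_a: float, effect_b: float, mode: PairMode) -> float:
    """Expected relative biofilm of the pair population under a mode."""
    hi, lo = max(effect_a, effect_b), min(effect_a, effect_b)
    if mode == "dominant_A":
        return effect_a
    if mode == "dominant_B":
        return effect_b
    if mode == "additive":
        return effect_a + effect_b - 1.0  # joint effect on the relative scale
    if mode == "increased":
        return hi * _INCREASE_FACTOR
    if mode == "decreased":
        return lo * _DECREASE_FACTOR
    if mode == "intermediate":
        return 0.5 * (hi + lo)
    if mode == "null":
        return 1.0
    raise ValueError(f"unknown pair mode {mode!r}")


def true_outcome(
    effect_a: float, effect_b: float, mode: PairMode, label_a: str = "A", label_b: str = "B"
) -> OutcomeClass:
    """Noiseless-limit category implied by a mode and the single effects.

    Obtained by feeding exact mean (in)equalities to the classifier's
    pattern map, so truth and pipeline share one taxonomy.
    """
    mean_ab = pair_mode_mean(effect_a, effect_b, mode)
    tol = 1e-12
    return pattern_to_outcome(
        sig_ab_a=abs(mean_ab - effect_a) > tol,
        sig_ab_b=abs(mean_ab - effect_b) > tol,
        sig_a_b=abs(effect_a - effect_b) > tol,
        mean_ab=mean_ab,
        mean_a=effect_a,
        mean_b=effect_b,
        label_a=label_a,
        label_b=label_b,
    )


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

def _well_name(index: int) -> str:
    if index >= 96:
        raise ValueError("plate layout exceeds 96 wells")
    return f"{'ABCDEFGH'[index // 12]}{index % 12 + 1}"


def _condition_table(cfg: SimulationConfig) -> dict[str, float]:
    """Condition label -> expected relative biofilm (vs. plasmid-free)."""
    table: dict[str, float] = {}
    for label, eff in cfg.plasmid_effects.items():
        table[label] = eff
    for (a, b), mode in cfg.pair_modes.items():
        mean = pair_mode_mean(cfg.plasmid_effects[a], cfg.plasmid_effects[b], mode)
        table[f"{a}+{b}"] = mean  # intracellular: one strain, two plasmids
        table[f"{a}|{b}"] = mean  # intercellular: two co-cultured strains
    return table


def simulate_plate_set(cfg: SimulationConfig) -> tuple[list[WellReading], GroundTruth]:
    """Generate a full plate study.

    Each biological replicate occupies one plate (replicates beyond
    ``n_plates`` wrap round-robin). Every plate carries its own
    plasmid-free reference wells and blanks; condition wells are
    ``baseline * effect * exp(N(0, noise_sd))``, clipped with a warning
    into the ``[inoculated_min, inoculated_max]`` read envelope (a plate
    reader's stain signal saturates at the top and bottoms out at the
    residual-stain level).
    """
    rng = np.random.default_rng(cfg.seed)
    conditions = _condition_table(cfg)
    readings: list[WellReading] = []
    n_clipped = 0
    plate_of = lambda bio: f"P{bio % cfg.n_plates + 1:02d}"
    # group biological replicates by plate so each plate is laid out once
    plates: dict[str, list[str]] = {}
    for bio in range(cfg.n_biological):
        plates.setdefault(plate_of(bio), []).append(f"B{bio + 1}")
    for plate_id, bio_ids in plates.items():
        baseline = rng.uniform(*cfg.baseline_range)
        widx = 0
        # each plasmid-free monoculture well is its own biological
        # replicate; otherwise per-plate WT values would collapse to
        # exactly 1 by the normalization identity
        for i in range(cfg.n_wt_wells):
            od = baseline * math.exp(rng.normal(0.0, cfg.noise_sd))
            readings.append(
                WellReading(
                    plate_id, _well_name(widx), REFERENCE_CONDITION, f"{bio_ids[0]}w{i + 1}", od
                )
            )
            widx += 1
        for _ in range(cfg.n_blank_wells):
            od = rng.uniform(*cfg.blank_range)
            readings.append(
                WellReading(plate_id, _well_name(widx), BLANK_CONDITION, bio_ids[0], od)
            )
            widx += 1
        for cond, effect in conditions.items():
            for bio_id in bio_ids:
                for _ in range(cfg.wells_per_condition):
                    od = baseline * effect * math.exp(rng.normal(0.0, cfg.noise_sd))
                    if not cfg.inoculated_min <= od <= cfg.inoculated_max:
                        od = min(max(od, cfg.inoculated_min), cfg.inoculated_max)
                        n_clipped += 1
                    readings.append(
                        WellReading(plate_id, _well_name(widx), cond, bio_id, od)
                    )
                    widx += 1
    if n_clipped:
        logger.warning(
            "%d wells clipped into the [%.2f, %.2f] inoculated-read envelope",
            n_clipped, cfg.inoculated_min, cfg.inoculated_max,
        )
    tol = 1e-12
    directions = {
        cond: ("increased" if eff > 1 + tol else "decreased" if eff < 1 - tol else "no_change")
        for cond, eff in conditions.items()
    }
    pair_truth = {}
    for (a, b), mode in cfg.pair_modes.items():
        oc = true_outcome(cfg.plasmid_effects[a], cfg.plasmid_effects[b], mode, a, b)
        pair_truth[f"{a}+{b}"] = oc
        pair_truth[f"{a}|{b}"] = oc
    truth = GroundTruth(
        effect_direction=directions,
        pair_outcome=pair_truth,
        growth_rate={s: p.rate for s, p in cfg.growth.items()},
        efficiency=dict(cfg.conjugation_efficiencies),
    )
    return readings, truth


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

def simulate_triplet_study(
    cfg: SimulationConfig,
    pair: tuple[str, str],
    mode: PairMode,
    n: int,
    condition_mode: Literal["intracellular", "intercellular"] = "intracellular",
    rng: np.random.Generator | None = None,
):
    """Replicate sets (B_AB, B_A, B_B) for one pair under a known mode.

    Values are the mode/effect means with multiplicative log-normal noise
    of scale ``cfg.noise_sd``. Pass an explicit ``rng`` to draw repeated
    studies from one stream; otherwise ``cfg.seed`` starts a fresh one.
    """
    from .classify import TripletMeasurements

    a, b = pair
    gen = rng if rng is not None else np.random.default_rng(cfg.seed)
    eff_a = cfg.plasmid_effects[a]
    eff_b = cfg.plasmid_effects[b]
    mean_ab = pair_mode_mean(eff_a, eff_b, mode)
    draw = lambda mean: tuple(mean * np.exp(gen.normal(0.0, cfg.noise_sd, n)))
    return TripletMeasurements(
        pair_id=f"{a}+{b}" if condition_mode == "intracellular" else f"{a}|{b}",
        condition_mode=condition_mode,
        label_a=a,
        label_b=b,
        values_ab=draw(mean_ab),
        values_a=draw(eff_a),
        values_b=draw(eff_b),
    )


# ---------------------------------------------------------------------------
# matings
# ---------------------------------------------------------------------------

def _auto_dilution(density: float, plated_volume_ml: float, target_colonies: float = 100.0) -> float:
    """Ten-fold dilution bringing the expected plate count near the target."""
    if density <= 0:
        return 1.0
    exact = density * plated_volume_ml / target_colonies
    return float(10 ** max(0, round(math.log10(exact)))) if exact > 1 else 1.0


def _count_at(
    rng: np.random.Generator, density: float, plated_volume_ml: float = 0.1
) -> CfuCount:
    dil = _auto_dilution(density, plated_volume_ml)
    expected = density * plated_volume_ml / dil
    return CfuCount(
        colonies=int(rng.poisson(expected)),
        dilution_factor=dil,
        plated_volume_ml=plated_volume_ml,
    )


def simulate_mating(
    cfg: SimulationConfig,
    plasmid: str,
    rng: np.random.Generator | None = None,
) -> tuple[MatingCounts, dict[str, CfuCount]]:
    """End-point mating between a donor (carrying ``plasmid``) and a
    plasmid-free recipient.

    Donors and recipients each settle near half the carrying capacity
    with mild log-normal variation; expected transconjugant density is
    ``gamma * D * R`` with the configured efficiency gamma. Colony counts
    are Poisson at automatically chosen ten-fold dilutions, and the
    returned densities are the ones a bench scientist would back-compute
    from those counts.
    """
    gen = rng if rng is not None else np.random.default_rng(cfg.seed)
    gamma = cfg.conjugation_efficiencies[plasmid]
    K = cfg.growth.get(plasmid, GrowthParams()).carrying_capacity
    d_true = 0.5 * K * math.exp(gen.normal(0.0, 0.05))
    r_true = 0.5 * K * math.exp(gen.normal(0.0, 0.05))
    t_true = gamma * d_true * r_true
    counts = {
        "D": _count_at(gen, d_true),
        "R": _count_at(gen, r_true),
        "T": _count_at(gen, t_true),
    }
    from .conjugation import cfu_per_ml

    mating = MatingCounts(
        T=cfu_per_ml(counts["T"]), D=cfu_per_ml(counts["D"]), R=cfu_per_ml(counts["R"])
    )
    return mating, counts


def simulate_double_proportion(
    cfg: SimulationConfig,
    pair: tuple[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[CfuCount, CfuCount]:
    """Counts for the double-plasmid proportion assay of one co-culture.

    The configured fraction defaults to 0.45 for pairs involving the
    high-efficiency plasmid F and 0.13 otherwise (the two regimes such
    assays typically show), jittered log-normally (sd 0.08).
    """
    gen = rng if rng is not None else np.random.default_rng(cfg.seed)
    frac = cfg.double_fractions.get(pair)
    if frac is None:
        frac = 0.45 if "F" in pair else 0.13
    frac = min(1.0, frac * math.exp(gen.normal(0.0, 0.08)))
    K = cfg.growth.get(REFERENCE_CONDITION, GrowthParams()).carrying_capacity
    total_true = K * math.exp(gen.normal(0.0, 0.05))
    return _count_at(gen, frac * total_true), _count_at(gen, total_true)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

_OD_PER_CFU_PER_ML = 0.5e-9  # OD600 1.0 ~ 2e9 CFU/mL


def simulate_growth_curves(
    cfg: SimulationConfig,
    strain: str,
    n_replicates: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[GrowthCurve]:
    """Logistic (or pure exponential) OD600 trajectories for one strain.

    Cultures start at the overnight density diluted 100-fold
    (carrying_capacity / 100) and are sampled every
    ``growth_sampling_min`` minutes with multiplicative log-normal noise
    ``growth_noise_sd``.
    """
    gen = rng if rng is not None else np.random.default_rng(cfg.seed)
    params = cfg.growth.get(strain, GrowthParams())
    n_rep = n_replicates if n_replicates is not None else cfg.wells_per_condition
    times = np.arange(0.0, cfg.growth_duration_min + 1e-9, cfg.growth_sampling_min)
    n0 = growth_assay_inoculum_density(params.carrying_capacity)
    curves = []
    for rep in range(n_rep):
        t_eff = np.clip(times - params.lag, 0.0, None)
        if cfg.growth_model == "exponential":
            n_t = n0 * np.exp(params.rate * t_eff)
            n_t = np.minimum(n_t, params.carrying_capacity)
        else:
            g = np.exp(params.rate * t_eff)
            n_t = params.carrying_capacity * n0 * g / (
                params.carrying_capacity + n0 * (g - 1.0)
            )
        od = n_t * _OD_PER_CFU_PER_ML
        if cfg.growth_noise_sd > 0:
            od = od * np.exp(gen.normal(0.0, cfg.growth_noise_sd, od.size))
        curves.append(
            GrowthCurve(times=tuple(times), od600=tuple(od), replicate_id=f"{strain}-t{rep + 1}")
        )
    return curves


# ---------------------------------------------------------------------------
# CSV emission (same dialects the readers consume)
# ---------------------------------------------------------------------------

def write_plate_csv(readings: Sequence[WellReading], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["plate_id", "well", "condition", "replicate_id", "od595"])
        for r in readings:
            w.writerow([r.plate_id, r.well, r.condition, r.replicate_id, f"{r.od595:.6f}"])


def write_mating_csv(cfg: SimulationConfig, path, n_replicates: int = 3) -> None:
    """Mating-count CSV for every configured plasmid, plus double-proportion
    counts for every configured pair."""
    import csv

    rng = np.random.default_rng(cfg.seed)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["pair_id", "replicate_id", "role", "colonies", "dilution_factor", "plated_volume_ml"]
        )
        for plasmid in cfg.conjugation_efficiencies:
            for rep in range(1, n_replicates + 1):
                _, counts = simulate_mating(cfg, plasmid, rng=rng)
                for role, c in counts.items():
                    w.writerow(
                        [plasmid, f"B{rep}", role, c.colonies, c.dilution_factor,
                         c.plated_volume_ml]
                    )
        for pair in cfg.pair_modes:
            for rep in range(1, n_replicates + 1):
                double, total = simulate_double_proportion(cfg, pair, rng=rng)
                for role, c in (("double", double), ("total", total)):
                    w.writerow(
                        ["|".join(pair), f"B{rep}", role, c.colonies, c.dilution_factor,
                         c.plated_volume_ml]
                    )


def write_growth_csv(cfg: SimulationConfig, path, n_replicates: int = 3) -> None:
    import csv

    rng = np.random.default_rng(cfg.seed)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["strain", "replicate_id", "time_min", "od600"])
        for strain in cfg.growth:
            curves = simulate_growth_curves(cfg, strain, n_replicates=n_replicates, rng=rng)
            for curve in curves:
                for t, od in zip(curve.times, curve.od600):
                    w.writerow([strain, curve.replicate_id, t, f"{od:.6g}"])
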