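"""Conjugation-efficiency and double-plasmid-proportion estimation.

Colony counts from plated serial dilutions convert to CFU/mL densities;
end-point conjugation efficiency is the classic transconjugants-per-
donor-and-recipient ratio T/(D*R) (units mL/CFU). The proportion of
double-plasmid cells after co-cultivation is the density ratio of
double-selected to total colonies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "CfuCount",
    "MatingCounts",
    "ConjugationEfficiency",
    "cfu_per_ml",
    "conjugation_efficiency",
    "double_plasmid_proportion",
]


@dataclass(frozen=True)
class CfuCount:
    """One plate count: colonies at a known dilution and plated volume."""

    colonies: int
    dilution_factor: float
    plated_volume_ml: float

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("negative colony count")
        if self.dilution_factor <= 0 or self.plated_volume_ml <= 0:
            raise ValueError("dilution factor and plated volume must be positive")


@dataclass(frozen=True)
class MatingCounts:
    """Transconjugant, donor and recipient densities (CFU/mL) for one mating."""

    T: float
    D: float
    R: float

    def __post_init__(self) -> None:
        if min(self.T, self.D, self.R) < 0:
            raise ValueError("densities must be non-negative")


@dataclass(frozen=True)
class ConjugationEfficiency:
    """Efficiency T/(D*R) in mL/CFU; ``zero_transconjugants`` flags T = 0."""

    value: float
    zero_transconjugants: bool = False


def cfu_per_ml(count: CfuCount) -> float:
    """Density = colonies * dilution_factor / plated_volume_ml."""
    return count.colonies * count.dilution_factor / count.plated_volume_ml


def conjugation_efficiency(m: MatingCounts) -> ConjugationEfficiency:
    """End-point conjugation efficiency T/(D*R), mL per CFU.

    Undefined (refused) when donors or recipients are absent. Zero
    transconjugants give efficiency 0 with a flag so that downstream
    log-transforms can exclude the point explicitly.
    """
    if m.D == 0 or m.R == 0:
        raise ValueError("efficiency undefined: zero donor or recipient density")
    if m.T == 0:
        logger.warning("zero transconjugants: efficiency 0 (flagged)")
        return ConjugationEfficiency(0.0, zero_transconjugants=True)
    return ConjugationEfficiency(m.T / (m.D * m.R))


def double_plasmid_proportion(double_selected: CfuCount, total: CfuCount) -> float:
    """Fraction of the population carrying both plasmids.

    Density ratio of doubly-selected to total colonies, clipped to [0, 1]
    with a warning when counting noise pushes it above 1.
    """
    total_density = cfu_per_ml(total)
    if total_density == 0:
        raise ValueError("zero total density: proportion undefined")
    prop = cfu_per_ml(double_selected) / total_density
    if prop > 1.0:
        logger.warning("double-selected density exceeds total (%.3f); clipping to 1", prop)
        return 1.0
    return prop
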