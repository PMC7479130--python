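"""Effect calls and the plasmid-pair dominance classification.

Two layers of phenotype calling:

* **Effect calls** — each population's relative biofilm level is compared
  to the plasmid-free reference with a Welch omnibus ANOVA followed (when
  significant) by Dunnett's many-to-one test; each population is then
  labelled increased / decreased / no_change.

* **Triplet outcomes** — for a plasmid pair (A, B), the two-plasmid
  population (B_AB) is compared simultaneously with the two single-plasmid
  strains (B_A, B_B) via Welch ANOVA + Tukey all-pairs, and the pattern of
  significant/non-significant differences maps to one of six categories:

  - DOMINANCE_HIGHEST / DOMINANCE_LOWEST: B_AB is indistinguishable from
    exactly one single-plasmid strain (the dominant plasmid); "highest" vs
    "lowest" says whether that strain was the stronger or weaker biofilm
    former.
  - INCREASED / DECREASED: B_AB differs from both and lies above the
    larger / below the smaller single-plasmid mean.
  - INTERMEDIATE: B_AB differs from both and lies between them, or is
    indistinguishable from both while the single-plasmid strains differ
    from each other.
  - UNDETERMINED: no significant differences anywhere in the triplet.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .plates import NormalizedSample
from .stats import ContingencyTable, SampleGroup, dunnett_many_to_one, tukey_all_pairs, welch_anova

__all__ = [
    "EffectDirection",
    "EffectCall",
    "TripletMeasurements",
    "Category",
    "OutcomeClass",
    "call_effects",
    "pattern_to_outcome",
    "classify_triplet",
    "tabulate_outcomes",
    "EFFECT_DIRECTIONS",
    "OUTCOME_CATEGORIES",
]

EffectDirection = Literal["increased", "decreased", "no_change"]
EFFECT_DIRECTIONS: tuple[str, ...] = ("increased", "decreased", "no_change")


@dataclass(frozen=True)
class EffectCall:
    """Direction of one population's biofilm effect vs. the reference."""

    condition: str
    direction: EffectDirection
    p_adjusted: float


class Category(str, enum.Enum):
    DOMINANCE_HIGHEST = "DOMINANCE_HIGHEST"
    DOMINANCE_LOWEST = "DOMINANCE_LOWEST"
    INCREASED = "INCREASED"
    DECREASED = "DECREASED"
    INTERMEDIATE = "INTERMEDIATE"
    UNDETERMINED = "UNDETERMINED"


OUTCOME_CATEGORIES: tuple[str, ...] = tuple(c.value for c in Category)


@dataclass(frozen=True)
class OutcomeClass:
    """A classified triplet outcome.

    ``dominant_plasmid`` is set exactly when the category is one of the
    two dominance classes. ``tied_means`` flags the measure-zero case of
    exactly equal single-plasmid means, which is broken deterministically
    toward DOMINANCE_HIGHEST.
    """

    category: Category
    dominant_plasmid: str | None = None
    tied_means: bool = False

    def __post_init__(self) -> None:
        is_dom = self.category in (Category.DOMINANCE_HIGHEST, Category.DOMINANCE_LOWEST)
        if is_dom != (self.dominant_plasmid is not None):
            raise ValueError("dominant_plasmid set iff category is a dominance class")


@dataclass(frozen=True)
class TripletMeasurements:
    """Replicate biofilm values for the pair population and both singles."""

    pair_id: str
    condition_mode: Literal["intracellular", "intercellular"]
    label_a: str
    label_b: str
    values_ab: tuple[float, ...]
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (
            ("values_ab", self.values_ab),
            ("values_a", self.values_a),
            ("values_b", self.values_b),
        ):
            if len(vals) < 3:
                raise ValueError(f"{name} needs at least 3 replicates, got {len(vals)}")


def call_effects(
    samples: Sequence[NormalizedSample],
    reference: NormalizedSample,
    alpha: float = 0.05,
    gate_on_omnibus: bool = True,
) -> list[EffectCall]:
    """Label each population increased / decreased / no_change vs. the reference.

    Welch's ANOVA over all populations plus the reference serves as the
    omnibus gate; when it is significant (or when ``gate_on_omnibus`` is
    off), Dunnett's many-to-one test against the reference supplies the
    per-population adjusted p-values and effect directions. A
    non-significant omnibus reports every population as no_change with
    the Dunnett p-values still attached for audit.
    """
    if not samples:
        raise ValueError("no non-reference samples supplied")
    groups = [SampleGroup(reference.condition, reference.values)] + [
        SampleGroup(s.condition, s.values) for s in samples
    ]
    omnibus = welch_anova(groups)
    comparisons = dunnett_many_to_one(groups, reference.condition, alpha=alpha)
    gate_open = omnibus.p < alpha or not gate_on_omnibus
    calls = []
    for cmp in comparisons:
        if gate_open and cmp.significant:
            direction: EffectDirection = (
                "increased" if cmp.estimate > 0 else "decreased"
            )
        else:
            direction = "no_change"
        calls.append(
            EffectCall(condition=cmp.pair[0], direction=direction, p_adjusted=cmp.p_adjusted)
        )
    return calls


def pattern_to_outcome(
    sig_ab_a: bool,
    sig_ab_b: bool,
    sig_a_b: bool,
    mean_ab: float,
    mean_a: float,
    mean_b: float,
    label_a: str = "A",
    label_b: str = "B",
) -> OutcomeClass:
    """Map a triplet's significance pattern and mean ordering to a category.

    Pure, total function over the 8 significance patterns and all mean
    orderings. ``sig_ab_a`` is True when B_AB differs significantly from
    B_A (similarly the other two flags).
    """
    tied = mean_a == mean_b
    if not sig_ab_a and sig_ab_b:
        # AB looks like A, differs from B: A dominates
        highest = mean_a > mean_b or tied
        return OutcomeClass(
            category=Category.DOMINANCE_HIGHEST if highest else Category.DOMINANCE_LOWEST,
            dominant_plasmid=label_a,
            tied_means=tied,
        )
    if sig_ab_a and not sig_ab_b:
        highest = mean_b > mean_a  # ties break toward A dominating, handled above
        if tied:
            highest = True
        return OutcomeClass(
            category=Category.DOMINANCE_HIGHEST if highest else Category.DOMINANCE_LOWEST,
            dominant_plasmid=label_b,
            tied_means=tied,
        )
    if sig_ab_a and sig_ab_b:
        if mean_ab > max(mean_a, mean_b):
            return OutcomeClass(category=Category.INCREASED)
        if mean_ab < min(mean_a, mean_b):
            return OutcomeClass(category=Category.DECREASED)
        return OutcomeClass(category=Category.INTERMEDIATE)
    # AB indistinguishable from both singles
    if sig_a_b:
        return OutcomeClass(category=Category.INTERMEDIATE)
    return OutcomeClass(category=Category.UNDETERMINED)


def classify_triplet(
    triplet: TripletMeasurements,
    alpha: float = 0.05,
    gate_on_omnibus: bool = True,
) -> OutcomeClass:
    """Classify a plasmid pair from its three replicate sets.

    Welch's ANOVA over {B_AB, B_A, B_B} gates Tukey's all-pairs test;
    the three Tukey significance flags and the sample means feed
    :func:`pattern_to_outcome`. A non-significant omnibus yields
    UNDETERMINED (no pairwise difference is claimed).
    """
    groups = [
        SampleGroup("AB", triplet.values_ab),
        SampleGroup(triplet.label_a, triplet.values_a),
        SampleGroup(triplet.label_b, triplet.values_b),
    ]
    omnibus = welch_anova(groups)
    sig = {("AB", triplet.label_a): False, ("AB", triplet.label_b): False,
           (triplet.label_a, triplet.label_b): False}
    if omnibus.p < alpha or not gate_on_omnibus:
        for cmp in tukey_all_pairs(groups, alpha=alpha):
            sig[cmp.pair] = cmp.significant
    return pattern_to_outcome(
        sig_ab_a=sig[("AB", triplet.label_a)],
        sig_ab_b=sig[("AB", triplet.label_b)],
        sig_a_b=sig[(triplet.label_a, triplet.label_b)],
        mean_ab=float(np.mean(triplet.values_ab)),
        mean_a=float(np.mean(triplet.values_a)),
        mean_b=float(np.mean(triplet.values_b)),
        label_a=triplet.label_a,
        label_b=triplet.label_b,
    )


def tabulate_outcomes(
    items_by_mode: Mapping[str, Sequence[EffectCall | OutcomeClass]],
) -> ContingencyTable:
    """Cross-tabulate condition modes against call categories.

    Rows are condition modes (e.g. intracellular / intercellular); columns
    are the three effect directions when given :class:`EffectCall` items,
    or the six outcome categories when given :class:`OutcomeClass` items.
    Row sums equal the number of populations per mode.
    """
    modes = list(items_by_mode)
    if not modes:
        raise ValueError("no modes supplied")
    all_items = [it for items in items_by_mode.values() for it in items]
    if all(isinstance(it, EffectCall) for it in all_items):
        columns = list(EFFECT_DIRECTIONS)
        key = lambda it: it.direction
    elif all(isinstance(it, OutcomeClass) for it in all_items):
        columns = list(OUTCOME_CATEGORIES)
        key = lambda it: it.category.value
    else:
        raise TypeError("items must be all EffectCall or all OutcomeClass")
    counts = tuple(
        tuple(sum(1 for it in items_by_mode[m] if key(it) == col) for col in columns)
        for m in modes
    )
    return ContingencyTable(counts=counts, row_labels=tuple(modes), col_labels=tuple(columns))
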