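"""Reading and normalizing crystal-violet plate data.

Raw OD595 well readings arrive in long format, one row per well. Each
plate carries its own plasmid-free ("WT") monoculture wells; every well
on a plate is divided by the outlier-filtered mean of those reference
wells, putting all measurements on the "biofilm formation relative to
the plasmid-free strain" scale. Uninoculated ("BLANK") wells are used
only for a raw-range sanity check — they are never subtracted.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .stats import iqr_filter

logger = logging.getLogger(__name__)

__all__ = [
    "WellReading",
    "NormalizedSample",
    "REFERENCE_CONDITION",
    "BLANK_CONDITION",
    "read_plate_csv",
    "reference_statistic",
    "normalize_plate",
    "aggregate_replicates",
    "check_raw_envelopes",
]

REFERENCE_CONDITION = "WT"
BLANK_CONDITION = "BLANK"

# expected raw-read envelopes; out-of-range wells are logged, not rejected
INOCULATED_ENVELOPE = (0.10, 0.51)
BLANK_ENVELOPE = (0.05, 0.07)

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

CoHabitation = Literal["single", "intracellular", "intercellular", "reference"]


@dataclass(frozen=True)
class WellReading:
    """One raw OD595 measurement with its plate/condition identity."""

    plate_id: str
    well: str
    condition: str
    replicate_id: str
    od595: float

    def __post_init__(self) -> None:
        if not _WELL_RE.match(self.well):
            raise ValueError(f"well {self.well!r} not on the 96-well A1-H12 grid")
        if not (math.isfinite(self.od595) and self.od595 >= 0):
            raise ValueError(f"od595 must be finite and >= 0, got {self.od595}")


@dataclass(frozen=True)
class NormalizedSample:
    """Per-population biological-replicate values on the relative scale."""

    condition: str
    co_habitation: CoHabitation
    values: tuple[float, ...]

    @property
    def n_biological(self) -> int:
        return len(self.values)


def read_plate_csv(path: str | Path) -> list[WellReading]:
    """Parse a long-format plate CSV into well readings.

    Requires header columns ``plate_id, well, condition, replicate_id,
    od595``; extra columns are ignored. Row order is preserved. A missing
    column, an unparsable od595 or a duplicated (plate_id, well) is
    refused with the offending row number (1-based, header = row 1).
    """
    required = ["plate_id", "well", "condition", "replicate_id", "od595"]
    readings: list[WellReading] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            key = (row["plate_id"], row["well"])
            if key in seen:
                raise ValueError(f"{path}: row {i}: duplicate well {key}")
            seen.add(key)
            try:
                od = float(row["od595"])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {i}: unparsable od595 {row['od595']!r}"
                ) from exc
            try:
                readings.append(
                    WellReading(
                        plate_id=row["plate_id"],
                        well=row["well"],
                        condition=row["condition"],
                        replicate_id=row["replicate_id"],
                        od595=od,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
    return readings


def reference_statistic(plate: Sequence[WellReading]) -> float:
    """Outlier-filtered mean of a plate's plasmid-free reference wells.

    Applies the Tukey-fence filter once to the WT wells and averages the
    survivors. Refuses with fewer than 4 WT wells (fences undefined) or
    fewer than 2 survivors (mean not trustworthy).
    """
    wt = [w.od595 for w in plate if w.condition == REFERENCE_CONDITION]
    if len(wt) < 4:
        raise ValueError(
            f"need at least 4 {REFERENCE_CONDITION} wells per plate, got {len(wt)}"
        )
    kept, removed = iqr_filter(wt)
    if len(kept) < 2:
        raise ValueError("fewer than 2 reference wells survive outlier filtering")
    if removed:
        logger.info("reference wells removed as outliers: %s", removed)
    return float(np.mean(kept))


def normalize_plate(plate: Sequence[WellReading]) -> list[tuple[WellReading, float]]:
    """Divide every inoculated well by the plate's reference statistic.

    BLANK wells are excluded from the output (they only feed the raw-range
    sanity check). Output order follows input order.
    """
    ref = reference_statistic(plate)
    return [
        (w, w.od595 / ref) for w in plate if w.condition != BLANK_CONDITION
    ]


def check_raw_envelopes(plate: Iterable[WellReading]) -> list[str]:
    """Warn (log + return messages) for wells outside the expected raw ranges.

    Inoculated wells are expected within [0.10, 0.51] and blanks within
    [0.05, 0.07]; out-of-envelope wells indicate a staining or inoculation
    problem but do not abort the analysis.
    """
    messages = []
    for w in plate:
        lo, hi = BLANK_ENVELOPE if w.condition == BLANK_CONDITION else INOCULATED_ENVELOPE
        if not (lo <= w.od595 <= hi):
            msg = (
                f"plate {w.plate_id} well {w.well} ({w.condition}): "
                f"od595={w.od595:.3f} outside expected [{lo}, {hi}]"
            )
            messages.append(msg)
            logger.debug(msg)
    if messages:
        logger.warning("%d wells outside the expected raw-read envelopes", len(messages))
    return messages


def aggregate_replicates(
    normalized: Sequence[tuple[WellReading, float]],
    co_habitation: dict[str, CoHabitation] | None = None,
    filter_outliers: bool = True,
) -> list[NormalizedSample]:
    """Collapse technical wells into biological replicates per condition.

    Each (condition, replicate_id) contributes one biological value — the
    mean of its technical wells. Per-condition biological values then pass
    once through the Tukey-fence filter (when at least 4 exist) before any
    downstream test. ``co_habitation`` maps condition labels to their
    cultivation mode; unmapped conditions default to "single"
    ("reference" for WT).
    """
    co_habitation = co_habitation or {}
    by_group: dict[tuple[str, str], list[float]] = {}
    order: list[str] = []
    for w, rel in normalized:
        key = (w.condition, w.replicate_id)
        if w.condition not in order:
            order.append(w.condition)
        by_group.setdefault(key, []).append(rel)
    samples = []
    for cond in order:
        bio = [
            float(np.mean(vals))
            for (c, _), vals in by_group.items()
            if c == cond
        ]
        if filter_outliers and len(bio) >= 4:
            kept, removed = iqr_filter(bio)
            if removed:
                logger.info("condition %s: removed outlier replicates %s", cond, removed)
            bio = kept
        mode = co_habitation.get(
            cond, "reference" if cond == REFERENCE_CONDITION else "single"
        )
        samples.append(
            NormalizedSample(condition=cond, co_habitation=mode, values=tuple(bio))
        )
    return samples
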