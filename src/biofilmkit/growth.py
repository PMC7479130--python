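"""Growth-rate estimation from OD600 time series.

The maximum specific growth rate is taken from the steepest log-linear
stretch of the OD curve with a two-phase "easy linear" fit: ln(OD) is
regressed on time over every window of ``min_window`` consecutive points
above the detection floor; the steepest window seeds the estimate, every
window whose slope reaches ``quota`` (default 95%) of the seed slope is
pooled with it, and a single regression over the pooled points gives the
rate. Pooling keeps the fit inside the exponential phase on saturating
(logistic) curves while averaging away the upward bias a bare
max-of-noisy-slopes rule would have on clean exponentials. The pooled
fit's R^2 gates acceptance; replicates failing the gate are discarded
before averaging, and strain rates are expressed relative to the mean
plasmid-free rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "DETECTION_FLOOR_OD",
    "fit_growth_rate",
    "aggregate_rates",
    "relative_growth_rate",
]

DETECTION_FLOOR_OD = 0.005
DEFAULT_MIN_WINDOW = 5
DEFAULT_R2_THRESHOLD = 0.95
DEFAULT_SLOPE_QUOTA = 0.95


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 vs. time (minutes) for one well."""

    times: tuple[float, ...]
    od600: tuple[float, ...]
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od600):
            raise ValueError("times and od600 lengths differ")
        if len(self.times) < 8:
            raise ValueError("need at least 8 time points")
        t = np.asarray(self.times)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if any(o < 0 or not math.isfinite(o) for o in self.od600):
            raise ValueError("od600 must be finite and non-negative")


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Fitted maximum specific growth rate (per minute).

    ``window`` is the (start, stop) index span of the points that entered
    the pooled fit, in the original curve's indexing.
    """

    rate: float
    window: tuple[int, int]
    r_squared: float
    accepted: bool


def _ols_slope_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tc = t - t.mean()
    yc = y - y.mean()
    sxx = float(tc @ tc)
    sxy = float(tc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    if syy <= 0:
        return slope, 1.0  # perfectly flat log series fits exactly
    return slope, min(1.0, sxy * sxy / (sxx * syy))


def fit_growth_rate(
    curve: GrowthCurve,
    min_window: int = DEFAULT_MIN_WINDOW,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    detection_floor: float = DETECTION_FLOOR_OD,
    slope_quota: float = DEFAULT_SLOPE_QUOTA,
) -> GrowthRateEstimate:
    """Two-phase maximum log-linear slope of an OD600 curve.

    Points at or below the detection floor are excluded. Seed = the
    ``min_window``-wide window with the largest slope (ties to the
    earliest); every window whose slope is at least
    ``slope_quota * seed slope`` is pooled, and the regression over the
    pooled points yields the rate. ``accepted`` is True when that fit's
    R^2 reaches ``r2_threshold``.
    """
    t_all = np.asarray(curve.times, dtype=float)
    y_all = np.asarray(curve.od600, dtype=float)
    mask = y_all > detection_floor
    if mask.sum() < min_window:
        raise ValueError(
            f"only {int(mask.sum())} points above the detection floor "
            f"({detection_floor} OD); need {min_window}"
        )
    idx = np.flatnonzero(mask)
    t = t_all[idx]
    logy = np.log(y_all[idx])
    n = t.size
    h = min_window

    slopes = np.empty(n - h + 1)
    for s in range(n - h + 1):
        slopes[s], _ = _ols_slope_r2(t[s : s + h], logy[s : s + h])
    seed = int(np.argmax(slopes))  # argmax takes the earliest on ties
    if slopes[seed] > 0:
        selected = np.flatnonzero(slopes >= slope_quota * slopes[seed])
    else:
        selected = np.array([seed])
    pooled = np.zeros(n, dtype=bool)
    for s in selected:
        pooled[s : s + h] = True
    rate, r2 = _ols_slope_r2(t[pooled], logy[pooled])
    span = np.flatnonzero(pooled)
    window = (int(idx[span[0]]), int(idx[span[-1]]) + 1)
    return GrowthRateEstimate(
        rate=float(rate),
        window=window,
        r_squared=float(r2),
        accepted=bool(r2 >= r2_threshold),
    )


def aggregate_rates(estimates: Sequence[GrowthRateEstimate]) -> float:
    """Biological-replicate rate: mean of accepted technical fits.

    Technical replicates rejected by the R^2 gate are discarded; refuses
    when none survive.
    """
    accepted = [e.rate for e in estimates if e.accepted]
    if not accepted:
        raise ValueError("no technical replicate passed the R^2 gate")
    return float(np.mean(accepted))


def relative_growth_rate(
    strain_rates: Sequence[float], reference_rates: Sequence[float]
) -> list[float]:
    """Each strain replicate divided by the mean plasmid-free rate."""
    if len(reference_rates) == 0:
        raise ValueError("no reference rates")
    ref_mean = float(np.mean(reference_rates))
    if ref_mean <= 0:
        raise ValueError("reference mean rate must be positive")
    return [float(r) / ref_mean for r in strain_rates]
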