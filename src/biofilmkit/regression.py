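"""Pearson correlation and simple regression with studentized-residual
outlier exclusion.

Used to relate per-plasmid summaries — mean relative biofilm vs. log10
conjugation efficiency, relative growth rate, or plasmid size. Outliers
are removed one at a time by the Bonferroni-corrected externally
studentized residual test (at most ``max_removals`` points, default 2),
then ordinary least squares and the two-sided Pearson test run on the
survivors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSeries",
    "RegressionResult",
    "studentized_outliers",
    "correlate_with_exclusion",
    "log10_positive",
]


@dataclass(frozen=True)
class PairedSeries:
    """Labelled (x, y) points, one per plasmid or strain."""

    labels: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise ValueError("labels, x and y must have equal length")
        if len(self.x) < 4:
            raise ValueError("need at least 4 points")
        if not all(map(math.isfinite, list(self.x) + list(self.y))):
            raise ValueError("non-finite coordinates")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    residual_variance: float
    rho: float
    df: int
    p: float
    excluded_labels: tuple[str, ...] = ()


def studentized_outliers(
    series: PairedSeries, max_removals: int = 2, alpha: float = 0.05
) -> list[str]:
    """Labels excluded by the iterated externally-studentized-residual test.

    Each iteration fits y ~ x, computes externally studentized residuals,
    and removes the single largest-|residual| point if its Bonferroni-
    corrected two-sided outlier p-value falls below ``alpha``; repeats up
    to ``max_removals`` times. Perfectly collinear data yield no
    exclusions.
    """
    if series.n < 5:
        raise ValueError("need at least 5 points for outlier testing")
    labels = list(series.labels)
    x = np.asarray(series.x, dtype=float)
    y = np.asarray(series.y, dtype=float)
    excluded: list[str] = []
    for _ in range(max_removals):
        if x.size < 5:
            break
        model = sm.OLS(y, sm.add_constant(x)).fit()
        if model.ssr <= 1e-14 * max(1.0, float(np.dot(y, y))):
            break  # (near-)perfect fit: no residual evidence
        r = np.asarray(OLSInfluence(model).resid_studentized_external)
        i = int(np.nanargmax(np.abs(r)))
        # Bonferroni-corrected two-sided outlier t-test, df = n - 3
        p_raw = 2.0 * stats.t.sf(abs(r[i]), x.size - 3)
        p_bonf = min(1.0, p_raw * x.size)
        if p_bonf >= alpha:
            break
        excluded.append(labels[i])
        keep = np.ones(x.size, dtype=bool)
        keep[i] = False
        x, y = x[keep], y[keep]
        labels = [l for k, l in enumerate(labels) if keep[k]]
    return excluded


def correlate_with_exclusion(
    series: PairedSeries, max_removals: int = 2, alpha: float = 0.05
) -> RegressionResult:
    """OLS fit and Pearson test after studentized-residual exclusion.

    Reports slope/intercept, R^2, residual variance (SSR / (n-2)),
    Pearson rho with df = n_used - 2 and its two-sided p, and the
    excluded labels. A constant y among survivors yields rho = 0, p = 1
    with a warning.
    """
    excluded = studentized_outliers(series, max_removals=max_removals, alpha=alpha) \
        if max_removals > 0 and series.n >= 5 else []
    keep = [i for i, l in enumerate(series.labels) if l not in excluded]
    if len(keep) < 4:
        raise ValueError("fewer than 4 points survive outlier exclusion")
    x = np.asarray([series.x[i] for i in keep])
    y = np.asarray([series.y[i] for i in keep])
    n = x.size
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        logger.warning("degenerate series (constant coordinate): rho = 0, p = 1")
        ybar = float(y.mean())
        return RegressionResult(
            slope=0.0, intercept=ybar, r_squared=0.0,
            residual_variance=float(np.var(y, ddof=1)) if np.ptp(y) else 0.0,
            rho=0.0, df=n - 2, p=1.0, excluded_labels=tuple(excluded),
        )
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    ssr = float(np.dot(resid, resid))
    rho, p = stats.pearsonr(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_variance=ssr / (n - 2),
        rho=float(rho),
        df=n - 2,
        p=float(p),
        excluded_labels=tuple(excluded),
    )


def log10_positive(
    labels: Sequence[str], values: Sequence[float]
) -> tuple[list[str], list[float]]:
    """log10 of strictly positive values; zero/negative entries are dropped
    with a warning (log undefined), returning the surviving labels."""
    kept_labels, kept = [], []
    for l, v in zip(labels, values):
        if v > 0:
            kept_labels.append(l)
            kept.append(math.log10(v))
        else:
            logger.warning("dropping %s: non-positive value %g has no log", l, v)
    return kept_labels, kept
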