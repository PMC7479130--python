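"""Statistical kernel for plate-assay analysis.

Implements the test battery used throughout the pipeline: Tukey-fence
outlier removal, Welch's heteroscedasticity-robust one-way ANOVA,
Dunnett many-to-one and Tukey all-pairs multiple comparisons, Welch's
t-test, Shapiro-Wilk normality, and an enumeration-based two-sided
exact test for r x c contingency tables (Freeman-Halton extension of
Fisher's exact test).

All procedures are two-sided and control the family-wise error rate at
the supplied ``alpha``. Dunnett adjusted p-values are computed from the
equicorrelated multivariate-t reference distribution by numerical
quadrature (no table lookup), so they remain exact for unbalanced
designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "SampleGroup",
    "ComparisonResult",
    "ContingencyTable",
    "WelchAnovaResult",
    "iqr_filter",
    "welch_anova",
    "dunnett_many_to_one",
    "tukey_all_pairs",
    "welch_t",
    "shapiro_wilk",
    "fisher_exact_rxc",
    "enumerate_table_probabilities",
    "dunnett_max_abs_cdf",
    "dunnett_critical_value",
]

Direction = Literal["positive", "negative", "none"]


@dataclass(frozen=True)
class SampleGroup:
    """A labelled set of replicate measurements entering a test."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) == 0:
            raise ValueError(f"group {self.label!r}: empty value list")
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"group {self.label!r}: non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def var(self) -> float:
        """Unbiased sample variance (ddof=1)."""
        if self.n < 2:
            return 0.0
        return float(np.var(self.values, ddof=1))


@dataclass(frozen=True)
class ComparisonResult:
    """One adjusted pairwise comparison from a multiple-comparison procedure."""

    pair: tuple[str, str]
    estimate: float
    p_adjusted: float
    significant: bool
    direction: Direction

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError(f"p_adjusted out of [0,1]: {self.p_adjusted}")


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of category counts, r >= 2 and c >= 2."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = tuple(tuple(int(c) for c in row) for row in self.counts)
        if len(counts) < 2 or any(len(r) < 2 for r in counts):
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if len({len(r) for r in counts}) != 1:
            raise ValueError("ragged contingency table")
        if any(c < 0 for row in counts for c in row):
            raise ValueError("negative counts")
        if sum(c for row in counts for c in row) == 0:
            raise ValueError("all-zero contingency table")
        object.__setattr__(self, "counts", counts)
        if not self.row_labels:
            object.__setattr__(self, "row_labels", tuple(f"r{i}" for i in range(len(counts))))
        if not self.col_labels:
            object.__setattr__(self, "col_labels", tuple(f"c{j}" for j in range(len(counts[0]))))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class WelchAnovaResult:
    F_statistic: float
    df1: float
    df2: float
    p: float


# ---------------------------------------------------------------------------
# outlier fences
# ---------------------------------------------------------------------------

def iqr_filter(values: Sequence[float]) -> tuple[list[float], list[float]]:
    """Single-pass Tukey-fence filter.

    Keeps values inside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` with quartiles by
    linear interpolation between order statistics. Not iterated: the fences
    are computed once from the full input.

    Returns ``(kept, removed)`` preserving input order within each list.
    """
    vals = [float(v) for v in values]
    if len(vals) < 4:
        raise ValueError(f"need at least 4 values to place fences, got {len(vals)}")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite values")
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation ("type 7")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = [v for v in vals if lo <= v <= hi]
    removed = [v for v in vals if not (lo <= v <= hi)]
    return kept, removed


# ---------------------------------------------------------------------------
# Welch ANOVA and Welch t
# ---------------------------------------------------------------------------

def welch_anova(groups: Sequence[SampleGroup]) -> WelchAnovaResult:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Group variances are not assumed equal; each group is weighted by
    ``n_i / s_i^2`` and the denominator degrees of freedom follow Welch's
    approximation. Groups with zero variance are rejected (the weight
    would be infinite).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has fewer than 2 values")
        if g.var == 0.0:
            raise ValueError(f"group {g.label!r} has zero variance")
    k = len(groups)
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    v = np.array([g.var for g in groups])
    w = n / v
    w_sum = w.sum()
    mw = float((w * m).sum() / w_sum)
    a = float((w * (m - mw) ** 2).sum() / (k - 1))
    lam = float((((1 - w / w_sum) ** 2) / (n - 1)).sum())
    b = 1.0 + 2.0 * (k - 2) / (k * k - 1.0) * lam
    F = a / b
    df1 = float(k - 1)
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(F, df1, df2))
    return WelchAnovaResult(F, df1, df2, p)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired two-sided Welch t-test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Two identical constant samples give ``t = 0, p = 1`` by convention;
    a single constant sample is handled with its zero variance.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    na, nb = xa.size, xb.size
    diff = xa.mean() - xb.mean()
    se2 = va / na + vb / nb
    if se2 == 0.0:
        # both samples constant
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        t = math.inf if diff > 0 else -math.inf
        return t, float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    # squaring can underflow for near-constant samples; fall back to the
    # pooled df in that degenerate case
    df = se2**2 / den if den > 0 and se2**2 > 0 else float(na + nb - 2)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (AS R94 as implemented in SciPy).

    Valid for 3 <= n <= 5000, non-constant input.
    """
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample: W undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Dunnett many-to-one
# ---------------------------------------------------------------------------

# Probability-scale Gauss-Legendre nodes: integrating E[g(Z)] as
# \int_0^1 g(Phi^{-1}(u)) du handles the unbounded domain with a bounded,
# smooth integrand (products of normal CDFs).
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)
_U = 0.5 * (_GL_NODES + 1.0)
_W = 0.5 * _GL_WEIGHTS


def dunnett_max_abs_cdf(t: float | np.ndarray, lambdas: np.ndarray, df: float) -> np.ndarray:
    """P(max_i |T_i| <= t) for Dunnett statistics.

    ``T_i = (lam_i*Z0 + sqrt(1-lam_i^2)*Z_i) / S`` with ``S^2 ~ chi2_df/df``
    shared across comparisons and ``lam_i = sqrt(n_i/(n_i+n_0))``, which
    yields the Dunnett correlation ``rho_ij = lam_i*lam_j``. The double
    integral over ``Z0`` and ``S`` is evaluated by 96-point Gauss-Legendre
    quadrature on the probability scale of each variable.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lam = np.asarray(lambdas, dtype=float)
    z0 = special.ndtri(_U)  # (nz,)
    s = np.sqrt(stats.chi2.ppf(_U, df) / df)  # (ns,)
    # grid: axes (t, s, z0)
    ts = t_arr[:, None, None] * s[None, :, None]  # (nt, ns, 1)
    out = np.empty(t_arr.shape)
    prod = np.ones((t_arr.size, s.size, z0.size))
    for li in lam:
        denom = math.sqrt(max(1.0 - li * li, 1e-300))
        upper = special.ndtr((ts + li * z0[None, None, :]) / denom)
        lower = special.ndtr((-ts + li * z0[None, None, :]) / denom)
        prod *= upper - lower
    inner = prod @ _W  # integrate over z0 -> (nt, ns)
    out = inner @ _W  # integrate over s -> (nt,)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(t) else out[0]


def dunnett_critical_value(lambdas: np.ndarray, df: float, alpha: float) -> float:
    """Two-sided Dunnett critical value: solves P(max|T| <= c) = 1 - alpha.

    Root-found to absolute tolerance 1e-4 on c.
    """
    from scipy.optimize import brentq

    f = lambda c: float(dunnett_max_abs_cdf(c, lambdas, df)) - (1.0 - alpha)
    lo, hi = 0.1, 5.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 200:
            raise RuntimeError("Dunnett critical value bracket failed")
    return float(brentq(f, lo, hi, xtol=1e-4))


def _pooled_variance(groups: Sequence[SampleGroup]) -> tuple[float, float]:
    n_total = sum(g.n for g in groups)
    df = float(n_total - len(groups))
    ss = sum((g.n - 1) * g.var for g in groups)
    return ss / df, df


def _direction(estimate: float, significant: bool) -> Direction:
    if not significant or estimate == 0.0:
        return "none"
    return "positive" if estimate > 0 else "negative"


def dunnett_many_to_one(
    groups: Sequence[SampleGroup],
    control_label: str,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Dunnett's many-to-one comparisons against a named control group.

    Classical pooled-variance form: the error variance is pooled across
    all groups (control included) and each treatment is compared to the
    control with a single-step adjusted p-value
    ``p_i = P(max_j |T_j| >= |t_i|)`` under the equicorrelated
    multivariate-t null, which controls the FWER at ``alpha`` two-sided.
    Estimates are treatment mean minus control mean.
    """
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ValueError(f"control group {control_label!r} not found among {labels}")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has fewer than 2 values")
    if len(groups) < 2:
        raise ValueError("need a control and at least one treatment group")
    control = groups[labels.index(control_label)]
    treatments = [g for g in groups if g.label != control_label]
    s2, df = _pooled_variance(groups)
    if s2 == 0.0:
        raise ValueError("zero pooled variance")
    n0 = control.n
    nt = np.array([g.n for g in treatments], dtype=float)
    lam = np.sqrt(nt / (nt + n0))
    t_stats = np.array(
        [(g.mean - control.mean) / math.sqrt(s2 * (1.0 / g.n + 1.0 / n0)) for g in treatments]
    )
    p_adj = 1.0 - dunnett_max_abs_cdf(np.abs(t_stats), lam, df)
    p_adj = np.clip(p_adj, 0.0, 1.0)
    results = []
    for g, t_i, p_i in zip(treatments, t_stats, p_adj):
        est = g.mean - control.mean
        sig = bool(p_i < alpha)
        results.append(
            ComparisonResult(
                pair=(g.label, control_label),
                estimate=est,
                p_adjusted=float(p_i),
                significant=sig,
                direction=_direction(est, sig),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Tukey all-pairs
# ---------------------------------------------------------------------------

def tukey_all_pairs(groups: Sequence[SampleGroup], alpha: float = 0.05) -> list[ComparisonResult]:
    """Tukey(-Kramer) all-pairs comparisons with studentized-range p-values.

    Classical pooled-variance form; for unbalanced groups the Kramer
    standard error ``s*sqrt((1/n_i + 1/n_j)/2)`` is used. Estimates are
    ``mean_i - mean_j`` in input order.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has fewer than 2 values")
    s2, df = _pooled_variance(groups)
    if s2 == 0.0:
        raise ValueError("zero pooled variance")
    k = len(groups)
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            est = gi.mean - gj.mean
            se = math.sqrt(s2 * 0.5 * (1.0 / gi.n + 1.0 / gj.n))
            q = abs(est) / se
            p = float(stats.studentized_range.sf(q, k, df))
            p = min(max(p, 0.0), 1.0)
            sig = p < alpha
            results.append(
                ComparisonResult(
                    pair=(gi.label, gj.label),
                    estimate=est,
                    p_adjusted=p,
                    significant=sig,
                    direction=_direction(est, sig),
                )
            )
    return results


# ---------------------------------------------------------------------------
# Freeman-Halton exact r x c test
# ---------------------------------------------------------------------------

def _table_log_prob(flat: np.ndarray, log_const: float) -> float:
    return log_const - float(special.gammaln(flat + 1.0).sum())


def enumerate_table_probabilities(
    row_margins: Sequence[int], col_margins: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """All margin-preserving tables and their multivariate hypergeometric
    probabilities.

    Returns ``(tables, probs)`` where ``tables`` has shape
    ``(n_tables, r, c)``. The probabilities sum to 1 (a tested invariant).
    Enumeration cost grows combinatorially with the margins; intended for
    the small tables of plate-assay tallies.
    """
    rows = [int(r) for r in row_margins]
    cols = [int(c) for c in col_margins]
    if sum(rows) != sum(cols):
        raise ValueError("margin totals disagree")
    n = sum(rows)
    log_const = float(
        special.gammaln(np.array(rows) + 1.0).sum()
        + special.gammaln(np.array(cols) + 1.0).sum()
        - special.gammaln(n + 1.0)
    )
    r, c = len(rows), len(cols)
    tables: list[np.ndarray] = []

    def fill_row(i: int, remaining_cols: list[int], acc: list[list[int]]) -> None:
        if i == r - 1:
            tables.append(np.array(acc + [remaining_cols], dtype=np.int64))
            return
        target = rows[i]

        def compose(j: int, left: int, row_acc: list[int]) -> None:
            if j == c - 1:
                if left <= remaining_cols[j]:
                    row = row_acc + [left]
                    new_rem = [remaining_cols[m] - row[m] for m in range(c)]
                    fill_row(i + 1, new_rem, acc + [row])
                return
            # cell (i, j) can hold at most min(col remainder, row remainder),
            # and must leave enough capacity in later columns
            later_cap = sum(remaining_cols[j + 1 :])
            lo = max(0, left - later_cap)
            hi = min(remaining_cols[j], left)
            for v in range(lo, hi + 1):
                compose(j + 1, left - v, row_acc + [v])

        compose(0, target, [])

    fill_row(0, cols, [])
    arr = np.stack(tables)
    lp = log_const - special.gammaln(arr + 1.0).sum(axis=(1, 2))
    return arr, np.exp(lp)


def fisher_exact_rxc(
    table: ContingencyTable,
    max_total: int = 500,
    method: Literal["exact", "monte-carlo"] = "exact",
    n_resamples: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided Freeman-Halton exact test for an r x c table.

    The p-value is the total probability, under the multivariate
    hypergeometric distribution with the observed margins fixed, of every
    table at most as probable as the observed one (relative comparison
    tolerance 1e-7, matching the convention of R's ``fisher.test``).

    Full enumeration is used up to ``max_total`` observations; beyond that
    ``method='monte-carlo'`` estimates the same tail by sampling
    margin-fixed tables.
    """
    arr = table.array
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("all-zero row or column: test undefined")
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = int(arr.sum())
    log_const = float(
        special.gammaln(rows + 1.0).sum()
        + special.gammaln(cols + 1.0).sum()
        - special.gammaln(n + 1.0)
    )
    lp_obs = log_const - float(special.gammaln(arr + 1.0).sum())
    threshold = lp_obs + math.log1p(1e-7)
    if method == "exact":
        if n > max_total:
            raise ValueError(
                f"total count {n} exceeds enumeration limit {max_total}; "
                "use method='monte-carlo'"
            )
        _, probs = enumerate_table_probabilities(rows.tolist(), cols.tolist())
        lp = np.log(probs)
        return float(min(1.0, probs[lp <= threshold].sum()))
    # Monte Carlo on margin-fixed tables
    gen = rng if rng is not None else np.random.default_rng()
    sampled = stats.random_table(rows, cols).rvs(n_resamples, random_state=gen)
    lp = log_const - special.gammaln(sampled + 1.0).sum(axis=(1, 2))
    hits = int((lp <= threshold).sum())
    return float((hits + 1) / (n_resamples + 1))
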