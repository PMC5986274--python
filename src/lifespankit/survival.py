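"""Survival estimators and tests implemented from first principles.

This module contains the statistical core of the package: the
Kaplan-Meier product-limit estimator, median survival with a documented
plateau convention, the two-group log-rank test, Fisher's exact test with
the minimum-likelihood two-sided rule, the pooled-variance (Student)
two-sample t-test with a Welch option, the maximum-lifespan decile test
(Wang-Allison-style: genotype representation among the longest-lived 10%
of the pooled cohorts, assessed by Fisher's exact test), and a daily
chi-square scan that tests the dead/alive split between two cohorts on
every day of the joint lifespan and reports maximal runs of consecutive
significant days.

Only distribution tail functions (chi-square, t, hypergeometric pmf) come
from :mod:`scipy.stats`; every statistic is computed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .errors import NotComputableError, UndefinedMedianError, ValidationError

__all__ = [
    "SurvivalCurve",
    "TestResult",
    "MaxLifespanResult",
    "ChiSquareScan",
    "TieWarning",
    "kaplan_meier",
    "median_survival",
    "percent_change",
    "logrank_test",
    "fisher_exact_2x2",
    "ttest_unpaired",
    "max_lifespan_test",
    "daily_chisquare_scan",
]


class TieWarning(UserWarning):
    """A lifespan tie spans the decile cutoff; membership used the tie-break."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate with at-risk/event bookkeeping.

    ``event_times`` holds the distinct times with at least one event;
    ``survival_prob[i]`` is S(event_times[i]), ``n_at_risk[i]`` the number
    at risk just before that time and ``n_events[i]`` the events at it.
    ``n_initial`` is the cohort size at time zero.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_initial: int

    def __post_init__(self) -> None:
        s = self.survival_prob
        if len(s) and (np.any(np.diff(s) > 1e-12) or s[0] > 1 + 1e-12):
            raise ValidationError("survival_prob must be non-increasing and <= 1")
        if np.any(self.n_events > self.n_at_risk):
            raise ValidationError("n_events cannot exceed n_at_risk")

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_prob,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    sidedness: str = "two"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "sidedness": self.sidedness,
        }
        d.update(self.extra)
        return d


@dataclass(frozen=True)
class MaxLifespanResult:
    """Maximum-lifespan decile test output.

    ``count_in_top`` holds, per input cohort (a, b), how many of the
    pooled top ``top_set_size`` longest-lived mice it contributed.
    ``top_mean`` holds per-cohort (mean, SEM) of the within-cohort top
    decile used for the t-test comparison.
    """

    quantile_q: float
    top_set_size: int
    count_in_top: tuple[int, int]
    fisher: TestResult
    top_mean: tuple[tuple[float, float], tuple[float, float]]
    top_mean_ttest: TestResult
    top_mean_percent_diff: float
    tie_at_cutoff: bool


@dataclass(frozen=True)
class ChiSquareScan:
    """Per-day chi-square p-values and the significant windows.

    ``windows`` lists maximal runs of consecutive days with p < alpha as
    ``(start_day, end_day, n_deaths_in_window)`` where the death count is
    over both cohorts; ``degenerate_days`` counts days where a zero margin
    forced p = 1 by convention.
    """

    days: np.ndarray
    p_per_day: np.ndarray
    alpha: float
    windows: list[tuple[int, int, int]]
    n_days_tested: int
    degenerate_days: int


# ---------------------------------------------------------------------------
# Kaplan-Meier and medians


def kaplan_meier(cohort: Cohort) -> SurvivalCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored records (``event_observed=False``) leave the risk set at
    their time without contributing an event.
    """
    if len(cohort) == 0:
        raise ValidationError("kaplan_meier requires a non-empty cohort")
    times = cohort.lifespans
    events = cohort.events
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    distinct = np.unique(times[events]) if events.any() else np.array([], dtype=int)
    n = len(times)
    at_risk, d_events, surv = [], [], []
    s = 1.0
    for t in distinct:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & events))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d_events.append(d_i)
        surv.append(s)
    return SurvivalCurve(
        event_times=np.asarray(distinct, dtype=int),
        survival_prob=np.asarray(surv, dtype=float),
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_events, dtype=int),
        n_initial=n,
    )


def median_survival(curve: SurvivalCurve, atol: float = 1e-12) -> float:
    """Smallest event time with S(t) <= 0.5.

    Convention: if the curve sits exactly at 0.5 over a plateau, the
    midpoint of the plateau (between the time reaching 0.5 and the next
    event time) is reported. Raises :class:`UndefinedMedianError` when the
    curve never reaches 0.5 (heavy censoring).
    """
    s = curve.survival_prob
    if len(s) == 0 or s[-1] > 0.5 + atol:
        raise UndefinedMedianError("survival curve never reaches 0.5")
    idx = int(np.argmax(s <= 0.5 + atol))
    t = float(curve.event_times[idx])
    if abs(s[idx] - 0.5) <= atol and idx + 1 < len(curve.event_times):
        return 0.5 * (t + float(curve.event_times[idx + 1]))
    return t


def percent_change(value_a: float, value_b: float) -> float:
    """100 * (b - a) / a, e.g. the percent increase of a median over baseline."""
    if value_a <= 0:
        raise ValidationError("baseline value must be positive")
    return 100.0 * (value_b - value_a) / value_a


# ---------------------------------------------------------------------------
# Log-rank


def logrank_test(cohort_a: Cohort, cohort_b: Cohort) -> TestResult:
    """Two-group log-rank test.

    At each distinct event time, the observed events in group a are
    compared with their hypergeometric expectation given the pooled risk
    set; statistic = (sum O - sum E)^2 / sum Var on 1 df.
    """
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise ValidationError("logrank_test requires two non-empty cohorts")
    t_a, e_a = cohort_a.lifespans, cohort_a.events
    t_b, e_b = cohort_b.lifespans, cohort_b.events
    if not (e_a.any() or e_b.any()):
        raise NotComputableError("log-rank undefined: no events in either group")

    all_event_times = np.unique(
        np.concatenate([t_a[e_a], t_b[e_b]])
    )
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n1 = int(np.sum(t_a >= t))
        n2 = int(np.sum(t_b >= t))
        d1 = int(np.sum((t_a == t) & e_a))
        d2 = int(np.sum((t_b == t) & e_b))
        n, d = n1 + n2, d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        # no time with both groups at risk: groups are perfectly separated in
        # time or degenerate; report statistic 0 / p 1 for the identical case
        stat = 0.0
    else:
        stat = o_minus_e * o_minus_e / var
    p = float(stats.chi2.sf(stat, df=1)) if var > 0 else 1.0
    return TestResult(
        method="logrank", statistic=float(stat), p_value=p, df=1,
        extra={"observed_minus_expected": o_minus_e, "variance": var},
    )


# ---------------------------------------------------------------------------
# Fisher's exact test


def _hypergeom_pmf_table(r1: int, r2: int, c1: int) -> dict[int, float]:
    """Point probabilities of all 2x2 tables with fixed margins.

    Keyed by the top-left cell a; computed with exact integer binomials.
    """
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    return {
        a: math.comb(r1, a) * math.comb(r2, c1 - a) / denom for a in range(lo, hi + 1)
    }


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p-value follows the minimum-likelihood rule: the sum of
    hypergeometric point probabilities of every table (with the observed
    margins) whose probability does not exceed the observed table's, with
    a 1e-7 relative slack absorbing floating-point ties. The sample odds
    ratio is reported as the statistic (inf when b*c = 0 and a*d > 0).
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 expects a 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValidationError("table cells must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("table total must be positive")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        p = 1.0  # a zero margin leaves a single attainable table
        odds = math.nan
    else:
        pmf = _hypergeom_pmf_table(r1, r2, c1)
        obs = pmf[a]
        p = min(1.0, sum(v for v in pmf.values() if v <= obs * (1 + 1e-7)))
        odds = math.inf if b * c == 0 and a * d > 0 else (
            math.nan if a * d == 0 and b * c == 0 else a * d / (b * c)
        )
    return TestResult(
        method="fisher_exact",
        statistic=float(odds) if odds == odds else math.nan,
        p_value=float(p),
        df=None,
        extra={"odds_ratio": odds, "table": [[a, b], [c, d]]},
    )


# ---------------------------------------------------------------------------
# t-test


def ttest_unpaired(sample_a, sample_b, welch: bool = False) -> TestResult:
    """Unpaired two-tailed two-sample t-test.

    Defaults to the pooled-variance (Student) form; ``welch=True`` uses
    the Welch-Satterthwaite variant. Degenerate inputs: zero variance in
    both samples gives p = 1 when the means agree and p = 0 (infinite
    statistic) when they differ.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each sample needs n >= 2")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return _degenerate_t(m1, m2, "welch_ttest")
        tstat = (m1 - m2) / math.sqrt(se2)
        df = se2 * se2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        method = "welch_ttest"
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        if sp2 == 0:
            return _degenerate_t(m1, m2, "student_ttest")
        tstat = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        method = "student_ttest"
    p = 2.0 * float(stats.t.sf(abs(tstat), df))
    return TestResult(
        method=method, statistic=float(tstat), p_value=min(1.0, p),
        df=int(round(df)) if not welch else None,
        extra={"df_exact": float(df), "mean_a": float(m1), "mean_b": float(m2)},
    )


def _degenerate_t(m1: float, m2: float, method: str) -> TestResult:
    if m1 == m2:
        return TestResult(method=method, statistic=0.0, p_value=1.0, df=None,
                          extra={"degenerate": "zero variance, equal means"})
    return TestResult(method=method, statistic=math.inf, p_value=0.0, df=None,
                      extra={"degenerate": "zero variance, unequal means"})


# ---------------------------------------------------------------------------
# Maximum-lifespan decile test


def max_lifespan_test(
    cohort_a: Cohort, cohort_b: Cohort, q: float = 0.10
) -> MaxLifespanResult:
    """Maximum-lifespan test on the pooled top-q fraction.

    The k = floor(q * (n_a + n_b)) longest-lived mice of the pooled
    cohorts are selected (ties at the cutoff broken by descending
    lifespan, then ascending mouse_id, then group; a tie spanning the
    cutoff raises :class:`TieWarning`). The genotype-by-membership 2x2
    table goes to :func:`fisher_exact_2x2`. Separately, the top
    floor(q * n) lifespans *within* each cohort are averaged (mean, SEM),
    compared by the pooled t-test, and the percent difference of the means
    is reported. Censored records are rejected: the test needs observed
    lifespans.
    """
    if not (cohort_a.all_events_observed and cohort_b.all_events_observed):
        raise ValidationError(
            "max_lifespan_test is undefined with censored records"
        )
    n_a, n_b = len(cohort_a), len(cohort_b)
    n = n_a + n_b
    k = int(math.floor(q * n))
    if k < 1:
        raise ValidationError("combined N * q must be >= 1")

    pooled = [(r.lifespan_days, r.mouse_id, 0) for r in cohort_a.records]
    pooled += [(r.lifespan_days, r.mouse_id, 1) for r in cohort_b.records]
    pooled.sort(key=lambda t: (-t[0], t[1], t[2]))
    top = pooled[:k]
    tie = k < n and pooled[k - 1][0] == pooled[k][0]
    if tie:
        warnings.warn(
            "lifespan tie spans the top-set cutoff; deterministic tie-break applied",
            TieWarning,
            stacklevel=2,
        )
    in_a = sum(1 for t in top if t[2] == 0)
    in_b = k - in_a
    fisher = fisher_exact_2x2([[in_a, n_a - in_a], [in_b, n_b - in_b]])

    def top_stats(c: Cohort) -> tuple[np.ndarray, tuple[float, float]]:
        kk = max(1, int(math.floor(q * len(c))))
        vals = np.sort(c.lifespans)[::-1][:kk].astype(float)
        sem = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else math.nan
        return vals, (float(vals.mean()), float(sem))

    vals_a, stat_a = top_stats(cohort_a)
    vals_b, stat_b = top_stats(cohort_b)
    if len(vals_a) >= 2 and len(vals_b) >= 2:
        ttest = ttest_unpaired(vals_a, vals_b)
    else:
        ttest = TestResult(method="student_ttest", statistic=math.nan,
                           p_value=math.nan, extra={"degenerate": "n < 2"})
    pct = percent_change(stat_a[0], stat_b[0])
    return MaxLifespanResult(
        quantile_q=q,
        top_set_size=k,
        count_in_top=(in_a, in_b),
        fisher=fisher,
        top_mean=(stat_a, stat_b),
        top_mean_ttest=ttest,
        top_mean_percent_diff=pct,
        tie_at_cutoff=tie,
    )


# ---------------------------------------------------------------------------
# Daily chi-square scan


def pearson_chi2_2x2(a: int, b: int, c: int, d: int, continuity: bool = False):
    """Pearson chi-square for a 2x2 table, N(ad-bc)^2 / (r1 r2 c1 c2).

    Returns (statistic, p). A zero margin makes the test degenerate:
    (0, 1) is returned by convention. ``continuity`` applies the Yates
    correction.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 0.0, 1.0
    delta = abs(a * d - b * c)
    if continuity:
        delta = max(0.0, delta - n / 2.0)
    chi2 = n * delta * delta / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def daily_chisquare_scan(
    cohort_a: Cohort,
    cohort_b: Cohort,
    alpha: float = 0.05,
    continuity: bool = False,
) -> ChiSquareScan:
    """Chi-square test of the dead/alive split on every day of the lifespan.

    For each day d from the first to the last death over both groups, the
    2x2 table (died on or before d vs alive after d) x group is tested by
    Pearson's chi-square (1 df, no continuity correction by default).
    Maximal runs of consecutive days with p < alpha are reported together
    with the number of deaths (both groups) falling inside each run. Days
    where a margin is zero get p = 1 by convention and are counted in
    ``degenerate_days``. Censoring is not supported.
    """
    if not (cohort_a.all_events_observed and cohort_b.all_events_observed):
        raise ValidationError("daily_chisquare_scan requires no censoring")
    t_a = np.sort(cohort_a.lifespans)
    t_b = np.sort(cohort_b.lifespans)
    if len(t_a) == 0 and len(t_b) == 0:
        raise ValidationError("daily_chisquare_scan needs at least one death")
    all_t = np.concatenate([t_a, t_b])
    days = np.arange(all_t.min(), all_t.max() + 1)
    n_a, n_b = len(t_a), len(t_b)

    dead_a = np.searchsorted(t_a, days, side="right")
    dead_b = np.searchsorted(t_b, days, side="right")
    alive_a = n_a - dead_a
    alive_b = n_b - dead_b

    n = n_a + n_b
    r1 = np.full_like(dead_a, n_a)
    r2 = np.full_like(dead_b, n_b)
    c1 = dead_a + dead_b
    c2 = alive_a + alive_b
    num = n * (dead_a * alive_b - alive_a * dead_b).astype(float) ** 2
    den = (r1 * r2 * c1 * c2).astype(float)
    degenerate = den == 0
    chi2 = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    if continuity:
        delta = np.maximum(
            np.abs(dead_a * alive_b - alive_a * dead_b) - n / 2.0, 0.0
        )
        chi2 = np.where(degenerate, 0.0, n * delta**2 / np.where(degenerate, 1.0, den))
        p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))

    sig = p < alpha
    windows: list[tuple[int, int, int]] = []
    i = 0
    while i < len(days):
        if sig[i]:
            j = i
            while j + 1 < len(days) and sig[j + 1]:
                j += 1
            lo, hi = int(days[i]), int(days[j])
            n_deaths = int(np.sum((all_t >= lo) & (all_t <= hi)))
            windows.append((lo, hi, n_deaths))
            i = j + 1
        else:
            i += 1
    return ChiSquareScan(
        days=days,
        p_per_day=p,
        alpha=alpha,
        windows=windows,
        n_days_tested=len(days),
        degenerate_days=int(degenerate.sum()),
    )
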