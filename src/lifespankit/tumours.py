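"""Tumour pathology metrics and tumour-stratified survival comparisons.

Definitions used throughout:

* incidence — percentage of tumour-bearing mice among the *necropsied*
  mice of a cohort (mice without necropsy never enter the denominator);
* occurrence — the age at death of each tumour-bearing mouse;
* load — number of distinct tumour types found in one mouse;
* spread — number of distinct (organ, tumour type) pairs in one mouse,
  which counts each organ once per type: a single type in two organs
  gives 2, and two different types in the same organ also give 2.

Type frequencies count mice, not findings, per tumour type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, incidence_percent
from .errors import NotComputableError, ValidationError
from .survival import (
    TestResult,
    fisher_exact_2x2,
    kaplan_meier,
    logrank_test,
    median_survival,
    percent_change,
)

__all__ = [
    "TumourSummary",
    "tumour_summary",
    "incidence_comparison",
    "tumour_stratified_survival",
    "occurrence_curve",
]


@dataclass(frozen=True)
class TumourSummary:
    """Per-cohort tumour pathology summary (necropsied mice only)."""

    n_necropsied: int
    n_tumour_bearing: int
    incidence_percent: float
    occurrence_days: tuple[int, ...]
    load_per_mouse: tuple[int, ...]
    spread_per_mouse: tuple[int, ...]
    type_frequency: dict[str, int]
    stratum_label: str = ""

    def to_dict(self) -> dict:
        return {
            "stratum_label": self.stratum_label,
            "n_necropsied": self.n_necropsied,
            "n_tumour_bearing": self.n_tumour_bearing,
            "incidence_percent": self.incidence_percent,
            "occurrence_days": list(self.occurrence_days),
            "load_per_mouse": list(self.load_per_mouse),
            "spread_per_mouse": list(self.spread_per_mouse),
            "type_frequency": dict(self.type_frequency),
        }


def tumour_summary(cohort: Cohort) -> TumourSummary:
    """Summarise tumour pathology for one cohort.

    Raises :class:`NotComputableError` when no mouse was necropsied.
    """
    if len(cohort) == 0:
        raise ValidationError("tumour_summary requires a non-empty cohort")
    necropsied = [r for r in cohort.records if r.necropsy_performed]
    if not necropsied:
        raise NotComputableError("no necropsied mice: incidence undefined")
    bearing = [r for r in necropsied if r.tumour_bearing]

    type_freq: dict[str, int] = {}
    for r in bearing:
        for t in sorted({f.tumour_type for f in r.tumour_findings}):
            type_freq[t] = type_freq.get(t, 0) + 1

    return TumourSummary(
        n_necropsied=len(necropsied),
        n_tumour_bearing=len(bearing),
        incidence_percent=incidence_percent(len(bearing), len(necropsied)),
        occurrence_days=tuple(r.lifespan_days for r in bearing),
        load_per_mouse=tuple(
            len({f.tumour_type for f in r.tumour_findings}) for r in bearing
        ),
        spread_per_mouse=tuple(
            len({(f.organ, f.tumour_type) for f in r.tumour_findings})
            for r in bearing
        ),
        type_frequency=type_freq,
        stratum_label=cohort.stratum_label,
    )


def incidence_comparison(
    summary_a: TumourSummary, summary_b: TumourSummary
) -> TestResult:
    """Fisher's exact test of tumour incidence between two cohorts."""
    table = [
        [summary_a.n_tumour_bearing,
         summary_a.n_necropsied - summary_a.n_tumour_bearing],
        [summary_b.n_tumour_bearing,
         summary_b.n_necropsied - summary_b.n_tumour_bearing],
    ]
    return fisher_exact_2x2(table)


def tumour_stratified_survival(
    cohort_a: Cohort, cohort_b: Cohort
) -> dict[str, dict]:
    """Log-rank comparisons within the tumour-bearing and tumour-free strata.

    Mice without necropsy are excluded (their tumour status is unknown).
    Each stratum's entry carries the log-rank :class:`TestResult`, the
    stratum sizes and, when both medians exist, the percent change of the
    median. A stratum empty on either side is marked not computable.
    """
    out: dict[str, dict] = {}
    for name, keep in (
        ("tumour_bearing", lambda r: r.tumour_bearing),
        ("tumour_free", lambda r: not r.tumour_bearing),
    ):
        sub_a = cohort_a.subset(
            lambda r, k=keep: r.necropsy_performed and k(r), f"a/{name}"
        )
        sub_b = cohort_b.subset(
            lambda r, k=keep: r.necropsy_performed and k(r), f"b/{name}"
        )
        entry: dict = {"n_a": len(sub_a), "n_b": len(sub_b)}
        if len(sub_a) == 0 or len(sub_b) == 0:
            entry["computable"] = False
            entry["logrank"] = None
        else:
            entry["computable"] = True
            entry["logrank"] = logrank_test(sub_a, sub_b)
            try:
                med_a = median_survival(kaplan_meier(sub_a))
                med_b = median_survival(kaplan_meier(sub_b))
                entry["median_a"] = med_a
                entry["median_b"] = med_b
                entry["median_percent_change"] = percent_change(med_a, med_b)
            except NotComputableError:
                entry["median_percent_change"] = None
        out[name] = entry
    return out


def occurrence_curve(summary: TumourSummary, fraction: bool = True) -> pd.DataFrame:
    """Cumulative tumour occurrence versus age at death.

    Returns a step function as a frame with columns ``age_days`` and
    ``cumulative`` (count, or fraction of tumour-bearing mice when
    ``fraction`` is True; the fraction curve ends at 1).
    """
    if summary.n_tumour_bearing == 0:
        raise NotComputableError("no tumour-bearing mice: occurrence curve empty")
    days = np.sort(np.asarray(summary.occurrence_days))
    uniq, counts = np.unique(days, return_counts=True)
    cum = np.cumsum(counts).astype(float)
    if fraction:
        cum /= summary.n_tumour_bearing
    return pd.DataFrame({"age_days": uniq, "cumulative": cum})
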