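"""Data model and TSV IO for mouse lifespan cohorts.

A :class:`Cohort` is a validated list of :class:`MouseRecord` objects, one
per animal, carrying the recorded lifespan in whole days, the cause flags
(death/euthanasia observed, ulcerative-dermatitis euthanasia) and the
necropsy tumour findings. Records are read from and written to plain
tab-separated tables so cohorts round-trip through text files.

On-disk format
--------------
Survival table (mandatory header, tabs, booleans as 0/1)::

    mouse_id  genotype  sex  lifespan_days  event_observed  ud_case  necropsy_performed

Tumour table (optional)::

    mouse_id  tumour_type  organ

Tumour rows are joined to survival rows by ``mouse_id``; a tumour row for
an unknown mouse, or for a mouse without necropsy, is an error.
"""

from __future__ import annotations

from collections.abc import Callable, Hashable, Iterable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

GENOTYPES = ("wt", "mutant")
SEXES = ("female", "male")

SURVIVAL_COLUMNS = (
    "mouse_id",
    "genotype",
    "sex",
    "lifespan_days",
    "event_observed",
    "ud_case",
    "necropsy_performed",
)
TUMOUR_COLUMNS = ("mouse_id", "tumour_type", "organ")

#: Record fields that stratification predicates may reference.
STRATIFIABLE_FIELDS = (
    "genotype",
    "sex",
    "ud_case",
    "event_observed",
    "necropsy_performed",
)


@dataclass(frozen=True)
class TumourFinding:
    """One pathologically confirmed tumour: its type and the organ it was found in."""

    tumour_type: str
    organ: str

    def __post_init__(self) -> None:
        if not self.tumour_type or not str(self.tumour_type).strip():
            raise ValidationError("tumour_type must be a non-empty label")
        if not self.organ or not str(self.organ).strip():
            raise ValidationError("organ must be a non-empty label")


@dataclass(frozen=True)
class MouseRecord:
    """One animal of the lifespan cohort.

    ``event_observed`` is True when the death or euthanasia was observed;
    False marks a right-censored record, which the data model accepts for
    generality although the lifespan-study analyses treat every animal as
    an event. ``ud_case`` flags euthanasia for ulcerative dermatitis.
    Tumour findings may only be attached when a necropsy was performed.
    """

    mouse_id: str
    genotype: str
    sex: str
    lifespan_days: int
    event_observed: bool = True
    ud_case: bool = False
    necropsy_performed: bool = True
    tumour_findings: tuple[TumourFinding, ...] = ()

    def __post_init__(self) -> None:
        if not self.mouse_id or not str(self.mouse_id).strip():
            raise ValidationError("mouse_id must be non-empty")
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if isinstance(self.lifespan_days, float) and not float(
            self.lifespan_days
        ).is_integer():
            raise ValidationError(
                f"lifespan_days must be an integer number of days, got {self.lifespan_days}"
            )
        object.__setattr__(self, "lifespan_days", int(self.lifespan_days))
        if self.lifespan_days <= 0:
            raise ValidationError(
                f"lifespan_days must be positive, got {self.lifespan_days}"
            )
        if not self.necropsy_performed and self.tumour_findings:
            raise ValidationError(
                f"mouse {self.mouse_id}: tumour findings recorded without necropsy"
            )
        object.__setattr__(self, "tumour_findings", tuple(self.tumour_findings))

    @property
    def tumour_bearing(self) -> bool:
        return len(self.tumour_findings) > 0


@dataclass
class Cohort:
    """A validated collection of mouse records sharing a stratum label."""

    records: list[MouseRecord] = field(default_factory=list)
    stratum_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.mouse_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate mouse_id within cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lifespans(self) -> np.ndarray:
        """Lifespans in days, as an integer array."""
        return np.array([r.lifespan_days for r in self.records], dtype=int)

    @property
    def events(self) -> np.ndarray:
        """Event indicators (True = death observed) aligned with ``lifespans``."""
        return np.array([r.event_observed for r in self.records], dtype=bool)

    @property
    def all_events_observed(self) -> bool:
        return bool(self.events.all()) if self.records else True

    def subset(
        self, predicate: Callable[[MouseRecord], bool], label: str | None = None
    ) -> "Cohort":
        recs = [r for r in self.records if predicate(r)]
        return Cohort(recs, label if label is not None else self.stratum_label)

    def relabel(self, label: str) -> "Cohort":
        return Cohort(list(self.records), label)


def _as_bool(series: pd.Series, column: str, path: str) -> list[bool]:
    out = []
    for v in series:
        if v in (0, 1, "0", "1", True, False):
            out.append(bool(int(v)))
        else:
            raise FormatError(
                f"{path}: column {column!r} must contain 0/1, got {v!r}"
            )
    return out


def read_cohort(
    survival_table: str, tumour_table: str | None = None, stratum_label: str = ""
) -> Cohort:
    """Read a cohort from a survival TSV, optionally joining a tumour TSV.

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` for duplicate ids, unmatched tumour rows, or
    tumour rows attached to mice without necropsy.
    """
    surv = pd.read_csv(survival_table, sep="\t", dtype={"mouse_id": str})
    for col in SURVIVAL_COLUMNS:
        if col not in surv.columns:
            raise FormatError(f"{survival_table}: missing column {col!r}")

    findings: dict[str, list[TumourFinding]] = {}
    if tumour_table is not None:
        tum = pd.read_csv(tumour_table, sep="\t", dtype=str)
        for col in TUMOUR_COLUMNS:
            if col not in tum.columns:
                raise FormatError(f"{tumour_table}: missing column {col!r}")
        known = set(surv["mouse_id"])
        for row in tum.itertuples(index=False):
            if row.mouse_id not in known:
                raise ValidationError(
                    f"{tumour_table}: tumour row references unknown mouse_id "
                    f"{row.mouse_id!r}"
                )
            findings.setdefault(row.mouse_id, []).append(
                TumourFinding(row.tumour_type, row.organ)
            )

    records = []
    events = _as_bool(surv["event_observed"], "event_observed", survival_table)
    uds = _as_bool(surv["ud_case"], "ud_case", survival_table)
    necs = _as_bool(surv["necropsy_performed"], "necropsy_performed", survival_table)
    for i, row in enumerate(surv.itertuples(index=False)):
        lifespan = row.lifespan_days
        try:
            lifespan = int(lifespan)
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{survival_table}: lifespan_days must be an integer, got "
                f"{row.lifespan_days!r}"
            ) from exc
        if float(row.lifespan_days) != lifespan:
            raise ValidationError(
                f"{survival_table}: fractional lifespan_days {row.lifespan_days!r} "
                f"for mouse {row.mouse_id!r} rejected (whole days only)"
            )
        records.append(
            MouseRecord(
                mouse_id=row.mouse_id,
                genotype=row.genotype,
                sex=row.sex,
                lifespan_days=lifespan,
                event_observed=events[i],
                ud_case=uds[i],
                necropsy_performed=necs[i],
                tumour_findings=tuple(findings.get(row.mouse_id, ())),
            )
        )
    return Cohort(records, stratum_label)


def write_cohort(
    cohort: Cohort, survival_table: str, tumour_table: str | None = None
) -> None:
    """Write a cohort to canonical TSVs (rows sorted by mouse_id, booleans 0/1)."""
    recs = sorted(cohort.records, key=lambda r: r.mouse_id)
    surv = pd.DataFrame(
        {
            "mouse_id": [r.mouse_id for r in recs],
            "genotype": [r.genotype for r in recs],
            "sex": [r.sex for r in recs],
            "lifespan_days": [r.lifespan_days for r in recs],
            "event_observed": [int(r.event_observed) for r in recs],
            "ud_case": [int(r.ud_case) for r in recs],
            "necropsy_performed": [int(r.necropsy_performed) for r in recs],
        }
    )
    surv.to_csv(survival_table, sep="\t", index=False)
    if tumour_table is not None:
        rows = [
            (r.mouse_id, f.tumour_type, f.organ)
            for r in recs
            for f in r.tumour_findings
        ]
        pd.DataFrame(rows, columns=list(TUMOUR_COLUMNS)).to_csv(
            tumour_table, sep="\t", index=False
        )


def stratify(
    cohort: Cohort,
    by: str | Sequence[str] | Callable[[MouseRecord], Hashable],
) -> list[Cohort]:
    """Partition a cohort into strata.

    ``by`` is either a record field name (or sequence of names) from
    :data:`STRATIFIABLE_FIELDS`, in which case records are grouped by their
    value combination, or a callable mapping a record to a hashable group
    key. The returned strata are disjoint, exhaustive, and labelled by the
    grouping values; their order follows first appearance in the cohort.
    """
    if callable(by):
        keyfun = by
        fields: tuple[str, ...] = ()
    else:
        fields = (by,) if isinstance(by, str) else tuple(by)
        for f in fields:
            if f not in STRATIFIABLE_FIELDS and f != "lifespan_days":
                raise ValidationError(
                    f"cannot stratify by unknown field {f!r}; "
                    f"known fields: {STRATIFIABLE_FIELDS}"
                )
        keyfun = lambda r: tuple(getattr(r, f) for f in fields)  # noqa: E731

    groups: dict[Hashable, list[MouseRecord]] = {}
    for rec in cohort.records:
        groups.setdefault(keyfun(rec), []).append(rec)

    strata = []
    for key, recs in groups.items():
        if fields:
            label = "/".join(
                f"{f}={int(v) if isinstance(v, bool) else v}"
                for f, v in zip(fields, key)
            )
        else:
            label = str(key)
        if cohort.stratum_label:
            label = f"{cohort.stratum_label}/{label}" if label else cohort.stratum_label
        strata.append(Cohort(recs, label))
    return strata


def incidence_percent(numerator_count: int, denominator_count: int) -> float:
    """Percentage ``100 * numerator / denominator`` reported to one decimal.

    Used for e.g. ulcerative-dermatitis and tumour incidences (19 of 50
    mice -> 38.0).
    """
    if denominator_count <= 0:
        raise ValidationError("denominator_count must be positive")
    if numerator_count < 0 or numerator_count > denominator_count:
        raise ValidationError(
            "numerator_count must lie in [0, denominator_count], got "
            f"{numerator_count}/{denominator_count}"
        )
    return round(100.0 * numerator_count / denominator_count, 1)


def concat(cohorts: Iterable[Cohort], stratum_label: str = "") -> Cohort:
    """Concatenate cohorts with disjoint mouse ids into one."""
    records: list[MouseRecord] = []
    for c in cohorts:
        records.extend(c.records)
    return Cohort(records, stratum_label)


def with_unique_prefix(cohort: Cohort, prefix: str) -> Cohort:
    """Return a copy whose mouse ids are prefixed (for pooling across cohorts)."""
    return Cohort(
        [replace(r, mouse_id=f"{prefix}{r.mouse_id}") for r in cohort.records],
        cohort.stratum_label,
    )
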