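"""Case records and the registry inclusion/exclusion filter.

A population-based fracture registry accumulates candidate events from
hospital registers, trauma-unit and emergency logs, and primary-care
canvassing. Before rates can be computed the candidate set is reduced to
qualifying fragility fractures: residents of the catchment area, aged 50
or older, low-energy mechanism, non-pathological, inside the observation
window, with repeat admissions for the same fracture site removed. A
second fracture at the other hip counts as a new event.

The filter partitions its input into included and excluded cases, each
exclusion carrying exactly one reason, so the audit trail reconciles:
|included| + |excluded| equals the input count.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

SEX_VALUES = ("female", "male")
MECHANISM_VALUES = ("low_energy", "high_energy", "unknown")
SITE_VALUES = ("hip_left", "hip_right", "hip_unspecified")
SOURCE_VALUES = ("hospital", "trauma_unit", "emergency", "primary_care", "home_visit")

#: Exclusion reasons in precedence order: the first matching reason wins.
EXCLUSION_REASONS = (
    "out_of_window",
    "age",
    "nonresident",
    "pathological",
    "high_energy",
    "duplicate",
)


class RegistryError(ValueError):
    """Record-level validation failure; carries the offending case ids."""

    def __init__(self, message: str, case_ids: Sequence[str] = ()):
        super().__init__(message)
        self.case_ids = list(case_ids)


@dataclass(frozen=True)
class FractureCase:
    """One candidate registry event with its eligibility attributes."""

    case_id: str
    person_id: str
    sex: str
    age_years: int
    event_date: _dt.date
    resident: bool = True
    mechanism: str = "low_energy"
    pathological: bool = False
    site: str = "hip_unspecified"
    hospitalized: bool = True
    source: str = "hospital"


@dataclass(frozen=True)
class FilterRules:
    """Inclusion/exclusion rules for the registry filter.

    ``strict_mechanism`` controls mechanism=unknown: by default unknown is
    treated as low-energy (cases were clinically validated upstream);
    strict mode excludes it as high-energy.  ``unspecified_site_matches_both``
    makes hip_unspecified match either side during de-duplication, which is
    conservative against double counting.
    """

    window_start: _dt.date
    window_end: _dt.date
    min_age: int = 50
    require_resident: bool = True
    exclude_high_energy: bool = True
    exclude_pathological: bool = True
    strict_mechanism: bool = False
    unspecified_site_matches_both: bool = True

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")


@dataclass
class FilterReport:
    """Auditable partition of the candidate cases."""

    included: list[FractureCase] = field(default_factory=list)
    excluded: list[tuple[FractureCase, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {reason: 0 for reason in EXCLUSION_REASONS}
        for _, reason in self.excluded:
            out[reason] += 1
        return out

    @property
    def n_input(self) -> int:
        return len(self.included) + len(self.excluded)


def _validate(cases: Sequence[FractureCase]) -> None:
    bad: list[str] = []
    msgs: list[str] = []
    for c in cases:
        if c.sex not in SEX_VALUES:
            bad.append(c.case_id)
            msgs.append(f"case {c.case_id}: unknown sex {c.sex!r}")
        if not isinstance(c.event_date, _dt.date):
            bad.append(c.case_id)
            msgs.append(f"case {c.case_id}: event_date is not a date")
        if c.age_years < 0:
            bad.append(c.case_id)
            msgs.append(f"case {c.case_id}: negative age {c.age_years}")
        if c.mechanism not in MECHANISM_VALUES:
            bad.append(c.case_id)
            msgs.append(f"case {c.case_id}: unknown mechanism {c.mechanism!r}")
        if c.site not in SITE_VALUES:
            bad.append(c.case_id)
            msgs.append(f"case {c.case_id}: unknown site {c.site!r}")
    if bad:
        raise RegistryError("; ".join(msgs), case_ids=bad)


def _sites_match(a: str, b: str, unspecified_matches_both: bool) -> bool:
    if a == b:
        return True
    if unspecified_matches_both and ("hip_unspecified" in (a, b)):
        return True
    return False


def filter_cases(cases: Sequence[FractureCase], rules: FilterRules) -> FilterReport:
    """Partition candidate cases into included and excluded-with-reason.

    Reason precedence (first match wins): out_of_window, age, nonresident,
    pathological, high_energy, duplicate.  De-duplication keeps, per person
    and fracture site, only the earliest in-window event (ties broken by
    case_id), so the partition is independent of input order.
    """
    _validate(cases)

    report = FilterReport()
    decisions: dict[str, Optional[str]] = {}

    for c in cases:
        if not (rules.window_start <= c.event_date <= rules.window_end):
            decisions[c.case_id] = "out_of_window"
        elif c.age_years < rules.min_age:
            decisions[c.case_id] = "age"
        elif rules.require_resident and not c.resident:
            decisions[c.case_id] = "nonresident"
        elif rules.exclude_pathological and c.pathological:
            decisions[c.case_id] = "pathological"
        elif rules.exclude_high_energy and (
            c.mechanism == "high_energy"
            or (rules.strict_mechanism and c.mechanism == "unknown")
        ):
            decisions[c.case_id] = "high_energy"
        else:
            decisions[c.case_id] = None  # survives non-duplicate rules

    # De-duplicate among survivors, chronologically per person.
    survivors = [c for c in cases if decisions[c.case_id] is None]
    by_person: dict[str, list[FractureCase]] = {}
    for c in survivors:
        by_person.setdefault(c.person_id, []).append(c)
    for events in by_person.values():
        events.sort(key=lambda c: (c.event_date, c.case_id))
        kept: list[FractureCase] = []
        for c in events:
            if any(
                _sites_match(c.site, k.site, rules.unspecified_site_matches_both)
                for k in kept
            ):
                decisions[c.case_id] = "duplicate"
            else:
                kept.append(c)

    for c in cases:  # emit in input order
        reason = decisions[c.case_id]
        if reason is None:
            report.included.append(c)
        else:
            report.excluded.append((c, reason))
    return report


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AscertainmentSummary:
    n_total: int
    n_hospitalized: int
    pct_hospitalized: float
    pct_not_hospitalized: float
    n_female: int
    n_male: int
    female_male_ratio: Optional[float]  # None when n_male == 0


def ascertainment_summary(report: FilterReport) -> AscertainmentSummary:
    """Hospitalization and sex split of the included cases.

    Percentages are on included cases only, rounded half-up to one decimal;
    the female:male ratio is undefined (None) when there are no male cases.
    """
    inc = report.included
    n = len(inc)
    n_hosp = sum(1 for c in inc if c.hospitalized)
    n_f = sum(1 for c in inc if c.sex == "female")
    n_m = n - n_f
    if n == 0:
        return AscertainmentSummary(0, 0, 0.0, 0.0, 0, 0, None)
    return AscertainmentSummary(
        n_total=n,
        n_hospitalized=n_hosp,
        pct_hospitalized=_round1(100.0 * n_hosp / n),
        pct_not_hospitalized=_round1(100.0 * (n - n_hosp) / n),
        n_female=n_f,
        n_male=n_m,
        female_male_ratio=_round1(n_f / n_m) if n_m else None,
    )
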