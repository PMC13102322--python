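"""Safety-event data model and tabular I/O.

The data elements follow the WHO International Classification for Patient
Safety / AHRQ Common Formats conventions: every incident is coded with an
event type (near miss, no-harm incident, harmful incident), whether it
reached the patient, how it was detected, the unit or domain where it
occurred, and — for events that feed severity-weighted analytics — an
ordinal severity class giving the worst reasonable outcome had the event
not been intercepted.

Three CSV dialects are the interchange formats:

* ``events.csv``    — event_id, event_date, event_type, reached_patient,
  detection_mode, unit_domain, severity_class (blank allowed)
* ``exposures.csv`` — period_id, unit_domain, denominator_type,
  exposure_count, scaling_constant (blank → default for the denominator type)
* ``actions.csv``   — action_id, event_id, report_date, implemented_date,
  sustainment_verified_date, sustainment_evidence

Validation is *total*: every input row is either accepted or appears exactly
once in the returned :class:`ValidationReport`.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .periods import PeriodFormatError, parse_period


class EventType(str, enum.Enum):
    NEAR_MISS = "near_miss"
    NO_HARM_INCIDENT = "no_harm_incident"
    HARMFUL_INCIDENT = "harmful_incident"


class DetectionMode(str, enum.Enum):
    HUMAN = "human"
    ALARM = "alarm"
    PATIENT = "patient"
    CHANCE = "chance"


class UnitDomain(str, enum.Enum):
    ICU = "icu"
    OPERATING_ROOM = "operating_room"
    EMERGENCY_DEPARTMENT = "emergency_department"
    PHARMACY = "pharmacy"
    LABORATORY = "laboratory"
    TRANSFUSION = "transfusion"
    WARD = "ward"
    OTHER = "other"


#: Scope label for exposure records that cover the whole hospital.
HOSPITAL_WIDE = "hospital_wide"


class SeverityClass(str, enum.Enum):
    MINOR = "minor"
    MODERATE = "moderate"
    MAJOR = "major"
    CATASTROPHIC = "catastrophic"


class DenominatorType(str, enum.Enum):
    PATIENT_DAYS = "patient_days"
    DOSES = "doses"
    SPECIMENS = "specimens"
    UNITS = "units"
    PROCEDURES = "procedures"
    ADMISSIONS = "admissions"


class SustainmentEvidence(str, enum.Enum):
    AUDIT = "audit"
    PERFORMANCE_DATA = "performance_data"
    NONE = "none"


#: Scaling constants by denominator type: pharmacy doses per 10,000, all
#: other exposures per 1,000.
DEFAULT_SCALING: dict[DenominatorType, int] = {
    DenominatorType.DOSES: 10_000,
}
FALLBACK_SCALING = 1_000

#: Sustainment counts at the 180-day mark with a 7-day audit-timing grace,
#: so a verification at day ≥ 173 after implementation qualifies.
SUSTAINMENT_MIN_DAYS = 173


class ValidationError(ValueError):
    """A row violates the data-model invariants (strict mode, or construction)."""


class FormatError(ValueError):
    """The file itself is malformed (missing columns, unreadable dates)."""


@dataclass(frozen=True)
class SafetyEvent:
    """One coded safety incident."""

    event_id: str
    event_date: _dt.date
    event_type: EventType
    reached_patient: bool
    detection_mode: DetectionMode
    unit_domain: UnitDomain
    severity_class: Optional[SeverityClass] = None

    def __post_init__(self) -> None:
        if self.event_type is EventType.NEAR_MISS and self.reached_patient:
            raise ValidationError(
                f"event {self.event_id}: taxonomy conflict — a near miss did "
                "not reach the patient"
            )
        if self.event_type is EventType.NO_HARM_INCIDENT and not self.reached_patient:
            raise ValidationError(
                f"event {self.event_id}: taxonomy conflict — a no-harm "
                "incident reached the patient"
            )


@dataclass(frozen=True)
class ExposurePeriod:
    """A period × unit denominator record (patient-days, doses, ...)."""

    period_id: str
    unit_domain: str  # a UnitDomain value or HOSPITAL_WIDE
    denominator_type: DenominatorType
    exposure_count: float
    scaling_constant: int = 0  # 0 → fill default from denominator_type

    def __post_init__(self) -> None:
        if self.exposure_count <= 0:
            raise ValidationError(
                f"exposure {self.period_id}/{self.unit_domain}: "
                f"exposure_count must be > 0, got {self.exposure_count}"
            )
        parse_period(self.period_id)  # raises PeriodFormatError if malformed
        if self.scaling_constant == 0:
            object.__setattr__(
                self,
                "scaling_constant",
                DEFAULT_SCALING.get(self.denominator_type, FALLBACK_SCALING),
            )
        elif self.scaling_constant < 0:
            raise ValidationError("scaling_constant must be positive")


@dataclass(frozen=True)
class ActionRecord:
    """A corrective action linked to a reported event.

    The 90-day clock starts at ``report_date``; sustainment is credited when
    an objective verification (audit or performance data) falls at least
    :data:`SUSTAINMENT_MIN_DAYS` after implementation.
    """

    action_id: str
    event_id: str
    report_date: _dt.date
    implemented_date: Optional[_dt.date] = None
    sustainment_verified_date: Optional[_dt.date] = None
    sustainment_evidence: SustainmentEvidence = SustainmentEvidence.NONE

    def __post_init__(self) -> None:
        if self.implemented_date is not None and self.implemented_date < self.report_date:
            raise ValidationError(
                f"action {self.action_id}: implemented_date precedes report_date"
            )
        if self.sustainment_verified_date is not None:
            if self.implemented_date is None:
                raise ValidationError(
                    f"action {self.action_id}: sustainment verified without an "
                    "implemented_date"
                )
            if self.sustainment_verified_date < self.implemented_date:
                raise ValidationError(
                    f"action {self.action_id}: sustainment_verified_date "
                    "precedes implemented_date"
                )

    @property
    def implemented_within(self) -> Optional[int]:
        """Days from report to implementation, or None if not implemented."""
        if self.implemented_date is None:
            return None
        return (self.implemented_date - self.report_date).days

    @property
    def sustained(self) -> bool:
        """True when sustainment is verified at the 180-day mark with evidence."""
        return (
            self.implemented_date is not None
            and self.sustainment_verified_date is not None
            and self.sustainment_evidence is not SustainmentEvidence.NONE
            and (self.sustainment_verified_date - self.implemented_date).days
            >= SUSTAINMENT_MIN_DAYS
        )


@dataclass
class ValidationIssue:
    row: int  # 0-based data-row index in the source file
    field: str
    code: str  # e.g. "taxonomy_conflict", "unknown_enum", "duplicate_id"
    message: str
    severity: str = "error"  # "error" rows are quarantined; "warning" rows kept


@dataclass
class ValidationReport:
    source: str = ""
    n_rows: int = 0
    n_accepted: int = 0
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def n_quarantined(self) -> int:
        return len({i.row for i in self.errors})

    def add(self, row: int, field_: str, code: str, message: str,
            severity: str = "error") -> None:
        self.issues.append(ValidationIssue(row, field_, code, message, severity))

    def raise_if_errors(self) -> None:
        if self.errors:
            first = self.errors[0]
            raise ValidationError(
                f"{self.source}: {len(self.errors)} validation error(s); first: "
                f"row {first.row}, {first.field}: {first.message}"
            )


# ---------------------------------------------------------------------------
# CSV readers / writers

EVENT_COLUMNS = ["event_id", "event_date", "event_type", "reached_patient",
                 "detection_mode", "unit_domain", "severity_class"]
EXPOSURE_COLUMNS = ["period_id", "unit_domain", "denominator_type",
                    "exposure_count", "scaling_constant"]
ACTION_COLUMNS = ["action_id", "event_id", "report_date", "implemented_date",
                  "sustainment_verified_date", "sustainment_evidence"]

_REACHED = {"yes": True, "no": False}


def _read_csv(path, required: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for c in optional:
        if c not in df.columns:
            df[c] = ""
    return df


def _parse_date(raw: str) -> _dt.date:
    return _dt.date.fromisoformat(raw.strip())


def _parse_enum(enum_cls, raw: str):
    return enum_cls(raw.strip())


def read_events(path, strict: bool = False) -> tuple[list[SafetyEvent], ValidationReport]:
    """Read and validate an events CSV.

    In strict mode any validation error raises; otherwise offending rows are
    quarantined and listed in the report. Unknown ``unit_domain`` codes are
    mapped to ``other`` with a warning so hospital-wide analysis never loses
    events to stratification vocabulary.
    """
    df = _read_csv(path, EVENT_COLUMNS[:-1], optional=["severity_class"])
    report = ValidationReport(source=str(path), n_rows=len(df))
    events: list[SafetyEvent] = []
    seen_ids: set[str] = set()

    for i, row in enumerate(df.itertuples(index=False)):
        ok = True

        def err(field_: str, code: str, message: str) -> None:
            nonlocal ok
            ok = False
            report.add(i, field_, code, message)

        event_id = row.event_id.strip()
        if not event_id:
            err("event_id", "missing_value", "empty event_id")
        elif event_id in seen_ids:
            err("event_id", "duplicate_id", f"duplicate event_id {event_id!r}")

        try:
            event_date = _parse_date(row.event_date)
        except ValueError:
            err("event_date", "bad_date", f"unparseable date {row.event_date!r}")
            event_date = None

        try:
            event_type = _parse_enum(EventType, row.event_type)
        except ValueError:
            err("event_type", "unknown_enum",
                f"unknown event_type {row.event_type!r}")
            event_type = None

        raw_reached = row.reached_patient.strip().lower()
        if raw_reached in _REACHED:
            reached = _REACHED[raw_reached]
        else:
            err("reached_patient", "unknown_enum",
                f"reached_patient must be yes/no, got {row.reached_patient!r}")
            reached = None

        try:
            detection = _parse_enum(DetectionMode, row.detection_mode)
        except ValueError:
            err("detection_mode", "unknown_enum",
                f"unknown detection_mode {row.detection_mode!r}")
            detection = None

        raw_domain = row.unit_domain.strip()
        try:
            domain = UnitDomain(raw_domain)
        except ValueError:
            domain = UnitDomain.OTHER
            report.add(i, "unit_domain", "unknown_code",
                       f"unknown unit_domain {raw_domain!r} mapped to 'other'",
                       severity="warning")

        raw_sev = row.severity_class.strip()
        severity: Optional[SeverityClass] = None
        if raw_sev:
            try:
                severity = SeverityClass(raw_sev)
            except ValueError:
                err("severity_class", "unknown_enum",
                    f"unknown severity_class {raw_sev!r}")

        if ok and event_type is EventType.NEAR_MISS and reached:
            err("reached_patient", "taxonomy_conflict",
                "taxonomy conflict: near miss must not reach the patient")
        if ok and event_type is EventType.NO_HARM_INCIDENT and not reached:
            err("reached_patient", "taxonomy_conflict",
                "taxonomy conflict: no-harm incident must reach the patient")

        if ok:
            events.append(SafetyEvent(event_id, event_date, event_type,
                                      reached, detection, domain, severity))
            seen_ids.add(event_id)
            report.n_accepted += 1

    if strict:
        report.raise_if_errors()
    return events, report


def read_exposures(path, strict: bool = True) -> tuple[list[ExposurePeriod], ValidationReport]:
    """Read exposure denominators; blank scaling constants are filled from
    the denominator type (10,000 for doses, 1,000 otherwise)."""
    df = _read_csv(path, EXPOSURE_COLUMNS[:-1], optional=["scaling_constant"])
    report = ValidationReport(source=str(path), n_rows=len(df))
    exposures: list[ExposurePeriod] = []

    for i, row in enumerate(df.itertuples(index=False)):
        try:
            denom_type = DenominatorType(row.denominator_type.strip())
            count = float(row.exposure_count)
            raw_scale = str(row.scaling_constant).strip()
            scale = int(float(raw_scale)) if raw_scale else 0
            domain = row.unit_domain.strip()
            if domain != HOSPITAL_WIDE:
                domain = UnitDomain(domain).value
            exposures.append(ExposurePeriod(row.period_id.strip(), domain,
                                            denom_type, count, scale))
            report.n_accepted += 1
        except (ValueError, PeriodFormatError) as exc:
            report.add(i, "*", "validation", str(exc))

    if strict:
        report.raise_if_errors()
    return exposures, report


def read_actions(path, events: Optional[Iterable[SafetyEvent]] = None,
                 strict: bool = False,
                 dangling_is_error: bool = False) -> tuple[list[ActionRecord], ValidationReport]:
    """Read the corrective-action log.

    Date-ordering invariants are enforced; an action referencing an event_id
    absent from ``events`` (when supplied) is a warning by default.
    """
    df = _read_csv(path, ACTION_COLUMNS[:3],
                   optional=["implemented_date", "sustainment_verified_date",
                             "sustainment_evidence"])
    report = ValidationReport(source=str(path), n_rows=len(df))
    known_ids = {e.event_id for e in events} if events is not None else None
    actions: list[ActionRecord] = []

    for i, row in enumerate(df.itertuples(index=False)):
        try:
            report_date = _parse_date(row.report_date)
            implemented = (_parse_date(row.implemented_date)
                           if row.implemented_date.strip() else None)
            verified = (_parse_date(row.sustainment_verified_date)
                        if row.sustainment_verified_date.strip() else None)
            raw_ev = row.sustainment_evidence.strip()
            evidence = SustainmentEvidence(raw_ev) if raw_ev else SustainmentEvidence.NONE
            record = ActionRecord(row.action_id.strip(), row.event_id.strip(),
                                  report_date, implemented, verified, evidence)
        except (ValueError,) as exc:
            report.add(i, "*", "validation", str(exc))
            continue

        if (record.implemented_date is not None
                and record.sustainment_verified_date is not None
                and (record.sustainment_verified_date - record.implemented_date).days
                < SUSTAINMENT_MIN_DAYS):
            report.add(i, "sustainment_verified_date", "early_verification",
                       f"action {record.action_id}: verified "
                       f"{(record.sustainment_verified_date - record.implemented_date).days} "
                       f"days after implementation (< {SUSTAINMENT_MIN_DAYS}); "
                       "not counted as sustained", severity="warning")

        if known_ids is not None and record.event_id not in known_ids:
            sev = "error" if dangling_is_error else "warning"
            report.add(i, "event_id", "dangling_reference",
                       f"action {record.action_id} references unknown event "
                       f"{record.event_id!r}", severity=sev)
            if dangling_is_error:
                continue

        actions.append(record)
        report.n_accepted += 1

    if strict:
        report.raise_if_errors()
    return actions, report


def _date_str(d: Optional[_dt.date]) -> str:
    return d.isoformat() if d is not None else ""


def write_events(events: Iterable[SafetyEvent], path) -> None:
    rows = [{
        "event_id": e.event_id,
        "event_date": e.event_date.isoformat(),
        "event_type": e.event_type.value,
        "reached_patient": "yes" if e.reached_patient else "no",
        "detection_mode": e.detection_mode.value,
        "unit_domain": e.unit_domain.value,
        "severity_class": e.severity_class.value if e.severity_class else "",
    } for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_exposures(exposures: Iterable[ExposurePeriod], path) -> None:
    rows = [{
        "period_id": x.period_id,
        "unit_domain": x.unit_domain,
        "denominator_type": x.denominator_type.value,
        "exposure_count": x.exposure_count,
        "scaling_constant": x.scaling_constant,
    } for x in exposures]
    pd.DataFrame(rows, columns=EXPOSURE_COLUMNS).to_csv(path, index=False)


def write_actions(actions: Iterable[ActionRecord], path) -> None:
    rows = [{
        "action_id": a.action_id,
        "event_id": a.event_id,
        "report_date": a.report_date.isoformat(),
        "implemented_date": _date_str(a.implemented_date),
        "sustainment_verified_date": _date_str(a.sustainment_verified_date),
        "sustainment_evidence": a.sustainment_evidence.value,
    } for a in actions]
    pd.DataFrame(rows, columns=ACTION_COLUMNS).to_csv(path, index=False)
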