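"""Event/exposure/action data model: validation, defaults, round-trips."""

import datetime as dt

import pytest

from nm3.events import (
    ActionRecord,
    DenominatorType,
    DetectionMode,
    EventType,
    ExposurePeriod,
    SafetyEvent,
    SeverityClass,
    SustainmentEvidence,
    UnitDomain,
    ValidationError,
    FormatError,
    read_actions,
    read_events,
    read_exposures,
    write_actions,
    write_events,
    write_exposures,
)


def _csv(path, text):
    path.write_text(text.strip() + "\n")
    return path


EVENTS_HEADER = ("event_id,event_date,event_type,reached_patient,"
                 "detection_mode,unit_domain,severity_class")


class TestReadEvents:
    def test_valid_row_accepted(self, tmp_path):
        p = _csv(tmp_path / "e.csv",
                 f"{EVENTS_HEADER}\ne1,2025-01-10,near_miss,no,human,pharmacy,minor")
        events, report = read_events(p)
        assert len(events) == 1 and report.n_accepted == 1 and not report.issues
        ev = events[0]
        assert ev.event_type is EventType.NEAR_MISS
        assert ev.unit_domain is UnitDomain.PHARMACY
        assert ev.severity_class is SeverityClass.MINOR
        assert ev.reached_patient is False

    def test_taxonomy_conflict_quarantined(self, tmp_path):
        p = _csv(tmp_path / "e.csv",
                 f"{EVENTS_HEADER}\ne1,2025-01-10,near_miss,yes,human,icu,")
        events, report = read_events(p)
        assert events == []
        assert report.n_quarantined == 1
        assert any(i.code == "taxonomy_conflict" for i in report.errors)

    def test_no_harm_incident_must_reach_patient(self, tmp_path):
        p = _csv(tmp_path / "e.csv",
                 f"{EVENTS_HEADER}\ne1,2025-01-10,no_harm_incident,no,alarm,ward,")
        events, report = read_events(p)
        assert events == [] and report.n_quarantined == 1

    def test_strict_mode_raises(self, tmp_path):
        p = _csv(tmp_path / "e.csv",
                 f"{EVENTS_HEADER}\ne1,2025-01-10,near_miss,yes,human,icu,")
        with pytest.raises(ValidationError):
            read_events(p, strict=True)

    def test_duplicate_event_id_rejected(self, tmp_path):
        p = _csv(tmp_path / "e.csv", f"""{EVENTS_HEADER}
e1,2025-01-10,near_miss,no,human,icu,
e1,2025-01-11,near_miss,no,alarm,icu,""")
        events, report = read_events(p)
        assert len(events) == 1
        assert any(i.code == "duplicate_id" for i in report.errors)

    def test_unknown_unit_domain_maps_to_other_with_warning(self, tmp_path):
        p = _csv(tmp_path / "e.csv",
                 f"{EVENTS_HEADER}\ne1,2025-01-10,near_miss,no,human,helipad,")
        events, report = read_events(p)
        assert events[0].unit_domain is UnitDomain.OTHER
        assert report.warnings and report.warnings[0].code == "unknown_code"

    def test_unknown_enum_named_in_report(self, tmp_path):
        p = _csv(tmp_path / "e.csv",
                 f"{EVENTS_HEADER}\ne1,2025-01-10,oops,no,human,icu,")
        _, report = read_events(p)
        assert report.errors[0].field == "event_type"
        assert report.errors[0].row == 0

    def test_missing_column_is_format_error(self, tmp_path):
        p = _csv(tmp_path / "e.csv", "event_id,event_date\ne1,2025-01-10")
        with pytest.raises(FormatError):
            read_events(p)

    def test_reference_quarter_loads_fully(self, reference_csvs):
        events, report = read_events(reference_csvs["events"], strict=True)
        assert len(events) == 60
        assert report.n_quarantined == 0
        by_type = {}
        for e in events:
            by_type[e.event_type] = by_type.get(e.event_type, 0) + 1
        assert by_type[EventType.NEAR_MISS] == 10
        assert by_type[EventType.HARMFUL_INCIDENT] == 50

    def test_validation_is_total(self, tmp_path):
        """Every row is either accepted or quarantined, never both or neither."""
        p = _csv(tmp_path / "e.csv", f"""{EVENTS_HEADER}
e1,2025-01-10,near_miss,no,human,icu,minor
e2,2025-01-10,near_miss,yes,human,icu,
e3,bad-date,near_miss,no,human,icu,
e4,2025-02-01,harmful_incident,yes,chance,ward,""")
        events, report = read_events(p)
        assert len(events) + report.n_quarantined == report.n_rows == 4


class TestReadExposures:
    def test_default_scaling_patient_days(self, tmp_path):
        p = _csv(tmp_path / "x.csv",
                 "period_id,unit_domain,denominator_type,exposure_count\n"
                 "2025-Q1,hospital_wide,patient_days,50000")
        exposures, _ = read_exposures(p)
        assert exposures[0].scaling_constant == 1000

    def test_default_scaling_doses(self, tmp_path):
        p = _csv(tmp_path / "x.csv",
                 "period_id,unit_domain,denominator_type,exposure_count\n"
                 "2025-01,pharmacy,doses,20000")
        exposures, _ = read_exposures(p)
        assert exposures[0].scaling_constant == 10_000
        assert exposures[0].denominator_type is DenominatorType.DOSES

    def test_explicit_scaling_kept(self, tmp_path):
        p = _csv(tmp_path / "x.csv",
                 "period_id,unit_domain,denominator_type,exposure_count,scaling_constant\n"
                 "2025-01,icu,patient_days,800,1000")
        exposures, _ = read_exposures(p)
        assert exposures[0].scaling_constant == 1000

    def test_zero_exposure_is_validation_error(self, tmp_path):
        p = _csv(tmp_path / "x.csv",
                 "period_id,unit_domain,denominator_type,exposure_count\n"
                 "2025-01,icu,patient_days,0")
        with pytest.raises(ValidationError):
            read_exposures(p)

    def test_bad_period_label_rejected(self):
        with pytest.raises(Exception):
            ExposurePeriod("Jan-2025", "icu", DenominatorType.PATIENT_DAYS, 100)


class TestReadActions:
    HEADER = ("action_id,event_id,report_date,implemented_date,"
              "sustainment_verified_date,sustainment_evidence")

    def test_implemented_within_window(self, tmp_path):
        p = _csv(tmp_path / "a.csv",
                 f"{self.HEADER}\na1,e1,2025-01-10,2025-03-01,,")
        actions, report = read_actions(p)
        assert actions[0].implemented_within == 50
        assert not report.errors

    def test_ordering_violation(self, tmp_path):
        p = _csv(tmp_path / "a.csv",
                 f"{self.HEADER}\na2,e2,2025-01-10,2025-01-05,,")
        actions, report = read_actions(p)
        assert actions == [] and report.n_quarantined == 1

    def test_dangling_event_id_warns(self, tmp_path, reference_quarter):
        events = reference_quarter[0]
        p = _csv(tmp_path / "a.csv",
                 f"{self.HEADER}\na1,ghost,2025-01-10,2025-03-01,,")
        actions, report = read_actions(p, events)
        assert len(actions) == 1  # kept, but flagged
        assert report.warnings[0].code == "dangling_reference"
        _, report2 = read_actions(p, events, dangling_is_error=True)
        assert report2.n_quarantined == 1

    def test_sustainment_requires_evidence_and_173_days(self):
        base = dict(action_id="a", event_id="e",
                    report_date=dt.date(2025, 1, 1),
                    implemented_date=dt.date(2025, 2, 1))
        sustained = ActionRecord(**base,
                                 sustainment_verified_date=dt.date(2025, 8, 1),
                                 sustainment_evidence=SustainmentEvidence.AUDIT)
        assert sustained.sustained  # 181 days, audit evidence
        early = ActionRecord(**base,
                             sustainment_verified_date=dt.date(2025, 6, 1),
                             sustainment_evidence=SustainmentEvidence.AUDIT)
        assert not early.sustained  # 120 days < 173
        no_evidence = ActionRecord(**base,
                                   sustainment_verified_date=dt.date(2025, 8, 1),
                                   sustainment_evidence=SustainmentEvidence.NONE)
        assert not no_evidence.sustained

    def test_verified_without_implementation_rejected(self):
        with pytest.raises(ValidationError):
            ActionRecord("a", "e", dt.date(2025, 1, 1), None,
                         dt.date(2025, 8, 1), SustainmentEvidence.AUDIT)

    def test_reference_quarter_actions(self, reference_csvs):
        actions, report = read_actions(reference_csvs["actions"])
        assert len(actions) == 3
        assert sum(a.sustained for a in actions) == 2
        assert not report.errors


class TestRoundTrip:
    def test_events_round_trip(self, reference_quarter, tmp_path):
        events = reference_quarter[0]
        write_events(events, tmp_path / "e.csv")
        back, report = read_events(tmp_path / "e.csv", strict=True)
        assert back == events and not report.issues

    def test_exposures_round_trip(self, reference_quarter, tmp_path):
        exposures = reference_quarter[1]
        write_exposures(exposures, tmp_path / "x.csv")
        back, _ = read_exposures(tmp_path / "x.csv")
        assert back == exposures

    def test_actions_round_trip(self, reference_quarter, tmp_path):
        actions = reference_quarter[2]
        write_actions(actions, tmp_path / "a.csv")
        back, _ = read_actions(tmp_path / "a.csv")
        assert back == actions
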