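"""Seeded synthetic event, exposure, and action logs.

The generator emulates the statistical structure the analytics assume:
monthly near-miss and harm counts are Poisson with intensity
``rate/1000 × exposure``, optionally gamma-multiplied to inject
overdispersion (a negative-binomial marginal — the mechanism the Laney
adjustment exists to absorb); severities are multinomial; corrective-action
follow-through is Bernoulli at the 90- and 180-day windows. Defaults mirror
the framework's reference worked example: a hospital running ~50,000
patient-days per quarter with a true near-miss rate of 0.2 and harm rate of
1.0 per 1000 patient-days, a 30% action-implementation probability and a
2/3 sustainment probability.

:func:`worked_example` returns that reference quarter itself as a fully
deterministic fixture.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .events import (
    HOSPITAL_WIDE,
    ActionRecord,
    DenominatorType,
    DetectionMode,
    EventType,
    ExposurePeriod,
    SafetyEvent,
    SeverityClass,
    SustainmentEvidence,
    UnitDomain,
)

_SEVERITIES = [SeverityClass.MINOR, SeverityClass.MODERATE,
               SeverityClass.MAJOR, SeverityClass.CATASTROPHIC]
_DETECTIONS = [DetectionMode.HUMAN, DetectionMode.ALARM,
               DetectionMode.PATIENT, DetectionMode.CHANCE]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic hospital.

    ``dispersion`` is the squared coefficient of variation of the latent
    monthly rate: 0 gives pure Poisson counts; 1.0 roughly doubles the
    variance-to-mean ratio at these intensities.
    """

    months: int = 36
    #: scalar → hospital-wide patient-days; mapping of unit-domain code →
    #: monthly exposure → one stratified series per domain with its
    #: conventional denominator type.
    exposure_per_month: Union[float, Mapping[str, float]] = 16_667.0  # ≈ 50,000/quarter
    true_nm_rate: float = 0.2             # per 1000 exposure units
    true_harm_rate: float = 1.0
    dispersion: float = 0.0
    severity_mix: tuple[float, float, float, float] = (0.5, 0.3, 0.1, 0.1)
    p_action_90: float = 0.3
    p_sustain_180: float = 2 / 3
    start: str = "2025-01"                # first month, YYYY-MM
    unit_domain: UnitDomain = UnitDomain.WARD
    seed: int = 0

    def validate(self) -> None:
        if self.months < 1:
            raise ValueError("months must be ≥ 1")
        values = (self.exposure_per_month.values()
                  if isinstance(self.exposure_per_month, Mapping)
                  else [self.exposure_per_month])
        if not values or any(v <= 0 for v in values):
            raise ValueError("exposure_per_month must be positive")
        if self.true_nm_rate < 0 or self.true_harm_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if len(self.severity_mix) != 4 or any(p < 0 for p in self.severity_mix):
            raise ValueError("severity_mix must be 4 nonnegative probabilities")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")
        for p in (self.p_action_90, self.p_sustain_180):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _month_starts(start: str, months: int) -> list[_dt.date]:
    y, m = (int(p) for p in start.split("-"))
    out = []
    for _ in range(months):
        out.append(_dt.date(y, m, 1))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


#: Conventional denominator type per stratified domain; everything else
#: (ICU, wards, ED) is measured in patient-days.
_DOMAIN_DENOMINATOR = {
    UnitDomain.PHARMACY.value: DenominatorType.DOSES,
    UnitDomain.LABORATORY.value: DenominatorType.SPECIMENS,
    UnitDomain.TRANSFUSION.value: DenominatorType.UNITS,
    UnitDomain.OPERATING_ROOM.value: DenominatorType.PROCEDURES,
}


def generate(config: SimulationConfig
             ) -> tuple[list[SafetyEvent], list[ExposurePeriod], list[ActionRecord]]:
    """Draw a full (events, exposures, actions) triple, reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    if isinstance(config.exposure_per_month, Mapping):
        strata = [(dom, UnitDomain(dom),
                   _DOMAIN_DENOMINATOR.get(dom, DenominatorType.PATIENT_DAYS), v)
                  for dom, v in config.exposure_per_month.items()]
    else:
        strata = [(HOSPITAL_WIDE, config.unit_domain,
                   DenominatorType.PATIENT_DAYS, config.exposure_per_month)]

    events: list[SafetyEvent] = []
    exposures: list[ExposurePeriod] = []
    actions: list[ActionRecord] = []
    eid = aid = 0

    for first in _month_starts(config.start, config.months):
        label = f"{first.year:04d}-{first.month:02d}"
        ndays = calendar.monthrange(first.year, first.month)[1]
        for scope, domain, denom_type, exposure in strata:
            exposures.append(ExposurePeriod(label, scope, denom_type, exposure))

            def intensity(rate_per_1000: float) -> float:
                lam = rate_per_1000 / 1000.0 * exposure
                if config.dispersion > 0 and lam > 0:
                    shape = 1.0 / config.dispersion
                    lam *= rng.gamma(shape, 1.0 / shape)
                return lam

            n_nm = rng.poisson(intensity(config.true_nm_rate))
            n_harm = rng.poisson(intensity(config.true_harm_rate))

            for kind, n in ((EventType.NEAR_MISS, n_nm),
                            (EventType.HARMFUL_INCIDENT, n_harm)):
                days = rng.integers(0, ndays, size=n)
                detections = rng.integers(0, len(_DETECTIONS), size=n)
                sev_idx = rng.choice(4, size=n, p=list(config.severity_mix))
                for j in range(n):
                    eid += 1
                    date = first + _dt.timedelta(days=int(days[j]))
                    severity = (_SEVERITIES[sev_idx[j]]
                                if kind is EventType.NEAR_MISS else None)
                    ev = SafetyEvent(f"e{eid:06d}", date, kind,
                                     reached_patient=(kind is not EventType.NEAR_MISS),
                                     detection_mode=_DETECTIONS[detections[j]],
                                     unit_domain=domain,
                                     severity_class=severity)
                    events.append(ev)
                    if kind is EventType.NEAR_MISS and rng.random() < config.p_action_90:
                        aid += 1
                        implemented = date + _dt.timedelta(days=int(rng.integers(1, 91)))
                        if rng.random() < config.p_sustain_180:
                            verified = implemented + _dt.timedelta(
                                days=180 + int(rng.integers(0, 15)))
                            evidence = SustainmentEvidence.AUDIT
                        else:
                            verified, evidence = None, SustainmentEvidence.NONE
                        actions.append(ActionRecord(f"a{aid:05d}", ev.event_id, date,
                                                    implemented, verified, evidence))

    return events, exposures, actions


def worked_example() -> tuple[list[SafetyEvent], list[ExposurePeriod], list[ActionRecord]]:
    """The framework's reference quarter, fully deterministic.

    One quarter (2025-Q1) of 50,000 patient-days with 50 harmful incidents
    and 10 near misses distributed 5 minor / 3 moderate / 1 major /
    1 catastrophic; 3 corrective actions implemented within 90 days of
    reporting, 2 of them sustained (audit-verified) at the 180-day mark.
    The resulting metrics: near-miss rate 0.2 and harm rate 1.0 per 1000
    patient-days, ratio 0.2:1, NMI 19, learning yields 3/10 and 2/3.
    """
    exposures = [ExposurePeriod("2025-Q1", HOSPITAL_WIDE,
                                DenominatorType.PATIENT_DAYS, 50_000.0)]
    events: list[SafetyEvent] = []

    # 10 near misses, severity assigned positionally: 5 minor, 3 moderate,
    # 1 major, 1 catastrophic; dates spaced a week apart through the quarter.
    tally = ([SeverityClass.MINOR] * 5 + [SeverityClass.MODERATE] * 3
             + [SeverityClass.MAJOR] + [SeverityClass.CATASTROPHIC])
    for i, severity in enumerate(tally):
        events.append(SafetyEvent(
            f"nm{i + 1:02d}", _dt.date(2025, 1, 6) + _dt.timedelta(weeks=i),
            EventType.NEAR_MISS, reached_patient=False,
            detection_mode=_DETECTIONS[i % 4],
            unit_domain=UnitDomain.WARD, severity_class=severity))

    for i in range(50):
        events.append(SafetyEvent(
            f"h{i + 1:02d}", _dt.date(2025, 1, 2) + _dt.timedelta(days=(i * 7) % 89),
            EventType.HARMFUL_INCIDENT, reached_patient=True,
            detection_mode=_DETECTIONS[i % 4],
            unit_domain=UnitDomain.WARD, severity_class=None))

    # 3 actions implemented within 90 days of reporting; 2 sustained with
    # audit evidence at/after day 180.
    actions = []
    for i, (nm_idx, sustained) in enumerate([(0, True), (5, True), (1, False)]):
        ev = events[nm_idx]
        implemented = ev.event_date + _dt.timedelta(days=60)
        verified = implemented + _dt.timedelta(days=182) if sustained else None
        evidence = SustainmentEvidence.AUDIT if sustained else SustainmentEvidence.NONE
        actions.append(ActionRecord(f"a{i + 1:02d}", ev.event_id, ev.event_date,
                                    implemented, verified, evidence))

    return events, exposures, actions
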