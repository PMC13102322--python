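"""Standardized near-miss rates and the near-miss-to-harm ratio.

Raw event counts are confounded by patient volume; the framework therefore
expresses them as rates per a scaling constant of exposure units — near
misses per 1000 patient-days hospital-wide, per 10,000 doses in pharmacy,
per 1000 specimens in the laboratory, and so on. Where monthly denominators
are too small for stable charting, series are aggregated to calendar
quarters with numerators and denominators summed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional

import pandas as pd

from ._markers import UNDEFINED
from .events import (
    HOSPITAL_WIDE,
    DenominatorType,
    EventType,
    ExposurePeriod,
    SafetyEvent,
)
from .periods import is_month, is_quarter, month_of, quarter_of, sort_key

#: Default smallest per-period denominator considered stable for monthly
#: charting; below it the series is re-binned by quarter. A tunable, not a
#: published constant.
DEFAULT_STABILITY_THRESHOLD = 500.0


class MissingDenominatorError(ValueError):
    """An event falls in a period with no exposure record."""


@dataclass(frozen=True)
class RateEntry:
    period_id: str
    numerator: int
    denominator: float
    rate: float  # events per scaling_constant exposure units


@dataclass
class RateSeries:
    """An ordered per-period rate table for one scope."""

    entries: list[RateEntry]
    scaling_constant: int
    unit_domain: str = HOSPITAL_WIDE
    denominator_type: DenominatorType = DenominatorType.PATIENT_DAYS
    label: str = "near_miss"

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: sort_key(e.period_id))

    @property
    def periods(self) -> list[str]:
        return [e.period_id for e in self.entries]

    @property
    def numerators(self) -> list[int]:
        return [e.numerator for e in self.entries]

    @property
    def denominators(self) -> list[float]:
        return [e.denominator for e in self.entries]

    @property
    def rates(self) -> list[float]:
        return [e.rate for e in self.entries]

    def is_monthly(self) -> bool:
        return all(is_month(p) for p in self.periods)

    def is_quarterly(self) -> bool:
        return all(is_quarter(p) for p in self.periods)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "period_id": self.periods,
            "scope": self.unit_domain,
            "numerator": self.numerators,
            "denominator": self.denominators,
            "scaling_constant": self.scaling_constant,
            "rate": self.rates,
        })


def near_miss_rate(count: int, exposure: float, scaling_constant: int = 1000) -> float:
    """Events per ``scaling_constant`` exposure units: (count ÷ exposure) × k."""
    if exposure <= 0:
        raise ValueError(f"exposure must be positive, got {exposure}")
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    return (count / exposure) * scaling_constant


def nm_to_harm_ratio(near_miss_count: int, harm_count: int):
    """Reported near misses per reported harm event.

    Returns :data:`~nm3._markers.UNDEFINED` when there are no harm events;
    a ratio far below 1 reflects the usual underreporting of near misses.
    """
    if near_miss_count < 0 or harm_count < 0:
        raise ValueError("counts must be nonnegative")
    if harm_count == 0:
        return UNDEFINED
    return near_miss_count / harm_count


def _default_filter(event: SafetyEvent) -> bool:
    return event.event_type is EventType.NEAR_MISS


def build_rate_series(
    events: Iterable[SafetyEvent],
    exposures: Iterable[ExposurePeriod],
    scope: str = HOSPITAL_WIDE,
    event_filter: Optional[Callable[[SafetyEvent], bool]] = None,
    label: str = "near_miss",
) -> RateSeries:
    """Count filtered events per exposure period and standardize to a rate.

    ``scope`` selects both the exposure records (by their ``unit_domain``)
    and, for unit scopes, the events; ``hospital_wide`` uses all events
    against hospital-wide denominators. Periods with exposure but no events
    get numerator 0; an event in a period lacking an exposure record raises
    :class:`MissingDenominatorError`.
    """
    event_filter = event_filter or _default_filter
    scoped_exp = [x for x in exposures if x.unit_domain == scope]
    if not scoped_exp:
        raise MissingDenominatorError(f"no exposure records for scope {scope!r}")
    scales = {x.scaling_constant for x in scoped_exp}
    dtypes = {x.denominator_type for x in scoped_exp}
    if len(scales) > 1 or len(dtypes) > 1:
        raise ValueError(
            f"scope {scope!r} mixes denominator types/scaling constants")
    monthly = all(is_month(x.period_id) for x in scoped_exp)

    counts: dict[str, int] = {x.period_id: 0 for x in scoped_exp}
    for ev in events:
        if scope != HOSPITAL_WIDE and ev.unit_domain.value != scope:
            continue
        if not event_filter(ev):
            continue
        pid = month_of(ev.event_date) if monthly else quarter_of(ev.event_date)
        if pid not in counts:
            raise MissingDenominatorError(
                f"event {ev.event_id} falls in period {pid} with no exposure "
                f"record for scope {scope!r}")
        counts[pid] += 1

    scaling = scales.pop()
    entries = [
        RateEntry(x.period_id, counts[x.period_id], x.exposure_count,
                  near_miss_rate(counts[x.period_id], x.exposure_count, scaling))
        for x in scoped_exp
    ]
    return RateSeries(entries, scaling, scope, dtypes.pop(), label)


def aggregate_to_quarters(
    series: RateSeries,
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
) -> RateSeries:
    """Re-bin a monthly series by calendar quarter when any monthly
    denominator falls below ``stability_threshold``.

    Aggregation is all-or-nothing: either every month is re-binned (keeping
    the chart's periods homogeneous) or the series is returned unchanged.
    Total numerator and denominator are conserved exactly.
    """
    if not series.is_monthly():
        if series.is_quarterly():
            raise ValueError("series is already quarterly")
        raise ValueError("series mixes monthly and quarterly periods")
    if all(e.denominator >= stability_threshold for e in series.entries):
        return series

    binned: dict[str, list[RateEntry]] = {}
    for e in series.entries:
        binned.setdefault(quarter_of(e.period_id), []).append(e)
    entries = []
    for q, members in binned.items():
        num = sum(m.numerator for m in members)
        den = sum(m.denominator for m in members)
        entries.append(RateEntry(q, num, den,
                                 near_miss_rate(num, den, series.scaling_constant)))
    return replace(series, entries=entries)


def write_rate_table(series: RateSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)
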