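"""Learning-yield metrics: is reporting actually producing change?

Two process metrics quantify the organizational learning loop:

* **90-day yield** — the proportion of near misses that generate at least
  one corrective action implemented within 90 days of reporting
  (responsiveness; a near miss with several actions counts once).
* **180-day yield** — the proportion of implemented actions whose
  sustainment is verified at the 180-day mark by objective evidence
  (embedding; denominator is implemented actions, not events).

Both are process metrics: they measure timeliness and persistence of the
response, not whether the actions reduced harm.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass
from typing import Iterable, Optional

from ._markers import UNDEFINED
from .events import ActionRecord, EventType, SafetyEvent

IMPLEMENTATION_WINDOW_DAYS = 90
SUSTAINMENT_WINDOW_DAYS = 180


class YieldWindow(str, enum.Enum):
    DAY_90 = "day_90"
    DAY_180 = "day_180"


@dataclass(frozen=True)
class LearningYield:
    window_label: YieldWindow
    numerator: int
    denominator: int
    provisional: bool = False  # as_of precedes window closure for some records

    @property
    def value(self):
        if self.denominator == 0:
            return UNDEFINED
        return self.numerator / self.denominator

    def to_record(self, scope: str = "") -> dict:
        v = self.value
        return {
            "scope": scope,
            "window": self.window_label.value,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "value": (v if v is not UNDEFINED else ""),
            "provisional": self.provisional,
        }


def learning_yield_90(
    events: Iterable[SafetyEvent],
    actions: Iterable[ActionRecord],
    as_of: Optional[_dt.date] = None,
) -> LearningYield:
    """Near misses with an action implemented within 90 days of reporting,
    over all near misses in scope.

    The clock starts at the action's ``report_date`` (the event's report).
    The result is flagged provisional when ``as_of`` does not yet cover the
    90-day window of every report.
    """
    near_misses = [e for e in events if e.event_type is EventType.NEAR_MISS]
    actions = list(actions)
    nm_ids = {e.event_id for e in near_misses}

    responded: set[str] = set()
    latest_report: Optional[_dt.date] = None
    for a in actions:
        if a.event_id not in nm_ids:
            continue
        latest_report = max(latest_report or a.report_date, a.report_date)
        if (a.implemented_within is not None
                and a.implemented_within <= IMPLEMENTATION_WINDOW_DAYS):
            responded.add(a.event_id)

    provisional = (
        as_of is not None
        and latest_report is not None
        and as_of < latest_report + _dt.timedelta(days=IMPLEMENTATION_WINDOW_DAYS)
    )
    return LearningYield(YieldWindow.DAY_90, len(responded), len(near_misses),
                         provisional)


def learning_yield_180(
    actions: Iterable[ActionRecord],
    as_of: Optional[_dt.date] = None,
) -> LearningYield:
    """Implemented actions with verified sustainment, over implemented actions.

    Sustainment requires objective evidence (audit or performance data) at
    the 180-day mark; see :attr:`nm3.events.ActionRecord.sustained`.
    """
    implemented = [a for a in actions if a.implemented_date is not None]
    sustained = [a for a in implemented if a.sustained]

    provisional = as_of is not None and any(
        as_of < a.implemented_date + _dt.timedelta(days=SUSTAINMENT_WINDOW_DAYS)
        for a in implemented
    )
    return LearningYield(YieldWindow.DAY_180, len(sustained), len(implemented),
                         provisional)
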