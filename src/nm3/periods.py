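"""Reporting-period labels.

Periods are calendar months labelled ``YYYY-MM`` or calendar quarters
labelled ``YYYY-Qn``; both sort lexicographically within their own kind.
pandas ``Period`` objects do the calendar arithmetic underneath.
"""

from __future__ import annotations

import datetime as _dt
import re

import pandas as pd

_MONTH_RE = re.compile(r"^(\d{4})-(0[1-9]|1[0-2])$")
_QUARTER_RE = re.compile(r"^(\d{4})-Q([1-4])$")


class PeriodFormatError(ValueError):
    """Raised for a label that is neither ``YYYY-MM`` nor ``YYYY-Qn``."""


def is_month(label: str) -> bool:
    return bool(_MONTH_RE.match(label))


def is_quarter(label: str) -> bool:
    return bool(_QUARTER_RE.match(label))


def parse_period(label: str) -> pd.Period:
    if is_month(label):
        return pd.Period(label, freq="M")
    m = _QUARTER_RE.match(label)
    if m:
        return pd.Period(f"{m.group(1)}Q{m.group(2)}", freq="Q")
    raise PeriodFormatError(
        f"period label {label!r} is neither 'YYYY-MM' nor 'YYYY-Qn'"
    )


def format_period(period: pd.Period) -> str:
    if period.freqstr.startswith("M"):
        return f"{period.year:04d}-{period.month:02d}"
    if period.freqstr.startswith("Q"):
        return f"{period.year:04d}-Q{period.quarter}"
    raise PeriodFormatError(f"unsupported period frequency {period.freqstr!r}")


def month_of(date: _dt.date) -> str:
    """Calendar-month label an event dated ``date`` belongs to."""
    return f"{date.year:04d}-{date.month:02d}"


def quarter_of(label_or_date) -> str:
    """Quarter label containing a month label or a date."""
    if isinstance(label_or_date, _dt.date):
        q = (label_or_date.month - 1) // 3 + 1
        return f"{label_or_date.year:04d}-Q{q}"
    p = parse_period(label_or_date)
    if p.freqstr.startswith("Q"):
        return format_period(p)
    return f"{p.year:04d}-Q{p.quarter}"


def sort_key(label: str) -> pd.Period:
    return parse_period(label)
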