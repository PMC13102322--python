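"""Leadership interpretation matrix for near-miss trend patterns.

A rise in reported near misses is ambiguous: it can mean better interception,
better detection, an improving reporting culture under system strain — or
nothing at all. The interpretation matrix resolves the joint movement of
three series (near-miss rate, harm rate, overall reporting volume) plus the
presence of special-cause SPC signals into one of five named patterns, each
carrying the diagnostic checks, hedged interpretation, and leadership action
the framework prescribes. Classification is a pure function of the four
inputs, with an explicit precedence order so overlapping patterns resolve
deterministically — the riskiest misread (reporting disengagement
masquerading as improvement) is checked first.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rates import RateSeries


class Trend(str, enum.Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    FLAT = "flat"


class PatternId(str, enum.Enum):
    INTERCEPTION_IMPROVED = "interception_improved"
    DETECTION_IMPROVED = "detection_improved"
    CULTURE_PLUS_STRAIN = "culture_plus_strain"
    DISENGAGEMENT_RISK = "disengagement_risk"
    EQUILIBRIUM = "equilibrium"
    UNCLASSIFIED = "unclassified"


#: Row templates of the interpretation matrix: diagnostics, interpretation,
#: recommended leadership action.
PATTERN_TEXTS: dict[PatternId, dict[str, str]] = {
    PatternId.INTERCEPTION_IMPROVED: {
        "observed": "Increasing near misses while harm decreases or remains flat",
        "diagnostics": "Stability of denominators and SPC signals",
        "interpretation": "Interception and reporting culture have improved",
        "action": "Reinforce effective defenses and promote open reporting",
    },
    PatternId.DETECTION_IMPROVED: {
        "observed": "Increasing near misses while overall reporting remains stable",
        "diagnostics": "Clustering in specific domains and detection processes "
                       "in those areas",
        "interpretation": "Detection has improved in selected domains",
        "action": "Investigate process precursors and address system "
                  "vulnerabilities",
    },
    PatternId.CULTURE_PLUS_STRAIN: {
        "observed": "Both near misses and overall reports increase",
        "diagnostics": "Harm rates, exposure changes, system vulnerabilities, "
                       "and SPC variation",
        "interpretation": "Reporting culture is improving, but system stress "
                          "may be rising",
        "action": "Review high-consequence clusters using the Near Miss Index, "
                  "apply corrective actions, and monitor sustainment",
    },
    PatternId.DISENGAGEMENT_RISK: {
        "observed": "Both near misses and harm decrease",
        "diagnostics": "Culture survey trends, reporting volume, and staff "
                       "engagement data",
        "interpretation": "Reporting fatigue or disengagement rather than true "
                          "safety improvement",
        "action": "Conduct targeted culture assessment, reinforce nonpunitive "
                  "reporting, and verify harm data completeness",
    },
    PatternId.EQUILIBRIUM: {
        "observed": "Both near misses and harm remain flat (no SPC signals)",
        "diagnostics": "Denominator stability, process changes, and culture "
                       "survey trends",
        "interpretation": "The system is at equilibrium, or surveillance "
                          "sensitivity has plateaued",
        "action": "Conduct periodic review of detection processes and consider "
                  "proactive audits to test reporting sensitivity",
    },
    PatternId.UNCLASSIFIED: {
        "observed": "Pattern outside the interpretation matrix",
        "diagnostics": "Review all indicators: denominators, SPC variation, "
                       "harm rates, reporting volume, and culture scores",
        "interpretation": "No matrix row matches this combination of trends",
        "action": "Escalate for case-by-case review with full triangulation data",
    },
}

#: Default fraction of the series center the fitted drift must exceed over
#: the window for a slope to be declared a trend rather than flat.
DEFAULT_FLAT_EPSILON = 0.10


class InsufficientDataError(ValueError):
    pass


@dataclass
class TrendAssessment:
    pattern_id: PatternId
    nm_trend: Trend
    harm_trend: Trend
    reporting_trend: Trend
    spc_signal_present: bool
    diagnostics: list[str] = field(default_factory=list)
    interpretation_text: str = ""
    action_text: str = ""
    precedence_trace: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "inputs": {
                "nm_trend": self.nm_trend.value,
                "harm_trend": self.harm_trend.value,
                "reporting_trend": self.reporting_trend.value,
                "spc_signal_present": self.spc_signal_present,
            },
            "pattern_id": self.pattern_id.value,
            "diagnostics": self.diagnostics,
            "interpretation_text": self.interpretation_text,
            "action_text": self.action_text,
            "precedence_trace": self.precedence_trace,
        }


def trend_direction(series, epsilon: float = DEFAULT_FLAT_EPSILON,
                    min_periods: int = 4) -> Trend:
    """Label a rate or count series increasing / decreasing / flat.

    Fits a least-squares slope against the period index and declares the
    series flat when the total fitted drift over the window, |slope| × length,
    is below ``epsilon`` × the series mean. Requires ≥ ``min_periods``
    periods — trend talk on shorter windows is noise.
    """
    values = np.asarray(series.rates if isinstance(series, RateSeries) else series,
                        dtype=float)
    if len(values) < min_periods:
        raise InsufficientDataError(
            f"need at least {min_periods} periods for a trend, got {len(values)}")
    slope = np.polyfit(np.arange(len(values)), values, 1)[0]
    center = float(np.mean(values))
    if abs(slope) * len(values) < epsilon * abs(center):
        return Trend.FLAT
    if slope > 0:
        return Trend.INCREASING
    if slope < 0:
        return Trend.DECREASING
    return Trend.FLAT


def _assessment(pattern: PatternId, nm: Trend, harm: Trend, rep: Trend,
                signal: bool, trace: list[str],
                extra_diagnostics: Sequence[str] = ()) -> TrendAssessment:
    texts = PATTERN_TEXTS[pattern]
    diagnostics = [texts["diagnostics"], *extra_diagnostics]
    return TrendAssessment(
        pattern_id=pattern,
        nm_trend=nm, harm_trend=harm, reporting_trend=rep,
        spc_signal_present=signal,
        diagnostics=diagnostics,
        interpretation_text=texts["interpretation"],
        action_text=texts["action"],
        precedence_trace=trace,
    )


def classify_pattern(nm_trend: Trend, harm_trend: Trend, reporting_trend: Trend,
                     spc_signal_present: bool) -> TrendAssessment:
    """Map the four triangulation inputs to a matrix pattern.

    Precedence (first match wins):

    1. disengagement_risk — near misses and harm both decreasing; the
       riskiest misread, checked before anything that could look benign.
    2. equilibrium — near misses and harm both flat with no SPC signal.
    3. culture_plus_strain — near misses and overall reporting both
       increasing (harm not increasing).
    4. interception_improved — near misses increasing, harm not increasing.
    5. detection_improved — near misses increasing, reporting flat.
    6. unclassified — anything else; near misses and harm both rising is
       deliberately not given a named interpretation and carries an
       "investigate harm rise" diagnostic instead.
    """
    nm, harm, rep = Trend(nm_trend), Trend(harm_trend), Trend(reporting_trend)
    signal = bool(spc_signal_present)
    trace: list[str] = []
    harm_rising = harm is Trend.INCREASING
    extra = ["investigate harm rise"] if harm_rising else []

    trace.append("disengagement_risk: nm decreasing and harm decreasing?")
    if nm is Trend.DECREASING and harm is Trend.DECREASING:
        return _assessment(PatternId.DISENGAGEMENT_RISK, nm, harm, rep, signal, trace)

    trace.append("equilibrium: nm flat, harm flat, no SPC signal?")
    if nm is Trend.FLAT and harm is Trend.FLAT and not signal:
        return _assessment(PatternId.EQUILIBRIUM, nm, harm, rep, signal, trace)

    trace.append("culture_plus_strain: nm increasing and reporting increasing?")
    if (nm is Trend.INCREASING and rep is Trend.INCREASING and not harm_rising):
        return _assessment(PatternId.CULTURE_PLUS_STRAIN, nm, harm, rep, signal, trace)

    trace.append("interception_improved: nm increasing, harm not increasing?")
    if nm is Trend.INCREASING and not harm_rising:
        return _assessment(PatternId.INTERCEPTION_IMPROVED, nm, harm, rep,
                           signal, trace)

    trace.append("detection_improved: nm increasing, reporting flat?")
    if nm is Trend.INCREASING and rep is Trend.FLAT:
        return _assessment(PatternId.DETECTION_IMPROVED, nm, harm, rep, signal,
                           trace, extra)

    trace.append("unclassified: no matrix row matched")
    return _assessment(PatternId.UNCLASSIFIED, nm, harm, rep, signal, trace, extra)
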