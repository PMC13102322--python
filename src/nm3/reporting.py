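"""Governance outputs: the three maturity-level report sets.

* Level 1 — a monthly organizational dashboard: hospital-wide near-miss and
  harm rates, the near-miss-to-harm ratio, and an SPC chart (u-chart, or
  Laney U′ when overdispersed) with special-cause signals.
* Level 2 — unit trend cards: one rate series and chart per unit/domain with
  its conventional denominator, quarterly-aggregated when monthly
  denominators are unstable. Cards are interpreted longitudinally, never as
  a cross-unit league table.
* Level 3 — a quarterly prioritization brief: severity-weighted Near Miss
  Index per quarter, 90- and 180-day learning yields, trend inputs and the
  classified interpretation-matrix pattern.

Levels are cumulative (a maturity pathway): level 3 runs 1 and 2 first.
Every run writes a machine-readable ``run_log.json``; wall-clock timestamps
are isolated to ``run_meta.json`` so report artifacts are byte-deterministic.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from ._markers import UNDEFINED
from .events import (
    HOSPITAL_WIDE,
    ActionRecord,
    EventType,
    ExposurePeriod,
    SafetyEvent,
    ValidationReport,
    read_actions,
    read_events,
    read_exposures,
)
from .interpret import (
    InsufficientDataError as TrendDataError,
    TrendAssessment,
    classify_pattern,
    trend_direction,
)
from .learning import LearningYield, learning_yield_90, learning_yield_180
from .periods import quarter_of, sort_key
from .rates import (
    DEFAULT_STABILITY_THRESHOLD,
    MissingDenominatorError,
    RateSeries,
    aggregate_to_quarters,
    build_rate_series,
    nm_to_harm_ratio,
)
from .severity import DEFAULT_WEIGHTS, NearMissIndex, SeverityWeights, compute_nmi
from .spc import (
    DEFAULT_SIGMA_Z_THRESHOLD,
    ControlChart,
    InsufficientDataError as ChartDataError,
    RuleId,
    select_chart,
    write_chart_table,
)

EXIT_OK = 0
EXIT_VALIDATION = 1
EXIT_INSUFFICIENT = 2


@dataclass
class RunConfig:
    events_path: Path
    exposures_path: Path
    actions_path: Optional[Path] = None
    level: int = 1
    out_dir: Path = Path("nm3_out")
    sigma_z_threshold: float = DEFAULT_SIGMA_Z_THRESHOLD
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD
    weights: SeverityWeights = DEFAULT_WEIGHTS
    flat_epsilon: float = 0.10
    as_of: Optional[_dt.date] = None
    strict: bool = False
    plots: bool = False


def _jsonable(value):
    if value is UNDEFINED:
        return None
    if isinstance(value, float):
        return value
    return value


@dataclass
class Level1Result:
    nm_series: RateSeries
    harm_series: RateSeries
    reporting_counts: list[int]  # all reported events per period
    ratios: list  # per period, number or UNDEFINED
    chart: Optional[ControlChart]
    gaps: list[str] = field(default_factory=list)

    def dashboard_frame(self) -> pd.DataFrame:
        flagged = ({p for p, r in self.chart.signals if r is RuleId.RULE_1}
                   if self.chart else set())
        return pd.DataFrame({
            "period_id": self.nm_series.periods,
            "near_miss_count": self.nm_series.numerators,
            "harm_count": self.harm_series.numerators,
            "reports_total": self.reporting_counts,
            "denominator": self.nm_series.denominators,
            "near_miss_rate": self.nm_series.rates,
            "harm_rate": self.harm_series.rates,
            "nm_to_harm_ratio": [_jsonable(r) for r in self.ratios],
            "spc_signal": [p in flagged for p in self.nm_series.periods],
        })


def level1_dashboard(events: list[SafetyEvent], exposures: list[ExposurePeriod],
                     sigma_z_threshold: float = DEFAULT_SIGMA_Z_THRESHOLD) -> Level1Result:
    """Hospital-wide rates, ratios, and the selected SPC chart."""
    nm = build_rate_series(events, exposures, HOSPITAL_WIDE,
                           lambda e: e.event_type is EventType.NEAR_MISS,
                           label="near_miss")
    harm = build_rate_series(events, exposures, HOSPITAL_WIDE,
                             lambda e: e.event_type is EventType.HARMFUL_INCIDENT,
                             label="harm")
    reporting = build_rate_series(events, exposures, HOSPITAL_WIDE,
                                  lambda e: True, label="reports")
    ratios = [nm_to_harm_ratio(c_nm, c_h)
              for c_nm, c_h in zip(nm.numerators, harm.numerators)]
    gaps: list[str] = []
    chart = None
    try:
        chart = select_chart(nm.numerators, nm.denominators,
                             sigma_z_threshold, period_ids=nm.periods)
    except ChartDataError as exc:
        gaps.append(f"SPC chart unavailable: {exc}")
    return Level1Result(nm, harm, reporting.numerators, ratios, chart, gaps)


@dataclass
class UnitCard:
    unit_domain: str
    series: RateSeries
    aggregated: bool
    chart: Optional[ControlChart]
    gaps: list[str] = field(default_factory=list)


@dataclass
class Level2Result:
    cards: dict[str, UnitCard]
    errors: list[str] = field(default_factory=list)


def level2_cards(events: list[SafetyEvent], exposures: list[ExposurePeriod],
                 stability_threshold: float = DEFAULT_STABILITY_THRESHOLD,
                 sigma_z_threshold: float = DEFAULT_SIGMA_Z_THRESHOLD) -> Level2Result:
    """One near-miss trend card per unit/domain with exposure records."""
    domains_with_exposure = sorted({x.unit_domain for x in exposures}
                                   - {HOSPITAL_WIDE})
    domains_with_events = {e.unit_domain.value for e in events
                           if e.event_type is EventType.NEAR_MISS}
    result = Level2Result(cards={})
    for dom in sorted(domains_with_events - set(domains_with_exposure)):
        result.errors.append(
            f"domain {dom!r} has near-miss events but no exposure records; skipped")

    for dom in domains_with_exposure:
        series = build_rate_series(events, exposures, dom)
        aggregated = False
        if series.is_monthly():
            agg = aggregate_to_quarters(series, stability_threshold)
            aggregated = agg is not series
            series = agg
        card = UnitCard(dom, series, aggregated, chart=None)
        try:
            card.chart = select_chart(series.numerators, series.denominators,
                                      sigma_z_threshold, period_ids=series.periods)
        except ChartDataError as exc:
            card.gaps.append(f"SPC chart unavailable: {exc}")
        result.cards[dom] = card
    return result


@dataclass
class Level3Result:
    nmi_by_quarter: list[NearMissIndex]
    nmi_total: NearMissIndex
    yield_90: Optional[LearningYield]
    yield_180: Optional[LearningYield]
    assessment: Optional[TrendAssessment]
    gaps: list[str] = field(default_factory=list)

    def brief_dict(self) -> dict:
        def yield_rec(y: Optional[LearningYield]) -> Optional[dict]:
            if y is None:
                return None
            return {"numerator": y.numerator, "denominator": y.denominator,
                    "value": _jsonable(y.value), "provisional": y.provisional}

        return {
            "near_miss_index": {
                "total": self.nmi_total.value,
                "unscored_near_misses": self.nmi_total.unscored_count,
                "weights": self.nmi_total.weights_used.as_dict(),
                "by_quarter": [
                    {"period_id": q.period_id, "value": q.value,
                     "counts_by_class": {s.value: c for s, c in
                                         q.counts_by_class.items()},
                     "unscored": q.unscored_count}
                    for q in self.nmi_by_quarter
                ],
            },
            "learning_yield_90": yield_rec(self.yield_90),
            "learning_yield_180": yield_rec(self.yield_180),
            "pattern": self.assessment.to_dict() if self.assessment else None,
            "gaps": self.gaps,
        }


def level3_brief(events: list[SafetyEvent], exposures: list[ExposurePeriod],
                 actions: Optional[list[ActionRecord]],
                 weights: SeverityWeights = DEFAULT_WEIGHTS,
                 level1: Optional[Level1Result] = None,
                 flat_epsilon: float = 0.10,
                 as_of: Optional[_dt.date] = None) -> Level3Result:
    """Quarterly NMI, learning yields, and the classified trend pattern."""
    gaps: list[str] = []
    near_misses = [e for e in events if e.event_type is EventType.NEAR_MISS]

    by_quarter: dict[str, list[SafetyEvent]] = {}
    for e in near_misses:
        by_quarter.setdefault(quarter_of(e.event_date), []).append(e)
    nmi_by_quarter = [compute_nmi(evs, weights, period_id=q)
                      for q, evs in sorted(by_quarter.items(),
                                           key=lambda kv: sort_key(kv[0]))]
    nmi_total = compute_nmi(near_misses, weights, period_id="all")
    if nmi_total.unscored_count:
        gaps.append(f"{nmi_total.unscored_count} near miss(es) lack a severity "
                    "class and are excluded from the index")

    if actions is None:
        y90 = y180 = None
        gaps.append("no actions file: learning yields unavailable")
    else:
        if as_of is None:
            dates = ([a.sustainment_verified_date or a.implemented_date
                      or a.report_date for a in actions]
                     + [e.event_date for e in events])
            as_of = max(dates) if dates else None
        y90 = learning_yield_90(events, actions, as_of)
        y180 = learning_yield_180(actions, as_of)
        if y90.provisional or y180.provisional:
            gaps.append("learning-yield windows not yet closed at as_of; "
                        "values are provisional")

    assessment = None
    if level1 is not None:
        try:
            nm_trend = trend_direction(level1.nm_series, flat_epsilon)
            harm_trend = trend_direction(level1.harm_series, flat_epsilon)
            rep_trend = trend_direction(level1.reporting_counts, flat_epsilon)
            signal = bool(level1.chart and any(
                r is RuleId.RULE_1 for _, r in level1.chart.signals))
            assessment = classify_pattern(nm_trend, harm_trend, rep_trend, signal)
        except TrendDataError as exc:
            gaps.append(f"trend classification unavailable: {exc}")
    else:
        gaps.append("level-1 series unavailable: trend classification skipped")

    return Level3Result(nmi_by_quarter, nmi_total, y90, y180, assessment, gaps)


# ---------------------------------------------------------------------------
# File-level runner


@dataclass
class RunOutcome:
    exit_code: int
    out_dir: Path
    artifacts: list[str]
    log: dict


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run(config: RunConfig) -> RunOutcome:
    """Execute the pipeline at the configured level, writing all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    log: dict = {
        "config": {
            "level": config.level,
            "sigma_z_threshold": config.sigma_z_threshold,
            "stability_threshold": config.stability_threshold,
            "weights": config.weights.as_dict(),
            "flat_epsilon": config.flat_epsilon,
            "as_of": str(config.as_of) if config.as_of else None,
            "strict": config.strict,
        },
        "validation": {},
        "gaps": [],
    }

    def finish(code: int) -> RunOutcome:
        _dump_json(log, out / "run_log.json")
        artifacts.append("run_log.json")
        _dump_json({"written_at": _dt.datetime.now().isoformat()},
                   out / "run_meta.json")
        return RunOutcome(code, out, artifacts, log)

    def _summary(rep: ValidationReport) -> dict:
        return {"rows": rep.n_rows, "accepted": rep.n_accepted,
                "quarantined": rep.n_quarantined,
                "warnings": len(rep.warnings)}

    try:
        events, ev_report = read_events(config.events_path, strict=config.strict)
        exposures, ex_report = read_exposures(config.exposures_path,
                                              strict=config.strict)
    except (ValueError, FileNotFoundError) as exc:
        log["error"] = str(exc)
        return finish(EXIT_VALIDATION)
    log["validation"]["events"] = _summary(ev_report)
    log["validation"]["exposures"] = _summary(ex_report)

    actions = None
    if config.actions_path is not None:
        try:
            actions, ac_report = read_actions(config.actions_path, events,
                                              strict=config.strict)
        except ValueError as exc:
            log["error"] = str(exc)
            return finish(EXIT_VALIDATION)
        log["validation"]["actions"] = _summary(ac_report)

    # Level 1
    try:
        lvl1 = level1_dashboard(events, exposures, config.sigma_z_threshold)
    except MissingDenominatorError as exc:
        log["error"] = str(exc)
        return finish(EXIT_INSUFFICIENT)
    lvl1.dashboard_frame().to_csv(out / "dashboard.csv", index=False)
    artifacts.append("dashboard.csv")
    log["gaps"].extend(lvl1.gaps)
    if lvl1.chart is not None:
        charts_dir = out / "charts"
        charts_dir.mkdir(exist_ok=True)
        write_chart_table(lvl1.chart, charts_dir / "level1_near_miss.csv")
        artifacts.append("charts/level1_near_miss.csv")
        log["level1_chart"] = {
            "chart_type": lvl1.chart.chart_type.value,
            "sigma_z": lvl1.chart.sigma_z,
            "center": lvl1.chart.center_line,
            "signals": [[p, r.value] for p, r in lvl1.chart.signals],
        }
        if config.plots:
            from .spc import plot_chart
            plot_chart(lvl1.chart, charts_dir / "level1_near_miss.png",
                       "Level 1: hospital-wide near-miss rate")
            artifacts.append("charts/level1_near_miss.png")

    # Level 2
    if config.level >= 2:
        lvl2 = level2_cards(events, exposures, config.stability_threshold,
                            config.sigma_z_threshold)
        cards_dir = out / "unit_cards"
        cards_dir.mkdir(exist_ok=True)
        log["level2"] = {"domains": sorted(lvl2.cards), "errors": lvl2.errors}
        for dom, card in lvl2.cards.items():
            frame = card.series.to_frame()
            frame["aggregated_quarterly"] = card.aggregated
            if card.chart is not None:
                frame = frame.merge(
                    card.chart.to_frame()[["period_id", "center", "LCL_i",
                                           "UCL_i", "sigma_z", "chart_type",
                                           "signal"]],
                    on="period_id", how="left")
            frame.to_csv(cards_dir / f"{dom}.csv", index=False)
            artifacts.append(f"unit_cards/{dom}.csv")
            if config.plots and card.chart is not None:
                from .spc import plot_chart
                plot_chart(card.chart, cards_dir / f"{dom}.png",
                           f"Level 2: {dom} near-miss rate")
                artifacts.append(f"unit_cards/{dom}.png")
            log["gaps"].extend(f"{dom}: {g}" for g in card.gaps)

    # Level 3
    if config.level >= 3:
        lvl3 = level3_brief(events, exposures, actions, config.weights,
                            level1=lvl1, flat_epsilon=config.flat_epsilon,
                            as_of=config.as_of)
        brief = lvl3.brief_dict()
        _dump_json(brief, out / "brief.json")
        artifacts.append("brief.json")
        rows = [q for q in (x.to_record() for x in lvl3.nmi_by_quarter)]
        pd.DataFrame(rows).to_csv(out / "nmi.csv", index=False)
        artifacts.append("nmi.csv")
        yrows = [y.to_record(HOSPITAL_WIDE)
                 for y in (lvl3.yield_90, lvl3.yield_180) if y is not None]
        pd.DataFrame(yrows).to_csv(out / "learning.csv", index=False)
        artifacts.append("learning.csv")
        log["gaps"].extend(lvl3.gaps)
        if lvl3.assessment is not None:
            log["level3_pattern"] = lvl3.assessment.to_dict()

    return finish(EXIT_OK)
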