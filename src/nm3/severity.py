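"""Severity weighting and the Near Miss Index (NMI).

Each near miss is scored on a 4-point ordinal scale — minor, moderate,
major, catastrophic — representing the worst reasonable outcome had the
event not been intercepted (the consequence axis of the IHI Severity
Assessment Code matrix). The NMI for a reporting period is the
severity-weighted sum Σ(weight × count); under the default weights
(1, 2, 3, 5) a single catastrophic near miss outweighs five minor ones,
which is the point: the index elevates high-consequence signals that raw
counts dilute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._markers import UNSCORED
from .events import EventType, SafetyEvent, SeverityClass

_ORDER = [SeverityClass.MINOR, SeverityClass.MODERATE,
          SeverityClass.MAJOR, SeverityClass.CATASTROPHIC]


@dataclass(frozen=True)
class SeverityWeights:
    """Positive integer weights, strictly increasing with severity."""

    minor: int = 1
    moderate: int = 2
    major: int = 3
    catastrophic: int = 5

    def __post_init__(self) -> None:
        w = [self.minor, self.moderate, self.major, self.catastrophic]
        if any(x <= 0 for x in w):
            raise ValueError("severity weights must be positive")
        if not all(a < b for a, b in zip(w, w[1:])):
            raise ValueError(
                "weights must increase strictly minor < moderate < major "
                f"< catastrophic, got {w}")

    def __getitem__(self, severity: SeverityClass) -> int:
        return getattr(self, severity.value)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "SeverityWeights":
        return cls(**{k: int(v) for k, v in mapping.items()})

    def as_dict(self) -> dict[str, int]:
        return {s.value: self[s] for s in _ORDER}


DEFAULT_WEIGHTS = SeverityWeights()


@dataclass
class NearMissIndex:
    """A computed severity-weighted index for one scope/period."""

    value: int
    period_id: str = ""
    counts_by_class: dict[SeverityClass, int] = field(default_factory=dict)
    unscored_count: int = 0
    weights_used: SeverityWeights = DEFAULT_WEIGHTS

    def to_record(self) -> dict:
        rec = {"period_id": self.period_id}
        rec.update({f"n_{s.value}": self.counts_by_class.get(s, 0) for s in _ORDER})
        rec["n_unscored"] = self.unscored_count
        rec["weights"] = "/".join(str(self.weights_used[s]) for s in _ORDER)
        rec["nmi"] = self.value
        return rec


def score_event(event: SafetyEvent, weights: SeverityWeights = DEFAULT_WEIGHTS):
    """Weight of one event's severity class, or :data:`UNSCORED` if absent."""
    if event.severity_class is None:
        return UNSCORED
    return weights[event.severity_class]


def compute_nmi(
    events: Iterable[SafetyEvent],
    weights: SeverityWeights = DEFAULT_WEIGHTS,
    period_id: str = "",
    scope: Optional[Callable[[SafetyEvent], bool]] = None,
) -> NearMissIndex:
    """Severity-weighted index Σ(weight × count) over scored events in scope.

    The scope defaults to near misses only. Events lacking a severity class
    are excluded from the sum and tallied in ``unscored_count``.
    """
    scope = scope or (lambda e: e.event_type is EventType.NEAR_MISS)
    counts: dict[SeverityClass, int] = {s: 0 for s in _ORDER}
    unscored = 0
    for ev in events:
        if not scope(ev):
            continue
        if ev.severity_class is None:
            unscored += 1
        else:
            counts[ev.severity_class] += 1
    value = sum(weights[s] * c for s, c in counts.items())
    return NearMissIndex(value, period_id,
                         {s: c for s, c in counts.items() if c},
                         unscored, weights)


def nmi_per_exposure(index: NearMissIndex, exposure: float,
                     scaling_constant: int = 1000) -> float:
    """Optional exposure-normalized NMI (index points per 1000 patient-days)."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    return index.value / exposure * scaling_constant


def interrater_kappa(ratings_a: Sequence[str], ratings_b: Sequence[str]) -> float:
    """Cohen's kappa between two raters' severity assignments.

    Severity scoring is judgment-based; periodic agreement checks on a
    double-scored sample are the standard calibration exercise. Inputs are
    parallel sequences of severity-class codes.
    """
    from sklearn.metrics import cohen_kappa_score

    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating sequences must be the same length")
    labels = [s.value for s in _ORDER]
    return float(cohen_kappa_score(list(ratings_a), list(ratings_b), labels=labels))


def write_nmi_report(indices: Iterable[NearMissIndex], path, scope: str = "") -> None:
    rows = []
    for idx in indices:
        rec = idx.to_record()
        rec["scope"] = scope
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)
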