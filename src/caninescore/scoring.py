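"""The 1-10 Health Score: weighted sub-scores, memory risk, history smoothing.

Each behavior's ordinal category maps to a 1-10 sub-score ``x_k`` (level 0
is always 10); the base score is the weighted sum ``sum_k w_k x_k`` with the
per-behavior weights ``w_a..w_d`` normalized to 1 (defaults equal).  The
associative-memory disease risk enters as a multiplicative penalty
``base * (1 - 0.5 * risk)``; with history present, the new score is averaged
with the previous one, ``(penalized + previous) / 2``, so that under a
constant behavioral pattern the displayed score converges to that pattern's
own score.  The displayed value is clamped to [1, 10] and rounded half-up;
a (low, high) range of +/-1 around the unrounded value accompanies it.

Scores of 5 or below flag *examination required*; 6-10 is *healthy*.  The
score monitors health status, it does not diagnose disease.

Weights adapt to behavioral drift: per behavior the ratio of the sub-score
mean over all ``n`` history entries to the mean over the first ``n-1``
entries measures recent change; weights divide by the ratio and renormalize,
so behaviors whose sub-scores are worsening gain weight.

The sub-score mapping, penalty strength and smoothing are configuration, not
clinical constants; :class:`ScoreConfig` documents itself as an
interpretation and exposes every knob.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .fam import RiskDegree
from .taxonomy import BehaviorKind, CategoryProfile

__all__ = [
    "BehaviorWeights",
    "ScoreConfig",
    "ScoreHistory",
    "HealthReport",
    "HealthState",
    "sub_scores",
    "compute_score",
    "update_weights",
    "classify",
]


class HealthState:
    EXAMINATION_REQUIRED = "examination_required"
    HEALTHY = "healthy"


@dataclass(frozen=True)
class BehaviorWeights:
    """Non-negative per-behavior weights w_a..w_d (scratch, lick, swallow, sleep)."""

    scratch: float = 0.25
    lick: float = 0.25
    swallow: float = 0.25
    sleep: float = 0.25

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if min(vals) < 0:
            raise ValueError("weights must be non-negative")
        if sum(vals) <= 0:
            raise ValueError("weights must not all be zero")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.scratch, self.lick, self.swallow, self.sleep)

    def as_dict(self) -> dict[BehaviorKind, float]:
        return dict(zip(BehaviorKind, self.as_tuple()))

    @property
    def normalized(self) -> "BehaviorWeights":
        s = sum(self.as_tuple())
        return BehaviorWeights(*(w / s for w in self.as_tuple()))

    @property
    def is_normalized(self) -> bool:
        return abs(sum(self.as_tuple()) - 1.0) < 1e-9


@dataclass(frozen=True)
class ScoreConfig:
    """Declared interpretation of the scoring formula (every term separable)."""

    #: ordinal level -> 1-10 sub-score, per behavior
    subscore_map: Mapping[BehaviorKind, tuple[int, ...]] = field(
        default_factory=lambda: {
            BehaviorKind.SCRATCH: (10, 7, 4, 1),
            BehaviorKind.LICK: (10, 7, 4, 1),
            BehaviorKind.SWALLOW: (10, 5, 5),
            BehaviorKind.SLEEP: (10, 6, 2),
        }
    )
    risk_penalty: float = 0.5   # final = base * (1 - risk_penalty * risk)
    interpretation: str = (
        "weighted sub-score sum; history smoothing by two-point averaging; "
        "weight drift ratio of consecutive history means"
    )


DEFAULT_CONFIG = ScoreConfig()


def sub_scores(
    profile: CategoryProfile, config: ScoreConfig = DEFAULT_CONFIG
) -> dict[BehaviorKind, int]:
    """Map each behavior's ordinal level to its 1-10 sub-score."""
    return {
        k: config.subscore_map[k][profile.level(k)] for k in BehaviorKind
    }


@dataclass
class ScoreHistory:
    """Chronological record of sub-score vectors and computed scores."""

    entries: list[tuple[str, dict[BehaviorKind, float], float]] = field(
        default_factory=list
    )

    def append(self, x: Mapping[BehaviorKind, float], score: float,
               date: Optional[str] = None) -> None:
        if not 1 <= score <= 10:
            raise ValueError("scores must lie in [1, 10]")
        stamp = date or _dt.date.today().isoformat()
        if self.entries and stamp < self.entries[-1][0]:
            raise ValueError("history must stay chronologically ordered")
        self.entries.append((stamp, dict(x), float(score)))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def last_score(self) -> float:
        return self.entries[-1][2]


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


def classify(score: int) -> str:
    """<= 5 requires examination; >= 6 is healthy."""
    if not 1 <= score <= 10:
        raise ValueError(f"score must lie in [1, 10], got {score!r}")
    return HealthState.EXAMINATION_REQUIRED if score <= 5 else HealthState.HEALTHY


@dataclass
class HealthReport:
    score: int
    score_raw: float
    score_range: tuple[int, int]
    state: str
    sub_scores: dict[BehaviorKind, float]
    weights: BehaviorWeights
    fam_risk: Optional[RiskDegree] = None
    timestamp: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    schema_version: str = "1"

    def to_json(self, path=None) -> str:
        risk = self.fam_risk
        payload = {
            "schema_version": self.schema_version,
            "timestamp": self.timestamp,
            "score": self.score,
            "score_raw": round(self.score_raw, 4),
            "score_range": list(self.score_range),
            "state": self.state,
            "sub_scores": {k.value: v for k, v in self.sub_scores.items()},
            "weights": {k.value: v for k, v in self.weights.as_dict().items()},
            "fam_risk": None if risk is None else {
                "value": round(risk.value, 4),
                "no_evidence": risk.no_evidence,
                "attribution": {k.value: round(v, 4) for k, v in risk.attribution.items()},
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compute_score(
    x: Mapping[BehaviorKind, float],
    weights: BehaviorWeights = BehaviorWeights(),
    risk: Optional[RiskDegree] = None,
    history: Optional[ScoreHistory] = None,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> HealthReport:
    """Compute the Health Score from sub-scores, weights, risk and history."""
    if not weights.is_normalized:
        raise ValueError("weights must be normalized to sum 1 (use .normalized)")
    for k in BehaviorKind:
        if k not in x:
            raise ValueError(f"missing sub-score for {k.value}")
        if not 1 <= x[k] <= 10:
            raise ValueError(f"sub-scores must lie in [1, 10], got {x[k]} for {k.value}")

    w = weights.as_dict()
    base = sum(w[k] * x[k] for k in BehaviorKind)
    risk_value = 0.0 if risk is None else risk.value
    penalized = base * (1.0 - config.risk_penalty * risk_value)
    penalized = min(10.0, max(1.0, penalized))
    if history is not None and len(history) > 0:
        final = (penalized + history.last_score) / 2.0
    else:
        final = penalized
    final = min(10.0, max(1.0, final))
    score = _round_half_up(final)
    score = min(10, max(1, score))
    import math
    lo = max(1, int(math.floor(final - 1)))
    hi = min(10, int(math.ceil(final + 1)))
    return HealthReport(
        score=score,
        score_raw=final,
        score_range=(lo, hi),
        state=classify(score),
        sub_scores=dict(x),
        weights=weights,
        fam_risk=risk,
    )


def update_weights(
    history: ScoreHistory, weights: BehaviorWeights
) -> BehaviorWeights:
    """Adapt weights to behavioral drift across the history.

    For each behavior the drift ratio r_k compares the per-entry sub-score
    mean over all n entries with the mean over the first n-1; r_k < 1 means
    the latest observation worsened that behavior.  Weights divide by r_k
    and renormalize, so worsening behaviors gain weight.
    """
    n = len(history)
    if n < 2:
        raise ValueError("weight updating needs at least 2 history entries")
    new = {}
    w = weights.as_dict()
    for k in BehaviorKind:
        all_mean = sum(e[1][k] for e in history.entries) / n
        prev_mean = sum(e[1][k] for e in history.entries[:-1]) / (n - 1)
        r = all_mean / prev_mean
        new[k] = w[k] / r
    total = sum(new.values())
    return BehaviorWeights(*(new[k] / total for k in BehaviorKind))
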