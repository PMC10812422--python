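"""Percent agreement between the AI health states and expert (veterinary) labels.

Two raters assign each unit one of two states; the 2x2 concordance table
has cells a (both positive), b (expert positive / AI negative), c (expert
negative / AI positive) and d (both negative), and

    percent agreement % = 100 * (a + d) / (a + b + c + d).

Agreement for the study's published comparison is computed at the
breed-group level (8 units): that is the only reading under which the
published per-dog sub-counts are arithmetically consistent with the printed
total.  A per-dog mode is available for user data via :func:`confusion` on
any list of labeled pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .scoring import HealthState, classify

__all__ = [
    "LabeledPair",
    "ConfusionCounts",
    "confusion",
    "percent_agreement",
    "format_agreement",
    "table6_fixture",
    "read_pairs_csv",
]

_VALID_STATES = {HealthState.EXAMINATION_REQUIRED, HealthState.HEALTHY}


@dataclass(frozen=True)
class LabeledPair:
    """One unit's (dog or breed group) AI state and expert state."""

    unit_id: str
    ai_state: str
    expert_state: str

    def __post_init__(self) -> None:
        for s in (self.ai_state, self.expert_state):
            if s not in _VALID_STATES:
                raise ValueError(
                    f"unknown state {s!r}; expected one of {sorted(_VALID_STATES)}"
                )


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 concordance cells (a: both positive ... d: both negative)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one pair")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def confusion(
    pairs: Sequence[LabeledPair],
    positive_means: str = HealthState.EXAMINATION_REQUIRED,
) -> ConfusionCounts:
    """Tabulate labeled pairs into the 2x2 concordance cells."""
    if len(pairs) == 0:
        raise ValueError("cannot tabulate an empty pair list")
    if positive_means not in _VALID_STATES:
        raise ValueError(f"unknown positive_means {positive_means!r}")
    a = b = c = d = 0
    for p in pairs:
        expert_pos = p.expert_state == positive_means
        ai_pos = p.ai_state == positive_means
        if expert_pos and ai_pos:
            a += 1
        elif expert_pos and not ai_pos:
            b += 1
        elif ai_pos:
            c += 1
        else:
            d += 1
    return ConfusionCounts(a, b, c, d)


def percent_agreement(counts: ConfusionCounts) -> float:
    """100 x (a + d) / (a + b + c + d); unrounded."""
    return 100.0 * (counts.a + counts.d) / counts.total


def format_agreement(value: float) -> str:
    """One-decimal display formatting of a percent agreement."""
    return f"{value:.1f}"


#: published breed-group comparison: (breed group, AI Health Score, expert state)
_TABLE6_ROWS: tuple[tuple[str, int, str], ...] = (
    ("retriever", 4, HealthState.EXAMINATION_REQUIRED),
    ("siberian_husky", 9, HealthState.HEALTHY),
    ("jindo", 3, HealthState.EXAMINATION_REQUIRED),
    ("poodle", 8, HealthState.HEALTHY),
    ("beagle", 4, HealthState.HEALTHY),        # the documented AI/vet disagreement
    ("maltese", 8, HealthState.HEALTHY),
    ("shih_tzu", 4, HealthState.EXAMINATION_REQUIRED),
    ("other", 9, HealthState.HEALTHY),
)


def table6_fixture() -> list[LabeledPair]:
    """The study's 8 breed-group pairs; the AI state derives from the
    published Health Score (<= 5 -> examination required), the expert state
    is the veterinarians' published judgement."""
    return [
        LabeledPair(unit_id=breed, ai_state=classify(score), expert_state=expert)
        for breed, score, expert in _TABLE6_ROWS
    ]


def read_pairs_csv(path) -> list[LabeledPair]:
    """Read labeled pairs from CSV with columns unit_id, ai_state, expert_state."""
    df = pd.read_csv(path)
    missing = [c for c in ("unit_id", "ai_state", "expert_state") if c not in df.columns]
    if missing:
        raise ValueError(f"pairs CSV missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("pairs CSV contains no rows")
    return [
        LabeledPair(str(r.unit_id), str(r.ai_state), str(r.expert_state))
        for r in df.itertuples()
    ]
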