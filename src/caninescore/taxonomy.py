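"""Domain types and classification tables for collar-sensor dog behavior analytics.

The four monitored behaviors are scratching, licking, swallowing (food and
water) and sleeping.  Scratch/lick/swallow are measured as events per hour,
sleep as hours per day.  Each behavior's numeric value maps to an ordinal
category; level 0 is always the normal band.  For swallowing both tails are
abnormal: a low count flags digestive/esophageal trouble, a high count
excessive water intake (a chronic-kidney-disease signal), so "below average"
and "above average" both carry level > 0 while "average" is level 0.

Dogs are stratified by weight (small < 7 kg, medium 7-15 kg, large > 15 kg)
and by age (babyhood 0-2 y, adolescence 3-7 y, adulthood 8-10 y).  The study
population is restricted to dogs of age <= 10 years.

Threshold tables ship as a versioned JSON resource
(``caninescore/data/thresholds.json``) and may be overridden by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Optional

__all__ = [
    "BehaviorKind",
    "SizeClass",
    "LifeStage",
    "DogProfile",
    "OrdinalCategory",
    "CategoryProfile",
    "ThresholdTables",
    "load_thresholds",
    "classify_weight",
    "classify_age",
    "categorize_count",
    "categorize_sleep",
    "category_profile",
    "COUNT_BEHAVIORS",
]


class BehaviorKind(str, Enum):
    SCRATCH = "scratch"
    LICK = "lick"
    SWALLOW = "swallow"
    SLEEP = "sleep"


#: behaviors counted per hour (sleep is hours per day)
COUNT_BEHAVIORS = (BehaviorKind.SCRATCH, BehaviorKind.LICK, BehaviorKind.SWALLOW)


class SizeClass(str, Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


class LifeStage(str, Enum):
    BABYHOOD = "babyhood"
    ADOLESCENCE = "adolescence"
    ADULTHOOD = "adulthood"


def classify_weight(weight_kg: float) -> SizeClass:
    """Map body weight to a size class.

    Small < 7 kg, medium 7-15 kg (boundaries inclusive to medium),
    large > 15 kg.
    """
    if not weight_kg > 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg!r}")
    if weight_kg < 7:
        return SizeClass.SMALL
    if weight_kg <= 15:
        return SizeClass.MEDIUM
    return SizeClass.LARGE


def classify_age(age_years: float) -> LifeStage:
    """Map age to a life stage (babyhood 0-2, adolescence 3-7, adulthood 8-10)."""
    if age_years < 0:
        raise ValueError(f"age_years must be non-negative, got {age_years!r}")
    if age_years > 10:
        raise ValueError("dogs over 10 years are outside the studied population")
    if age_years < 3:
        return LifeStage.BABYHOOD
    if age_years < 8:
        return LifeStage.ADOLESCENCE
    return LifeStage.ADULTHOOD


@dataclass(frozen=True)
class DogProfile:
    """Identity and stratification of one dog; size/life-stage are derived."""

    dog_id: str
    breed: str
    weight_kg: float
    age_years: float

    def __post_init__(self) -> None:
        classify_weight(self.weight_kg)
        classify_age(self.age_years)

    @property
    def size_class(self) -> SizeClass:
        return classify_weight(self.weight_kg)

    @property
    def life_stage(self) -> LifeStage:
        return classify_age(self.age_years)


@dataclass(frozen=True)
class OrdinalCategory:
    """One behavior's ordinal bin; level 0 is the normal band."""

    behavior: BehaviorKind
    label: str
    level: int


@dataclass(frozen=True)
class _Bin:
    label: str
    level: int
    lower: float
    upper: Optional[float]  # None = open-ended top bin, closed as >= lower

    def contains(self, value: float) -> bool:
        if self.upper is None:
            return value >= self.lower
        return self.lower <= value <= self.upper


class ThresholdTables:
    """Per-behavior ordinal bins, loaded from the packaged JSON resource."""

    def __init__(self, raw: Mapping) -> None:
        self.version: str = str(raw.get("version", "unversioned"))
        self._bins: dict[BehaviorKind, tuple[_Bin, ...]] = {}
        for kind in COUNT_BEHAVIORS:
            spec = raw[kind.value]["bins"]
            self._bins[kind] = tuple(
                _Bin(b["label"], int(b["level"]), float(b["lower"]),
                     None if b["upper"] is None else float(b["upper"]))
                for b in spec
            )
        sleep = raw[BehaviorKind.SLEEP.value]
        self._bins[BehaviorKind.SLEEP] = tuple(
            _Bin(b["label"], int(b["level"]), float(b["lower"]), float(b["upper"]))
            for b in sleep["bands"]
        )
        self.alt_trouble_cutoff_h: float = float(sleep.get("alt_trouble_cutoff_h", 9.6))

    def bins(self, behavior: BehaviorKind) -> tuple[_Bin, ...]:
        return self._bins[behavior]

    def lookup_count(self, behavior: BehaviorKind, count: float) -> OrdinalCategory:
        if behavior not in COUNT_BEHAVIORS:
            raise TypeError(
                f"{behavior.value} is not a count-per-hour behavior; "
                "use lookup_sleep for sleep"
            )
        if count < 0:
            raise ValueError(f"count must be non-negative, got {count!r}")
        for b in self._bins[behavior]:
            if b.contains(count):
                return OrdinalCategory(behavior, b.label, b.level)
        raise AssertionError("bins are total on the non-negative reals")

    def lookup_sleep(self, hours: float) -> OrdinalCategory:
        if not 0 <= hours <= 24:
            raise ValueError(f"sleep hours must lie in [0, 24], got {hours!r}")
        # bands are ordered ascending; lower inclusive, upper exclusive except
        # the top band ("deep sleep" starts at 12 h inclusive, runs to 24 h)
        bands = self._bins[BehaviorKind.SLEEP]
        for b in bands[:-1]:
            if b.lower <= hours < b.upper:
                return OrdinalCategory(BehaviorKind.SLEEP, b.label, b.level)
        top = bands[-1]
        return OrdinalCategory(BehaviorKind.SLEEP, top.label, top.level)


_DEFAULT: Optional[ThresholdTables] = None


def load_thresholds(override: Optional[Mapping] = None) -> ThresholdTables:
    """Return the packaged threshold tables, or build them from *override*."""
    global _DEFAULT
    if override is not None:
        return ThresholdTables(override)
    if _DEFAULT is None:
        text = resources.files("caninescore.data").joinpath("thresholds.json").read_text()
        _DEFAULT = ThresholdTables(json.loads(text))
    return _DEFAULT


def categorize_count(
    behavior: BehaviorKind,
    count_per_hour: float,
    tables: Optional[ThresholdTables] = None,
) -> OrdinalCategory:
    """Ordinal bin for an hourly scratch/lick/swallow count."""
    return (tables or load_thresholds()).lookup_count(behavior, count_per_hour)


def categorize_sleep(
    hours_per_day: float, tables: Optional[ThresholdTables] = None
) -> OrdinalCategory:
    """Sleep band for daily sleep hours (deep sleep >= 12 h)."""
    return (tables or load_thresholds()).lookup_sleep(hours_per_day)


@dataclass(frozen=True)
class CategoryProfile:
    """All four behaviors' numeric values and their ordinal categories."""

    values: Mapping[BehaviorKind, float]
    categories: Mapping[BehaviorKind, OrdinalCategory] = field(hash=False, default=None)

    def __post_init__(self) -> None:
        missing = [k for k in BehaviorKind if k not in self.values]
        if missing:
            raise ValueError(f"missing behaviors: {[m.value for m in missing]}")
        for k, v in self.values.items():
            if v < 0:
                raise ValueError(f"{k.value} value must be non-negative")
        if not self.values[BehaviorKind.SLEEP] <= 24:
            raise ValueError("sleep hours cannot exceed 24")
        if self.categories is None:
            t = load_thresholds()
            cats = {
                k: (t.lookup_sleep(v) if k is BehaviorKind.SLEEP
                    else t.lookup_count(k, v))
                for k, v in self.values.items()
            }
            object.__setattr__(self, "categories", cats)

    def level(self, behavior: BehaviorKind) -> int:
        return self.categories[behavior].level

    @property
    def levels(self) -> tuple[int, int, int, int]:
        return tuple(self.categories[k].level for k in BehaviorKind)


def category_profile(
    counts, sleep_hours: Optional[float] = None,
    tables: Optional[ThresholdTables] = None,
) -> CategoryProfile:
    """Build a :class:`CategoryProfile` from hourly counts plus sleep hours.

    *counts* may be a mapping ``{BehaviorKind: value}`` (sleep included or
    given separately via *sleep_hours*) or any object with ``scratch``,
    ``lick``, ``swallow`` and ``sleep_hours`` attributes (e.g. the detection
    module's ``HourlyCounts``).
    """
    t = tables or load_thresholds()
    if isinstance(counts, Mapping):
        values = {BehaviorKind(k): float(v) for k, v in counts.items()}
        if sleep_hours is not None:
            values[BehaviorKind.SLEEP] = float(sleep_hours)
    else:
        values = {
            BehaviorKind.SCRATCH: float(counts.scratch),
            BehaviorKind.LICK: float(counts.lick),
            BehaviorKind.SWALLOW: float(counts.swallow),
            BehaviorKind.SLEEP: float(counts.sleep_hours),
        }
    missing = [k for k in BehaviorKind if k not in values]
    if missing:
        raise ValueError(f"missing behaviors: {[m.value for m in missing]}")
    cats = {
        k: (t.lookup_sleep(values[k]) if k is BehaviorKind.SLEEP
            else t.lookup_count(k, values[k]))
        for k in BehaviorKind
    }
    return CategoryProfile(values=values, categories=cats)
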