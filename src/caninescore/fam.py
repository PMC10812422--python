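"""Fuzzy associative memory (FAM) mapping behavior patterns to disease risk.

The memory follows Kosko's correlation-minimum construction.  A stored pair
of fuzzy membership vectors (input pattern ``a``, output pattern ``b``)
contributes the min outer product ``min(a_i, b_j)``; pairs are superimposed
elementwise by max, so storage is idempotent and monotone.  Recall of an
input vector ``v`` is the max-min composition ``out_j = max_i min(v_i,
M_ij)``, defuzzified to a scalar risk in [0, 1] by the centroid of the
clipped output sets.

Inputs are fuzzified against a Ruspini partition per behavior (trapezoidal
sets whose plateaus span the ordinal bins of the classification tables, with
narrow linear crossovers at the bin boundaries), 14 components in all:
4 scratch + 4 lick + 3 swallow + 3 sleep sets.  The output partition holds
three triangular risk sets (low / medium / high) on [0, 1].

Training pairs associate clinical exemplars with risk: disease-labeled
profiles are stored as their *symptom pattern* (non-symptomatic components
masked to zero, mirroring how symptomatology - not the background behavior -
is what the clinical record associates with the disease), healthy profiles
are stored whole.  Without the masking, every normal-band component would
acquire a full-strength high-risk association from the disease exemplars'
backgrounds and the superimposed memory would lose all discrimination.

A homogeneous (auto-associative) layer stores recurring profiles associated
with themselves, reinforcing the individual dog's normal baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .taxonomy import (
    BehaviorKind,
    CategoryProfile,
    ThresholdTables,
    load_thresholds,
)

__all__ = [
    "FuzzySet",
    "FamModel",
    "RiskDegree",
    "input_partitions",
    "component_index",
    "fuzzify",
    "encode_output",
    "encode_pair",
    "train",
    "recall",
    "update_homogeneous",
    "reference_model",
    "defuzzify_centroid",
    "OUTPUT_SETS",
    "SYMPTOM_COMPONENTS",
]

#: crossover halfwidth around bin boundaries (events/hour for counts, hours for sleep)
CROSSOVER_COUNTS = 1.0
CROSSOVER_SLEEP = 0.25

_INF = float("inf")


@dataclass(frozen=True)
class FuzzySet:
    """Trapezoidal membership function (a <= b <= c <= d); open ends via +/-inf."""

    name: str
    a: float
    b: float
    c: float
    d: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        mu = np.zeros_like(x)
        core = (x >= self.b) & (x <= self.c)
        mu[core] = 1.0
        if np.isfinite(self.a) and self.b > self.a:
            rising = (x > self.a) & (x < self.b)
            mu[rising] = (x[rising] - self.a) / (self.b - self.a)
        if np.isfinite(self.d) and self.d > self.c:
            falling = (x > self.c) & (x < self.d)
            mu[falling] = (self.d - x[falling]) / (self.d - self.c)
        return mu if mu.shape else float(mu)


def _partition_from_bins(bins, halfwidth: float) -> list[FuzzySet]:
    """Trapezoidal Ruspini partition with crossovers at the bin midpoint boundaries."""
    # boundary between bin k and k+1: midpoint of upper_k .. lower_{k+1}
    bounds = [
        (bins[k].upper + bins[k + 1].lower) / 2.0 for k in range(len(bins) - 1)
    ]
    sets = []
    for k, b in enumerate(bins):
        lo = bounds[k - 1] if k > 0 else None
        hi = bounds[k] if k < len(bins) - 1 else None
        sets.append(FuzzySet(
            name=b.label,
            a=-_INF if lo is None else lo - halfwidth,
            b=-_INF if lo is None else lo + halfwidth,
            c=_INF if hi is None else hi - halfwidth,
            d=_INF if hi is None else hi + halfwidth,
        ))
    return sets


def input_partitions(
    tables: Optional[ThresholdTables] = None,
) -> dict[BehaviorKind, list[FuzzySet]]:
    """Per-behavior fuzzy partitions aligned to the ordinal bins."""
    t = tables or load_thresholds()
    out: dict[BehaviorKind, list[FuzzySet]] = {}
    for kind in BehaviorKind:
        hw = CROSSOVER_SLEEP if kind is BehaviorKind.SLEEP else CROSSOVER_COUNTS
        out[kind] = _partition_from_bins(t.bins(kind), hw)
    return out


def component_index(
    tables: Optional[ThresholdTables] = None,
) -> list[tuple[BehaviorKind, int, str]]:
    """Flat (behavior, ordinal level, label) list in fuzzify's component order."""
    t = tables or load_thresholds()
    idx = []
    for kind in BehaviorKind:
        for b in t.bins(kind):
            idx.append((kind, b.level, b.label))
    return idx


def _symptom_mask(tables: Optional[ThresholdTables] = None) -> np.ndarray:
    """True for components that are disease symptoms.

    Skin disease: scratch/lick at "often"/"serious" (level >= 2).  Digestive
    and kidney flags: swallowing below or above its normal band (level >= 1).
    Severe sleep loss ("strikingly little", level 2) flags insomnia.
    """
    mask = []
    for kind, level, _ in component_index(tables):
        if kind in (BehaviorKind.SCRATCH, BehaviorKind.LICK):
            mask.append(level >= 2)
        elif kind is BehaviorKind.SWALLOW:
            mask.append(level >= 1)
        else:
            mask.append(level >= 2)
    return np.array(mask)


SYMPTOM_COMPONENTS = _symptom_mask


#: output risk partition: triangular low / medium / high on [0, 1].  The low
#: set is deliberately narrower than the high set so that a profile matching
#: both a healthy exemplar (through its normal background) and a symptom rule
#: defuzzifies strictly above 0.5 instead of landing on a knife-edge tie.
OUTPUT_SETS: tuple[FuzzySet, ...] = (
    FuzzySet("low", 0.0, 0.0, 0.0, 0.3),
    FuzzySet("medium", 0.1, 0.5, 0.5, 0.9),
    FuzzySet("high", 0.5, 1.0, 1.0, 1.0),
)
OUTPUT_NAMES = tuple(s.name for s in OUTPUT_SETS)
_Z_GRID = np.linspace(0.0, 1.0, 2001)


def fuzzify(
    profile: CategoryProfile, tables: Optional[ThresholdTables] = None
) -> np.ndarray:
    """Membership vector (14 components) of a profile's numeric values."""
    parts = input_partitions(tables)
    vec = []
    for kind in BehaviorKind:
        x = profile.values[kind]
        vec.extend(float(s(x)) for s in parts[kind])
    return np.array(vec)


def encode_output(label: Union[str, float]) -> np.ndarray:
    """Output membership vector for a risk label or a crisp risk value."""
    if isinstance(label, str):
        key = {"healthy": "low", "disease": "high"}.get(label, label)
        if key not in OUTPUT_NAMES:
            raise ValueError(f"unknown risk label {label!r}")
        return np.array([1.0 if n == key else 0.0 for n in OUTPUT_NAMES])
    risk = float(label)
    if not 0 <= risk <= 1:
        raise ValueError("crisp risk must lie in [0, 1]")
    return np.array([float(s(risk)) for s in OUTPUT_SETS])


def encode_pair(
    profile: CategoryProfile,
    label: Union[str, float],
    tables: Optional[ThresholdTables] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Training pair (input vector, output vector) with symptom masking.

    Disease-labeled profiles store only their symptomatic components;
    healthy profiles store the full pattern.
    """
    vec = fuzzify(profile, tables)
    out = encode_output(label)
    if isinstance(label, str) and {"disease": "high"}.get(label, label) == "high":
        vec = np.where(_symptom_mask(tables), vec, 0.0)
    return vec, out


@dataclass
class RiskDegree:
    """Defuzzified disease risk with per-behavior attribution."""

    value: float
    attribution: Mapping[BehaviorKind, float] = field(default_factory=dict)
    no_evidence: bool = False
    output_memberships: Optional[np.ndarray] = None


@dataclass
class FamModel:
    """Correlation-minimum FAM: association matrices plus an auto-associative layer.

    ``matrices`` maps a class key (``"global"`` or a breed/size class when the
    per-class flag is used) to a (n_inputs x n_outputs) matrix with entries in
    [0, 1].  ``auto`` is the homogeneous memory (n_inputs x n_inputs).
    """

    matrices: dict[str, np.ndarray] = field(default_factory=dict)
    auto: Optional[np.ndarray] = None
    tables_version: str = "1.0"

    @property
    def trained(self) -> bool:
        return bool(self.matrices)

    def matrix(self, breed_class: Optional[str] = None) -> np.ndarray:
        if not self.trained:
            raise ValueError("model has no stored associations; train it first")
        if breed_class is None:
            if len(self.matrices) == 1:
                return next(iter(self.matrices.values()))
            breed_class = "global"
        try:
            return self.matrices[breed_class]
        except KeyError:
            raise KeyError(f"no matrix for class {breed_class!r}") from None

    def to_json(self, path=None) -> str:
        payload = {
            "tables_version": self.tables_version,
            "output_sets": [[s.name, s.a, s.b, s.c, s.d] for s in OUTPUT_SETS],
            "matrices": {k: np.asarray(m).tolist() for k, m in self.matrices.items()},
            "auto": None if self.auto is None else np.asarray(self.auto).tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FamModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            matrices={k: np.array(m, dtype=float) for k, m in payload["matrices"].items()},
            auto=None if payload.get("auto") is None else np.array(payload["auto"], dtype=float),
            tables_version=payload.get("tables_version", "unversioned"),
        )


def _min_outer(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.minimum.outer(a, b)


def train(
    pairs: Sequence[tuple[np.ndarray, Union[np.ndarray, str, float]]],
    breed_class: Optional[str] = None,
) -> FamModel:
    """Correlation-minimum encoding: M = elementwise max of min outer products."""
    if len(pairs) == 0:
        raise ValueError("training requires at least one pair")
    n_in = len(np.asarray(pairs[0][0]))
    M = np.zeros((n_in, len(OUTPUT_SETS)))
    for vec, out in pairs:
        vec = np.asarray(vec, dtype=float)
        out_vec = out if isinstance(out, np.ndarray) else encode_output(out)
        np.maximum(M, _min_outer(vec, np.asarray(out_vec, dtype=float)), out=M)
    key = breed_class if breed_class is not None else "global"
    return FamModel(matrices={key: M})


def maxmin_compose(vec: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Max-min composition: out_j = max_i min(vec_i, M_ij)."""
    return np.max(np.minimum(vec[:, None], M), axis=0)


def defuzzify_centroid(out: np.ndarray) -> float:
    """Centroid of the output sets clipped at their recalled memberships."""
    mu = np.zeros_like(_Z_GRID)
    for level, fset in zip(out, OUTPUT_SETS):
        np.maximum(mu, np.minimum(level, fset(_Z_GRID)), out=mu)
    total = mu.sum()
    if total == 0:
        return 0.0
    return float((mu * _Z_GRID).sum() / total)


def recall(
    model: FamModel,
    profile: Union[CategoryProfile, np.ndarray],
    breed_class: Optional[str] = None,
    tables: Optional[ThresholdTables] = None,
) -> RiskDegree:
    """Recall the disease-risk degree for a profile (or raw membership vector)."""
    M = model.matrix(breed_class)
    vec = profile if isinstance(profile, np.ndarray) else fuzzify(profile, tables)
    out = maxmin_compose(vec, M)
    if out.max() == 0.0:
        return RiskDegree(value=0.0, no_evidence=True,
                          output_memberships=out, attribution={})
    # ties between output sets resolve toward the higher-risk set, so the
    # attribution explains what is driving the risk up
    j_star = int(np.flatnonzero(out == out.max())[-1])
    attribution: dict[BehaviorKind, float] = {}
    pos = 0
    for kind, _, _ in component_index(tables):
        contrib = min(vec[pos], M[pos, j_star])
        attribution[kind] = max(attribution.get(kind, 0.0), float(contrib))
        pos += 1
    return RiskDegree(
        value=defuzzify_centroid(out),
        attribution=attribution,
        no_evidence=False,
        output_memberships=out,
    )


def update_homogeneous(
    model: FamModel,
    profile: Union[CategoryProfile, np.ndarray],
    tables: Optional[ThresholdTables] = None,
) -> FamModel:
    """Store a profile associated with itself in the auto-associative layer.

    Max-encoding makes the update idempotent and monotone non-decreasing, so
    recurring normal patterns reinforce the dog's healthy baseline without
    ever erasing stored associations.
    """
    vec = profile if isinstance(profile, np.ndarray) else fuzzify(profile, tables)
    auto = _min_outer(vec, vec)
    new_auto = auto if model.auto is None else np.maximum(model.auto, auto)
    return FamModel(matrices=dict(model.matrices), auto=new_auto,
                    tables_version=model.tables_version)


def recall_auto(model: FamModel, vec: np.ndarray) -> np.ndarray:
    """Max-min recall through the homogeneous layer (pattern completion)."""
    if model.auto is None:
        raise ValueError("model has no homogeneous layer")
    return maxmin_compose(np.asarray(vec, dtype=float), model.auto)


def reference_model(tables: Optional[ThresholdTables] = None) -> FamModel:
    """The shipped default memory, built from the canonical clinical rules.

    One healthy exemplar (the full normal envelope: levels 0-1 for scratch,
    lick and sleep, the normal swallow band) maps to low risk; each symptom
    component maps on its own to high risk.  This is the fixed point that
    training on a large balanced clinical sample converges to, stated
    deterministically.
    """
    idx = component_index(tables)
    n = len(idx)
    healthy = np.zeros(n)
    for pos, (kind, level, _) in enumerate(idx):
        if kind is BehaviorKind.SWALLOW:
            healthy[pos] = 1.0 if level == 0 else 0.0
        else:
            healthy[pos] = 1.0 if level <= 1 else 0.0
    mask = _symptom_mask(tables)
    pairs: list[tuple[np.ndarray, str]] = [(healthy, "low")]
    for pos in range(n):
        if mask[pos]:
            one = np.zeros(n)
            one[pos] = 1.0
            pairs.append((one, "high"))
    return train(pairs)
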