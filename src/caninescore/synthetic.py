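"""Seeded generator of collar IMU streams and ground-truth behavior events.

Emulates what the study's collar sensor records: a 50 Hz six-channel stream
(tri-axial accelerometer, +/-2 g; tri-axial gyro, +/-2000 deg/s) in which
episodic behaviors appear as short, band-separable waveforms:

* scratch  - 4-6 Hz high-amplitude oscillation bursts (accel + gyro),
* lick     - 2-3 Hz moderate rhythmic acceleration,
* swallow  - isolated short spikes,
* sleep    - one long near-zero-variance block per day.

Event start times follow a homogeneous Poisson process per behavior at the
breed's hourly rate; episodes are rejection-thinned so no two episodes of any
behavior overlap (the rendered stream stays physically interpretable).  The
sleep block occupies the last ``sleep_hours`` of each 24 h day, and hourly
event rates apply to awake time.  Default per-breed rates bracket the study
averages (e.g. retriever scratch ~122/h, husky ~42/h).

Waveform morphology (frequencies, amplitudes, episode durations) is this
package's invention, exposed through :class:`WaveformConfig`; only episode
detectability downstream matters, not biomechanical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .taxonomy import (
    BehaviorKind,
    COUNT_BEHAVIORS,
    CategoryProfile,
    ThresholdTables,
    load_thresholds,
)

__all__ = [
    "BehaviorRateSpec",
    "EventLog",
    "SensorStream",
    "WaveformConfig",
    "BREED_RATE_SPECS",
    "simulate_events",
    "render_imu",
    "make_training_set",
    "draw_profile",
]

ACCEL_RANGE_G = 2.0
GYRO_RANGE_DPS = 2000.0
DEFAULT_SAMPLE_RATE_HZ = 50.0


@dataclass(frozen=True)
class BehaviorRateSpec:
    """Per-breed hourly behavior rates and episode-duration distributions."""

    breed: str = "generic"
    scratch_per_hour: float = 60.0
    lick_per_hour: float = 12.0
    swallow_per_hour: float = 45.0
    sleep_hours_per_day: float = 12.0
    #: (mean_s, sd_s) episode duration per count behavior
    episode_s: Mapping[BehaviorKind, tuple[float, float]] = field(
        default_factory=lambda: {
            BehaviorKind.SCRATCH: (1.0, 0.3),
            BehaviorKind.LICK: (4.0, 1.0),
            BehaviorKind.SWALLOW: (0.5, 0.1),
        }
    )

    def __post_init__(self) -> None:
        for r in (self.scratch_per_hour, self.lick_per_hour, self.swallow_per_hour):
            if r < 0:
                raise ValueError("behavior rates must be non-negative")
        if not 0 <= self.sleep_hours_per_day <= 24:
            raise ValueError("sleep_hours_per_day must lie in [0, 24]")

    def rate(self, behavior: BehaviorKind) -> float:
        return {
            BehaviorKind.SCRATCH: self.scratch_per_hour,
            BehaviorKind.LICK: self.lick_per_hour,
            BehaviorKind.SWALLOW: self.swallow_per_hour,
        }[behavior]

    @classmethod
    def from_dict(cls, d: Mapping) -> "BehaviorRateSpec":
        known = {
            "breed", "scratch_per_hour", "lick_per_hour",
            "swallow_per_hour", "sleep_hours_per_day",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown BehaviorRateSpec keys: {sorted(unknown)}")
        return cls(**d)


#: Study-average hourly rates and sleep hours per breed group.
BREED_RATE_SPECS: dict[str, BehaviorRateSpec] = {
    "retriever": BehaviorRateSpec("retriever", 122, 18, 42, 9.7),
    "siberian_husky": BehaviorRateSpec("siberian_husky", 42, 8, 58, 12.5),
    "jindo": BehaviorRateSpec("jindo", 130, 22, 34, 8.7),
    "poodle": BehaviorRateSpec("poodle", 53, 5, 74, 13.0),
    "beagle": BehaviorRateSpec("beagle", 37, 9, 26, 13.2),
    "maltese": BehaviorRateSpec("maltese", 40, 7, 61, 14.2),
    "shih_tzu": BehaviorRateSpec("shih_tzu", 144, 6, 50, 10.2),
    "other": BehaviorRateSpec("other", 46, 3, 23, 12.4),
}


@dataclass(frozen=True)
class EventLog:
    """Ground-truth behavior episodes: (behavior, start_s, end_s) within a window."""

    events: tuple[tuple[BehaviorKind, float, float], ...]
    duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "events",
            tuple(sorted(self.events, key=lambda ev: (ev[1], ev[2], ev[0].value))),
        )
        last_end: dict[BehaviorKind, float] = {}
        for kind, start, end in self.events:
            if not (0 <= start < end <= self.duration_s + 1e-9):
                raise ValueError(f"event ({kind.value}, {start}, {end}) outside window")
            if start < last_end.get(kind, -1.0):
                raise ValueError(f"overlapping {kind.value} events")
            last_end[kind] = end

    def of_kind(self, kind: BehaviorKind) -> list[tuple[float, float]]:
        return [(s, e) for k, s, e in self.events if k is kind]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(k.value, s, e) for k, s, e in self.events],
            columns=["behavior", "start_s", "end_s"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration_s: float) -> "EventLog":
        df = pd.read_csv(path)
        events = tuple(
            (BehaviorKind(row.behavior), float(row.start_s), float(row.end_s))
            for row in df.itertuples()
        )
        return cls(events=events, duration_s=duration_s)


@dataclass(frozen=True)
class SensorStream:
    """Fixed-rate six-channel IMU samples (accel in g, gyro in deg/s)."""

    sample_rate_hz: float
    t: np.ndarray          # (n,) seconds
    data: np.ndarray       # (n, 6): ax ay az gx gy gz

    CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if len(self.t) != len(self.data):
            raise ValueError("t and data length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def accel(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.data[:, 3:]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.data, columns=list(self.CHANNELS))
        df.insert(0, "t", self.t)
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "SensorStream":
        df = pd.read_csv(path)
        missing = [c for c in ("t", *cls.CHANNELS) if c not in df.columns]
        if missing:
            raise ValueError(f"sensor CSV missing columns: {missing}")
        t = df["t"].to_numpy(float)
        if len(t) > 1:
            rate = 1.0 / float(np.median(np.diff(t)))
        else:
            rate = DEFAULT_SAMPLE_RATE_HZ
        return cls(sample_rate_hz=rate, t=t,
                   data=df[list(cls.CHANNELS)].to_numpy(float))


def _sleep_intervals(sleep_hours: float, duration_s: float) -> list[tuple[float, float]]:
    """Sleep blocks: the last ``sleep_hours`` of each 24 h day, clipped to the window."""
    out = []
    day = 0
    while day * 86400.0 < duration_s:
        start = day * 86400.0 + (24.0 - sleep_hours) * 3600.0
        end = (day + 1) * 86400.0
        lo, hi = max(0.0, start), min(duration_s, end)
        if hi > lo:
            out.append((lo, hi))
        day += 1
    return out


def simulate_events(
    spec: BehaviorRateSpec, duration_h: float, seed: int
) -> EventLog:
    """Draw a ground-truth event log for ``duration_h`` hours.

    Scratch/lick/swallow starts follow a homogeneous Poisson process at the
    spec's rate over awake time; episodes that would overlap an already
    placed episode (of any behavior) or the sleep block are rejected.
    Deterministic under ``seed``.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    rng = np.random.default_rng(seed)
    duration_s = duration_h * 3600.0
    sleep = _sleep_intervals(spec.sleep_hours_per_day, duration_s)
    awake_s = duration_s - sum(e - s for s, e in sleep)

    busy = sum(
        spec.rate(k) * (awake_s / 3600.0) * spec.episode_s[k][0]
        for k in COUNT_BEHAVIORS
    )
    if awake_s > 0 and busy > 0.8 * awake_s:
        raise ValueError(
            "behavior rates too high to pack episodes without overlap "
            f"(expected busy time {busy:.0f}s of {awake_s:.0f}s awake)"
        )

    awake: list[tuple[float, float]] = []
    cursor = 0.0
    for s, e in sleep + [(duration_s, duration_s)]:
        if s > cursor:
            awake.append((cursor, s))
        cursor = max(cursor, e)
    awake_lens = np.array([e - s for s, e in awake]) if awake else np.array([])

    placed: list[tuple[BehaviorKind, float, float]] = []

    def overlaps(start: float, end: float) -> bool:
        return any(start < e and end > s for _, s, e in placed)

    for kind in COUNT_BEHAVIORS:
        lam = spec.rate(kind) * awake_s / 3600.0
        if lam <= 0 or awake_s <= 0:
            continue
        n = rng.poisson(lam)
        mean_d, sd_d = spec.episode_s[kind]
        # uniform positions over concatenated awake time = Poisson process
        pos = np.sort(rng.uniform(0.0, awake_s, size=n))
        durs = np.maximum(0.1, rng.normal(mean_d, sd_d, size=n))
        offsets = np.concatenate([[0.0], np.cumsum(awake_lens)]) if len(awake) else [0.0]
        for p, d in zip(pos, durs):
            seg = int(np.searchsorted(offsets, p, side="right")) - 1
            seg = min(seg, len(awake) - 1)
            start = awake[seg][0] + (p - offsets[seg])
            end = min(start + d, awake[seg][1])
            if end - start < 0.1 or overlaps(start, end):
                continue
            placed.append((kind, start, end))

    for s, e in sleep:
        placed.append((BehaviorKind.SLEEP, s, e))
    events = tuple(sorted(placed, key=lambda ev: (ev[1], ev[0].value)))
    return EventLog(events=events, duration_s=duration_s)


@dataclass(frozen=True)
class WaveformConfig:
    """Invented per-behavior waveform templates used by :func:`render_imu`."""

    scratch_freq_hz: tuple[float, float] = (4.0, 6.0)
    scratch_amp_g: float = 0.8
    scratch_gyro_dps: float = 300.0
    lick_freq_hz: tuple[float, float] = (2.0, 3.0)
    lick_amp_g: float = 0.3
    swallow_amp_g: float = 0.9
    swallow_sigma_s: float = 0.04
    sleep_still_factor: float = 0.1
    gyro_noise_scale: float = 100.0  # gyro noise sd = noise_sd * this (deg/s per g)


def render_imu(
    log: EventLog,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    noise_sd: float = 0.05,
    seed: int = 0,
    waveforms: Optional[WaveformConfig] = None,
) -> SensorStream:
    """Render an event log into a six-channel IMU stream.

    Baseline channels are Gaussian noise (sd ``noise_sd`` g on accel);
    behavior episodes superimpose their templates; sleep events damp the
    noise to near-stillness.  All samples are clipped to the sensor ranges.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    wf = waveforms or WaveformConfig()
    rng = np.random.default_rng(seed)
    n = int(round(log.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    data = np.empty((n, 6))
    data[:, :3] = rng.normal(0.0, noise_sd, size=(n, 3))
    data[:, 3:] = rng.normal(0.0, noise_sd * wf.gyro_noise_scale, size=(n, 3))

    for kind, s, e in log.events:
        if kind is BehaviorKind.SLEEP:
            i0, i1 = int(s * sample_rate_hz), int(e * sample_rate_hz)
            data[i0:i1] *= wf.sleep_still_factor

    for kind, s, e in log.events:
        if kind is BehaviorKind.SLEEP:
            continue
        i0, i1 = int(s * sample_rate_hz), max(int(e * sample_rate_hz), int(s * sample_rate_hz) + 1)
        seg_t = t[i0:i1]
        if kind is BehaviorKind.SCRATCH:
            f = rng.uniform(*wf.scratch_freq_hz)
            ph = rng.uniform(0, 2 * np.pi)
            osc = np.sin(2 * np.pi * f * (seg_t - s) + ph)
            data[i0:i1, 0] += wf.scratch_amp_g * osc
            data[i0:i1, 2] += 0.6 * wf.scratch_amp_g * np.cos(2 * np.pi * f * (seg_t - s) + ph)
            data[i0:i1, 3] += wf.scratch_gyro_dps * osc
        elif kind is BehaviorKind.LICK:
            f = rng.uniform(*wf.lick_freq_hz)
            ph = rng.uniform(0, 2 * np.pi)
            data[i0:i1, 1] += wf.lick_amp_g * np.sin(2 * np.pi * f * (seg_t - s) + ph)
        elif kind is BehaviorKind.SWALLOW:
            mid = (s + e) / 2.0
            pulse = wf.swallow_amp_g * np.exp(-((seg_t - mid) ** 2) / (2 * wf.swallow_sigma_s ** 2))
            data[i0:i1, 2] += pulse

    np.clip(data[:, :3], -ACCEL_RANGE_G, ACCEL_RANGE_G, out=data[:, :3])
    np.clip(data[:, 3:], -GYRO_RANGE_DPS, GYRO_RANGE_DPS, out=data[:, 3:])
    return SensorStream(sample_rate_hz=sample_rate_hz, t=t, data=data)


def simulated_day(
    spec: BehaviorRateSpec,
    duration_h: float,
    seed: int,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    noise_sd: float = 0.05,
    waveforms: Optional[WaveformConfig] = None,
) -> tuple[EventLog, SensorStream]:
    """Convenience: simulate events and render them in one call."""
    log = simulate_events(spec, duration_h, seed)
    stream = render_imu(log, sample_rate_hz, noise_sd, seed=seed + 1, waveforms=waveforms)
    return log, stream


# ---------------------------------------------------------------------------
# labeled category-profile generator (FAM training / held-out evaluation)
# ---------------------------------------------------------------------------

#: span used to bound open-ended top bins when drawing representative values
_TOP_BIN_SPAN = {BehaviorKind.SCRATCH: 100, BehaviorKind.LICK: 16, BehaviorKind.SWALLOW: 30}
_COUNT_MARGIN = 2       # stay clear of bin-boundary crossover zones
_SLEEP_MARGIN = 0.5
_SLEEP_MAX_DRAW = 16.0  # typical upper end of canine daily sleep


def _draw_count(behavior: BehaviorKind, level: int, rng, tables: ThresholdTables) -> int:
    b = next(x for x in tables.bins(behavior) if x.level == level)
    lo = int(b.lower) + (_COUNT_MARGIN if b.lower > 0 else 0)
    hi = int(b.upper) - _COUNT_MARGIN if b.upper is not None else lo + _TOP_BIN_SPAN[behavior]
    return int(rng.integers(lo, hi + 1))


def _draw_sleep(level: int, rng, tables: ThresholdTables) -> float:
    b = next(x for x in tables.bins(BehaviorKind.SLEEP) if x.level == level)
    lo = b.lower + (_SLEEP_MARGIN if b.lower > 0 else 0.0)
    hi = min(b.upper - _SLEEP_MARGIN, _SLEEP_MAX_DRAW) if b.level != 0 else _SLEEP_MAX_DRAW
    if b.level == 0:
        lo = b.lower + _SLEEP_MARGIN
    return float(rng.uniform(lo, hi))


def draw_profile(levels: Mapping[BehaviorKind, int], rng,
                 tables: Optional[ThresholdTables] = None) -> CategoryProfile:
    """Random numeric profile realizing the given ordinal levels."""
    t = tables or load_thresholds()
    values = {
        k: (float(_draw_sleep(levels[k], rng, t)) if k is BehaviorKind.SLEEP
            else float(_draw_count(k, levels[k], rng, t)))
        for k in BehaviorKind
    }
    from .taxonomy import category_profile
    return category_profile(values)


def _healthy_levels(rng) -> dict[BehaviorKind, int]:
    # swallow stays in its single normal band; elsewhere mild level-1 values
    # are part of the healthy envelope
    return {
        BehaviorKind.SCRATCH: int(rng.choice([0, 1], p=[0.7, 0.3])),
        BehaviorKind.LICK: int(rng.choice([0, 1], p=[0.7, 0.3])),
        BehaviorKind.SWALLOW: 0,
        BehaviorKind.SLEEP: int(rng.choice([0, 1], p=[0.8, 0.2])),
    }


def _disease_levels(rng) -> dict[BehaviorKind, int]:
    if rng.random() < 0.5:  # skin disease: excessive scratching/licking
        return {
            BehaviorKind.SCRATCH: int(rng.integers(2, 4)),
            BehaviorKind.LICK: int(rng.integers(2, 4)),
            BehaviorKind.SWALLOW: 0,
            BehaviorKind.SLEEP: int(rng.choice([0, 1], p=[0.8, 0.2])),
        }
    # digestive (below-average swallowing) or kidney (above-average) flag
    return {
        BehaviorKind.SCRATCH: int(rng.choice([0, 1], p=[0.7, 0.3])),
        BehaviorKind.LICK: int(rng.choice([0, 1], p=[0.7, 0.3])),
        BehaviorKind.SWALLOW: int(rng.integers(1, 3)),
        BehaviorKind.SLEEP: int(rng.choice([0, 1], p=[0.8, 0.2])),
    }


def make_training_set(
    n_instances: int, healthy_fraction: float, seed: int,
    tables: Optional[ThresholdTables] = None,
) -> list[tuple[CategoryProfile, str]]:
    """Labeled category profiles emulating the study's clinical training data.

    Healthy instances sit in the normal envelope (levels 0-1 for scratch,
    lick and sleep; swallowing in its single normal band).  Disease instances
    carry either the skin-disease symptom pattern (scratch/lick at level 2-3)
    or the digestive/kidney pattern (swallow at level 1-2).  Labels are
    ``"healthy"`` / ``"disease"``; deterministic under ``seed``.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if not 0 <= healthy_fraction <= 1:
        raise ValueError("healthy_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_healthy = int(round(n_instances * healthy_fraction))
    out: list[tuple[CategoryProfile, str]] = []
    for i in range(n_instances):
        healthy = i < n_healthy
        levels = _healthy_levels(rng) if healthy else _disease_levels(rng)
        out.append((draw_profile(levels, rng, tables), "healthy" if healthy else "disease"))
    perm = rng.permutation(n_instances)
    return [out[int(i)] for i in perm]
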