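"""Event detection: IMU stream -> behavior events -> hourly counts.

The detector is a sliding-window band-energy classifier (default 1 s windows
with 50% overlap).  Each window of the accelerometer channels is labeled by
a cascade:

1. *stillness* - pooled standard deviation below a threshold; contiguous
   still windows of at least 20 minutes count as sleep,
2. *energy gate* - windows whose energy does not clear a multiple of the
   stream's estimated noise floor (median window energy) stay unlabeled,
3. *swallow* - impulsive windows: high crest factor and a narrow
   above-half-peak support (isolated spikes),
4. *scratch* / *lick* - dominant spectral band 3.5-7 Hz or 1.5-3.2 Hz.

Adjacent same-label windows (gap <= merge gap) merge into events.  Counts
are normalized per hour; sleep hours are summed per 24 h of recording.

Streams are pre-cleaned by :func:`filter_stream`, which drops sensor
non-response (flat-line runs) and saturated samples together with a one
window guard margin before and after each anomalous run, and reports the
surviving-sample fraction as coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .synthetic import (
    ACCEL_RANGE_G,
    EventLog,
    GYRO_RANGE_DPS,
    SensorStream,
)
from .taxonomy import BehaviorKind

__all__ = [
    "DetectionConfig",
    "HourlyCounts",
    "FilterResult",
    "filter_stream",
    "detect_events",
    "tally",
    "counts_from_stream",
]


@dataclass(frozen=True)
class HourlyCounts:
    """Per-hour behavior counts plus daily sleep hours."""

    scratch: int
    lick: int
    swallow: int
    sleep_hours: float
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if min(self.scratch, self.lick, self.swallow) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.sleep_hours <= 24:
            raise ValueError("sleep_hours must lie in [0, 24]")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "scratch": self.scratch, "lick": self.lick, "swallow": self.swallow,
            "sleep_hours": self.sleep_hours, "coverage": self.coverage,
        }


@dataclass(frozen=True)
class DetectionConfig:
    window_s: float = 1.0
    overlap: float = 0.5
    scratch_band_hz: tuple[float, float] = (3.5, 7.0)
    lick_band_hz: tuple[float, float] = (1.5, 3.2)
    band_fraction: float = 0.4
    energy_gate_factor: float = 3.0
    crest_threshold: float = 3.2
    spike_support_max: float = 0.2   # max fraction of samples above half peak
    spike_min_amp_g: float = 0.25
    stillness_std_g: float = 0.02
    sleep_min_s: float = 1200.0      # naps shorter than 20 min are not sleep
    merge_gap_s: float = 0.6
    flatline_min_s: float = 2.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")


@dataclass(frozen=True)
class FilterResult:
    stream: SensorStream
    coverage: float
    empty: bool


def filter_stream(
    stream: SensorStream, config: Optional[DetectionConfig] = None
) -> FilterResult:
    """Drop anomalous sensor data with a guard margin around each bad run.

    Anomalies are saturated samples (at or beyond the +/-2 g / +/-2000 deg/s
    sensor range) and flat-line runs (all six channels frozen for at least
    ``flatline_min_s``), the signature of sensor non-response.  A margin of
    one window before and after each anomalous run is dropped too, since
    data adjoining the anomaly's starting point cannot be trusted.
    """
    if len(stream) == 0:
        raise ValueError("stream is empty")
    cfg = config or DetectionConfig()
    n = len(stream)
    bad = np.zeros(n, dtype=bool)

    sat = (np.abs(stream.accel) >= ACCEL_RANGE_G).any(axis=1) | (
        np.abs(stream.gyro) >= GYRO_RANGE_DPS
    ).any(axis=1)
    bad |= sat

    frozen = np.zeros(n, dtype=bool)
    if n > 1:
        same = (np.diff(stream.data, axis=0) == 0).all(axis=1)
        run_len = int(round(cfg.flatline_min_s * stream.sample_rate_hz))
        # mark runs of identical consecutive samples of at least run_len samples
        idx = 0
        while idx < len(same):
            if same[idx]:
                j = idx
                while j < len(same) and same[j]:
                    j += 1
                if (j - idx + 1) >= run_len:
                    frozen[idx:j + 1] = True
                idx = j
            else:
                idx += 1
    bad |= frozen

    guard = int(round(cfg.window_s * stream.sample_rate_hz))
    if bad.any() and guard > 0:
        kernel = np.ones(2 * guard + 1)
        bad = np.convolve(bad.astype(float), kernel, mode="same") > 0

    keep = ~bad
    coverage = float(keep.sum() / n)
    kept = SensorStream(
        sample_rate_hz=stream.sample_rate_hz,
        t=stream.t[keep],
        data=stream.data[keep],
    )
    return FilterResult(stream=kept, coverage=coverage, empty=not keep.any())


def _segments(stream: SensorStream) -> list[tuple[int, int]]:
    """Index ranges of contiguous sampling (filtered streams may have gaps)."""
    if len(stream) == 0:
        return []
    dt = 1.0 / stream.sample_rate_hz
    breaks = np.where(np.diff(stream.t) > 1.5 * dt)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(stream)]])
    return list(zip(starts.tolist(), ends.tolist()))


def _band_energy(psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[sel].sum())


def detect_events(
    stream: SensorStream, config: Optional[DetectionConfig] = None
) -> EventLog:
    """Classify sliding windows and merge them into behavior events."""
    cfg = config or DetectionConfig()
    rate = stream.sample_rate_hz
    if rate < 2 * cfg.scratch_band_hz[1]:
        raise ValueError(
            f"sample rate {rate} Hz is below twice the highest detection band "
            f"({cfg.scratch_band_hz[1]} Hz)"
        )
    win = int(round(cfg.window_s * rate))
    step = max(1, int(round(win * (1 - cfg.overlap))))

    windows: list[tuple[float, float, Optional[BehaviorKind], float]] = []
    for seg_lo, seg_hi in _segments(stream):
        for i0 in range(seg_lo, max(seg_lo + 1, seg_hi - win + 1), step):
            i1 = min(i0 + win, seg_hi)
            if i1 - i0 < win // 2:
                continue
            acc = stream.data[i0:i1, :3]
            acc = acc - acc.mean(axis=0)
            var = float(acc.var(axis=0).mean())
            t0, t1 = stream.t[i0], stream.t[i1 - 1] + 1.0 / rate
            windows.append((t0, t1, None, var))
            if np.sqrt(var) < cfg.stillness_std_g:
                windows[-1] = (t0, t1, BehaviorKind.SLEEP, var)

    active_vars = [v for (_, _, lab, v) in windows if lab is not BehaviorKind.SLEEP]
    noise_floor = float(np.median(active_vars)) if active_vars else 0.0
    gate = cfg.energy_gate_factor * noise_floor

    labeled: list[tuple[float, float, BehaviorKind]] = []
    w_idx = 0
    for seg_lo, seg_hi in _segments(stream):
        for i0 in range(seg_lo, max(seg_lo + 1, seg_hi - win + 1), step):
            i1 = min(i0 + win, seg_hi)
            if i1 - i0 < win // 2:
                continue
            t0, t1, lab, var = windows[w_idx]
            w_idx += 1
            if lab is BehaviorKind.SLEEP:
                labeled.append((t0, t1, BehaviorKind.SLEEP))
                continue
            if var <= gate:
                continue
            acc = stream.data[i0:i1, :3]
            acc = acc - acc.mean(axis=0)
            # a window holding only the sliver of an episode that leaks over
            # its edge has its energy piled up at that edge; the neighboring
            # window covers the episode properly, so skip the sliver
            energy = (acc ** 2).sum(axis=1)
            q = max(1, len(energy) // 5)
            total_e = float(energy.sum())
            if total_e > 0 and max(energy[:q].sum(), energy[-q:].sum()) / total_e > 0.7:
                continue
            peak_ch = int(np.argmax(np.abs(acc).max(axis=0)))
            abs_ch = np.abs(acc[:, peak_ch])
            peak = float(abs_ch.max())
            rms = float(np.sqrt(var))
            crest = peak / rms if rms > 0 else 0.0
            above = abs_ch > 0.5 * peak
            support = float(above.mean())
            # one contiguous above-half-peak run = isolated spike; an
            # oscillation sliver shows several lobes
            n_runs = int(np.count_nonzero(np.diff(above.astype(int)) == 1) + above[0])
            # a spike peaks in the window interior; a sliver leaking over the
            # window edge peaks at that edge
            peak_pos = int(np.argmax(abs_ch)) / max(1, len(abs_ch) - 1)
            if (crest >= cfg.crest_threshold and support <= cfg.spike_support_max
                    and peak >= cfg.spike_min_amp_g and n_runs == 1
                    and 0.15 <= peak_pos <= 0.85):
                labeled.append((t0, t1, BehaviorKind.SWALLOW))
                continue
            spec = np.abs(np.fft.rfft(acc, axis=0)) ** 2
            psd = spec[1:].sum(axis=1)  # drop DC, pool channels
            freqs = np.fft.rfftfreq(i1 - i0, d=1.0 / rate)[1:]
            total = float(psd.sum())
            if total <= 0:
                continue
            if _band_energy(psd, freqs, cfg.scratch_band_hz) / total >= cfg.band_fraction:
                labeled.append((t0, t1, BehaviorKind.SCRATCH))
            elif _band_energy(psd, freqs, cfg.lick_band_hz) / total >= cfg.band_fraction:
                labeled.append((t0, t1, BehaviorKind.LICK))

    # merge same-label windows into events
    events: list[tuple[BehaviorKind, float, float]] = []
    for kind in BehaviorKind:
        gap = cfg.merge_gap_s if kind is not BehaviorKind.SLEEP else cfg.window_s
        spans = sorted((t0, t1) for t0, t1, k in labeled if k is kind)
        merged: list[list[float]] = []
        for t0, t1 in spans:
            if merged and t0 - merged[-1][1] <= gap:
                merged[-1][1] = max(merged[-1][1], t1)
            else:
                merged.append([t0, t1])
        for t0, t1 in merged:
            if kind is BehaviorKind.SLEEP and (t1 - t0) < cfg.sleep_min_s:
                continue
            events.append((kind, t0, t1))

    duration = float(stream.t[-1] + 1.0 / rate) if len(stream) else 0.0
    return EventLog(events=tuple(events), duration_s=duration)


def tally(log: EventLog, duration_h: float, coverage: float = 1.0) -> HourlyCounts:
    """Per-hour counts (nearest integer, ties to even) and daily sleep hours."""
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    n = {k: len(log.of_kind(k)) for k in BehaviorKind}
    sleep_s = sum(e - s for s, e in log.of_kind(BehaviorKind.SLEEP))
    days = max(1.0, duration_h / 24.0)
    return HourlyCounts(
        scratch=round(n[BehaviorKind.SCRATCH] / duration_h),
        lick=round(n[BehaviorKind.LICK] / duration_h),
        swallow=round(n[BehaviorKind.SWALLOW] / duration_h),
        sleep_hours=min(24.0, sleep_s / 3600.0 / days),
        coverage=coverage,
    )


def counts_from_stream(
    stream: SensorStream, config: Optional[DetectionConfig] = None
) -> HourlyCounts:
    """Full detection pipeline: filter, detect, tally."""
    cfg = config or DetectionConfig()
    filt = filter_stream(stream, cfg)
    if filt.empty:
        return HourlyCounts(0, 0, 0, 0.0, coverage=0.0)
    duration_h = (stream.t[-1] + 1.0 / stream.sample_rate_hz) / 3600.0
    log = detect_events(filt.stream, cfg)
    return replace(tally(log, duration_h), coverage=filt.coverage)
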