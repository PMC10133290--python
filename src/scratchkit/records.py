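"""Core in-memory containers: sensor recordings, annotation tracks, intervals.

Timestamps are float seconds (UTC epoch); intervals are half-open
``[start, end)``.  Accelerometer units are g, gyroscope deg/s, temperature
degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import OverlapError, RateMismatchError, VocabularyError

#: fixed annotation vocabulary (ground-truth video labels)
LABELS = ("scratch", "non-scratch movement", "in-bed still", "out-of-bed")
HANDS = ("left", "right")


@dataclass
class SensorRecording:
    """One hand-night of 6-axis samples plus device temperature.

    Attributes
    ----------
    timestamps : (n,) float seconds since epoch, strictly increasing
    accel : (n, 3) in g
    gyro : (n, 3) in deg/s or None
    temp : (n,) in deg C or None
    rate_hz : nominal sampling rate
    hand : "left" or "right"
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray | None
    temp: np.ndarray | None
    rate_hz: float
    hand: str = "left"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
        if self.temp is not None:
            self.temp = np.asarray(self.temp, dtype=float)
        self.validate()

    def validate(self):
        t = self.timestamps
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("recording needs >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.accel.shape != (len(t), 3):
            raise ValueError("accel must be n x 3")
        if not np.all(np.isfinite(self.accel)):
            raise ValueError("accel contains non-finite values")
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}")
        gap = float(np.median(np.diff(t)))
        if abs(gap - 1.0 / self.rate_hz) > 0.1 / self.rate_hz:
            raise RateMismatchError(
                f"median gap {gap:.4f}s inconsistent with declared "
                f"{self.rate_hz:g} Hz"
            )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, counting one trailing sample period."""
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.rate_hz

    @property
    def start_s(self) -> float:
        return float(self.timestamps[0])


@dataclass(frozen=True)
class Event:
    label: str
    start_s: float
    end_s: float
    hand: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise VocabularyError(f"unknown label {self.label!r}")
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}")
        if not self.start_s < self.end_s:
            raise ValueError("event must have start < end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Ordered, per-hand non-overlapping labeled events (ground truth)."""

    events: list[Event]

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.hand, e.start_s))
        for hand in HANDS:
            evs = [e for e in self.events if e.hand == hand]
            for a, b in zip(evs, evs[1:]):
                if b.start_s < a.end_s - 1e-9:
                    raise OverlapError(
                        f"{hand}: {a.label} [{a.start_s},{a.end_s}) overlaps "
                        f"{b.label} [{b.start_s},{b.end_s})"
                    )

    def for_hand(self, hand: str) -> "AnnotationTrack":
        return AnnotationTrack([e for e in self.events if e.hand == hand])

    def with_label(self, label: str) -> list[Event]:
        return [e for e in self.events if e.label == label]

    def shift(self, offset_s: float) -> "AnnotationTrack":
        return AnnotationTrack(
            [replace(e, start_s=e.start_s + offset_s, end_s=e.end_s + offset_s)
             for e in self.events]
        )

    def total_seconds(self, label: str, hand: str | None = None) -> float:
        evs = self.with_label(label)
        if hand is not None:
            evs = [e for e in evs if e.hand == hand]
        return float(sum(e.duration_s for e in evs))

    def occupancy(self, label: str, t0: float, t1: float,
                  hand: str | None = None) -> float:
        """Total seconds of `label` overlapping the half-open window [t0, t1)."""
        evs = self.with_label(label)
        if hand is not None:
            evs = [e for e in evs if e.hand == hand]
        return float(sum(max(0.0, min(e.end_s, t1) - max(e.start_s, t0))
                         for e in evs))


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError("interval must have start < end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "Interval") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s

    def intersect(self, other: "Interval") -> "Interval | None":
        lo, hi = max(self.start_s, other.start_s), min(self.end_s, other.end_s)
        return Interval(lo, hi) if lo < hi else None


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list."""
    out: list[Interval] = []
    for iv in sorted(intervals, key=lambda i: i.start_s):
        if out and iv.start_s <= out[-1].end_s:
            out[-1] = Interval(out[-1].start_s, max(out[-1].end_s, iv.end_s))
        else:
            out.append(iv)
    return out


def total_duration(intervals: list[Interval]) -> float:
    return float(sum(iv.duration_s for iv in merge_intervals(intervals)))
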