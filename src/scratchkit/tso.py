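"""Total-sleep-opportunity (TSO) window detection and two-hand combination.

The TSO is the nighttime interval a subject intends to sleep.  With a bed
sensor or annotations it is given; otherwise a heuristic on the wrist
z-angle finds it: the z-angle (arm elevation estimated from the low-passed
accelerometer) barely changes during sustained lying, so runs of 5-s
epochs whose 5-min rolling-median z-angle changes by less than 5 degrees
for at least 30 minutes mark sleep-like inactivity; the TSO spans the
first to the last such bout inside a nighttime gate (18:00-12:00), after
excising detected non-wear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as ssig

from .movement import NonwearMask
from .records import Interval, SensorRecording

ANGLE_CHANGE_DEG = 5.0
BOUT_MIN_MINUTES = 30.0
EPOCH_S = 5.0
MEDIAN_WIN_MIN = 5.0
NIGHT_GATE = (18.0, 12.0)  # hours of day, wrapping midnight


@dataclass
class TSOWindow:
    start_s: float
    end_s: float
    source: str = "heuristic"

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("TSO must have start < end")

    @property
    def interval(self) -> Interval:
        return Interval(self.start_s, self.end_s)

    @property
    def duration_h(self) -> float:
        return (self.end_s - self.start_s) / 3600.0


def tso_from_reference(interval: Interval,
                       recording_span: Interval | None = None) -> TSOWindow:
    """Validated pass-through of a bed-sensor / annotation TSO."""
    if recording_span is not None:
        if (interval.start_s < recording_span.start_s - 1e-6
                or interval.end_s > recording_span.end_s + 1e-6):
            raise ValueError("reference TSO outside the recording span")
    return TSOWindow(interval.start_s, interval.end_s, source="reference")


def _hour_of_day(t_epoch: np.ndarray) -> np.ndarray:
    return (np.asarray(t_epoch) % 86400.0) / 3600.0


def _in_gate(hours: np.ndarray, gate=NIGHT_GATE) -> np.ndarray:
    lo, hi = gate
    if lo <= hi:
        return (hours >= lo) & (hours < hi)
    return (hours >= lo) | (hours < hi)


def z_angle_deg(accel: np.ndarray, rate_hz: float) -> np.ndarray:
    """Arm-elevation angle from the low-passed accelerometer (degrees)."""
    b, a = ssig.butter(2, 0.5, btype="low", fs=rate_hz)
    lp = ssig.filtfilt(b, a, np.asarray(accel, dtype=float), axis=0)
    return np.degrees(np.arctan2(
        lp[:, 2], np.sqrt(lp[:, 0] ** 2 + lp[:, 1] ** 2)))


def tso_heuristic(rec: SensorRecording,
                  nonwear: NonwearMask | None = None,
                  night_gate=NIGHT_GATE) -> TSOWindow | None:
    """Sustained-inactivity heuristic TSO for one hand; None when no
    candidate bout exists."""
    angle = z_angle_deg(rec.accel, rec.rate_hz)
    epoch = int(EPOCH_S * rec.rate_hz)
    n_ep = len(angle) // epoch
    if n_ep < 2:
        warnings.warn("recording too short for TSO heuristic")
        return None
    ep_angle = angle[:n_ep * epoch].reshape(n_ep, epoch).mean(axis=1)
    ep_t = rec.start_s + (np.arange(n_ep) + 0.5) * EPOCH_S
    med_win = max(int(MEDIAN_WIN_MIN * 60 / EPOCH_S) | 1, 3)
    med = ssig.medfilt(ep_angle, kernel_size=med_win)
    still = np.abs(np.diff(med, prepend=med[0])) < ANGLE_CHANGE_DEG
    still &= _in_gate(_hour_of_day(ep_t), night_gate)
    if nonwear is not None:
        for iv in nonwear.intervals:
            still &= ~((ep_t >= iv.start_s) & (ep_t < iv.end_s))
    # sustained bouts
    min_epochs = int(BOUT_MIN_MINUTES * 60 / EPOCH_S)
    edges = np.flatnonzero(np.diff(np.concatenate(
        [[0], still.view(np.int8), [0]])))
    bouts = [(lo, hi) for lo, hi in zip(edges[::2], edges[1::2])
             if hi - lo >= min_epochs]
    if not bouts:
        warnings.warn("no sustained-inactivity bout: empty TSO")
        return None
    start = rec.start_s + bouts[0][0] * EPOCH_S
    end = rec.start_s + bouts[-1][1] * EPOCH_S
    return TSOWindow(start, end, source=f"heuristic-{rec.hand}")


def combine_hands(tso_left: TSOWindow | None,
                  tso_right: TSOWindow | None) -> TSOWindow | None:
    """Two valid overlapping hands: union; disjoint: the longer window with
    a discordance warning; one valid hand: that hand; none: None."""
    if tso_left is None and tso_right is None:
        return None
    if tso_left is None or tso_right is None:
        only = tso_left or tso_right
        return TSOWindow(only.start_s, only.end_s, source=only.source)
    if tso_left.interval.overlaps(tso_right.interval):
        return TSOWindow(min(tso_left.start_s, tso_right.start_s),
                         max(tso_left.end_s, tso_right.end_s),
                         source="combined")
    warnings.warn("discordant per-hand TSO windows; keeping the longer")
    longer = max(tso_left, tso_right, key=lambda w: w.end_s - w.start_s)
    return TSOWindow(longer.start_s, longer.end_s, source=longer.source)
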