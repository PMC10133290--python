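"""Sensor/annotation CSV readers and writers, and clock alignment.

Sensor schema: ``timestamp, ax, ay, az, gx, gy, gz, temp_c`` with ISO-8601
timestamps (gyro/temperature columns optional).  Annotation schema:
``start, end, label, hand`` with ISO-8601 timestamps and the fixed label
vocabulary.  Round-trips are lossless at microsecond / 1e-6 unit precision.

Device real-time clocks drift and may be configured in the wrong zone, so
annotation tracks can be offset from the sensor stream by seconds to hours.
:func:`estimate_time_offset` recovers a single per-night integer-second
shift by cross-correlating per-second signal activity with the annotated
movement indicator; sub-second within-night drift is deliberately ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError, VocabularyError
from .records import LABELS, AnnotationTrack, Event, SensorRecording

SENSOR_COLUMNS = ["timestamp", "ax", "ay", "az", "gx", "gy", "gz", "temp_c"]
ANNOTATION_COLUMNS = ["start", "end", "label", "hand"]


def write_recording(rec: SensorRecording, path) -> None:
    ts = pd.to_datetime(rec.timestamps, unit="s", utc=True)
    df = pd.DataFrame({
        "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
        "ax": rec.accel[:, 0], "ay": rec.accel[:, 1], "az": rec.accel[:, 2],
    })
    if rec.gyro is not None:
        df[["gx", "gy", "gz"]] = rec.gyro
    if rec.temp is not None:
        df["temp_c"] = rec.temp
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(path, rate_hz: float | None = None,
                   hand: str = "left") -> SensorRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = {"timestamp", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    t = pd.to_datetime(df["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
    if np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path}: timestamps not strictly increasing")
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    gyro = df[["gx", "gy", "gz"]].to_numpy() if "gx" in df.columns else None
    temp = df["temp_c"].to_numpy() if "temp_c" in df.columns else None
    return SensorRecording(
        timestamps=t, accel=df[["ax", "ay", "az"]].to_numpy(),
        gyro=gyro, temp=temp, rate_hz=rate_hz, hand=hand,
        meta={"path": str(path)},
    )


def write_annotations(track: AnnotationTrack, path) -> None:
    rows = [{
        "start": pd.Timestamp(e.start_s, unit="s", tz="UTC").strftime(
            "%Y-%m-%dT%H:%M:%S.%f"),
        "end": pd.Timestamp(e.end_s, unit="s", tz="UTC").strftime(
            "%Y-%m-%dT%H:%M:%S.%f"),
        "label": e.label,
        "hand": e.hand,
    } for e in track.events]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path) -> AnnotationTrack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise VocabularyError(f"{path}: unknown labels {sorted(bad)}")
    start = pd.to_datetime(df["start"], utc=True).astype("int64").to_numpy() / 1e9
    end = pd.to_datetime(df["end"], utc=True).astype("int64").to_numpy() / 1e9
    events = [Event(lbl, s, e, h)
              for lbl, s, e, h in zip(df["label"], start, end, df["hand"])]
    return AnnotationTrack(events)


MOVEMENT_LABELS = ("scratch", "non-scratch movement", "out-of-bed")


def _per_second_activity(rec: SensorRecording) -> tuple[np.ndarray, np.ndarray]:
    """SD of the accelerometer vector magnitude within each whole second."""
    vm = np.linalg.norm(rec.accel, axis=1)
    sec = np.floor(rec.timestamps - rec.timestamps[0]).astype(int)
    n_sec = sec[-1] + 1
    sums = np.bincount(sec, weights=vm, minlength=n_sec)
    sums2 = np.bincount(sec, weights=vm**2, minlength=n_sec)
    counts = np.bincount(sec, minlength=n_sec).astype(float)
    counts[counts == 0] = 1.0
    var = np.maximum(sums2 / counts - (sums / counts) ** 2, 0.0)
    return np.sqrt(var), rec.timestamps[0] + np.arange(n_sec)


def estimate_time_offset(rec: SensorRecording, track: AnnotationTrack,
                         max_shift_s: int = 300,
                         resolution_s: int = 1) -> int:
    """Integer-second offset to add to annotation timestamps.

    Maximizes the normalized cross-correlation between per-second vector-
    magnitude activity and the binary movement-annotated indicator over
    shifts in ``[-max_shift_s, max_shift_s]``.  ``track.shift(offset)``
    aligns the annotations to the recording.
    """
    activity, sec_t = _per_second_activity(rec)
    if np.ptp(activity) < 1e-9:
        raise AlignmentError("flat signal: no activity to align on")
    act = activity - activity.mean()
    act_norm = np.linalg.norm(act)
    evs = [e for e in track.events if e.label in MOVEMENT_LABELS
           and e.hand == rec.hand]
    if not evs:
        raise AlignmentError("no movement-annotated events to align on")
    shifts = np.arange(-max_shift_s, max_shift_s + 1, resolution_s)
    best, best_score = 0, -np.inf
    for s in shifts:
        ind = np.zeros(len(sec_t))
        for e in evs:
            # indicator evaluated at second t for annotations shifted by +s
            lo = np.searchsorted(sec_t, e.start_s + s - 0.5)
            hi = np.searchsorted(sec_t, e.end_s + s - 0.5)
            ind[lo:hi] = 1.0
        ind -= ind.mean()
        denom = act_norm * np.linalg.norm(ind)
        if denom == 0:
            continue
        score = float(act @ ind) / denom
        if score > best_score:
            best_score, best = score, int(s)
    if not np.isfinite(best_score):
        raise AlignmentError("cross-correlation undefined for all shifts")
    return best
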