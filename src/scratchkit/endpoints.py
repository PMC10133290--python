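"""Per-night digital endpoints and agreement statistics.

Deployment tiles the TSO window (minus non-wear) into non-overlapping 3-s
windows, keeps those with at least 1 s of detected movement, classifies
them, and pools both hands (a window is scratch when either hand calls
it).  Endpoints: total scratch seconds, hourly scratch duration
(seconds per TSO hour), and mean scratch intensity (the mean dominant
frequency, in Hz, of the positive windows' vector magnitude).

Agreement statistics: Bland-Altman mean difference and 95% limits of
agreement, one-way random-effects single-measure ICC(1,1) across repeated
nights, and Pearson/Spearman correlations against reference endpoints and
patient-reported outcome columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .features import (WIN_S, WindowSet, assemble_features, segment_windows,
                       time_freq_features)
from .movement import MovementMask, NonwearMask
from .records import Interval
from .tso import TSOWindow

PREDICTION_THRESHOLD = 0.5


def window_intensity_hz(slice3: np.ndarray) -> float:
    """Scratch intensity of one window: dominant frequency (Hz) of the
    leading principal-component projection of the gravity-free window.

    The PC projection is orientation-invariant and keeps the oscillation
    signed, so a pure f Hz scratch reads f; the vector magnitude of a
    zero-mean oscillation is rectified and would read 2f.
    """
    from .preprocess import _pc_projections
    proj, _ = _pc_projections(np.asarray(slice3, dtype=float))
    return float(time_freq_features(proj[:, 0])[12])  # dominant frequency


@dataclass
class NightEndpoints:
    subject: str
    night: str
    total_scratch_s: float
    hourly_scratch_duration: float  # s per TSO hour
    mean_scratch_intensity: float | None  # Hz; None when no scratch windows
    tso_hours: float
    n_windows: int = 0
    n_scratch_windows: int = 0

    def as_row(self) -> dict:
        return {
            "subject": self.subject, "night": self.night,
            "total_s": self.total_scratch_s,
            "hourly_s_per_h": self.hourly_scratch_duration,
            "intensity_hz": (np.nan if self.mean_scratch_intensity is None
                             else self.mean_scratch_intensity),
            "tso_h": self.tso_hours,
        }


def predict_night(
    model,
    hand_data: dict[str, dict],
    tso: TSOWindow,
    nonwear_by_hand: dict[str, NonwearMask] | None = None,
    threshold: float = PREDICTION_THRESHOLD,
) -> pd.DataFrame:
    """Classify non-overlapping 3-s tiles of a night, pooling hands.

    ``hand_data[hand]`` supplies ``signals`` (sensor -> (n, 3) series on the
    20 Hz grid), ``mask`` (MovementMask), and ``start_s``.  Returns one row
    per positive-or-negative tile with per-hand probabilities; the pooled
    call is the union over hands.
    """
    if tso is None:
        warnings.warn("empty TSO: no prediction")
        return pd.DataFrame(columns=["tile_start_s", "call"])
    nonwear_by_hand = nonwear_by_hand or {}
    calls: dict[float, dict] = {}
    for hand, data in hand_data.items():
        mask: MovementMask = data["mask"]
        ws = segment_windows(
            mask, data["signals"], data["start_s"], annotations=None,
            hand=hand, hop_s=WIN_S)
        if len(ws) == 0:
            continue
        keep_idx, tiles = [], []
        nonwear = nonwear_by_hand.get(hand)
        for i, w in enumerate(ws.windows):
            if not (w.start_s >= tso.start_s - 1e-9
                    and w.start_s + WIN_S <= tso.end_s + 1e-9):
                continue
            if nonwear is not None and any(
                    Interval(w.start_s, w.start_s + WIN_S).overlaps(iv)
                    for iv in nonwear.intervals):
                continue
            keep_idx.append(i)
            tiles.append(w)
        if not keep_idx:
            continue
        sub = WindowSet(windows=[ws.windows[i] for i in keep_idx],
                        signals=ws.signals, rate_hz=ws.rate_hz,
                        win_samples=ws.win_samples)
        X, _ = assemble_features(sub, sensors=model.sensors)
        proba = model.predict_proba(X, sub.nn_input(model.sensors))
        for w, p, i in zip(tiles, proba, keep_idx):
            sl = sub.signals["acc"][w.start_idx:w.start_idx + sub.win_samples]
            domfreq = window_intensity_hz(sl)
            entry = calls.setdefault(
                round(w.start_s - tso.start_s, 6),
                {"tile_start_s": w.start_s, "call": False, "domfreqs": []})
            entry[f"proba_{hand}"] = float(p)
            if p >= threshold:
                entry["call"] = True
                entry["domfreqs"].append(float(domfreq))
    rows = []
    for key in sorted(calls):
        e = calls[key]
        e["domfreq"] = float(np.mean(e["domfreqs"])) if e["domfreqs"] else np.nan
        del e["domfreqs"]
        rows.append(e)
    return pd.DataFrame(rows)


def compute_endpoints(tiles: pd.DataFrame, tso: TSOWindow,
                      subject: str = "?", night: str = "?") -> NightEndpoints:
    """Per-night endpoints from pooled non-overlapping tile calls."""
    tso_hours = tso.duration_h
    if len(tiles) == 0 or "call" not in tiles:
        return NightEndpoints(subject, night, 0.0, 0.0, None, tso_hours)
    pos = tiles[tiles["call"]]
    total = float(len(pos) * WIN_S)
    domfreqs = pos["domfreq"].dropna()
    intensity = float(domfreqs.mean()) if len(domfreqs) else None
    return NightEndpoints(
        subject=subject, night=night, total_scratch_s=total,
        hourly_scratch_duration=total / tso_hours,
        mean_scratch_intensity=intensity, tso_hours=tso_hours,
        n_windows=len(tiles), n_scratch_windows=len(pos))


def bland_altman(derived, reference) -> dict:
    """Mean difference and 95% limits of agreement for paired measures."""
    derived = np.asarray(derived, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if derived.shape != reference.shape:
        raise ValueError("paired vectors must have equal length")
    if len(derived) < 2:
        raise ValueError("need at least 2 pairs")
    d = derived - reference
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"mean_diff": mean_diff,
            "lower_loa": mean_diff - 1.96 * sd,
            "upper_loa": mean_diff + 1.96 * sd,
            "sd_diff": sd, "n": len(d)}


def icc(values: pd.DataFrame, subject_col: str = "subject",
        value_col: str = "value") -> float:
    """One-way random-effects single-measure ICC(1,1).

    ``(MSB - MSW) / (MSB + (k - 1) MSW)`` with ``k`` the mean group size
    for unbalanced designs.  Subjects with fewer than 2 repeats are
    excluded with a warning.
    """
    groups = [g[value_col].to_numpy(dtype=float)
              for _, g in values.groupby(subject_col)]
    small = [g for g in groups if len(g) < 2]
    if small:
        warnings.warn(f"excluding {len(small)} subject(s) with a single night")
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ICC needs >= 2 subjects with >= 2 nights")
    a = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ss_between / (a - 1)
    msw = ss_within / (n_total - a)
    k = n_total / a
    denom = msb + (k - 1) * msw
    return float((msb - msw) / denom) if denom > 0 else float("nan")


def correlate_with_pro(endpoints: pd.DataFrame, pro: pd.DataFrame,
                       endpoint_col: str = "total_s") -> pd.DataFrame:
    """Correlations between endpoints and patient-reported outcomes.

    SCORAD (one value per subject) correlates with subject-level mean
    endpoints; ADSS items (per night) correlate night-level.  Both Pearson
    and Spearman are reported; fewer than 3 pairs yields NaN.
    """
    rows = []

    def corr_pair(x, y, name, level):
        x, y = np.asarray(x, float), np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append({"pro": name, "level": level,
                         "pearson": np.nan, "spearman": np.nan,
                         "n": int(ok.sum())})
            return
        rows.append({
            "pro": name, "level": level,
            "pearson": float(sstats.pearsonr(x[ok], y[ok])[0]),
            "spearman": float(sstats.spearmanr(x[ok], y[ok])[0]),
            "n": int(ok.sum())})

    if "SCORAD" in pro.columns:
        subj_end = endpoints.groupby("subject")[endpoint_col].mean()
        subj_pro = pro.groupby("subject")["SCORAD"].first()
        joined = pd.concat([subj_end, subj_pro], axis=1).dropna()
        corr_pair(joined[endpoint_col], joined["SCORAD"], "SCORAD", "subject")
    adss_cols = [c for c in pro.columns if c.upper().startswith("ADSS")]
    if adss_cols and "night" in pro.columns:
        joined = endpoints.merge(pro, on=["subject", "night"], how="inner")
        for c in adss_cols:
            corr_pair(joined[endpoint_col], joined[c], c, "night")
    return pd.DataFrame(rows)
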