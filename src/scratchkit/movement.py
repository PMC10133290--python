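"""Threshold-based hand-movement detection and temperature non-wear rule.

The movement filter runs on 20 Hz calibrated accelerometer data (gravity
still present): the vector magnitude is low-passed (6th-order Butterworth,
3 Hz) to suppress noise and high-passed (1st-order, 0.25 Hz) to suppress
the constant; a rolling 1-s coefficient of variation (SD over |mean|) of
the band-passed VM and the per-second maximum axis SD of the band-passed
axes drive the rule.  The CoV separates oscillatory motion (a scratch in
the 2-5 Hz band has near-zero 1-s mean, so its CoV is large) from slow
mean-dominated drift; the SD criterion separates any motion from noise.  A second is movement iff strictly more than half of its
20 CoV samples exceed ``theta_cov`` AND the max axis SD exceeds
``theta_sd``.  The default thresholds (0.41, 0.013) correspond to the 8%
quantiles of the pooled distributions in the original clinical dataset;
:func:`fit_thresholds` recomputes them on any cohort.

Non-wear: a still period whose case temperature stays below 25 deg C for
more than 10 contiguous minutes is off-wrist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ssig

from .records import AnnotationTrack, Interval, SensorRecording

THETA_COV = 0.41
THETA_SD = 0.013
NONWEAR_TEMP_C = 25.0
NONWEAR_MIN_MINUTES = 10.0


@dataclass
class MovementMask:
    """Per-second movement flags on the 20 Hz grid."""

    seconds: np.ndarray  # bool, one per whole second
    start_s: float  # timestamp of second 0
    theta_cov: float = THETA_COV
    theta_sd: float = THETA_SD

    @property
    def fraction_movement(self) -> float:
        return float(self.seconds.mean()) if len(self.seconds) else 0.0

    def intervals(self) -> list[Interval]:
        return _runs_to_intervals(self.seconds, self.start_s)


@dataclass
class NonwearMask:
    intervals: list[Interval] = field(default_factory=list)
    temp_threshold_c: float = NONWEAR_TEMP_C
    min_duration_min: float = NONWEAR_MIN_MINUTES

    def total_seconds(self) -> float:
        return float(sum(iv.duration_s for iv in self.intervals))

    def covers(self, t: float) -> bool:
        return any(iv.start_s <= t < iv.end_s for iv in self.intervals)


def _runs_to_intervals(flags: np.ndarray, start_s: float,
                       step_s: float = 1.0) -> list[Interval]:
    out = []
    flags = np.asarray(flags, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flags.view(np.int8), [0]])))
    for lo, hi in zip(edges[::2], edges[1::2]):
        out.append(Interval(start_s + lo * step_s, start_s + hi * step_s))
    return out


def _causal(b, a, x: np.ndarray) -> np.ndarray:
    """Single-pass filter seeded at steady state for the first sample, so
    the startup step does not masquerade as movement."""
    zi = ssig.lfilter_zi(b, a)
    if x.ndim == 1:
        y, _ = ssig.lfilter(b, a, x, zi=zi * x[0])
        return y
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j], _ = ssig.lfilter(b, a, x[:, j], zi=zi * x[0, j])
    return out


def _band_filters(rate_hz: float):
    b_lp, a_lp = ssig.butter(6, 3.0, btype="low", fs=rate_hz)
    b_hp, a_hp = ssig.butter(1, 0.25, btype="high", fs=rate_hz)
    return (b_lp, a_lp), (b_hp, a_hp)


def _rolling_mean_sd(x: np.ndarray, win: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered rolling mean and SD, one value per sample (edges shrink)."""
    kernel = np.ones(win)
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    mean = np.convolve(x, kernel, mode="same") / counts
    sq = np.convolve(x**2, kernel, mode="same") / counts
    var = np.maximum(sq - mean**2, 0.0)
    return mean, np.sqrt(var)


def movement_statistics(accel_20hz: np.ndarray, rate_hz: float = 20.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """The two per-signal statistics driving the rule.

    Returns
    -------
    cov : (n,) rolling 1-s coefficient of variation of the band-passed VM
    max_sd : (n_seconds,) per-second max axis SD of the band-passed axes
    """
    accel_20hz = np.asarray(accel_20hz, dtype=float)
    (b_lp, a_lp), (b_hp, a_hp) = _band_filters(rate_hz)
    vm = np.linalg.norm(accel_20hz, axis=1)
    # single-pass filters: a zero-phase pass would square the 6th-order
    # low-pass response and wipe out the upper scratch band (4-5 Hz)
    vm_bp = _causal(b_hp, a_hp, _causal(b_lp, a_lp, vm))
    win = int(rate_hz)
    mean, sd = _rolling_mean_sd(vm_bp, win)
    # oscillation in the scratch band averages to ~0 over 1 s, driving the
    # CoV high; slow drift keeps a mean-dominated window, driving it low
    cov = sd / np.maximum(np.abs(mean), 1e-6)
    axes_bp = _causal(b_hp, a_hp, _causal(b_lp, a_lp, accel_20hz))
    n_sec = len(vm) // win
    tiles = axes_bp[:n_sec * win].reshape(n_sec, win, 3)
    max_sd = tiles.std(axis=1, ddof=0).max(axis=1)
    return cov, max_sd


def detect_movement(accel_20hz: np.ndarray, start_s: float = 0.0,
                    rate_hz: float = 20.0,
                    theta_cov: float = THETA_COV,
                    theta_sd: float = THETA_SD) -> MovementMask:
    """Per-second movement mask by the two-threshold rule."""
    if theta_cov <= 0 or theta_sd <= 0:
        raise ValueError("thresholds must be positive")
    cov, max_sd = movement_statistics(accel_20hz, rate_hz)
    win = int(rate_hz)
    n_sec = len(max_sd)
    cov_tiles = cov[:n_sec * win].reshape(n_sec, win)
    cov_votes = (cov_tiles > theta_cov).sum(axis=1)
    seconds = (cov_votes > win // 2) & (max_sd > theta_sd)
    return MovementMask(seconds=seconds, start_s=start_s,
                        theta_cov=theta_cov, theta_sd=theta_sd)


def fit_thresholds(accel_nights: list[np.ndarray], quantile: float = 0.08,
                   rate_hz: float = 20.0) -> tuple[float, float]:
    """Thresholds as the given quantiles of the pooled CoV and max-axis-SD
    distributions across a cohort of nights."""
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    if not accel_nights:
        raise ValueError("need at least one night")
    covs, sds = [], []
    for accel in accel_nights:
        cov, max_sd = movement_statistics(accel, rate_hz)
        covs.append(cov)
        sds.append(max_sd)
    return (float(np.quantile(np.concatenate(covs), quantile)),
            float(np.quantile(np.concatenate(sds), quantile)))


def detect_nonwear(mask: MovementMask, temp_c: np.ndarray | None,
                   temp_rate_hz: float = 20.0,
                   temp_threshold_c: float = NONWEAR_TEMP_C,
                   min_duration_min: float = NONWEAR_MIN_MINUTES) -> NonwearMask:
    """Still periods colder than the threshold for more than the minimum
    contiguous duration are flagged off-wrist."""
    if temp_c is None:
        warnings.warn("no temperature stream: non-wear detection skipped")
        return NonwearMask()
    temp_c = np.asarray(temp_c, dtype=float)
    n_sec = len(mask.seconds)
    win = int(temp_rate_hz)
    n_use = min(n_sec, len(temp_c) // win)
    temp_sec = temp_c[:n_use * win].reshape(n_use, win).mean(axis=1)
    cold_still = (~mask.seconds[:n_use]) & (temp_sec < temp_threshold_c)
    min_s = min_duration_min * 60.0
    intervals = [iv for iv in _runs_to_intervals(cold_still, mask.start_s)
                 if iv.duration_s > min_s]
    return NonwearMask(intervals=intervals, temp_threshold_c=temp_threshold_c,
                       min_duration_min=min_duration_min)


def movement_filter_report(mask: MovementMask,
                           annotations: AnnotationTrack,
                           hand: str | None = None) -> dict:
    """How much annotated scratch the movement filter loses, and the scratch
    prevalence within the kept movement seconds (both in percent)."""
    sec_starts = mask.start_s + np.arange(len(mask.seconds), dtype=float)
    occ = np.array([annotations.occupancy("scratch", s, s + 1.0, hand=hand)
                    for s in sec_starts])
    total_scratch = occ.sum()
    if total_scratch <= 0:
        return {"pct_scratch_lost": float("nan"),
                "scratch_prevalence_within_movement": 0.0}
    lost = occ[~mask.seconds].sum()
    movement_s = mask.seconds.sum()
    prevalence = (100.0 * occ[mask.seconds].sum() / movement_s
                  if movement_s else 0.0)
    return {"pct_scratch_lost": float(100.0 * lost / total_scratch),
            "scratch_prevalence_within_movement": float(prevalence)}


def apply_mask_to_recording(rec: SensorRecording) -> MovementMask:
    """Convenience: movement mask of a 20 Hz recording."""
    return detect_movement(rec.accel, start_s=rec.start_s, rate_hz=rec.rate_hz)
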