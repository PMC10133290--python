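"""Signal conditioning: autocalibration, resampling, gravity removal,
and the 12 orientation-invariant channels per sensor.

The accelerometer measures specific force, so at rest it reads a unit
gravity vector rotated into the sensor frame.  Gravity is removed either
by a zero-phase first-order 0.25 Hz high-pass Butterworth filter
(accelerometer-only deployments) or, when a gyroscope is present, by
integrating the orientation quaternion ODE ``q' = 1/2 q (0, omega)`` and
subtracting the gravity vector predicted by the orientation, with a small
complementary correction toward the accelerometer-measured gravity during
stationary regions to bound drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as ssig

from .records import SensorRecording

GRAVITY_CUTOFF_HZ = 0.25
TARGET_RATE_HZ = 20.0
#: complementary-filter gain toward measured gravity, per sample, in
#: stationary regions
FUSION_ALPHA = 0.02

CHANNEL_NAMES = ("x", "y", "z", "pc1", "pc2", "vm",
                 "dx", "dy", "dz", "dpc1", "dpc2", "dvm")


@dataclass
class CalibrationParams:
    """Per-axis gain/offset mapping raw to calibrated: a' = gain*a + offset."""

    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, accel: np.ndarray) -> np.ndarray:
        return accel * self.gain[None, :] + self.offset[None, :]

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.gain, 1) and np.allclose(self.offset, 0))


def _stationary_epochs(accel: np.ndarray, rate_hz: float,
                       epoch_s: float = 10.0,
                       sd_thresh_g: float = 0.013) -> np.ndarray:
    """Mean accel vector of each low-variance epoch (candidate rest points)."""
    n_e = int(epoch_s * rate_hz)
    n = (len(accel) // n_e) * n_e
    if n == 0:
        return np.empty((0, 3))
    tiles = accel[:n].reshape(-1, n_e, 3)
    sd = tiles.std(axis=1)
    keep = sd.max(axis=1) < sd_thresh_g
    return tiles[keep].mean(axis=1)


def autocalibrate(rec: SensorRecording, min_minutes: float = 10.0,
                  max_iter: int = 50) -> tuple[CalibrationParams, SensorRecording]:
    """Estimate per-axis gain/offset so stationary epochs lie on the unit
    gravity sphere (iterative least squares against the closest sphere
    point), then return the calibrated recording.

    Falls back to identity parameters with a warning when there is less
    than ``min_minutes`` of stationary data or the rest orientations do not
    span enough of the sphere to identify six parameters.
    """
    pts = _stationary_epochs(rec.accel, rec.rate_hz)
    needed = int(min_minutes * 6)  # 10-s epochs
    spread = 0.0
    if len(pts) >= 2:
        unit = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cos = unit @ unit.T
        spread = float(np.degrees(np.arccos(np.clip(cos.min(), -1, 1))))
    if len(pts) < needed or spread < 20.0:
        warnings.warn("insufficient stationary data / orientation spread; "
                      "returning identity calibration")
        return CalibrationParams(), rec
    gain, offset = np.ones(3), np.zeros(3)
    for _ in range(max_iter):
        cur = pts * gain + offset
        norm = np.linalg.norm(cur, axis=1, keepdims=True)
        target = cur / norm  # closest point on the unit sphere
        new_gain, new_offset = np.empty(3), np.empty(3)
        for ax in range(3):
            A = np.column_stack([pts[:, ax], np.ones(len(pts))])
            coef, *_ = np.linalg.lstsq(A, target[:, ax], rcond=None)
            new_gain[ax], new_offset[ax] = coef
        if (np.abs(new_gain - gain).max() < 1e-9
                and np.abs(new_offset - offset).max() < 1e-9):
            gain, offset = new_gain, new_offset
            break
        gain, offset = new_gain, new_offset
    params = CalibrationParams(gain=gain, offset=offset)
    if np.any(np.abs(gain - 1) > 0.2) or np.any(np.abs(offset) > 0.5):
        warnings.warn("calibration outside plausible range; using identity")
        return CalibrationParams(), rec
    calibrated = replace(rec, accel=params.apply(rec.accel),
                         meta={**rec.meta, "calibration": params})
    return params, calibrated


def resample(rec: SensorRecording, target_hz: float = TARGET_RATE_HZ) -> SensorRecording:
    """Linear interpolation onto a uniform grid; ``floor(duration*target)``
    samples.  Upsampling is refused."""
    if target_hz > rec.rate_hz + 1e-9:
        raise ValueError("resample only downsamples (target above native rate)")
    n_out = int(np.floor(rec.duration_s * target_hz))
    t_new = rec.start_s + np.arange(n_out) / target_hz
    def interp(col):
        return np.interp(t_new, rec.timestamps, col)
    accel = np.column_stack([interp(rec.accel[:, i]) for i in range(3)])
    gyro = (np.column_stack([interp(rec.gyro[:, i]) for i in range(3)])
            if rec.gyro is not None else None)
    temp = interp(rec.temp) if rec.temp is not None else None
    return replace(rec, timestamps=t_new, accel=accel, gyro=gyro, temp=temp,
                   rate_hz=target_hz)


def _highpass(x: np.ndarray, rate_hz: float,
              cutoff_hz: float = GRAVITY_CUTOFF_HZ) -> np.ndarray:
    b, a = ssig.butter(1, cutoff_hz, btype="highpass", fs=rate_hz)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= 3 * padlen:
        raise ValueError("signal shorter than filter settling time")
    return ssig.filtfilt(b, a, x, axis=0)


def remove_gravity_accel_only(accel: np.ndarray, rate_hz: float) -> np.ndarray:
    """Zero-phase first-order 0.25 Hz Butterworth high-pass per axis."""
    return _highpass(np.asarray(accel, dtype=float), rate_hz)


def butter_highpass_gain_db(freq_hz: float, rate_hz: float,
                            cutoff_hz: float = GRAVITY_CUTOFF_HZ,
                            zero_phase: bool = False) -> float:
    """Magnitude response (dB) of the gravity-removal filter; the
    zero-phase (forward-backward) response is the squared single pass."""
    b, a = ssig.butter(1, cutoff_hz, btype="highpass", fs=rate_hz)
    _, h = ssig.freqz(b, a, worN=[freq_hz], fs=rate_hz)
    mag = np.abs(h[0]) ** (2 if zero_phase else 1)
    return float(20 * np.log10(mag))


def _quat_mul(q, p):
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = p
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _gravity_in_sensor(q):
    """Rotate world +z into the sensor frame for sensor->world quaternion q."""
    w, x, y, z = q
    return np.array([
        2 * (x * z - w * y),
        2 * (y * z + w * x),
        w * w - x * x - y * y + z * z,
    ])


def remove_gravity_fused(
    accel: np.ndarray,
    gyro_dps: np.ndarray,
    rate_hz: float,
    stationary: np.ndarray | None = None,
    alpha: float = FUSION_ALPHA,
) -> tuple[np.ndarray, np.ndarray]:
    """Gravity removal by quaternion-ODE integration with stationary fusion.

    Parameters
    ----------
    accel : (n, 3) specific force in g
    gyro_dps : (n, 3) angular velocity in deg/s (converted internally)
    stationary : optional (n,) bool; where True, the orientation is nudged
        toward the accelerometer-measured gravity direction with per-sample
        gain ``alpha`` (complementary filter), bounding gyro-bias drift.

    Returns
    -------
    linear : (n, 3) gravity-free acceleration in the sensor frame (g)
    quaternions : (n, 4) scalar-first unit sensor->world quaternions
    """
    if gyro_dps is None:
        raise ValueError("gyroscope required; use remove_gravity_accel_only")
    accel = np.asarray(accel, dtype=float)
    omega = np.radians(np.asarray(gyro_dps, dtype=float))
    n = len(accel)
    if stationary is None:
        stationary = np.zeros(n, dtype=bool)
    dt = 1.0 / rate_hz

    # initialize from the first accel sample: rotation taking measured
    # gravity to +z (world), i.e. sensor->world
    g0 = accel[0] / (np.linalg.norm(accel[0]) + 1e-12)
    axis = np.cross(g0, [0.0, 0.0, 1.0])
    s = np.linalg.norm(axis)
    c = np.clip(g0[2], -1.0, 1.0)
    if s < 1e-12:
        q = np.array([1.0, 0, 0, 0]) if c > 0 else np.array([0.0, 1, 0, 0])
    else:
        ang = np.arctan2(s, c)
        axis = axis / s
        q = np.concatenate([[np.cos(ang / 2)], np.sin(ang / 2) * axis])

    quats = np.empty((n, 4))
    linear = np.empty((n, 3))
    for k in range(n):
        if stationary[k]:
            a_norm = np.linalg.norm(accel[k])
            if a_norm > 1e-9:
                g_meas = accel[k] / a_norm
                g_pred = _gravity_in_sensor(q)
                corr_axis = np.cross(g_pred, g_meas)
                sn = np.linalg.norm(corr_axis)
                if sn > 1e-12:
                    ang = np.arctan2(sn, np.clip(g_pred @ g_meas, -1, 1)) * alpha
                    corr_axis = corr_axis / sn
                    # rotate sensor frame: right-multiply by the small
                    # body-frame correction, inverted sign to move the
                    # predicted gravity toward the measurement
                    dq = np.concatenate([[np.cos(ang / 2)],
                                         -np.sin(ang / 2) * corr_axis])
                    q = _quat_mul(q, dq)
                    q = q / np.linalg.norm(q)
        quats[k] = q
        linear[k] = accel[k] - _gravity_in_sensor(q)
        if k + 1 < n:
            w = 0.5 * (omega[k] + omega[k + 1])
            ang = np.linalg.norm(w) * dt
            if ang > 1e-12:
                axis = w / np.linalg.norm(w)
                dq = np.concatenate([[np.cos(ang / 2)],
                                     np.sin(ang / 2) * axis])
                q = _quat_mul(q, dq)
                q = q / np.linalg.norm(q)
    return linear, quats


def _pc_projections(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leading two principal-axis projections of an (m, 3) tile.

    The projection sign is fixed so the largest-|value| sample of each
    projected series is positive: a convention that depends only on the
    projection itself, hence invariant under rotations of the input axes.
    Zero-variance tiles project to zeros; explained variances accompany.
    """
    centered = xyz - xyz.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / max(len(xyz) - 1, 1)
    if np.allclose(cov, 0):
        return np.zeros((len(xyz), 2)), np.zeros(3)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    proj = centered @ evecs[:, :2]
    for j in range(2):
        i_max = int(np.argmax(np.abs(proj[:, j])))
        if proj[i_max, j] < 0:
            proj[:, j] = -proj[:, j]
    return proj, np.maximum(evals, 0.0)


def derive_channels(series3: np.ndarray, rate_hz: float = TARGET_RATE_HZ,
                    tile_s: float = 3.0) -> dict[str, np.ndarray]:
    """The 12 channels of one sensor: x, y, z, pc1, pc2, vm and their
    central-difference derivatives.  PC projections are computed per
    non-overlapping 3-s tile (the analysis-window scale)."""
    series3 = np.asarray(series3, dtype=float)
    n = len(series3)
    vm = np.linalg.norm(series3, axis=1)
    pcs = np.zeros((n, 2))
    step = max(int(tile_s * rate_hz), 2)
    for i0 in range(0, n, step):
        tile = series3[i0:i0 + step]
        if len(tile) >= 2:
            pcs[i0:i0 + len(tile)], _ = _pc_projections(tile)
    chans = {"x": series3[:, 0], "y": series3[:, 1], "z": series3[:, 2],
             "pc1": pcs[:, 0], "pc2": pcs[:, 1], "vm": vm}
    dt = 1.0 / rate_hz
    for name in list(chans):
        chans["d" + name] = np.gradient(chans[name], dt)
    return chans
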