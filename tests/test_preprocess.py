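"""Calibration recovery, resampling, gravity removal (both variants), and
the 12-channel derivation with its rotation invariances."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scratchkit.preprocess import (CalibrationParams, autocalibrate,
                                   butter_highpass_gain_db, derive_channels,
                                   remove_gravity_accel_only,
                                   remove_gravity_fused, resample)
from scratchkit.records import SensorRecording
from scratchkit.synthetic import (NightScenario, ScheduledEvent,
                                  simulate_night)


def _make_rec(accel, rate=50.0, gyro=None, temp=None):
    n = len(accel)
    return SensorRecording(timestamps=np.arange(n) / rate, accel=accel,
                           gyro=gyro, temp=temp, rate_hz=rate)


@pytest.fixture(scope="module")
def multi_posture_night():
    """Quiet night with several posture turns: calibration needs several
    rest orientations."""
    events = [ScheduledEvent("non-scratch movement", t, t + 8.0, "left")
              for t in (300.0, 800.0, 1300.0, 2000.0, 2600.0)]
    scen = NightScenario(duration_h=1.0, events=events, tso=(0.0, 3600.0),
                         noise_sd_g=0.005, seed=21)
    return simulate_night(scen)


def test_autocalibration_recovers_injected_params(rng):
    """Known-perturbation recovery on rest segments spanning the sphere."""
    rate = 50.0
    segs = [np.tile(Rotation.random(rng=rng).inv().apply([0, 0, 1.0]),
                    (int(90 * rate), 1)) for _ in range(10)]
    accel = np.concatenate(segs) + rng.normal(0, 0.004,
                                              (len(segs) * int(90 * rate), 3))
    true_gain = np.array([1.05, 1.0, 1.0])
    true_offset = np.array([0.0, 0.02, 0.0])
    # corrupt: raw = (calibrated - offset) / gain
    raw = (accel - true_offset) / true_gain
    params, calibrated = autocalibrate(_make_rec(raw, rate=rate))
    assert np.allclose(params.gain, true_gain, atol=0.01)
    assert np.allclose(params.offset, true_offset, atol=0.01)
    vm = np.linalg.norm(calibrated.accel, axis=1)
    assert abs(vm.mean() - 1.0) < 0.005


def test_autocalibration_identity_when_calibrated(multi_posture_night):
    params, _ = autocalibrate(multi_posture_night.recording_left)
    assert np.allclose(params.gain, 1.0, atol=0.01)
    assert np.allclose(params.offset, 0.0, atol=0.01)


def test_autocalibration_single_orientation_warns(rng):
    accel = np.tile([0.0, 0.0, 1.0], (50 * 1200, 1)) + rng.normal(
        0, 0.003, (50 * 1200, 3))
    with pytest.warns(UserWarning):
        params, _ = autocalibrate(_make_rec(accel))
    assert params.is_identity


def test_resample_counts_and_constant(rng):
    accel = np.tile([0.1, 0.2, 0.9], (3000, 1))  # 60 s at 50 Hz
    out = resample(_make_rec(accel), 20.0)
    assert out.n_samples == 1200  # floor(60 * 20)
    assert np.allclose(out.accel, accel[0])
    with pytest.raises(ValueError):
        resample(_make_rec(accel), 100.0)  # upsampling refused


def test_gravity_highpass_rejects_dc():
    accel = np.tile([0.0, 0.0, 1.0], (20 * 600, 1))
    out = remove_gravity_accel_only(accel, 20.0)
    trim = slice(40, -40)
    assert np.abs(out[trim]).max() < 1e-6


def test_gravity_highpass_preserves_motion_band():
    t = np.arange(20 * 600) / 20.0
    sig = np.column_stack([np.sin(2 * np.pi * 3.0 * t),
                           np.zeros_like(t), np.ones_like(t)])
    out = remove_gravity_accel_only(sig, 20.0)
    amp = np.abs(out[200:-200, 0]).max()
    assert amp == pytest.approx(1.0, rel=0.02)


def test_single_pass_gain_at_cutoff_is_minus_3db():
    g = butter_highpass_gain_db(0.25, 20.0, zero_phase=False)
    assert g == pytest.approx(-3.0103, abs=0.1)
    g2 = butter_highpass_gain_db(0.25, 20.0, zero_phase=True)
    assert g2 == pytest.approx(2 * g, abs=0.05)


def test_fused_cancels_gravity_at_fixed_orientation(rng):
    noise_sd = 0.005
    R = Rotation.from_euler("xyz", [30, -40, 70], degrees=True)
    g_sensor = R.inv().apply([0, 0, 1.0])
    n = 20 * 120
    accel = g_sensor + rng.normal(0, noise_sd, (n, 3))
    gyro = rng.normal(0, 0.05, (n, 3))
    linear, quats = remove_gravity_fused(accel, gyro, 20.0,
                                         stationary=np.ones(n, bool))
    rms = np.sqrt((linear[40:] ** 2).mean())
    assert rms < 2 * noise_sd
    assert np.allclose(np.linalg.norm(quats, axis=1), 1.0, atol=1e-6)


def test_fused_orientation_matches_closed_form_rotation():
    """Constant angular velocity about the gravity axis: the integrated
    orientation must match the axis-angle closed form within 0.5 degrees
    over 60 s (noise-free)."""
    rate = 20.0
    omega_dps = 10.0
    n = int(60 * rate)
    # start aligned with world (gravity along +z), rotate about z
    accel = np.tile([0.0, 0.0, 1.0], (n, 1))
    gyro = np.tile([0.0, 0.0, omega_dps], (n, 1))
    _, quats = remove_gravity_fused(accel, gyro, rate,
                                    stationary=np.zeros(n, bool))
    got = Rotation.from_quat(quats[-1], scalar_first=True)
    expected_angle = np.radians(omega_dps) * (n - 1) / rate
    expected = Rotation.from_rotvec([0, 0, expected_angle])
    err = (got.inv() * expected).magnitude()
    assert np.degrees(err) < 0.5


def test_fusion_reduces_gyro_bias_drift(rng):
    rate, n = 20.0, int(20 * 300)
    accel = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0, 0.003, (n, 3))
    gyro = np.tile([0.5, 0.0, 0.0], (n, 1))  # 0.5 deg/s bias
    def terminal_error(stationary):
        _, quats = remove_gravity_fused(accel, gyro, rate,
                                        stationary=stationary)
        R = Rotation.from_quat(quats[-1], scalar_first=True)
        g_pred = R.inv().apply([0, 0, 1.0])
        return np.degrees(np.arccos(np.clip(g_pred[2], -1, 1)))
    with_fusion = terminal_error(np.ones(n, bool))
    without = terminal_error(np.zeros(n, bool))
    assert with_fusion < without


def test_fused_requires_gyro():
    with pytest.raises(ValueError):
        remove_gravity_fused(np.zeros((100, 3)), None, 20.0)


def test_channels_vm_345():
    sig = np.tile([3.0, 4.0, 0.0], (120, 1))
    chans = derive_channels(sig, 20.0)
    assert np.allclose(chans["vm"], 5.0)
    assert np.allclose(chans["dvm"], 0.0)  # derivative of constant
    assert len(chans) == 12
    assert all(len(v) == 120 for v in chans.values())


def test_channels_rotation_invariance(rng):
    sig = rng.normal(size=(120, 3))
    chans = derive_channels(sig, 20.0)
    R = Rotation.random(rng=np.random.default_rng(7)).as_matrix()
    chans_rot = derive_channels(sig @ R.T, 20.0)
    assert np.allclose(chans_rot["vm"], chans["vm"], atol=1e-12)
    assert np.allclose(np.abs(chans_rot["pc1"]), np.abs(chans["pc1"]),
                       atol=1e-8)


def test_pc_energy_ordering(rng):
    sig = rng.normal(size=(600, 3)) * np.array([3.0, 1.0, 0.3])
    chans = derive_channels(sig, 20.0, tile_s=3.0)
    for i0 in range(0, 600, 60):
        v1 = chans["pc1"][i0:i0 + 60].var()
        v2 = chans["pc2"][i0:i0 + 60].var()
        assert v1 >= v2 - 1e-12


def test_fused_and_accel_only_agree_in_motion_band(rng):
    """Both gravity-removal paths must agree on >= 1 Hz motion."""
    rate = 20.0
    t = np.arange(int(120 * rate)) / rate
    motion = 0.3 * np.sin(2 * np.pi * 2.5 * t)
    accel = np.column_stack([motion, np.zeros_like(t), np.ones_like(t)])
    accel += rng.normal(0, 0.002, accel.shape)
    gyro = rng.normal(0, 0.05, accel.shape)
    lin_fused, _ = remove_gravity_fused(accel, gyro, rate,
                                        stationary=np.zeros(len(t), bool))
    lin_hp = remove_gravity_accel_only(accel, rate)
    sl = slice(100, -100)
    rms_ref = np.sqrt((lin_hp[sl, 0] ** 2).mean())
    rms_diff = np.sqrt(((lin_fused[sl, 0] - lin_hp[sl, 0]) ** 2).mean())
    assert rms_diff / rms_ref < 0.05
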