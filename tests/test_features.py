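"""Window segmentation/labeling rules and the fixed feature bank."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scratchkit.features import (CHANNEL_ORDER, N_PER_SENSOR,
                                 TDA_FEATURE_NAMES, TIME_FREQ_FEATURE_NAMES,
                                 WindowSet, assemble_features,
                                 interpretable_features, segment_windows,
                                 sensor_features, time_freq_features)
from scratchkit.movement import MovementMask
from scratchkit.records import AnnotationTrack, Event


def _full_mask(seconds, start=0.0):
    return MovementMask(seconds=np.ones(seconds, bool), start_s=start)


def _ws(rng, n_seconds=60, hop_s=1.5, annotations=None):
    sig = {"acc": rng.normal(0, 0.1, (n_seconds * 20, 3))}
    return segment_windows(_full_mask(n_seconds), sig, 0.0,
                           annotations=annotations, hand="left",
                           hop_s=hop_s)


def test_sixty_second_run_gives_39_training_windows(rng):
    ws = _ws(rng, 60)
    assert len(ws) == 39  # floor((60 - 3) / 1.5) + 1


def test_deployment_tiling_is_non_overlapping(rng):
    ws = _ws(rng, 60, hop_s=3.0)
    starts = [w.start_s for w in ws.windows]
    assert starts == [3.0 * k for k in range(20)]


@pytest.mark.parametrize("scratch_s,expected", [
    (1.6, 1),   # more than 1 s annotated scratch
    (1.0, 0),   # exactly 1 s: strict inequality
    (0.4, 0),
])
def test_window_label_rule(rng, scratch_s, expected):
    ann = AnnotationTrack([Event("scratch", 0.0, scratch_s, "left"),
                           Event("in-bed still", scratch_s, 60.0, "left")])
    ws = _ws(rng, 6, annotations=ann)
    assert ws.windows[0].label == expected


def test_windows_need_one_second_of_movement(rng):
    flags = np.zeros(30, bool)
    flags[10:20] = True  # a single 10-s movement run
    mask = MovementMask(seconds=flags, start_s=0.0)
    sig = {"acc": rng.normal(0, 0.1, (30 * 20, 3))}
    ws = segment_windows(mask, sig, 0.0, hand="left")
    for w in ws.windows:
        lo, hi = w.start_s, w.start_s + 3.0
        overlap = max(0.0, min(hi, 20.0) - max(lo, 10.0))
        assert overlap >= 1.0
    # windows straddling the run edge are flagged as edge cases
    assert any(w.edge_flag for w in ws.windows)


def test_dominant_frequency_of_pure_tone():
    t = np.arange(60) / 20.0
    x = np.sin(2 * np.pi * 3.0 * t)
    feats = dict(zip(TIME_FREQ_FEATURE_NAMES, time_freq_features(x)))
    assert abs(feats["domfreq"] - 3.0) <= 20.0 / 60  # one FFT bin
    assert feats["zcr"] > 0.2


def test_constant_window_guards():
    feats = dict(zip(TIME_FREQ_FEATURE_NAMES,
                     time_freq_features(np.full(60, 2.5))))
    assert feats["mean"] == 2.5
    for name in ("sd", "zcr", "skew", "kurt", "domfreq", "dompower",
                 "specentropy", "speccentroid", "autocorr1"):
        assert feats[name] == 0.0


def test_white_noise_spectral_entropy_near_maximum(rng):
    """Flat-spectrum limit: entropy approaches log(bin count).  The
    single-periodogram estimator is biased low by about 1 - gamma (the
    bins are exponentially distributed), hence the 15% band."""
    vals = [dict(zip(TIME_FREQ_FEATURE_NAMES,
                     time_freq_features(rng.normal(size=60))))["specentropy"]
            for _ in range(50)]
    n_bins = 30  # rfft bins of a 60-sample window, DC excluded
    assert abs(np.mean(vals) - np.log(n_bins)) < 0.15 * np.log(n_bins)
    # and a pure tone is far from the maximum
    t = np.arange(60) / 20.0
    tone = dict(zip(TIME_FREQ_FEATURE_NAMES,
                    time_freq_features(np.sin(2 * np.pi * 3 * t))))
    assert tone["specentropy"] < 0.5 * np.log(n_bins)


def test_interpretable_feature_vector_width(rng):
    assert interpretable_features(rng.normal(size=60)).shape == (27,)
    assert len(TIME_FREQ_FEATURE_NAMES) == 16
    assert len(TDA_FEATURE_NAMES) == 11
    assert len(CHANNEL_ORDER) == 12
    assert N_PER_SENSOR == 338


def test_matrix_widths_accel_and_both(rng):
    n_sec = 12
    sig = {"acc": rng.normal(0, 0.1, (n_sec * 20, 3)),
           "gyr": rng.normal(0, 0.5, (n_sec * 20, 3))}
    ws = segment_windows(_full_mask(n_sec), sig, 0.0, hand="left")
    X_acc, meta = assemble_features(ws, sensors=("acc",))
    assert X_acc.shape[1] == 338
    X_both, _ = assemble_features(ws, sensors=("acc", "gyr"))
    assert X_both.shape[1] == 676
    assert len(set(X_both.columns)) == 676  # unique, stable names
    assert np.isfinite(X_both.to_numpy()).all()
    with pytest.raises(ValueError):
        assemble_features(WindowSet(ws.windows, {"acc": sig["acc"]}),
                          sensors=("acc", "gyr"))


def test_feature_extraction_deterministic(rng):
    sl = rng.normal(size=(60, 3))
    assert np.array_equal(sensor_features(sl), sensor_features(sl))


def test_rotation_invariance_of_vm_pc_tda_features(rng):
    """VM features (incl. TDA-on-VM), PC projections, and PC explained
    variances are unchanged under rotations of the raw axes."""
    sl = rng.normal(size=(60, 3)) * np.array([2.0, 1.0, 0.5])
    names = np.array([f"acc_{ch}_{f}" for ch in CHANNEL_ORDER
                      for f in TIME_FREQ_FEATURE_NAMES + TDA_FEATURE_NAMES]
                     + [f"acc_{f}" for f in (
                         "corr_xy", "corr_xz", "corr_yz", "corr_dxdy",
                         "corr_dxdz", "corr_dydz", "corr_x_vm", "corr_y_vm",
                         "corr_z_vm", "pc1_evr", "pc2_evr", "sma",
                         "tilt_mean", "tilt_sd")])
    base = sensor_features(sl)
    keep = np.array([n.split("_")[1] in ("vm", "dvm", "pc1", "pc2", "dpc1",
                                         "dpc2")
                     or n.endswith("_evr") for n in names])
    for k in range(20):
        R = Rotation.random(rng=np.random.default_rng(k)).as_matrix()
        rot = sensor_features(sl @ R.T)
        assert np.allclose(rot[keep], base[keep], atol=1e-8), k
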