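"""Feature selection, ensemble training, and leave-one-subject-out
evaluation bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score)

from scratchkit.model import (DL_FEATURE_NAMES, confusion_metrics,
                              evaluate_loso, recursive_feature_elimination,
                              train_ensemble)


def _planted_matrix(rng, n=400, n_noise=50):
    """5 informative features with complementary signal + pure noise.

    The label is a threshold on the sum of five independent latent
    factors, each observed through one feature, so every informative
    feature carries signal the others cannot supply."""
    z = rng.normal(size=(n, 5))
    y = (z.sum(axis=1) > 0).astype(int)
    cols = {f"info_{i}": z[:, i] + rng.normal(0, 0.1, n) for i in range(5)}
    for i in range(n_noise):
        cols[f"noise_{i}"] = rng.normal(size=n)
    return pd.DataFrame(cols), y


def test_rfe_identity_at_full_size(rng):
    X, y = _planted_matrix(rng, n=200, n_noise=10)
    cols, curve = recursive_feature_elimination(X, y, target_k=X.shape[1],
                                                seed=0)
    assert set(cols) == set(X.columns)
    assert len(curve) == 1


def test_rfe_recovers_planted_features(rng):
    X, y = _planted_matrix(rng)
    cols, curve = recursive_feature_elimination(X, y, target_k=10, seed=0)
    assert len(cols) == 10
    kept_informative = [c for c in cols if c.startswith("info_")]
    assert len(kept_informative) == 5  # all informative features survive
    assert curve["n_features"].iloc[-1] == 10
    with pytest.raises(ValueError):
        recursive_feature_elimination(X, y, target_k=X.shape[1] + 1)


def test_confusion_metrics_hand_computed():
    """TP=3, FP=1, FN=1, TN=15."""
    y_true = [1] * 4 + [0] * 16
    y_pred = [1, 1, 1, 0] + [1] + [0] * 15
    m = confusion_metrics(y_true, y_pred)
    assert m["recall"] == pytest.approx(0.75)
    assert m["ppv"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(0.9375)
    assert m["f1"] == pytest.approx(0.75)
    assert m["accuracy"] == pytest.approx(18 / 20)
    assert m["npv"] == pytest.approx(15 / 16)
    assert m["prevalence"] == pytest.approx(4 / 20)


def test_confusion_metrics_match_sklearn(rng):
    y_true = rng.integers(0, 2, 200)
    y_pred = rng.integers(0, 2, 200)
    m = confusion_metrics(y_true, y_pred)
    assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
    assert m["recall"] == pytest.approx(recall_score(y_true, y_pred))
    assert m["ppv"] == pytest.approx(precision_score(y_true, y_pred))
    assert m["f1"] == pytest.approx(f1_score(y_true, y_pred))


@pytest.fixture(scope="module")
def tiny_cohort():
    """Three subjects of separable windows: tone vs noise."""
    rng = np.random.default_rng(3)
    per_subj = 80
    frames, labels, subjects, tensors = [], [], [], []
    t = np.arange(60) / 20.0
    for s in range(3):
        y = (rng.random(per_subj) < 0.5).astype(int)
        freq = 2.5 + 0.5 * s
        x = rng.normal(0, 0.1, (per_subj, 3, 60))
        x[y == 1, 0, :] += 0.5 * np.sin(2 * np.pi * freq * t)[None, :]
        from scratchkit.features import sensor_features, sensor_feature_names
        X = pd.DataFrame(
            [sensor_features(x[i].T) for i in range(per_subj)],
            columns=sensor_feature_names("acc"))
        frames.append(X)
        labels.append(y)
        subjects.append(np.full(per_subj, f"S{s}"))
        tensors.append(x)
    return (pd.concat(frames, ignore_index=True), np.concatenate(labels),
            np.concatenate(subjects), np.concatenate(tensors))


def test_train_ensemble_appends_ten_learned_features(tiny_cohort):
    X, y, subj, nn = tiny_cohort
    model = train_ensemble(X, y, nn, epochs=2, seed=0)
    assert len(DL_FEATURE_NAMES) == 10
    assert len(model.selected_features) == 16  # default k for accel-only
    # learned + interpretable pool the selection draws from
    assert set(model.selected_features) <= set(X.columns) | set(
        DL_FEATURE_NAMES)
    proba = model.predict_proba(X, nn)
    assert np.all((proba >= 0) & (proba <= 1))


def test_loso_fold_bookkeeping_and_separable_performance(tiny_cohort):
    X, y, subj, nn = tiny_cohort
    report = evaluate_loso(X, y, subj, nn, epochs=2, seed=0)
    assert len(report.per_fold) == 3  # one fold per subject
    for fold in report.folds:
        assert fold["subject"] not in fold["train_subjects"]  # no leakage
    assert report.mean["auc"] > 0.95  # separable case
    assert (report.per_fold["prevalence"] > 0.2).all()


def test_gyro_features_help_on_finger_scratches():
    """On a finger-scratch night (accelerometer SNR low, wrist rotation
    still visible) the gyroscope feature set must not hurt in-sample
    separation."""
    import lightgbm as lgb
    from sklearn.metrics import roc_auc_score
    from scratchkit.features import segment_windows, assemble_features
    from scratchkit.movement import MovementMask
    from scratchkit.pipeline import PipelineConfig, preprocess_hand
    from scratchkit.synthetic import (NightScenario, ScheduledEvent,
                                      simulate_night)
    events = [ScheduledEvent("scratch", 120.0 + 90 * k, 138.0 + 90 * k,
                             "left", {"freq_hz": 3.5, "amp_g": 0.05})
              for k in range(6)]
    events += [ScheduledEvent("non-scratch movement", 60.0 + 90 * k,
                              75.0 + 90 * k, "left") for k in range(6)]
    night = simulate_night(NightScenario(duration_h=0.25, events=events,
                                         tso=(0.0, 900.0), seed=17))
    hn = preprocess_hand(night.recording_left, PipelineConfig(calibrate=False))
    # classify every window (bypass the movement filter: finger scratches
    # are exactly what it tends to lose)
    all_mask = MovementMask(seconds=np.ones(900, bool), start_s=hn.start_s)
    ws = segment_windows(all_mask, hn.signals, hn.start_s,
                         annotations=night.annotations, hand="left")
    y = ws.labels()
    aucs = {}
    for sensors in (("acc",), ("acc", "gyr")):
        X, _ = assemble_features(ws, sensors=sensors)
        clf = lgb.LGBMClassifier(n_estimators=60, random_state=0,
                                 verbosity=-1)
        clf.fit(X, y)
        aucs[sensors] = roc_auc_score(y, clf.predict_proba(X)[:, 1])
    assert aucs[("acc", "gyr")] >= aucs[("acc",)] - 1e-6


def test_loso_refuses_single_subject(tiny_cohort):
    X, y, subj, nn = tiny_cohort
    one = subj == "S0"
    with pytest.raises(ValueError):
        evaluate_loso(X[one], y[one], subj[one], nn[one])
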