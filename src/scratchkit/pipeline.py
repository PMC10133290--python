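"""Stage orchestration: training and deployment flows.

Training: ingest -> calibrate -> resample -> movement mask -> gravity
removal -> 3-s overlapping windows labeled from annotations -> feature
bank (+ learned features) -> ensemble classifier with LOSO evaluation.

Deployment: calibrate/resample -> movement filter -> non-wear -> TSO ->
non-overlapping 3-s tiles -> classify -> per-night endpoints.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .endpoints import compute_endpoints, predict_night
from .errors import StageError
from .features import WIN_S, assemble_features, segment_windows
from .movement import (THETA_COV, THETA_SD, MovementMask, NonwearMask,
                       detect_movement, detect_nonwear)
from .preprocess import (autocalibrate, remove_gravity_accel_only,
                         remove_gravity_fused, resample)
from .records import SensorRecording
from .synthetic import SyntheticNight
from .tso import TSOWindow, combine_hands, tso_from_reference, tso_heuristic

SENSORS_ACC = ("acc",)
SENSORS_BOTH = ("acc", "gyr")


@dataclass
class PipelineConfig:
    sensors: tuple[str, ...] = SENSORS_ACC
    gravity_removal: str = "accel_only"  # or "fused"
    theta_cov: float = THETA_COV
    theta_sd: float = THETA_SD
    tso_mode: str = "reference"  # or "heuristic"
    target_k: int | None = None
    epochs: int = 8
    seed: int = 0
    calibrate: bool = True
    out_dir: Path | None = None

    def __post_init__(self):
        if self.gravity_removal not in ("accel_only", "fused"):
            raise ValueError("gravity_removal must be accel_only or fused")
        if self.tso_mode not in ("reference", "heuristic"):
            raise ValueError("tso_mode must be reference or heuristic")
        if "gyr" not in self.sensors and self.gravity_removal == "fused":
            warnings.warn("fused gravity removal with accel-only features")


@dataclass
class HandNight:
    """Preprocessed single hand-night: 20 Hz grid artifacts."""

    rec20: SensorRecording
    mask: MovementMask
    nonwear: NonwearMask
    signals: dict[str, np.ndarray]

    @property
    def start_s(self) -> float:
        return self.rec20.start_s


def preprocess_hand(rec: SensorRecording, config: PipelineConfig) -> HandNight:
    """Calibrate, resample to 20 Hz, movement mask, non-wear, gravity
    removal; returns the per-hand artifact bundle."""
    if config.calibrate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, rec = autocalibrate(rec)
    rec20 = resample(rec)
    mask = detect_movement(rec20.accel, start_s=rec20.start_s,
                           rate_hz=rec20.rate_hz,
                           theta_cov=config.theta_cov,
                           theta_sd=config.theta_sd)
    nonwear = detect_nonwear(mask, rec20.temp, temp_rate_hz=rec20.rate_hz)
    if config.gravity_removal == "fused" and rec20.gyro is not None:
        sec_idx = np.minimum(
            np.floor(rec20.timestamps - rec20.start_s).astype(int),
            len(mask.seconds) - 1)
        stationary = ~mask.seconds[sec_idx]
        linear, _ = remove_gravity_fused(rec20.accel, rec20.gyro,
                                         rec20.rate_hz, stationary=stationary)
    else:
        linear = remove_gravity_accel_only(rec20.accel, rec20.rate_hz)
    signals = {"acc": linear}
    if rec20.gyro is not None:
        signals["gyr"] = np.radians(rec20.gyro)
    return HandNight(rec20=rec20, mask=mask, nonwear=nonwear, signals=signals)


def night_tso(night: SyntheticNight, hands: dict[str, HandNight],
              config: PipelineConfig) -> TSOWindow | None:
    if config.tso_mode == "reference":
        return tso_from_reference(night.true_tso)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_hand = [tso_heuristic(h.rec20, h.nonwear) for h in hands.values()]
    return combine_hands(*per_hand) if len(per_hand) == 2 else per_hand[0]


def training_windows(night: SyntheticNight, subject: str, night_id: str,
                     config: PipelineConfig,
                     hands: dict[str, HandNight] | None = None):
    """Labeled overlapping windows and features for one night (both hands).

    Windows are restricted to the reference TSO (the annotated span).
    Returns (features, meta, labels, nn_input).
    """
    if hands is None:
        hands = {h: preprocess_hand(night.recording(h), config)
                 for h in ("left", "right")}
    X_parts, meta_parts, nn_parts = [], [], []
    for hand, hn in hands.items():
        ws = segment_windows(hn.mask, hn.signals, hn.start_s,
                             annotations=night.annotations, hand=hand,
                             subject=subject, night=night_id)
        keep = [i for i, w in enumerate(ws.windows)
                if (w.start_s >= night.true_tso.start_s
                    and w.start_s + WIN_S <= night.true_tso.end_s)]
        if not keep:
            continue
        ws.windows = [ws.windows[i] for i in keep]
        X, meta = assemble_features(ws, sensors=config.sensors)
        X_parts.append(X)
        meta_parts.append(meta)
        nn_parts.append(ws.nn_input(config.sensors))
    if not X_parts:
        return None
    return (pd.concat(X_parts, ignore_index=True),
            pd.concat(meta_parts, ignore_index=True),
            np.concatenate(nn_parts))


def build_training_data(nights: list[SyntheticNight], subject_ids: list[str],
                        config: PipelineConfig):
    """Cohort-level training matrices: features, labels, subjects, tensors."""
    X_all, meta_all, nn_all = [], [], []
    for i, (night, subj) in enumerate(zip(nights, subject_ids)):
        out = training_windows(night, subj, f"N{i:03d}", config)
        if out is None:
            continue
        X, meta, nn = out
        X_all.append(X)
        meta_all.append(meta)
        nn_all.append(nn)
    X = pd.concat(X_all, ignore_index=True)
    meta = pd.concat(meta_all, ignore_index=True)
    return X, meta, np.concatenate(nn_all)


def deploy_night(model, night: SyntheticNight, config: PipelineConfig,
                 subject: str = "?", night_id: str = "?",
                 hands: dict[str, HandNight] | None = None):
    """Deploy a trained model on one night: movement filter, non-wear,
    TSO, non-overlapping tiling, classification, endpoints."""
    if hands is None:
        hands = {h: preprocess_hand(night.recording(h), config)
                 for h in ("left", "right")}
    tso = night_tso(night, hands, config)
    if tso is None:
        warnings.warn("no TSO found; empty endpoints")
        return compute_endpoints(pd.DataFrame(), TSOWindow(0, 1), subject,
                                 night_id)
    hand_data = {h: {"signals": hn.signals, "mask": hn.mask,
                     "start_s": hn.start_s}
                 for h, hn in hands.items()}
    tiles = predict_night(model, hand_data, tso,
                          nonwear_by_hand={h: hn.nonwear
                                           for h, hn in hands.items()})
    return compute_endpoints(tiles, tso, subject, night_id)


def run_deployment_pipeline(model, nights, config: PipelineConfig,
                            subjects=None):
    """Deploy a trained model on a list of nights; one endpoint row per
    night, in deployment stage order (movement filter, non-wear, TSO,
    tiling, classification, endpoints)."""
    subjects = subjects or ["?"] * len(nights)
    return [deploy_night(model, night, config, subject=s,
                         night_id=f"N{i:03d}")
            for i, (night, s) in enumerate(zip(nights, subjects))]


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def write_manifest(path: Path, stages: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(stages, indent=2, default=str))


def run_training_pipeline(nights, subject_ids, config: PipelineConfig):
    """Chain ingest -> preprocess -> windows -> features -> LOSO + model."""
    from .model import evaluate_loso, train_ensemble
    try:
        X, meta, nn = build_training_data(nights, subject_ids, config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("feature-extraction", str(exc)) from exc
    labels = meta["label"].to_numpy(dtype=int)
    subjects = meta["subject"].to_numpy()
    try:
        report = evaluate_loso(X, labels, subjects, nn,
                               sensors=config.sensors,
                               target_k=config.target_k,
                               epochs=config.epochs, seed=config.seed)
        model = train_ensemble(X, labels, nn, sensors=config.sensors,
                               target_k=config.target_k,
                               epochs=config.epochs, seed=config.seed)
    except Exception as exc:  # noqa: BLE001
        raise StageError("model", str(exc)) from exc
    if config.out_dir is not None:
        write_manifest(Path(config.out_dir) / "manifest.json", {
            "n_nights": len(nights),
            "n_windows": len(X),
            "feature_hash": _hash_array(X.to_numpy()),
            "seed": config.seed,
            "sensors": list(config.sensors),
        })
    return model, report
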