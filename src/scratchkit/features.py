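"""Window segmentation, labeling, and the fixed interpretable feature bank.

Movement periods are cut into 3-s windows (1.5-s overlap for training;
non-overlapping tiles in deployment); a window is kept when at least 1 s
of it is movement and labeled scratch when strictly more than 1 s of it is
annotated scratch.  Per sensor, 12 channels (x, y, z, pc1, pc2, vm and
their derivatives) each yield 27 features: 16 time/frequency statistics
and the 11 topological features; 14 cross-channel features complete the
338-wide interpretable bank per sensor (676 with both sensors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .movement import MovementMask
from .preprocess import _pc_projections
from .records import AnnotationTrack
from .topology import TDA_FEATURE_NAMES, tda_features

WIN_S = 3.0
HOP_TRAIN_S = 1.5
RATE_HZ = 20.0
WIN_SAMPLES = int(WIN_S * RATE_HZ)  # 60
DOMFREQ_MAX_HZ = 10.0

TIME_FREQ_FEATURE_NAMES = (
    "mean", "sd", "min", "max", "range", "rms", "iqr", "mad",
    "skew", "kurt", "zcr", "autocorr1",
    "domfreq", "dompower", "specentropy", "speccentroid",
)
CHANNEL_ORDER = ("x", "y", "z", "pc1", "pc2", "vm",
                 "dx", "dy", "dz", "dpc1", "dpc2", "dvm")
CROSS_FEATURE_NAMES = (
    "corr_xy", "corr_xz", "corr_yz",
    "corr_dxdy", "corr_dxdz", "corr_dydz",
    "corr_x_vm", "corr_y_vm", "corr_z_vm",
    "pc1_evr", "pc2_evr", "sma", "tilt_mean", "tilt_sd",
)
N_PER_CHANNEL = len(TIME_FREQ_FEATURE_NAMES) + len(TDA_FEATURE_NAMES)  # 27
N_PER_SENSOR = len(CHANNEL_ORDER) * N_PER_CHANNEL + len(CROSS_FEATURE_NAMES)

CATALOG_VERSION = "1.0"


@dataclass(frozen=True)
class Window:
    subject: str
    night: str
    hand: str
    start_s: float
    start_idx: int
    label: int | None
    edge_flag: bool


@dataclass
class WindowSet:
    """Windows plus references to the full-night 3-axis source signals.

    ``signals`` maps sensor name ("acc", "gyr") to the gravity-free (n, 3)
    series on the 20 Hz grid the window indices refer to.
    """

    windows: list[Window]
    signals: dict[str, np.ndarray]
    rate_hz: float = RATE_HZ
    win_samples: int = WIN_SAMPLES
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.windows)

    def slices(self, sensor: str) -> np.ndarray:
        """(n_windows, win_samples, 3) stack of raw window slices."""
        sig = self.signals[sensor]
        return np.stack([sig[w.start_idx:w.start_idx + self.win_samples]
                         for w in self.windows])

    def labels(self) -> np.ndarray:
        if any(w.label is None for w in self.windows):
            raise ValueError("window labels undefined (prediction mode)")
        return np.array([w.label for w in self.windows], dtype=int)

    def nn_input(self, sensors: tuple[str, ...]) -> np.ndarray:
        """(n_windows, channels, win_samples) tensor for the extractors."""
        parts = [self.slices(s).transpose(0, 2, 1) for s in sensors]
        return np.concatenate(parts, axis=1)


def _movement_occupancy(mask: MovementMask, t0: float, t1: float) -> float:
    sec = np.arange(len(mask.seconds), dtype=float) + mask.start_s
    overlap = np.clip(np.minimum(sec + 1.0, t1) - np.maximum(sec, t0), 0.0, 1.0)
    return float((overlap * mask.seconds).sum())


def segment_windows(
    mask: MovementMask,
    signals: dict[str, np.ndarray],
    start_s: float,
    annotations: AnnotationTrack | None = None,
    hand: str = "left",
    subject: str = "?",
    night: str = "?",
    win_s: float = WIN_S,
    hop_s: float = HOP_TRAIN_S,
    rate_hz: float = RATE_HZ,
    min_movement_s: float = 1.0,
    scratch_label_s: float = 1.0,
) -> WindowSet:
    """Windows at hop multiples; kept when >= ``min_movement_s`` of the
    window is movement; labeled scratch when annotated scratch strictly
    exceeds ``scratch_label_s`` (training hop 1.5 s; deployment hop 3 s)."""
    n = min(len(sig) for sig in signals.values())
    win = int(win_s * rate_hz)
    hop = int(hop_s * rate_hz)
    windows: list[Window] = []
    for i0 in range(0, n - win + 1, hop):
        t0 = start_s + i0 / rate_hz
        t1 = t0 + win_s
        mov = _movement_occupancy(mask, t0, t1)
        if mov < min_movement_s:
            continue
        label = None
        if annotations is not None:
            occ = annotations.occupancy("scratch", t0, t1, hand=hand)
            label = int(occ > scratch_label_s)
        windows.append(Window(subject=subject, night=night, hand=hand,
                              start_s=t0, start_idx=i0, label=label,
                              edge_flag=mov < win_s - 1e-9))
    return WindowSet(windows=windows, signals=signals, rate_hz=rate_hz,
                     win_samples=win,
                     meta={"hop_s": hop_s, "start_s": start_s})


def time_freq_features(x: np.ndarray, rate_hz: float = RATE_HZ) -> np.ndarray:
    """The 16 time/frequency statistics of one channel window."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = x.mean()
    sd = x.std(ddof=1) if n > 1 else 0.0
    xmin, xmax = x.min(), x.max()
    rms = float(np.sqrt((x**2).mean()))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    mad = float(np.median(np.abs(x - np.median(x))))
    if sd > 0:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x))
        c = x - mean
        zcr = float((c[:-1] * c[1:] < 0).sum() / (n - 1))
        ac_sd = c[:-1].std() * c[1:].std()
        autocorr1 = (float(np.mean((c[:-1] - c[:-1].mean())
                                   * (c[1:] - c[1:].mean())) / ac_sd)
                     if ac_sd > 0 else 0.0)
    else:
        skew = kurt = zcr = autocorr1 = 0.0

    # spectrum: mean removed (Hann leakage would smear DC into bin 1),
    # Hann window, magnitude-squared rfft, DC excluded
    w = np.hanning(n)
    psd = np.abs(np.fft.rfft((x - mean) * w)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    band = (freqs > 0) & (freqs <= DOMFREQ_MAX_HZ)
    p = psd[band]
    f = freqs[band]
    total = p.sum()
    if total > 0:
        k = int(np.argmax(p))
        domfreq, dompower = float(f[k]), float(p[k])
        q = p[p > 0] / total
        specentropy = float(-(q * np.log(q)).sum())
        speccentroid = float((f * p).sum() / total)
    else:
        domfreq = dompower = specentropy = speccentroid = 0.0
    return np.array([mean, sd, xmin, xmax, xmax - xmin, rms, iqr, mad,
                     skew, kurt, zcr, autocorr1,
                     domfreq, dompower, specentropy, speccentroid])


def interpretable_features(x: np.ndarray, rate_hz: float = RATE_HZ) -> np.ndarray:
    """All 27 per-channel features (time/frequency + topological)."""
    return np.concatenate([time_freq_features(x, rate_hz), tda_features(x)])


def window_channels(slice3: np.ndarray, rate_hz: float = RATE_HZ
                    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """The 12 channels of one (win, 3) slice plus PC eigenvalues."""
    slice3 = np.asarray(slice3, dtype=float)
    vm = np.linalg.norm(slice3, axis=1)
    pcs, evals = _pc_projections(slice3)
    chans = {"x": slice3[:, 0], "y": slice3[:, 1], "z": slice3[:, 2],
             "pc1": pcs[:, 0], "pc2": pcs[:, 1], "vm": vm}
    dt = 1.0 / rate_hz
    for name in list(chans):
        chans["d" + name] = np.gradient(chans[name], dt)
    return chans, evals


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cross_channel_features(chans: dict[str, np.ndarray],
                           evals: np.ndarray) -> np.ndarray:
    x, y, z, vm = chans["x"], chans["y"], chans["z"], chans["vm"]
    dx, dy, dz = chans["dx"], chans["dy"], chans["dz"]
    ev_total = evals.sum()
    evr1 = float(evals[0] / ev_total) if ev_total > 0 else 0.0
    evr2 = float(evals[1] / ev_total) if ev_total > 0 else 0.0
    sma = float(np.mean(np.abs(x) + np.abs(y) + np.abs(z)))
    tilt = np.degrees(np.arctan2(np.sqrt(x**2 + y**2), z))
    return np.array([
        _safe_corr(x, y), _safe_corr(x, z), _safe_corr(y, z),
        _safe_corr(dx, dy), _safe_corr(dx, dz), _safe_corr(dy, dz),
        _safe_corr(x, vm), _safe_corr(y, vm), _safe_corr(z, vm),
        evr1, evr2, sma, float(tilt.mean()),
        float(tilt.std(ddof=1)) if len(tilt) > 1 else 0.0,
    ])


def sensor_feature_names(sensor: str) -> list[str]:
    names = [f"{sensor}_{ch}_{feat}"
             for ch in CHANNEL_ORDER
             for feat in TIME_FREQ_FEATURE_NAMES + TDA_FEATURE_NAMES]
    names += [f"{sensor}_{feat}" for feat in CROSS_FEATURE_NAMES]
    return names


def sensor_features(slice3: np.ndarray, rate_hz: float = RATE_HZ) -> np.ndarray:
    """The 338 interpretable features of one sensor's window slice."""
    chans, evals = window_channels(slice3, rate_hz)
    parts = [interpretable_features(chans[ch], rate_hz) for ch in CHANNEL_ORDER]
    parts.append(cross_channel_features(chans, evals))
    return np.concatenate(parts)


def assemble_features(ws: WindowSet,
                      sensors: tuple[str, ...] = ("acc",)
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interpretable feature matrix (rows = windows) and window metadata.

    338 columns per sensor (676 for acc+gyr); non-finite entries are
    imputed to 0.
    """
    for s in sensors:
        if s not in ws.signals:
            raise ValueError(f"sensor {s!r} not present in window set")
    columns = [n for s in sensors for n in sensor_feature_names(s)]
    rows = np.empty((len(ws), len(columns)))
    for i, w in enumerate(ws.windows):
        feats = [sensor_features(
            ws.signals[s][w.start_idx:w.start_idx + ws.win_samples],
            ws.rate_hz) for s in sensors]
        rows[i] = np.concatenate(feats)
    rows = np.nan_to_num(rows, nan=0.0, posinf=0.0, neginf=0.0)
    X = pd.DataFrame(rows, columns=columns)
    X.attrs["catalog_version"] = CATALOG_VERSION
    meta = pd.DataFrame({
        "subject": [w.subject for w in ws.windows],
        "night": [w.night for w in ws.windows],
        "hand": [w.hand for w in ws.windows],
        "start_s": [w.start_s for w in ws.windows],
        "label": [w.label for w in ws.windows],
        "edge_flag": [w.edge_flag for w in ws.windows],
    })
    return X, meta
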