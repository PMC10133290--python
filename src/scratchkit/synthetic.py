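"""Seeded simulator of annotated nocturnal hand-nights.

Emulates what a wrist-worn 6-axis logger records during a clinic night:
quiet sleep (rotated gravity plus device noise), oscillatory scratch bouts
(hand scratches at 0.3-1.0 g, finger scratches at 0.02-0.08 g, 2-5 Hz),
posture turns, out-of-bed excursions, and non-wear (frozen signal with the
case temperature decaying below 25 deg C).  Ground-truth annotations are
written at millisecond resolution with the clinical label vocabulary, so
every downstream stage - alignment, movement detection, sleep-window
estimation, classification, endpoints - can be exercised and scored without
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .errors import OverlapError
from .records import AnnotationTrack, Event, Interval, SensorRecording

__all__ = ["ScheduledEvent", "NightScenario", "SyntheticNight",
           "simulate_night", "simulate_cohort"]

#: annotation timestamps are rounded to this resolution (seconds)
ANNOTATION_RESOLUTION_S = 1e-3
_RAMP_S = 3.0  # posture-turn duration


@dataclass(frozen=True)
class ScheduledEvent:
    label: str
    start_s: float
    end_s: float
    hand: str
    params: dict = field(default_factory=dict)


@dataclass
class NightScenario:
    """Full description of one simulated night (both hands)."""

    duration_h: float = 8.0
    sample_rate_hz: float = 50.0
    events: list[ScheduledEvent] = field(default_factory=list)
    scratch_freq_hz: float | None = None  # None: draw uniformly in 2-5 Hz
    scratch_amp_g: float = 0.5
    noise_sd_g: float = 0.01
    gyro_noise_sd_dps: float = 0.3
    temp_base_c: float = 32.0
    tso: tuple[float, float] | None = None  # seconds from night start
    nonwear: list[tuple[float, float]] = field(default_factory=list)
    start_epoch_s: float = 1_700_000_000.0 + 79200.0  # a 22:00 local start
    seed: int = 0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        dur = self.duration_h * 3600.0
        if self.tso is None:
            self.tso = (600.0, dur - 600.0) if dur > 1800.0 else (0.0, dur)
        for ev in self.events:
            if not (0.0 <= ev.start_s < ev.end_s <= dur):
                raise ValueError(f"event outside night span: {ev}")
            if ev.label == "scratch" and not (
                self.tso[0] - 1e-9 <= ev.start_s and ev.end_s <= self.tso[1] + 1e-9
            ):
                raise ValueError("scratch events must lie inside the TSO")
        for hand in ("left", "right"):
            evs = sorted((e for e in self.events if e.hand == hand),
                         key=lambda e: e.start_s)
            for a, b in zip(evs, evs[1:]):
                if b.start_s < a.end_s:
                    raise OverlapError(f"overlapping events on {hand} hand")

    @property
    def duration_s(self) -> float:
        return self.duration_h * 3600.0


@dataclass
class SyntheticNight:
    recording_left: SensorRecording
    recording_right: SensorRecording
    annotations: AnnotationTrack
    true_tso: Interval
    true_nonwear: list[Interval]
    scenario: NightScenario | None = None

    def recording(self, hand: str) -> SensorRecording:
        return self.recording_left if hand == "left" else self.recording_right


def _random_orientation(rng) -> Rotation:
    return Rotation.from_quat(rng.normal(size=4) / 1.0, scalar_first=False)


def _orientation_path(rng, t: np.ndarray, turn_times: list[float]) -> Rotation:
    """Piecewise-constant orientation with 3-s smooth turns at `turn_times`."""
    key_t = [t[0] - 1.0]
    key_r = [_random_orientation(rng)]
    for tc in sorted(turn_times):
        tc = float(np.clip(tc, t[0], t[-1] - _RAMP_S - 0.1))
        if tc <= key_t[-1] + _RAMP_S:
            continue
        key_t.append(tc)
        key_r.append(key_r[-1])
        key_t.append(tc + _RAMP_S)
        key_r.append(_random_orientation(rng))
    key_t.append(t[-1] + 1.0)
    key_r.append(key_r[-1])
    slerp = Slerp(key_t, Rotation.concatenate(key_r))
    return slerp(t)


def _oscillation(rng, n: int, rate: float, freq: float, amp: float) -> np.ndarray:
    """Amplitude-modulated sinusoid, +-10% jittered frequency, Hann onset."""
    tt = np.arange(n) / rate
    f_inst = freq * (1.0 + 0.1 * np.sin(2 * np.pi * rng.uniform(0.1, 0.4) * tt
                                        + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(f_inst) / rate
    env = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.3, 0.9) * tt
                             + rng.uniform(0, 2 * np.pi))
    taper = np.ones(n)
    edge = max(2, int(0.25 * rate))
    if n > 2 * edge:
        w = np.hanning(2 * edge)
        taper[:edge], taper[-edge:] = w[:edge], w[edge:]
    return amp * env * np.sin(phase + rng.uniform(0, 2 * np.pi)) * taper


def _smooth_noise(rng, n: int, rate: float, cutoff_hz: float, amp: float,
                  axes: int = 3) -> np.ndarray:
    """Low-frequency band-limited random motion (posture shifts, fidgeting)."""
    from scipy.signal import butter, filtfilt
    x = rng.normal(size=(max(n, 64), axes))
    b, a = butter(2, cutoff_hz, btype="low", fs=rate)
    y = filtfilt(b, a, x, axis=0)[:n]
    sd = y.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return amp * y / sd


def _round_ms(x: float) -> float:
    return round(x / ANNOTATION_RESOLUTION_S) * ANNOTATION_RESOLUTION_S


def simulate_night(scenario: NightScenario) -> SyntheticNight:
    """Generate both hand recordings and the ground-truth annotation track."""
    rng = np.random.default_rng(scenario.seed)
    rate = scenario.sample_rate_hz
    n = int(round(scenario.duration_s * rate))
    t_rel = np.arange(n) / rate
    t_abs = scenario.start_epoch_s + t_rel
    dur = scenario.duration_s
    tso = Interval(*scenario.tso)
    nonwear = [Interval(a, b) for a, b in scenario.nonwear]

    recordings = {}
    for hand in ("left", "right"):
        hand_rng = np.random.default_rng(rng.integers(2**31))
        evs = sorted((e for e in scenario.events if e.hand == hand),
                     key=lambda e: e.start_s)
        turn_times = [e.start_s for e in evs if e.label == "non-scratch movement"]
        path = _orientation_path(hand_rng, t_rel, turn_times)
        # gravity measured in the sensor frame (specific force, +1 g upward)
        g_sensor = path.inv().apply(np.array([0.0, 0.0, 1.0]))
        # body angular velocity from successive orientations (rad/s)
        dq = path[:-1].inv() * path[1:]
        omega = np.vstack([dq.as_rotvec() * rate, np.zeros((1, 3))])

        accel = g_sensor.copy()
        gyro = np.degrees(omega)
        for ev in evs:
            i0 = int(round(ev.start_s * rate))
            i1 = min(int(round(ev.end_s * rate)), n)
            m = i1 - i0
            if m <= 1:
                continue
            if ev.label == "scratch":
                freq = ev.params.get(
                    "freq_hz",
                    scenario.scratch_freq_hz
                    if scenario.scratch_freq_hz is not None
                    else hand_rng.uniform(2.0, 5.0),
                )
                amp = ev.params.get("amp_g", scenario.scratch_amp_g)
                osc = _oscillation(hand_rng, m, rate, freq, amp)
                # random mixing onto 1-2 axes
                k_active = 1 + int(hand_rng.random() < 0.7)
                w = np.zeros(3)
                idx = hand_rng.choice(3, size=k_active, replace=False)
                w[idx] = hand_rng.normal(size=k_active)
                w /= np.linalg.norm(w) + 1e-12
                accel[i0:i1] += osc[:, None] * w[None, :]
                # small consistent wrist-rotation wobble: angle theta about a
                # random axis; gyro gets theta', gravity its 1st-order tilt
                axis = hand_rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                theta0 = min(0.15, 0.2 * amp)
                tt = np.arange(m) / rate
                theta = theta0 * np.sin(2 * np.pi * freq * tt)
                dtheta = theta0 * 2 * np.pi * freq * np.cos(2 * np.pi * freq * tt)
                gyro[i0:i1] += np.degrees(dtheta)[:, None] * axis[None, :]
                accel[i0:i1] += theta[:, None] * np.cross(axis, g_sensor[i0:i1])
            elif ev.label == "non-scratch movement":
                amp = ev.params.get("amp_g", 0.25)
                accel[i0:i1] += _smooth_noise(hand_rng, m, rate, 1.5, amp)
                gyro[i0:i1] += _smooth_noise(hand_rng, m, rate, 1.5,
                                             40.0 * amp / 0.25)
            elif ev.label == "out-of-bed":
                amp = ev.params.get("amp_g", 0.3)
                walk = _oscillation(hand_rng, m, rate, 1.8, amp)
                accel[i0:i1] += (walk[:, None]
                                 * np.array([0.5, 0.3, 0.8])[None, :])
                accel[i0:i1] += _smooth_noise(hand_rng, m, rate, 2.0, amp / 2)
                gyro[i0:i1] += _smooth_noise(hand_rng, m, rate, 2.0, 60.0)

        accel += hand_rng.normal(scale=scenario.noise_sd_g, size=(n, 3))
        gyro += hand_rng.normal(scale=scenario.gyro_noise_sd_dps, size=(n, 3))

        # worn temperature: slow drift around the skin baseline
        temp = (scenario.temp_base_c
                + 1.0 * np.sin(2 * np.pi * t_rel / dur + hand_rng.uniform(0, 6))
                + hand_rng.normal(scale=0.05, size=n))

        # non-wear: frozen signal, temperature relaxing toward ambient
        tau = 180.0  # s
        ambient = 22.0
        for iv in nonwear:
            i0, i1 = int(round(iv.start_s * rate)), min(int(round(iv.end_s * rate)), n)
            if i1 <= i0:
                continue
            accel[i0:i1] = accel[max(i0 - 1, 0)]
            accel[i0:i1] += hand_rng.normal(scale=1e-4, size=(i1 - i0, 3))
            gyro[i0:i1] = hand_rng.normal(scale=1e-3, size=(i1 - i0, 3))
            dt = (np.arange(i1 - i0) / rate)
            t_start = temp[max(i0 - 1, 0)]
            temp[i0:i1] = ambient + (t_start - ambient) * np.exp(-dt / tau)
            if i1 < n:  # recovery back toward worn baseline
                m2 = min(n - i1, int(round(4 * tau * rate)))
                dt2 = np.arange(m2) / rate
                temp[i1:i1 + m2] = (temp[i1:i1 + m2]
                                    + (temp[i1 - 1] - temp[i1:i1 + m2])
                                    * np.exp(-dt2 / tau))

        recordings[hand] = SensorRecording(
            timestamps=t_abs, accel=accel, gyro=gyro, temp=temp,
            rate_hz=rate, hand=hand,
            meta={"seed": scenario.seed},
        )

    # ground truth: scheduled events plus in-bed-still fill over the TSO
    events: list[Event] = []
    for hand in ("left", "right"):
        evs = sorted((e for e in scenario.events if e.hand == hand),
                     key=lambda e: e.start_s)
        for e in evs:
            events.append(Event(e.label, _round_ms(e.start_s + scenario.start_epoch_s),
                                _round_ms(e.end_s + scenario.start_epoch_s), hand))
        cursor = tso.start_s
        for e in evs:
            lo, hi = max(e.start_s, tso.start_s), min(e.end_s, tso.end_s)
            if lo >= hi:
                continue
            if lo > cursor + ANNOTATION_RESOLUTION_S / 2:
                events.append(Event("in-bed still",
                                    _round_ms(cursor + scenario.start_epoch_s),
                                    _round_ms(lo + scenario.start_epoch_s), hand))
            cursor = max(cursor, hi)
        if cursor < tso.end_s - ANNOTATION_RESOLUTION_S / 2:
            events.append(Event("in-bed still",
                                _round_ms(cursor + scenario.start_epoch_s),
                                _round_ms(tso.end_s + scenario.start_epoch_s), hand))

    t0 = scenario.start_epoch_s
    return SyntheticNight(
        recording_left=recordings["left"],
        recording_right=recordings["right"],
        annotations=AnnotationTrack(events),
        true_tso=Interval(t0 + tso.start_s, t0 + tso.end_s),
        true_nonwear=[Interval(t0 + iv.start_s, t0 + iv.end_s) for iv in nonwear],
        scenario=scenario,
    )


def random_schedule(
    rng,
    duration_s: float,
    tso: tuple[float, float],
    scratch_rate_per_h: float,
    scratch_freq_hz: float,
    scratch_amp_g: float,
    other_rate_per_h: float = 6.0,
    scratch_dur_s: tuple[float, float] = (9.0, 24.0),
) -> list[ScheduledEvent]:
    """Draw a non-overlapping per-hand event schedule for one night."""
    events: list[ScheduledEvent] = []
    tso_h = (tso[1] - tso[0]) / 3600.0
    for hand in ("left", "right"):
        taken: list[tuple[float, float]] = []

        def place(dur_ev: float, lo: float, hi: float) -> tuple[float, float] | None:
            for _ in range(50):
                s = rng.uniform(lo, hi - dur_ev)
                if all(s + dur_ev + 2.0 <= a or s >= b + 2.0 for a, b in taken):
                    taken.append((s, s + dur_ev))
                    return (s, s + dur_ev)
            return None

        n_scratch = rng.poisson(scratch_rate_per_h * tso_h / 2.0)
        for _ in range(n_scratch):
            span = place(rng.uniform(*scratch_dur_s), tso[0] + 5, tso[1] - 5)
            if span:
                events.append(ScheduledEvent(
                    "scratch", span[0], span[1], hand,
                    {"freq_hz": float(scratch_freq_hz * rng.uniform(0.95, 1.05)),
                     "amp_g": float(scratch_amp_g * rng.uniform(0.8, 1.2))}))
        n_other = rng.poisson(other_rate_per_h * tso_h / 2.0)
        for _ in range(n_other):
            span = place(rng.uniform(5.0, 20.0), tso[0] + 5, tso[1] - 5)
            if span:
                events.append(ScheduledEvent("non-scratch movement",
                                             span[0], span[1], hand))
    return events


def simulate_cohort(
    n_subjects: int,
    nights_per_subject: int,
    severity=6.0,
    seed: int = 0,
    duration_h: float = 8.0,
    finger_fraction: float = 0.0,
    n_dropped: int = 0,
    noise_sd_g: float = 0.01,
) -> tuple[list[SyntheticNight], list[str]]:
    """Simulate a cohort with per-subject idiosyncratic scratch style.

    Each subject draws a scratch frequency in 2-5 Hz and an amplitude (hand
    style 0.3-1.0 g, or finger style 0.02-0.08 g with probability
    ``finger_fraction``) held across their nights, so leave-one-subject-out
    evaluation sees genuinely unseen styles.  ``severity`` is the expected
    scratch-bout rate per TSO hour (scalar or per-subject sequence).
    ``n_dropped`` removes that many nights at random from the full grid
    (device-failure attrition).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    sev = np.broadcast_to(np.asarray(severity, dtype=float), (n_subjects,))
    nights: list[SyntheticNight] = []
    subject_ids: list[str] = []
    slots = [(i, j) for i in range(n_subjects) for j in range(nights_per_subject)]
    if n_dropped:
        drop_idx = set(rng.choice(len(slots), size=n_dropped, replace=False).tolist())
        slots = [s for k, s in enumerate(slots) if k not in drop_idx]
    styles = []
    for i in range(n_subjects):
        freq = rng.uniform(2.0, 5.0)
        if rng.random() < finger_fraction:
            amp = rng.uniform(0.02, 0.08)
        else:
            amp = rng.uniform(0.3, 1.0)
        styles.append((freq, amp))
    for i, j in slots:
        freq, amp = styles[i]
        dur_s = duration_h * 3600.0
        tso = (min(600.0, dur_s * 0.1), dur_s - min(600.0, dur_s * 0.1))
        night_rng = np.random.default_rng(rng.integers(2**31))
        events = random_schedule(night_rng, dur_s, tso, sev[i], freq, amp)
        scen = NightScenario(
            duration_h=duration_h,
            events=events,
            scratch_freq_hz=freq,
            scratch_amp_g=amp,
            noise_sd_g=noise_sd_g,
            tso=tso,
            seed=int(night_rng.integers(2**31)),
        )
        nights.append(simulate_night(scen))
        subject_ids.append(f"S{i + 1:02d}")
    return nights, subject_ids
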