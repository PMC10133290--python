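"""Endpoint arithmetic and the agreement statistics against hand-computed
and library oracles."""

import numpy as np
import pandas as pd
import pytest

from scratchkit.endpoints import (bland_altman, compute_endpoints,
                                  correlate_with_pro, icc)
from scratchkit.tso import TSOWindow


def _tiles(n_pos, n_neg, domfreq=3.0):
    rows = [{"tile_start_s": 3.0 * k, "call": True, "domfreq": domfreq}
            for k in range(n_pos)]
    rows += [{"tile_start_s": 3.0 * (n_pos + k), "call": False,
              "domfreq": np.nan} for k in range(n_neg)]
    return pd.DataFrame(rows)


def test_hourly_duration_arithmetic():
    """96 scratch seconds in an 8-h sleep window -> 12 s/h."""
    tso = TSOWindow(0.0, 8 * 3600.0)
    ep = compute_endpoints(_tiles(32, 100), tso)  # 32 * 3 s = 96 s
    assert ep.total_scratch_s == pytest.approx(96.0)
    assert ep.hourly_scratch_duration == pytest.approx(12.0)
    assert ep.mean_scratch_intensity == pytest.approx(3.0)


def test_no_scratch_endpoints_undefined_intensity():
    ep = compute_endpoints(_tiles(0, 50), TSOWindow(0.0, 3600.0))
    assert ep.total_scratch_s == 0.0
    assert ep.mean_scratch_intensity is None


def test_window_intensity_recovers_known_tone(rng):
    """A pure f Hz scratch window reads f +- one FFT bin, at any
    orientation mixing."""
    from scratchkit.endpoints import window_intensity_hz
    t = np.arange(60) / 20.0
    for f in (2.0, 3.0, 4.5):
        sl = rng.normal(0, 0.02, (60, 3))
        sl[:, 0] += 0.5 * np.sin(2 * np.pi * f * t)
        sl[:, 1] += 0.3 * np.sin(2 * np.pi * f * t + 1.0)
        assert abs(window_intensity_hz(sl) - f) <= 20.0 / 60 + 1e-9


def test_bland_altman_identities():
    x = np.array([3.0, 7.0, 1.0, 9.0])
    same = bland_altman(x, x)
    assert (same["mean_diff"], same["lower_loa"], same["upper_loa"]) == (
        0.0, 0.0, 0.0)
    shifted = bland_altman(x + 5.0, x)
    assert shifted["mean_diff"] == pytest.approx(5.0)
    assert shifted["lower_loa"] == pytest.approx(5.0)
    ba = bland_altman([1.0, -1.0], [0.0, 0.0])
    assert ba["mean_diff"] == pytest.approx(0.0)
    assert ba["upper_loa"] == pytest.approx(1.96 * np.sqrt(2.0))
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0], [1.0])


def _icc_frame(groups):
    rows = [{"subject": f"S{i}", "value": v}
            for i, vals in enumerate(groups) for v in vals]
    return pd.DataFrame(rows)


def test_icc_perfect_within_subject_consistency():
    frame = _icc_frame([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
    assert icc(frame) == pytest.approx(1.0)


def test_icc_hand_computed_3x2_table():
    """3 subjects x 2 nights, mean squares computed by hand:
    values (1,2), (4,6), (9,11): MSB = 2*var([1.5,5,10]) = 36.5833...,
    MSW = mean within-pair var = (0.5+2+2)/3 = 1.5;
    ICC = (MSB - MSW)/(MSB + MSW)."""
    frame = _icc_frame([[1.0, 2.0], [4.0, 6.0], [9.0, 11.0]])
    means = np.array([1.5, 5.0, 10.0])
    msb = 2 * ((means - means.mean()) ** 2).sum() / 2
    msw = (0.5 + 2.0 + 2.0) / 3
    expected = (msb - msw) / (msb + msw)
    assert icc(frame) == pytest.approx(expected)


def test_icc_matches_pingouin_oracle(rng):
    pg = pytest.importorskip("pingouin")
    subjects = np.repeat([f"S{i}" for i in range(6)], 4)
    values = rng.normal(size=24) + np.repeat(rng.normal(0, 2, 6), 4)
    frame = pd.DataFrame({"subject": subjects, "value": values,
                          "night": list(range(4)) * 6})
    ours = icc(frame)
    table = pg.intraclass_corr(data=frame, targets="subject",
                               raters="night", ratings="value")
    ref = float(table["ICC"].iloc[0])  # first row: one-way single measure
    assert ours == pytest.approx(ref, abs=1e-9)


def test_icc_null_is_small(rng):
    subjects = np.repeat([f"S{i}" for i in range(50)], 5)
    frame = pd.DataFrame({"subject": subjects,
                          "value": rng.normal(size=250)})
    assert abs(icc(frame)) < 0.1


def test_icc_shift_invariance_and_exclusions(rng):
    frame = _icc_frame([[1.0, 2.0], [4.0, 6.0], [9.0, 11.0]])
    shifted = frame.assign(value=frame["value"] + 100.0)
    assert icc(shifted) == pytest.approx(icc(frame))
    with_single = pd.concat(
        [frame, pd.DataFrame([{"subject": "S9", "value": 5.0}])],
        ignore_index=True)
    with pytest.warns(UserWarning):
        assert icc(with_single) == pytest.approx(icc(frame))


def test_correlate_with_pro_exact_and_planted(rng):
    subjects = np.repeat([f"S{i}" for i in range(8)], 3)
    nights = np.tile([f"N{j}" for j in range(3)], 8)
    severity = np.repeat(rng.uniform(1, 10, 8), 3)
    total = severity * 10.0
    endpoints = pd.DataFrame({"subject": subjects, "night": nights,
                              "total_s": total})
    pro = pd.DataFrame({
        "subject": subjects, "night": nights,
        "SCORAD": severity * 7.0,  # exactly proportional
        "ADSS2": severity + rng.normal(0, 1.0, 24),  # planted correlation
        "ADSS1": rng.normal(size=24),  # independent
    })
    out = correlate_with_pro(endpoints, pro).set_index("pro")
    assert out.loc["SCORAD", "pearson"] == pytest.approx(1.0)
    assert out.loc["SCORAD", "level"] == "subject"
    assert out.loc["ADSS2", "pearson"] > 0.5
    assert abs(out.loc["ADSS1", "pearson"]) < 0.5


def test_correlation_undefined_below_three_pairs():
    endpoints = pd.DataFrame({"subject": ["A", "B"], "night": ["N0", "N0"],
                              "total_s": [1.0, 2.0]})
    pro = pd.DataFrame({"subject": ["A", "B"], "night": ["N0", "N0"],
                        "SCORAD": [5.0, 6.0]})
    out = correlate_with_pro(endpoints, pro).set_index("pro")
    assert np.isnan(out.loc["SCORAD", "pearson"])
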