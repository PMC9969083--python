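"""Segmented fits, event detectors and the event panel."""

import numpy as np
import pandas as pd
import pytest

from cpetkit import (
    classify_cop, detect_cop, detect_vo2max, detect_vt1, detect_vt2,
    extract_panel, fit_two_segment, window_average,
)
from cpetkit.errors import DataError, DetectionError
from cpetkit.events import _line_sse
from cpetkit.prep import MinuteSeries


# --------------------------------------------------------------------------
# two-segment regression

def test_exact_piecewise_input_recovers_the_knee():
    x = np.arange(1.0, 21.0)
    y = np.where(x <= 5, x, 2 * x - 5.0)
    fit = fit_two_segment(x, y)
    assert fit.has_breakpoint
    assert fit.intersection[0] == pytest.approx(5.0, abs=1e-9)
    assert fit.intersection[1] == pytest.approx(5.0, abs=1e-9)
    assert fit.sse_two == pytest.approx(0.0, abs=1e-18)


def test_straight_line_yields_no_breakpoint_flag():
    x = np.arange(20.0)
    fit = fit_two_segment(x, 3.0 * x + 1.0)
    assert not fit.has_breakpoint
    assert fit.improvement == pytest.approx(0.0, abs=1e-9)


def test_segmented_sse_never_above_single_line(rng):
    for _ in range(20):
        x = np.sort(rng.uniform(0, 10, 30))
        x += np.arange(30) * 1e-6          # enforce strict monotonicity
        y = rng.normal(size=30)
        fit = fit_two_segment(x, y)
        assert fit.sse_two <= fit.sse_one + 1e-12
        assert 0.0 <= fit.improvement <= 1.0


def _brute_force_min_sse(x, y, min_seg=5):
    best = np.inf
    for k in range(min_seg, len(x) - min_seg + 1):
        sse = _line_sse(x[:k], y[:k])[2] + _line_sse(x[k:], y[k:])[2]
        best = min(best, sse)
    return best


def test_fit_matches_exhaustive_oracle_on_random_piecewise_data(rng):
    for _ in range(100):
        n = int(rng.integers(14, 40))
        x = np.sort(rng.uniform(0, 100, n))
        x += np.arange(n) * 1e-9
        knee = rng.uniform(x[5], x[-6])
        m1, m2 = rng.uniform(0.2, 1.5), rng.uniform(1.5, 4.0)
        y = np.where(x <= knee, m1 * x, m1 * knee + m2 * (x - knee))
        y += rng.normal(0, 0.5, n)
        fit = fit_two_segment(x, y)
        assert fit.sse_two == pytest.approx(_brute_force_min_sse(x, y), rel=1e-10)


def test_short_input_rejected():
    with pytest.raises(DataError):
        fit_two_segment(np.arange(8.0), np.arange(8.0))
    with pytest.raises(DataError):
        fit_two_segment(np.array([1.0, 1.0, 2, 3, 4, 5, 6, 7, 8, 9]),
                        np.arange(10.0))


# --------------------------------------------------------------------------
# VO2max

def test_constant_vo2_gives_its_own_maximum(noiseless_test):
    series, _ = noiseless_test
    w = window_average(series)
    const = w.df.copy()
    const["vo2"] = 3000.0
    w2 = type(w)(df=const, width=w.width, anchor_time=w.anchor_time)
    res = detect_vo2max(w2, mass=70.0)
    assert res.vo2max_abs == pytest.approx(3000.0)
    assert res.vo2max_rel == pytest.approx(3000.0 / 70.0)


def test_rolling_max_equals_exhaustive_interval_max(noisy_test):
    series, _ = noisy_test
    w = window_average(series)
    res = detect_vo2max(w, mass=70.0)
    vo2 = w.complete()["vo2"].to_numpy()
    brute = max(vo2[i:i + 3].mean() for i in range(len(vo2) - 2))
    assert res.vo2max_abs == pytest.approx(brute, rel=1e-12)


def test_percent_of_predicted():
    # male cohort mean 56.05 against a 42.08 prediction is 133.2% of predicted
    rel, predicted = 56.05, 56.05 / 1.332
    assert 100 * rel / predicted == pytest.approx(133.2, abs=0.01)


# --------------------------------------------------------------------------
# thresholds on simulated data

def test_thresholds_recovered_on_noiseless_test(noiseless_test):
    series, truth = noiseless_test
    w = window_average(series)
    vo2max = detect_vo2max(w, mass=series.meta.mass_kg)
    vt1 = detect_vt1(w, vo2max)
    vt2 = detect_vt2(w, vo2max, vo2_floor=vt1.vo2_at_threshold)
    assert vt1.vo2_at_threshold == pytest.approx(truth.vt1_vo2, rel=0.02)
    assert vt2.vo2_at_threshold == pytest.approx(truth.vt2_vo2, rel=0.02)
    assert vt1.vo2_at_threshold < vt2.vo2_at_threshold <= vo2max.vo2max_abs
    # profile fractions show up as percent of VO2max
    assert vt1.percent_of_vo2max == pytest.approx(68.0, abs=2.0)
    assert vt2.percent_of_vo2max == pytest.approx(84.25, abs=2.0)
    assert vt1.confirmed and vt2.confirmed


def test_single_slope_series_is_detection_failure(noiseless_test):
    series, _ = noiseless_test
    w = window_average(series)
    df = w.complete().copy()
    df["vco2"] = 0.9 * df["vo2"]           # pure single-slope V-slope panel
    w2 = type(w)(df=df, width=w.width, anchor_time=w.anchor_time)
    vo2max = detect_vo2max(w2, mass=70.0)
    with pytest.raises(DetectionError):
        detect_vt1(w2, vo2max)


def test_truncation_before_vt2_is_detection_failure(noiseless_test, male_profile):
    # a test abandoned before the respiratory-compensation point must not
    # fabricate a VT2: whatever slope change remains sits at or below VT1,
    # which the ordering check flags
    series, truth = noiseless_test
    cut = series.df[series.df["t"] < truth.event_times["vt2"] - 120.0]
    trimmed = type(series)(df=cut.reset_index(drop=True), meta=series.meta)
    w = window_average(trimmed)
    vo2max = detect_vo2max(w, mass=male_profile.mass)
    vt1 = detect_vt1(w, vo2max)
    with pytest.raises(DetectionError):
        detect_vt2(w, vo2max, vt1=vt1, vo2_floor=vt1.vo2_at_threshold)


# --------------------------------------------------------------------------
# COP

def _minutes_from(ve_vo2_values, complete=None):
    n = len(ve_vo2_values)
    complete = [True] * n if complete is None else complete
    df = pd.DataFrame({
        "minute": range(n),
        "t": 600.0 + np.arange(n) * 60.0 + 30.0,
        "ve_vo2": ve_vo2_values,
        "vo2": 1000.0 + 250.0 * np.arange(n),
        "complete": complete,
    })
    return MinuteSeries(df=df, windows_per_minute=6)


def test_cop_is_minimum_complete_minute():
    m = _minutes_from([30.0, 26.0, 24.0, 25.0, 28.0])
    res = detect_cop(m)
    assert res.cop == 24.0
    assert res.minute == 2
    assert res.category == "moderate"


def test_cop_ignores_incomplete_minutes_and_breaks_ties_early():
    m = _minutes_from([30.0, 20.0, 24.0, 24.0, 28.0],
                      complete=[True, False, True, True, True])
    res = detect_cop(m)
    assert res.cop == 24.0
    assert res.minute == 2                 # earliest of the tied minutes


def test_cop_matches_brute_force_on_random_series(rng):
    for _ in range(100):
        vals = rng.uniform(18, 40, size=int(rng.integers(4, 15)))
        flags = rng.random(len(vals)) > 0.2
        if not flags.any():
            flags[0] = True
        res = detect_cop(_minutes_from(vals, list(flags)))
        assert res.cop == pytest.approx(vals[flags].min(), rel=1e-12)


def test_cop_permutation_safe(rng):
    vals = rng.uniform(18, 40, 10)
    m = _minutes_from(vals)
    shuffled = m.df.sample(frac=1.0, random_state=3).sort_values("t")
    m2 = MinuteSeries(df=shuffled.reset_index(drop=True), windows_per_minute=6)
    r1, r2 = detect_cop(m), detect_cop(m2)
    assert (r1.cop, r1.minute) == (r2.cop, r2.minute)


def test_no_complete_minutes_is_detection_failure():
    with pytest.raises(DetectionError):
        detect_cop(_minutes_from([25.0, 26.0], complete=[False, False]))


@pytest.mark.parametrize("cop,category", [
    (22.64, "moderate"),   # male cohort mean lands in the moderate band
    (27.24, "moderate"),
    (21.999, "low"),
    (22.0, "moderate"),
    (30.0, "moderate"),
    (30.001, "high"),
])
def test_cop_categories(cop, category):
    assert classify_cop(cop) == category


def test_cop_category_rejects_nonpositive():
    with pytest.raises(DataError):
        classify_cop(0.0)


# --------------------------------------------------------------------------
# event panel

def test_panel_arithmetic_on_noiseless_test(noiseless_test, male_profile):
    series, truth = noiseless_test
    w = window_average(series)
    panel = extract_panel(
        w, truth.cop_time, mass=male_profile.mass, age=male_profile.age,
        test_duration=900.0,
    )
    assert panel["ttot"] == pytest.approx(panel["ti"] + panel["te"], abs=1e-6)
    assert panel["ti_ttot"] == pytest.approx(panel["ti"] / panel["ttot"], rel=1e-9)
    assert panel["fat_pct"] + panel["cho_pct"] == pytest.approx(100.0, abs=1e-9)
    assert panel["vo2_hr"] == pytest.approx(panel["vo2"] / panel["hr"], rel=1e-9)
    assert panel["vt_ti"] == pytest.approx(panel["vt_tidal"] / panel["ti"], rel=1e-9)
    assert panel["mets"] == pytest.approx(panel["vo2"] / male_profile.mass / 3.5, rel=1e-9)
    # default heart-rate reserve uses 220 − age
    assert panel["hrr"] == pytest.approx(220.0 - male_profile.age - panel["hr"], rel=1e-9)


def test_oxygen_pulse_from_cohort_means():
    # per-subject ratio of the male cohort-mean VO2 and HR at the optimum
    assert 1534.0 / 120.8 == pytest.approx(12.7, abs=0.05)


def test_panel_outside_range_rejected(noiseless_test, male_profile):
    series, _ = noiseless_test
    w = window_average(series)
    with pytest.raises(DataError):
        extract_panel(w, 1e6, mass=male_profile.mass, age=20.0, test_duration=900.0)
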