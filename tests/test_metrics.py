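"""The exposure metric battery against hand counts and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luxdose.metrics import (
    ThresholdSpec,
    extreme_window_mean,
    frequency_crossing,
    interdaily_stability,
    intradaily_variability,
    mean_log_mel,
    mp_ratio,
    period_above_threshold,
    photoperiod_normalize,
    time_above_threshold,
    timing_above_threshold,
)
from luxdose.solar import civil_dawn_dusk

from conftest import full_day_values, make_day, make_series

T250 = ThresholdSpec(250.0)
B10 = ThresholdSpec(10.0, "at-or-below")


def test_tat_hand_count():
    day = make_day([100, 300, 250, 249, 1200])
    assert time_above_threshold(day, T250) == 180.0


def test_tat_all_below_is_zero_but_all_missing_is_nan():
    assert time_above_threshold(make_day([1, 2, 3]), T250) == 0.0
    assert math.isnan(time_above_threshold(make_day([np.nan] * 5), T250))


def test_tbt_evening_filter(basel_site):
    # full local day; evening = dusk (~22:07 CEST on Jul 10) to midnight
    values = full_day_values(100.0)
    values[-60:] = 5.0  # 23:00-24:00 dim
    day = make_day(values.tolist())
    sd = civil_dawn_dusk(day.local_date, basel_site)
    tbte = time_above_threshold(day, B10, segment="evening", sd=sd)
    assert tbte == 3600.0


def test_photoperiod_normalize():
    assert photoperiod_normalize(3600.0, 12.0) == 300.0
    assert photoperiod_normalize(0.0, 14.4) == 0.0
    assert photoperiod_normalize(7200.0, 4.0) == 1800.0
    with pytest.raises(ValueError):
        photoperiod_normalize(1.0, 0.0)


def test_timing_symmetric_epochs():
    values = full_day_values(0.0)
    for h in (8, 12, 16):
        values[h * 60] = 300.0
    first, last, mean = timing_above_threshold(make_day(values.tolist()), T250)
    assert (first, last, mean) == (8.0, 16.0, 12.0)


def test_timing_single_epoch():
    values = full_day_values(0.0)
    values[22 * 60 + 5] = 300.0
    first, last, mean = timing_above_threshold(make_day(values.tolist()), T250)
    assert first == last == mean == pytest.approx(22 + 5 / 60)


def test_timing_matches_brute_force():
    rng = np.random.default_rng(7)
    values = rng.uniform(0, 500, 1440)
    day = make_day(values.tolist())
    first, last, mean = timing_above_threshold(day, T250)
    hours = np.arange(1440) / 60.0
    qualifying = hours[values >= 250.0]
    assert first == qualifying[0]
    assert last == qualifying[-1]
    assert mean == pytest.approx(qualifying.mean())


def test_frequency_crossing_hand_counts():
    assert frequency_crossing(make_day([10, 300, 10, 260, 260, 40]), T250) == 2
    assert frequency_crossing(make_day([100] * 10), T250) == 0
    assert frequency_crossing(make_day([300, 10, 300]), T250) == 1


def test_frequency_crossing_ignores_pairs_spanning_missing():
    assert frequency_crossing(make_day([10, np.nan, 300]), T250) == 0


def test_period_above_threshold_runs():
    day = make_day([10, 300, 10, 260, 260, 40])
    assert period_above_threshold(day, T250) == 120.0
    assert period_above_threshold(make_day([300] * 7), T250) == 7 * 60.0
    assert period_above_threshold(make_day([300, 10] * 5), T250) == 60.0
    assert period_above_threshold(make_day([1, 2]), T250) == 0.0


def test_extreme_window_constant_day_ties_to_earliest_onset():
    day = make_day(full_day_values(100.0).tolist())
    assert extreme_window_mean(day, 10.0, "brightest") == (100.0, 0.0)


def test_extreme_window_rectangular_pulse():
    values = full_day_values(0.0)
    values[9 * 60 : 19 * 60] = 1000.0
    mean, onset = extreme_window_mean(make_day(values.tolist()), 10.0, "brightest")
    assert mean == 1000.0 and onset == 9.0


def test_dimmest_window_finds_dark_span():
    values = full_day_values(100.0)
    values[22 * 60 :] = 0.0
    values[: 3 * 60] = 0.0
    mean, onset = extreme_window_mean(make_day(values.tolist()), 5.0, "dimmest")
    # dark 22:00-03:00 wraps midnight; within one local day the dimmest
    # non-wrapping 5-h window still averages lowest starting at 22:00 minus
    # overlap -- the fully dark span inside the day is 00:00-03:00 + 22:00-24:00,
    # so the best window mixes dark and bright; check it is the 22:00 onset
    # only when wrapping is not allowed: brute force instead
    series = values
    n = 300
    means = np.array([series[i : i + n].mean() for i in range(series.size - n + 1)])
    assert mean == pytest.approx(means.min())
    assert onset == pytest.approx(np.argmin(means) / 60.0)


def test_extreme_window_matches_brute_force_scan():
    rng = np.random.default_rng(11)
    values = rng.uniform(0, 2000, 1440)
    day = make_day(values.tolist())
    n = 600
    means = np.array([values[i : i + n].mean() for i in range(values.size - n + 1)])
    got_mean, got_onset = extreme_window_mean(day, 10.0, "brightest")
    assert got_mean == pytest.approx(means.max())
    assert got_onset == pytest.approx(np.argmax(means) / 60.0)


def test_is_one_for_repeated_profile():
    profile = np.concatenate([np.zeros(720), np.full(720, 500.0)])
    ts = make_series(np.tile(profile, 5).tolist())
    assert interdaily_stability(ts) == pytest.approx(1.0)


def test_is_undefined_for_constant_series():
    ts = make_series(np.full(2 * 1440, 50.0).tolist())
    assert math.isnan(interdaily_stability(ts))


def test_is_of_iid_noise_is_about_one_over_days():
    """For d days of independent noise, IS concentrates near 1/d."""
    rng = np.random.default_rng(42)
    d = 8
    values = []
    for _ in range(200):
        ts = make_series(rng.uniform(0, 100, d * 1440).tolist())
        values.append(interdaily_stability(ts))
    assert np.mean(values) == pytest.approx(1 / d, rel=0.15)


def test_is_invariant_under_additive_constant():
    rng = np.random.default_rng(3)
    base = rng.uniform(0, 100, 4 * 1440)
    a = interdaily_stability(make_series(base.tolist()))
    b = interdaily_stability(make_series((base + 57.0).tolist()))
    assert a == pytest.approx(b, rel=1e-9)


def test_iv_exactly_four_for_hourly_alternation():
    hours = np.tile([0.0, 100.0], 5 * 12)  # 5 days alternating hourly
    values = np.repeat(hours, 60)
    ts = make_series(values.tolist())
    assert intradaily_variability(ts) == pytest.approx(4.0)


def test_iv_constant_undefined_and_sinusoid_small():
    assert math.isnan(intradaily_variability(make_series(np.full(2880, 9.0).tolist())))
    t = np.arange(3 * 1440)
    sin_vals = 100 + 50 * np.sin(2 * np.pi * t / 1440)
    assert intradaily_variability(make_series(sin_vals.tolist())) < 0.2


def test_iv_invariant_under_affine_rescaling():
    rng = np.random.default_rng(5)
    base = rng.uniform(0, 100, 3 * 1440)
    a = intradaily_variability(make_series(base.tolist()))
    b = intradaily_variability(make_series((3.5 * base + 20.0).tolist()))
    assert a == pytest.approx(b, rel=1e-9)


def test_mp_ratio():
    assert mp_ratio(make_series([10, 20], photopic=[10, 20])) == 1.0
    assert mp_ratio(make_series([10, 20], photopic=[20, 40])) == 2.0
    rng = np.random.default_rng(9)
    mel = rng.uniform(1, 100, 50)
    pho = rng.uniform(1, 200, 50)
    got = mp_ratio(make_series(mel.tolist(), photopic=pho.tolist()))
    assert got == pytest.approx(pho.mean() / mel.mean())


def test_mean_log_mel():
    assert mean_log_mel(make_day([100.0] * 10)) == pytest.approx(2.0)
    assert mean_log_mel(make_day([0.4] * 10)) == pytest.approx(-1.0)
    assert mean_log_mel(make_day([10.0] * 5 + [1000.0] * 5)) == pytest.approx(2.0)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_tat_monotone_in_threshold_and_pat_bounds(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 2000, 500)
    day = make_day(values.tolist())
    t_lo = time_above_threshold(day, ThresholdSpec(100.0))
    t_hi = time_above_threshold(day, ThresholdSpec(800.0))
    assert t_lo >= t_hi
    pat = period_above_threshold(day, T250)
    tat = time_above_threshold(day, T250)
    assert pat <= tat <= len(values) * 60
    fct = frequency_crossing(day, T250)
    assert fct <= tat / 60 + 1
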