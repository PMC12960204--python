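"""Correlation windows, Spearman+BH, circular correlation, bootstrap, sensitivity."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from luxdose.stats import (
    CorrelationTask,
    bh_adjust,
    bootstrap_item_stability,
    circular_correlation,
    compare_site_correlations,
    missing_data_sensitivity,
    spearman_fdr,
    window_average_metrics,
)


# ---------- window averaging ------------------------------------------------


def daily_table(pid, dates, values):
    return pd.DataFrame(
        {"participant_id": pid, "local_date": dates, "m": values}
    )


def test_window_covers_days_since_previous_assessment():
    daily = daily_table("p1", [date(2023, 7, d) for d in range(1, 8)], range(1, 8))
    assessments = pd.DataFrame(
        {"participant_id": ["p1", "p1"],
         "assessment_date": [date(2023, 7, 4), date(2023, 7, 7)]}
    )
    out = window_average_metrics(daily, assessments, scheme="windowed")
    # first window: days 1-4 -> mean 2.5; second: days 5-7 -> mean 6
    assert out["m"].tolist() == [2.5, 6.0]


def test_whole_period_scheme_is_grand_mean():
    daily = daily_table("p1", [date(2023, 7, d) for d in range(1, 11)], range(10))
    assessments = pd.DataFrame(
        {"participant_id": ["p1"], "assessment_date": [date(2023, 7, 31)]}
    )
    out = window_average_metrics(daily, assessments, scheme="whole-period")
    assert out["m"].iloc[0] == pytest.approx(4.5)


def test_constant_metric_window_mean_is_the_constant():
    daily = daily_table("p1", [date(2023, 7, d) for d in range(1, 8)], [7.0] * 7)
    assessments = pd.DataFrame(
        {"participant_id": ["p1"], "assessment_date": [date(2023, 7, 5)]}
    )
    out = window_average_metrics(daily, assessments, scheme="windowed")
    assert out["m"].iloc[0] == 7.0


# ---------- Spearman + BH ---------------------------------------------------


def test_bh_hand_example():
    adj = bh_adjust(np.array([0.01, 0.02, 0.04]))
    assert np.allclose(adj, [0.03, 0.03, 0.04])


def test_bh_monotone_and_never_decreases():
    rng = np.random.default_rng(0)
    p = rng.uniform(0, 1, 50)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_strictly_monotone_pair_gives_r_one():
    data = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6], "b": [2.0, 3.5, 7.1, 9.0, 11.2, 20.0]})
    res = spearman_fdr([CorrelationTask("a", "b")], data)
    assert res["r"].iloc[0] == pytest.approx(1.0)
    assert res["p"].iloc[0] < 0.01


def test_spearman_equals_rank_then_pearson():
    rng = np.random.default_rng(4)
    data = pd.DataFrame({"a": rng.permutation(40).astype(float), "b": rng.uniform(0, 1, 40)})
    res = spearman_fdr([CorrelationTask("a", "b")], data)
    ranks_a = sps.rankdata(data["a"])
    ranks_b = sps.rankdata(data["b"])
    expected = np.corrcoef(ranks_a, ranks_b)[0, 1]
    assert res["r"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_spearman_handles_ties_like_rank_pearson():
    rng = np.random.default_rng(6)
    data = pd.DataFrame(
        {"a": rng.integers(1, 5, 60).astype(float), "b": rng.integers(0, 10, 60).astype(float)}
    )
    res = spearman_fdr([CorrelationTask("a", "b")], data)
    expected = np.corrcoef(sps.rankdata(data["a"]), sps.rankdata(data["b"]))[0, 1]
    assert res["r"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_family_size_padding_is_conservative():
    data = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
    small = spearman_fdr([CorrelationTask("a", "b")], data, family_size=1)
    big = spearman_fdr([CorrelationTask("a", "b")], data, family_size=20)
    assert big["p_adj"].iloc[0] >= small["p_adj"].iloc[0]


# ---------- circular correlation -------------------------------------------


def test_circular_r_is_one_for_identical_samples():
    rng = np.random.default_rng(1)
    a = rng.uniform(0, 24, 50)
    r, p = circular_correlation(a, a)
    assert r == pytest.approx(1.0)
    assert p < 1e-6


def test_circular_rotation_invariance():
    rng = np.random.default_rng(2)
    a = rng.uniform(0, 24, 50)
    b = (a + 7.3) % 24.0
    r, _ = circular_correlation(a, b)
    assert r == pytest.approx(1.0, abs=1e-9)


def test_circular_independent_angles_are_near_zero():
    rng = np.random.default_rng(3)
    hits = 0
    for _ in range(200):
        a = rng.uniform(0, 24, 1000)
        b = rng.uniform(0, 24, 1000)
        r, _ = circular_correlation(a, b)
        hits += abs(r) < 0.1
    assert hits >= 190  # 95% of simulations


def test_circular_reduces_to_pearson_of_sin_deviations():
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 24, 40)
    b = (a + rng.normal(0, 2, 40)) % 24
    r, _ = circular_correlation(a, b)
    ar = a * 2 * np.pi / 24
    br = b * 2 * np.pi / 24
    abar = math.atan2(np.sin(ar).sum(), np.cos(ar).sum())
    bbar = math.atan2(np.sin(br).sum(), np.cos(br).sum())
    expected = np.corrcoef(np.sin(ar - abar), np.sin(br - bbar))[0, 1]
    assert r == pytest.approx(expected, abs=1e-12)


def test_circular_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    a = rng.uniform(0, 24, 30)
    b = (a + rng.normal(0, 3, 30)) % 24
    r, _ = circular_correlation(a, b)
    r_ref = pingouin.circ_corrcc(a * 2 * np.pi / 24, b * 2 * np.pi / 24)[0]
    assert r == pytest.approx(float(r_ref), abs=1e-9)


# ---------- site comparison -------------------------------------------------


def make_results(rs, ns):
    return pd.DataFrame(
        {"item": [f"i{k}" for k in range(len(rs))],
         "metric": "m", "r": rs, "p": 0.5, "n": ns}
    )


def test_identical_correlations_give_z_zero_p_one():
    a = make_results([0.4], [30])
    out = compare_site_correlations(a, a.copy())
    assert out["z"].iloc[0] == 0.0
    assert out["p"].iloc[0] == pytest.approx(1.0)


def test_fisher_z_closed_form():
    a = make_results([0.5], [50])
    b = make_results([0.0], [50])
    out = compare_site_correlations(a, b)
    expected = math.atanh(0.5) / math.sqrt(2 / 47)
    assert out["z"].iloc[0] == pytest.approx(expected)


def test_swapping_sites_flips_sign_only():
    a = make_results([0.5, -0.2], [40, 35])
    b = make_results([0.1, 0.3], [25, 60])
    ab = compare_site_correlations(a, b)
    ba = compare_site_correlations(b, a)
    assert np.allclose(ab["z"].to_numpy(), -ba["z"].to_numpy())
    assert np.allclose(ab["p"].to_numpy(), ba["p"].to_numpy())


def test_small_n_pairs_are_skipped():
    a = make_results([0.5, 0.4], [3, 30])
    b = make_results([0.1, 0.2], [30, 30])
    out = compare_site_correlations(a, b)
    assert len(out) == 1


# ---------- bootstrap stability ---------------------------------------------


def responses_frame(answers_by_pid):
    rows = []
    for pid, answers in answers_by_pid.items():
        for k, v in enumerate(answers):
            rows.append(
                {"participant_id": pid, "assessment_date": date(2023, 7, 1 + 3 * k),
                 "q1": v}
            )
    return pd.DataFrame(rows)


def test_constant_answers_not_significant():
    res = bootstrap_item_stability(responses_frame({"p1": [3] * 9}), n_boot=500, seed=0)
    row = res.per_participant.iloc[0]
    assert row["ci_lo"] == 0.0 and row["ci_hi"] == 0.0
    assert not row["significant"]
    assert res.per_item["stable"].iloc[0]


def test_alternating_answers_are_significant():
    res = bootstrap_item_stability(
        responses_frame({"p1": [1, 5, 1, 5, 1, 5, 1, 5, 1]}), n_boot=2000, seed=1
    )
    assert res.per_participant["significant"].iloc[0]


def test_same_seed_reproduces_cis():
    frame = responses_frame({"p1": [1, 3, 2, 5, 4, 2, 3, 1, 4]})
    a = bootstrap_item_stability(frame, n_boot=1000, seed=42).per_participant
    b = bootstrap_item_stability(frame, n_boot=1000, seed=42).per_participant
    pd.testing.assert_frame_equal(a, b)


def test_participants_with_too_few_assessments_skipped():
    res = bootstrap_item_stability(
        responses_frame({"p1": [1, 2], "p2": [1, 2, 3, 4]}), n_boot=100, seed=0
    )
    assert set(res.per_participant["participant_id"]) == {"p2"}


# ---------- missing-data sensitivity ----------------------------------------


def test_gap_zero_is_within_band_and_selection_is_seed_stable():
    from conftest import make_day

    rng = np.random.default_rng(9)
    days = [make_day((10 ** rng.uniform(0, 3, 1440)).tolist()) for _ in range(4)]

    def mean_metric(day):
        return float(np.nanmean(day.data["mel_edi"]))

    out1 = missing_data_sensitivity(
        days, {"mean": mean_metric}, [0.0, 2.0], n_boot=100, seed=5
    )
    out2 = missing_data_sensitivity(
        days, {"mean": mean_metric}, [0.0, 2.0], n_boot=100, seed=5
    )
    g0 = out1[out1["gap_h"] == 0.0].iloc[0]
    assert g0["within_band"]
    assert g0["resampled_mean"] == pytest.approx(g0["baseline_mean"], rel=0.05)
    pd.testing.assert_frame_equal(out1, out2)


def test_band_width_is_two_standard_errors():
    from conftest import make_day

    rng = np.random.default_rng(10)
    days = [make_day(np.full(1440, 100.0 + 10 * k).tolist()) for k in range(4)]

    def mean_metric(day):
        return float(np.nanmean(day.data["mel_edi"]))

    out = missing_data_sensitivity(days, {"m": mean_metric}, [0.0], n_boot=50, seed=0)
    row = out.iloc[0]
    vals = np.array([100.0, 110.0, 120.0, 130.0])
    se = vals.std(ddof=1) / 2.0
    assert row["band_hi"] - row["baseline_mean"] == pytest.approx(2 * se)


def test_gap_grid_validation():
    with pytest.raises(ValueError):
        missing_data_sensitivity([], {}, [30.0], n_boot=1, seed=0)


def test_default_metric_set_selects_a_threshold_on_stable_days():
    """On near-identical complete days, small injected gaps leave the
    default metrics (day IV, last time <=10 lx, MP ratio) within their
    original mean +/- 2 SE bands, so a positive threshold is selected."""
    from luxdose.stats import default_sensitivity_metrics
    from conftest import make_series
    from luxdose.timeseries import split_valid_days

    rng = np.random.default_rng(13)
    days = []
    for k in range(3):
        values = np.where(
            (np.arange(1440) >= 8 * 60) & (np.arange(1440) < 20 * 60),
            10 ** rng.normal(2.0, 0.3, 1440),
            10 ** rng.normal(0.0, 0.2, 1440),
        )
        ts = make_series(values.tolist(), start=f"2023-07-{10 + k} 00:00",
                         photopic=(values * 1.3).tolist())
        days.extend(split_valid_days(ts))
    out = missing_data_sensitivity(
        days, default_sensitivity_metrics(), [0.0, 1.0, 2.0], n_boot=300, seed=3
    )
    assert set(out["metric"]) == {"IV", "LT10", "MPratio"}
    assert out[out["gap_h"] == 0.0]["within_band"].all()
    assert out.attrs["selected_threshold_h"] >= 0.0
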