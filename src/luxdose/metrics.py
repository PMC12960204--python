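"""The light-exposure metric battery, per participant-day and per participant.

Duration metrics (TAT, TBT, PAT), timing metrics (FLiT/MLiT/LLiT), crossing
counts (FcT), extreme-window means (M10m/L5m), rhythm metrics (IS/IV), the
photopic-to-melanopic ratio, and mean log10 mel-EDI, together with
photoperiod correction (seconds above threshold per hour of the relevant
period: photoperiod for day metrics, dusk-to-midnight for evening metrics).

Conventions, applied uniformly:

* "above" a threshold means at-or-above (>=); "below" means at-or-below (<=);
* a metric over a window in which every epoch is missing is NaN, not zero;
* timing metrics are local clock hours since midnight, averaged within the
  day (non-circular -- exposures are bounded inside one local day);
* IS and IV are computed on hourly bins of raw (not log-transformed) mel-EDI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .solar import SolarDay
from .timeseries import CleaningPolicy, DayRecord, LightTimeseries

__all__ = [
    "ThresholdSpec",
    "time_above_threshold",
    "photoperiod_normalize",
    "timing_above_threshold",
    "frequency_crossing",
    "period_above_threshold",
    "extreme_window_mean",
    "interdaily_stability",
    "intradaily_variability",
    "mp_ratio",
    "mean_log_mel",
    "daily_metrics",
    "participant_metrics",
    "DAILY_METRIC_COLUMNS",
]

Comparator = Literal["at-or-above", "at-or-below"]
Segment = Literal["day", "evening", "night"]


@dataclass(frozen=True)
class ThresholdSpec:
    """A mel-EDI threshold and the side of it that qualifies."""

    threshold: float
    comparator: Comparator = "at-or-above"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    def qualifies(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of qualifying values; NaN never qualifies."""
        with np.errstate(invalid="ignore"):
            if self.comparator == "at-or-above":
                return values >= self.threshold
            return values <= self.threshold


def _clock_hours(index: pd.DatetimeIndex) -> np.ndarray:
    return (
        index.hour.to_numpy()
        + index.minute.to_numpy() / 60.0
        + index.second.to_numpy() / 3600.0
    )


def _segment_mask(index: pd.DatetimeIndex, segment: Segment, sd: SolarDay) -> np.ndarray:
    if segment == "day":
        return (index >= sd.civil_dawn) & (index < sd.civil_dusk)
    if segment == "evening":
        return index >= sd.civil_dusk
    if segment == "night":
        return index < sd.civil_dawn
    raise ValueError(f"unknown segment {segment!r}")


def _day_values(
    day: DayRecord, segment: Segment | None, sd: SolarDay | None
) -> tuple[np.ndarray, pd.DatetimeIndex]:
    values = day.data["mel_edi"].to_numpy(dtype=float)
    index = day.data.index
    if segment is not None:
        if sd is None:
            raise ValueError("segment filtering requires a SolarDay")
        mask = _segment_mask(index, segment, sd)
        values = values[mask]
        index = index[mask]
    return values, index


def time_above_threshold(
    day: DayRecord,
    spec: ThresholdSpec,
    segment: Segment | None = None,
    sd: SolarDay | None = None,
) -> float:
    """Seconds spent at the qualifying side of the threshold (TAT / TBT).

    NaN when every epoch in the (optionally segment-filtered) window is
    missing -- no data is not the same as no exposure.
    """
    values, _ = _day_values(day, segment, sd)
    if np.all(np.isnan(values)) or values.size == 0:
        return math.nan
    return float(spec.qualifies(values).sum()) * day.epoch_s


def photoperiod_normalize(value_s: float, period_h: float) -> float:
    """Seconds per hour of the relevant (photo)period."""
    if period_h <= 0:
        raise ValueError("period_h must be > 0")
    return value_s / period_h


def timing_above_threshold(
    day: DayRecord,
    spec: ThresholdSpec,
    segment: Segment | None = None,
    sd: SolarDay | None = None,
) -> tuple[float, float, float]:
    """(first, last, mean) local clock hour of qualifying epochs (FLiT/LLiT/MLiT).

    All three are NaN when no epoch qualifies.
    """
    values, index = _day_values(day, segment, sd)
    mask = spec.qualifies(values)
    if not mask.any():
        return (math.nan, math.nan, math.nan)
    hours = _clock_hours(index)[mask]
    return (float(hours[0]), float(hours[-1]), float(hours.mean()))


def frequency_crossing(day: DayRecord, spec: ThresholdSpec) -> float:
    """Count of upward crossings: below-threshold epoch followed by a qualifying one.

    Only adjacent non-missing epoch pairs are considered; pairs spanning a
    missing epoch are not counted.
    """
    values = day.data["mel_edi"].to_numpy(dtype=float)
    if values.size < 2:
        return 0.0
    q = spec.qualifies(values)
    ok = ~np.isnan(values)
    pair_ok = ok[:-1] & ok[1:]
    upward = ~q[:-1] & q[1:]
    return float(np.sum(pair_ok & upward))


def period_above_threshold(day: DayRecord, spec: ThresholdSpec) -> float:
    """Duration (s) of the longest contiguous run of qualifying epochs (PAT)."""
    q = spec.qualifies(day.data["mel_edi"].to_numpy(dtype=float))
    if not q.any():
        return 0.0
    # run lengths of True in q
    changes = np.diff(np.concatenate(([0], q.view(np.int8), [0])))
    starts = np.flatnonzero(changes == 1)
    ends = np.flatnonzero(changes == -1)
    return float((ends - starts).max()) * day.epoch_s


def extreme_window_mean(
    day: DayRecord,
    width_h: float,
    mode: Literal["brightest", "dimmest"],
    min_coverage: float = 0.5,
) -> tuple[float, float]:
    """Mean mel-EDI of the extreme sliding window (M10m / L5m) and its onset.

    Windows slide at epoch resolution; a window is eligible when at least
    ``min_coverage`` of its epochs are observed, and the mean is taken over
    the observed epochs. Ties are broken to the earliest onset. Returns
    (NaN, NaN) when the day has less than ``width_h`` of observed data.
    """
    series = day.data["mel_edi"]
    n = int(round(width_h * 3600 / day.epoch_s))
    if n < 1 or series.notna().sum() < n:
        return (math.nan, math.nan)
    roll = series.rolling(n, min_periods=max(1, int(math.ceil(n * min_coverage)))).mean()
    means = roll.to_numpy()[n - 1 :]  # window ending at i starts at i-n+1
    if np.all(np.isnan(means)):
        return (math.nan, math.nan)
    if mode == "brightest":
        i = int(np.nanargmax(means))
    elif mode == "dimmest":
        i = int(np.nanargmin(means))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    onset = _clock_hours(day.data.index[[i]])[0]
    return (float(means[i]), float(onset))


def _hourly_bins(
    ts: LightTimeseries, valid_days: list[DayRecord] | None, bin_minutes: int
) -> pd.Series:
    data = ts.data["mel_edi"]
    if valid_days is not None:
        keep = {d.local_date for d in valid_days if d.valid}
        mask = pd.Series(ts.data.index.date, index=ts.data.index).isin(keep)
        data = data[mask.to_numpy()]
    return data.resample(f"{bin_minutes}min").mean()


def interdaily_stability(
    ts: LightTimeseries,
    valid_days: list[DayRecord] | None = None,
    bin_minutes: int = 60,
) -> float:
    """Interdaily stability of the exposure rhythm, on hourly bins.

    IS = (N * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2) with
    x_i the binned means (N non-missing bins in total, p bins per day) and
    xbar_h the across-days mean of bin-of-day h. 1 for a perfectly repeated
    24-h profile, about 1/d for d days of independent noise. NaN (undefined)
    for a constant series.
    """
    binned = _hourly_bins(ts, valid_days, bin_minutes).dropna()
    if binned.empty:
        return math.nan
    p = int(round(24 * 60 / bin_minutes))
    x = binned.to_numpy(dtype=float)
    n_total = x.size
    grand = x.mean()
    denom = np.sum((x - grand) ** 2)
    if denom == 0:
        return math.nan
    bin_of_day = (
        binned.index.hour * 60 + binned.index.minute
    ) // bin_minutes
    hourly_means = binned.groupby(bin_of_day).mean().to_numpy(dtype=float)
    num = np.sum((hourly_means - grand) ** 2)
    return float(n_total * num / (p * denom))


def intradaily_variability(
    ts: LightTimeseries,
    valid_days: list[DayRecord] | None = None,
    bin_minutes: int = 60,
) -> float:
    """Intradaily variability (hour-to-hour fragmentation), on hourly bins.

    IV = (N * sum (x_i - x_{i-1})^2) / ((N-1) * sum (x_i - xbar)^2) with
    differences taken only between temporally adjacent non-missing bins.
    0 for smooth profiles, 2 for white noise (in expectation), exactly 4 for
    a strict two-level hourly alternation. NaN for a constant series.
    """
    binned = _hourly_bins(ts, valid_days, bin_minutes)
    x = binned.to_numpy(dtype=float)
    ok = ~np.isnan(x)
    n_total = int(ok.sum())
    if n_total < 2:
        return math.nan
    xbar = np.nanmean(x)
    denom = np.nansum((x - xbar) ** 2)
    if denom == 0:
        return math.nan
    adjacent = ok[1:] & ok[:-1]
    diffs = (x[1:] - x[:-1])[adjacent]
    if diffs.size == 0:
        return math.nan
    return float(n_total * np.sum(diffs**2) / ((n_total - 1) * denom))


def mp_ratio(ts: LightTimeseries) -> float:
    """Ratio of mean photopic to mean melanopic illuminance over paired samples."""
    if not ts.has_photopic:
        return math.nan
    paired = ts.data[["mel_edi", "photopic"]].dropna()
    if paired.empty:
        return math.nan
    mel_mean = paired["mel_edi"].mean()
    if mel_mean == 0:
        return math.nan
    return float(paired["photopic"].mean() / mel_mean)


def mean_log_mel(
    day: DayRecord,
    segment: Segment | None = None,
    sd: SolarDay | None = None,
    policy: CleaningPolicy | None = None,
) -> float:
    """Mean log10 mel-EDI over the (optionally segment-filtered) day.

    The dark-floor replacement (values below 1 lux -> 0.1 lux) is applied
    before the transform so the log is defined in darkness; it is applied
    here even if the caller passed a raw series.
    """
    policy = policy or CleaningPolicy()
    values, _ = _day_values(day, segment, sd)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return math.nan
    values = np.where(values < policy.dark_floor, policy.dark_replacement, values)
    return float(np.mean(np.log10(values)))


# Columns emitted by daily_metrics, in output order. The *_ph suffix marks
# photoperiod-corrected variants (s per h of photoperiod), *_pe per hour of
# evening (dusk to midnight).
DAILY_METRIC_COLUMNS = [
    "TAT250",
    "TAT1000",
    "TATd250",
    "TBTe10",
    "TAT250_ph",
    "TAT1000_ph",
    "TATd250_ph",
    "TBTe10_pe",
    "MLiT250",
    "FLiT250",
    "LLiT250",
    "LLiT10",
    "FcT250",
    "PAT1000",
    "M10m",
    "M10m_onset",
    "L5m",
    "L5m_onset",
    "mean_log_mel_day",
    "mean_log_mel_evening",
]

_T250 = ThresholdSpec(250.0)
_T1000 = ThresholdSpec(1000.0)
_B10 = ThresholdSpec(10.0, "at-or-below")
_A10 = ThresholdSpec(10.0)


def daily_metrics(day: DayRecord, sd: SolarDay) -> dict[str, float]:
    """The full per-day metric battery for one valid participant-day."""
    tat250 = time_above_threshold(day, _T250)
    tat1000 = time_above_threshold(day, _T1000)
    tatd250 = time_above_threshold(day, _T250, segment="day", sd=sd)
    tbte10 = time_above_threshold(day, _B10, segment="evening", sd=sd)
    flit250, llit250, mlit250 = timing_above_threshold(day, _T250)
    _, llit10, _ = timing_above_threshold(day, _A10, segment="evening", sd=sd)
    m10, m10_onset = extreme_window_mean(day, 10.0, "brightest")
    l5, l5_onset = extreme_window_mean(day, 5.0, "dimmest")
    return {
        "TAT250": tat250,
        "TAT1000": tat1000,
        "TATd250": tatd250,
        "TBTe10": tbte10,
        "TAT250_ph": photoperiod_normalize(tat250, sd.photoperiod_h),
        "TAT1000_ph": photoperiod_normalize(tat1000, sd.photoperiod_h),
        "TATd250_ph": photoperiod_normalize(tatd250, sd.photoperiod_h),
        "TBTe10_pe": photoperiod_normalize(tbte10, sd.evening_length_h),
        "MLiT250": mlit250,
        "FLiT250": flit250,
        "LLiT250": llit250,
        "LLiT10": llit10,
        "FcT250": frequency_crossing(day, _T250),
        "PAT1000": period_above_threshold(day, _T1000),
        "M10m": m10,
        "M10m_onset": m10_onset,
        "L5m": l5,
        "L5m_onset": l5_onset,
        "mean_log_mel_day": mean_log_mel(day, segment="day", sd=sd),
        "mean_log_mel_evening": mean_log_mel(day, segment="evening", sd=sd),
    }


def daily_metrics_table(
    days: list[DayRecord], solar_by_date: dict, participant_id: str | None = None
) -> pd.DataFrame:
    """DailyMetrics rows for every valid day (one row per participant-day)."""
    rows = []
    for day in days:
        if not day.valid:
            continue
        sd = solar_by_date[day.local_date]
        row = {"participant_id": participant_id or day.participant_id,
               "local_date": day.local_date}
        row.update(daily_metrics(day, sd))
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "local_date"] + DAILY_METRIC_COLUMNS)


def participant_metrics(
    ts: LightTimeseries,
    days: list[DayRecord],
    solar_by_date: dict,
) -> dict[str, float]:
    """Per-participant summary: means of daily metrics over valid days + IS/IV/MPratio."""
    valid = [d for d in days if d.valid]
    table = daily_metrics_table(valid, solar_by_date, ts.participant_id)
    out: dict[str, float] = {"n_valid_days": float(len(valid))}
    for col in DAILY_METRIC_COLUMNS:
        out[col] = float(table[col].mean()) if len(table) else math.nan
    out["IS"] = interdaily_stability(ts, days)
    out["IV"] = intradaily_variability(ts, days)
    if ts.has_photopic:
        out["MPratio"] = mp_ratio(ts)
    return out
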