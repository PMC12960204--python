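"""Compliance with the consensus healthy-light recommendations.

The recommendations divide the 24-h day by the individual sleep schedule:
*day* runs from wake until 3 h before sleep onset (target >= 250 lx mel
EDI), *evening* covers the last 3 h before onset (target <= 10 lx), *night*
covers the sleep episode itself (target <= 1 lx). Compliance is the
fraction of observed epochs inside each window that meet its target,
computed per participant-day, averaged per participant and then per site;
the *overall* figure is the time-weighted average of the three windows
using each participant's own window durations.

Missing epochs are excluded from numerator and denominator alike: a device
on its charger says nothing about the wearer's light environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from .questionnaires import SleepSchedule
from .timeseries import LightTimeseries

__all__ = [
    "RecommendationSpec",
    "ComplianceDay",
    "build_compliance_windows",
    "compliance_fractions",
    "aggregate_compliance",
]

WINDOWS = ("day", "evening", "night")


@dataclass(frozen=True)
class RecommendationSpec:
    """Healthy-light targets (lux mel EDI) and the evening lead time."""

    day_threshold: float = 250.0  # >= during day window
    evening_threshold: float = 10.0  # <= during evening window
    night_threshold: float = 1.0  # <= during night window
    evening_lead_h: float = 3.0

    def __post_init__(self) -> None:
        if not (self.day_threshold > self.evening_threshold > self.night_threshold):
            raise ValueError("require day > evening > night threshold")
        if self.evening_lead_h <= 0:
            raise ValueError("evening lead must be > 0")


@dataclass
class ComplianceDay:
    """Per-window compliance fractions for one participant-day."""

    participant_id: str
    local_date: Date
    fractions: dict[str, float]  # day/evening/night, each 0-1 or NaN
    durations_h: dict[str, float]


def build_compliance_windows(
    schedule: SleepSchedule,
    date: Date,
    tz,
    spec: RecommendationSpec | None = None,
) -> dict[str, tuple[datetime, datetime]]:
    """Half-open day/evening/night intervals anchored to one calendar date.

    The day window starts at the wake time on ``date``; evening and night
    follow, crossing midnight as needed, and together the three windows tile
    exactly 24 h. Raises for degenerate schedules (sleep or wake span not
    longer than the evening lead).
    """
    spec = spec or RecommendationSpec()
    awake_h = (schedule.onset - schedule.offset) % 24.0
    if schedule.duration <= spec.evening_lead_h or awake_h <= spec.evening_lead_h:
        raise ValueError(
            "degenerate windows: sleep and wake spans must both exceed "
            f"the {spec.evening_lead_h}-h evening lead"
        )
    wake_dt = datetime.combine(date, time.min, tzinfo=tz) + timedelta(
        hours=schedule.offset
    )
    onset_dt = wake_dt + timedelta(hours=awake_h)
    evening_start = onset_dt - timedelta(hours=spec.evening_lead_h)
    night_end = wake_dt + timedelta(hours=24.0)
    return {
        "day": (wake_dt, evening_start),
        "evening": (evening_start, onset_dt),
        "night": (onset_dt, night_end),
    }


def compliance_fractions(
    ts: LightTimeseries,
    windows: dict[str, tuple[datetime, datetime]],
    spec: RecommendationSpec | None = None,
    participant_id: str | None = None,
    local_date: Date | None = None,
) -> ComplianceDay:
    """Fraction of observed epochs meeting each window's target.

    A window with no observed epochs gets a NaN fraction (no evidence, not
    non-compliance).
    """
    spec = spec or RecommendationSpec()
    mel = ts.data["mel_edi"]
    idx = ts.data.index
    criteria = {
        "day": lambda v: v >= spec.day_threshold,
        "evening": lambda v: v <= spec.evening_threshold,
        "night": lambda v: v <= spec.night_threshold,
    }
    fractions: dict[str, float] = {}
    durations: dict[str, float] = {}
    for name in WINDOWS:
        start, end = windows[name]
        durations[name] = (end - start).total_seconds() / 3600.0
        values = mel[(idx >= start) & (idx < end)].dropna().to_numpy()
        if values.size == 0:
            fractions[name] = math.nan
        else:
            fractions[name] = float(np.mean(criteria[name](values)))
    return ComplianceDay(
        participant_id=participant_id or ts.participant_id,
        local_date=local_date or windows["day"][0].date(),
        fractions=fractions,
        durations_h=durations,
    )


def _overall(fracs: pd.Series, durs: pd.Series) -> float:
    """Time-weighted average of window fractions by mean window durations."""
    w = np.array([durs[k] for k in WINDOWS], dtype=float)
    f = np.array([fracs[k] for k in WINDOWS], dtype=float)
    ok = ~np.isnan(f)
    if not ok.any():
        return math.nan
    return float(np.sum(f[ok] * w[ok]) / np.sum(w[ok]))


def aggregate_compliance(
    days: list[ComplianceDay], site_of: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average fractions per participant over days, then per site.

    Returns (participant table, site table), each with day/evening/night
    mean fractions and the time-weighted ``overall``. Site rows are
    unweighted means over participants; each participant's overall uses
    that participant's own mean window durations.
    """
    rows = [
        {
            "participant_id": d.participant_id,
            **{k: d.fractions[k] for k in WINDOWS},
            **{f"{k}_h": d.durations_h[k] for k in WINDOWS},
        }
        for d in days
    ]
    df = pd.DataFrame(rows)
    per_part = df.groupby("participant_id").mean(numeric_only=True).reset_index()
    per_part["overall"] = [
        _overall(row[list(WINDOWS)], row[[f"{k}_h" for k in WINDOWS]].rename(
            {f"{k}_h": k for k in WINDOWS}))
        for _, row in per_part.iterrows()
    ]
    per_part["site_id"] = per_part["participant_id"].map(site_of)
    per_site = (
        per_part.drop(columns="participant_id")
        .groupby("site_id")
        .mean(numeric_only=True)
        .reset_index()
    )
    return per_part, per_site
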