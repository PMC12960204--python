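"""LEBA and PSQI scoring, and PSQI-derived sleep timing / chronotype proxy.

LEBA (Light Exposure Behaviour Assessment) has 23 Likert items (1 = never
... 5 = always) grouped into five factors: blue-light filter use (F1), time
spent outdoors (F2), phone/smartwatch use in bed (F3), light use before
bedtime (F4), and light use in the morning and daytime (F5). Factor scores
are plain item sums, with item 4 ("30 min or less outside per day")
reverse-scored inside F2 so that higher F2 always means more outdoor time.

The shipped item-to-factor map (``data/leba_factors.csv``) follows the
published instrument's five-factor structure; it can be overridden with any
table of the same shape.

PSQI (Pittsburgh Sleep Quality Index) is scored by the standard component
rules (seven components each 0-3, global 0-21, higher = worse); a global
score above 5 flags clinically relevant sleep difficulties. Items 1-3
additionally yield the typical sleep schedule, whose circular midpoint
(mid-sleep) serves as a chronotype proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from importlib import resources

import pandas as pd

__all__ = [
    "LEBAResponse",
    "LEBAFactors",
    "PSQIResponse",
    "PSQIScore",
    "SleepSchedule",
    "load_factor_map",
    "score_leba",
    "score_psqi",
    "derive_sleep_schedule",
    "LIKERT_LABELS",
]

LIKERT_LABELS = {"never": 1, "rarely": 2, "sometimes": 3, "often": 4, "always": 5}
FACTORS = ("F1", "F2", "F3", "F4", "F5")


def load_factor_map(path: str | None = None) -> pd.DataFrame:
    """Item-to-factor map: columns item (1..23), factor (F1..F5), reverse (0/1)."""
    if path is None:
        ref = resources.files("luxdose.data").joinpath("leba_factors.csv")
        with resources.as_file(ref) as p:
            fm = pd.read_csv(p)
    else:
        fm = pd.read_csv(path)
    if sorted(fm["item"]) != list(range(1, 24)):
        raise ValueError("factor map must cover items 1..23 exactly once")
    if not set(fm["factor"]).issubset(FACTORS):
        raise ValueError("factors must be F1..F5")
    return fm


@dataclass(frozen=True)
class LEBAResponse:
    """One LEBA assessment: 23 ordinal answers, each in 1..5."""

    participant_id: str
    assessment_date: Date
    items: tuple[int, ...]
    recall_window: str = "days"  # 'days' (past 3-4 days) or 'weeks' (past 4 weeks)

    def __post_init__(self) -> None:
        if len(self.items) != 23:
            raise ValueError(f"LEBA has 23 items, got {len(self.items)}")
        for i, v in enumerate(self.items, start=1):
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"item {i} out of range: {v!r} (must be 1..5)")


@dataclass(frozen=True)
class LEBAFactors:
    """Factor sums F1..F5 plus the raw item vector they were computed from."""

    participant_id: str
    assessment_date: Date
    F1: int
    F2: int
    F3: int
    F4: int
    F5: int
    items: tuple[int, ...]

    def as_dict(self) -> dict[str, int]:
        return {"F1": self.F1, "F2": self.F2, "F3": self.F3, "F4": self.F4, "F5": self.F5}


def score_leba(resp: LEBAResponse, factor_map: pd.DataFrame | None = None) -> LEBAFactors:
    """Sum items into the five factors, reverse-scoring where the map says so.

    A reversed item contributes 6 - raw to its factor (so raw 1 counts as 5).
    """
    fm = factor_map if factor_map is not None else load_factor_map()
    sums = {f: 0 for f in FACTORS}
    for _, row in fm.iterrows():
        raw = resp.items[int(row["item"]) - 1]
        sums[row["factor"]] += (6 - raw) if int(row["reverse"]) else raw
    return LEBAFactors(
        participant_id=resp.participant_id,
        assessment_date=resp.assessment_date,
        items=resp.items,
        **sums,
    )


@dataclass(frozen=True)
class PSQIResponse:
    """The PSQI items needed for standard component scoring.

    Clock times are fractional hours on the 24-h circle; ``latency_min`` in
    minutes; ``sleep_hours`` is self-reported actual sleep; the ordinal items
    are already coded 0-3 (disturbance items 5b-5j as a 9-tuple).
    """

    participant_id: str
    assessment_date: Date
    bedtime: float  # item 1, clock h
    latency_min: float  # item 2
    waketime: float  # item 3, clock h
    sleep_hours: float  # item 4
    latency_problem: int  # item 5a, 0-3
    disturbances: tuple[int, ...]  # items 5b-5j, each 0-3
    quality: int  # item 6, 0-3
    medication: int  # item 7, 0-3
    sleepiness: int  # item 8, 0-3
    enthusiasm_problem: int  # item 9, 0-3

    def __post_init__(self) -> None:
        if len(self.disturbances) != 9:
            raise ValueError("items 5b-5j must be a 9-tuple")
        for name in ("latency_problem", "quality", "medication", "sleepiness",
                     "enthusiasm_problem"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3):
                raise ValueError(f"{name} must be 0..3, got {v!r}")
        if any(v not in (0, 1, 2, 3) for v in self.disturbances):
            raise ValueError("disturbance items must each be 0..3")
        if self.latency_min < 0:
            raise ValueError("latency must be >= 0")


@dataclass(frozen=True)
class PSQIScore:
    participant_id: str
    assessment_date: Date
    components: tuple[int, ...]  # C1..C7, each 0-3
    global_score: int = field(init=False)
    poor_sleep: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.components) != 7:
            raise ValueError("PSQI has 7 components")
        g = int(sum(self.components))
        object.__setattr__(self, "global_score", g)
        object.__setattr__(self, "poor_sleep", g > 5)


def _band(value: float, cuts: tuple[float, float, float]) -> int:
    """0..3 by how many cut points the value exceeds (strictly)."""
    return sum(value > c for c in cuts)


def score_psqi(resp: PSQIResponse) -> PSQIScore:
    """Standard PSQI component scoring (Buysse rules)."""
    # C1 subjective quality
    c1 = resp.quality
    # C2 latency: banded minutes + item 5a, re-banded
    lat_band = _band(resp.latency_min, (15, 30, 60))
    c2 = _band(lat_band + resp.latency_problem, (0, 2, 4))
    # C3 duration: >7 h -> 0, 6-7 -> 1, 5-6 -> 2, <5 -> 3
    if resp.sleep_hours > 7:
        c3 = 0
    elif resp.sleep_hours >= 6:
        c3 = 1
    elif resp.sleep_hours >= 5:
        c3 = 2
    else:
        c3 = 3
    # C4 habitual efficiency = sleep hours / time in bed
    time_in_bed = (resp.waketime - resp.bedtime) % 24.0
    if time_in_bed == 0:
        raise ValueError("bedtime equals waketime: time in bed undefined")
    eff = 100.0 * resp.sleep_hours / time_in_bed
    if eff >= 85:
        c4 = 0
    elif eff >= 75:
        c4 = 1
    elif eff >= 65:
        c4 = 2
    else:
        c4 = 3
    # C5 disturbances: sum of 5b-5j, banded
    dist = sum(resp.disturbances)
    c5 = 0 if dist == 0 else _band(dist, (0, 9, 18))
    # C6 medication
    c6 = resp.medication
    # C7 daytime dysfunction: item 8 + item 9, re-banded
    c7 = _band(resp.sleepiness + resp.enthusiasm_problem, (0, 2, 4))
    return PSQIScore(
        participant_id=resp.participant_id,
        assessment_date=resp.assessment_date,
        components=(c1, c2, c3, c4, c5, c6, c7),
    )


@dataclass(frozen=True)
class SleepSchedule:
    """Typical sleep timing on the 24-h circle.

    onset = bedtime + latency; duration = waketime - onset (mod 24);
    mid_sleep = onset + duration/2 (mod 24), the chronotype proxy. No
    workday/free-day sleep-debt correction is applied (that information is
    not collected by the PSQI).
    """

    onset: float
    offset: float
    duration: float
    mid_sleep: float


def derive_sleep_schedule(
    bedtime: float, latency_min: float, waketime: float
) -> SleepSchedule:
    """Sleep schedule from PSQI items 1-3 (clock hours and latency minutes)."""
    if latency_min < 0:
        raise ValueError("latency must be >= 0")
    onset = (bedtime + latency_min / 60.0) % 24.0
    duration = (waketime - onset) % 24.0
    if duration == 0:
        raise ValueError("degenerate schedule: sleep duration computes to 0 or 24 h")
    mid = (onset + duration / 2.0) % 24.0
    return SleepSchedule(onset=onset, offset=waketime % 24.0, duration=duration, mid_sleep=mid)
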