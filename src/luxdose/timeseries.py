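"""Data model, ingestion, regularisation and cleaning of light-logger series.

A recording is a regular-epoch time series of melanopic equivalent daylight
illuminance (mel EDI, lux) with an optional photopic illuminance channel,
held in a pandas DataFrame indexed by timezone-aware local timestamps.
Missing epochs are explicit NaN rows; cleaning never deletes rows.

Cleaning rules
--------------
* photopic readings at or above the device ceiling (130,000 lux) mark the
  whole sample as missing (outside the sensor's plausible range);
* readings below 1 lux are kept as measured for threshold metrics, and are
  replaced by 0.1 lux only when a logarithmic analysis is requested
  (``log_mode``), so that log10 is defined in darkness;
* a participant-day with more than 6 h of missing data is flagged invalid
  and excluded from day-level metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from .solar import GeoSite, local_day_bounds

__all__ = [
    "CleaningPolicy",
    "LightTimeseries",
    "DayRecord",
    "read_logger_csv",
    "write_logger_csv",
    "regularize",
    "apply_exclusions",
    "split_valid_days",
]

log = logging.getLogger(__name__)

TIMESTAMP_COL = "timestamp"
MEL_COL = "mel_edi_lux"
PHOTOPIC_COL = "photopic_lux"


class FormatError(ValueError):
    """The input file does not match the expected column layout."""


class DataError(ValueError):
    """The input violates a data invariant (duplicates, non-monotone times)."""


class AlignmentError(ValueError):
    """Observed timestamps do not sit on the declared epoch grid."""


@dataclass(frozen=True)
class CleaningPolicy:
    """Thresholds governing exclusion, dark replacement and day validity."""

    photopic_ceiling: float = 130_000.0
    dark_floor: float = 1.0
    dark_replacement: float = 0.1
    max_daily_missing_h: float = 6.0

    def __post_init__(self) -> None:
        if not (self.photopic_ceiling > self.dark_floor > self.dark_replacement > 0):
            raise ValueError("require ceiling > floor > replacement > 0")
        if not 0 <= self.max_daily_missing_h <= 24:
            raise ValueError("max_daily_missing_h must be within [0, 24]")


@dataclass
class LightTimeseries:
    """One participant's recording: regular-epoch mel-EDI (+ photopic) series.

    ``data`` is indexed by tz-aware local timestamps and has a ``mel_edi``
    column and, if the device reported it, a ``photopic`` column. NaN means
    missing.
    """

    participant_id: str
    site_id: str
    epoch_s: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex) or self.data.index.tz is None:
            raise ValueError("data must be indexed by tz-aware timestamps")
        if "mel_edi" not in self.data.columns:
            raise ValueError("data must contain a 'mel_edi' column")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise DataError("timestamps must be strictly increasing")

    @property
    def has_photopic(self) -> bool:
        return "photopic" in self.data.columns

    @property
    def n_missing(self) -> int:
        return int(self.data["mel_edi"].isna().sum())

    @property
    def n_observed(self) -> int:
        return int(self.data["mel_edi"].notna().sum())

    def is_regular(self) -> bool:
        if len(self.data) < 2:
            return True
        deltas = np.diff(self.data.index.asi8) / 1e9
        return bool(np.all(deltas == self.epoch_s))


@dataclass
class DayRecord:
    """One local calendar day of a recording, with its validity flag.

    ``missing_fraction`` is missing epochs over the expected epoch count for
    the full local date (23/24/25 h on DST transition days); partial first
    and last days are therefore penalised against a full-day expectation.
    """

    participant_id: str
    local_date: Date
    data: pd.DataFrame
    epoch_s: int
    expected_epochs: int
    missing_fraction: float
    valid: bool

    @property
    def n_observed(self) -> int:
        return int(self.data["mel_edi"].notna().sum())


def read_logger_csv(
    path: str | Path,
    site: GeoSite,
    epoch_s: int,
    participant_id: str | None = None,
    sep: str = ",",
) -> LightTimeseries:
    """Read a delimited-text logger export into a LightTimeseries.

    The file must have a ``timestamp`` column (ISO-8601, with offset or naive
    local time in the site zone) and a ``mel_edi_lux`` column; a
    ``photopic_lux`` column is optional. Rows whose timestamp cannot be
    parsed are dropped with a logged count; duplicate timestamps are an
    error naming the offending instant.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    missing_cols = {TIMESTAMP_COL, MEL_COL} - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path.name}: missing required columns {sorted(missing_cols)}")

    stamps = pd.to_datetime(df[TIMESTAMP_COL], errors="coerce", format="ISO8601")
    n_bad = int(stamps.isna().sum())
    if n_bad:
        log.warning("%s: rejected %d rows with unparseable timestamps", path.name, n_bad)
    df = df.loc[stamps.notna()].copy()
    stamps = stamps.dropna()
    if stamps.dt.tz is None:
        stamps = stamps.dt.tz_localize(site.tzinfo)
    else:
        stamps = stamps.dt.tz_convert(site.tzinfo)

    out = pd.DataFrame({"mel_edi": pd.to_numeric(df[MEL_COL], errors="coerce").to_numpy()})
    if PHOTOPIC_COL in df.columns:
        out["photopic"] = pd.to_numeric(df[PHOTOPIC_COL], errors="coerce").to_numpy()
    out.index = pd.DatetimeIndex(stamps.to_numpy(), tz=site.tzinfo)
    out = out.sort_index()
    if out.index.has_duplicates:
        dup = out.index[out.index.duplicated()][0]
        raise DataError(f"{path.name}: duplicated timestamp {dup.isoformat()}")

    return LightTimeseries(
        participant_id=participant_id or path.stem,
        site_id=site.name,
        epoch_s=epoch_s,
        data=out,
    )


def write_logger_csv(ts: LightTimeseries, path: str | Path, sep: str = ",") -> None:
    """Write a series in the same dialect the reader accepts, plus a quality column."""
    out = pd.DataFrame(
        {
            TIMESTAMP_COL: [t.isoformat() for t in ts.data.index],
            MEL_COL: ts.data["mel_edi"].to_numpy(),
        }
    )
    if ts.has_photopic:
        out[PHOTOPIC_COL] = ts.data["photopic"].to_numpy()
    out["quality"] = np.where(ts.data["mel_edi"].isna(), "missing", "ok")
    out.to_csv(path, sep=sep, index=False)


def regularize(ts: LightTimeseries) -> LightTimeseries:
    """Make implicit gaps explicit: reindex onto the full epoch grid.

    Every epoch between the first and last observed timestamp is present in
    the output; inserted epochs carry NaN. Observed values are never altered.
    Timestamps off the epoch grid raise :class:`AlignmentError` rather than
    being silently snapped, since resampling would change metric values.
    """
    if ts.data.empty:
        return ts
    idx = ts.data.index
    offsets = (idx.asi8 - idx.asi8[0]) / 1e9
    misaligned = offsets % ts.epoch_s != 0
    if misaligned.any():
        bad = idx[misaligned][0]
        raise AlignmentError(
            f"timestamp {bad.isoformat()} is not aligned to the {ts.epoch_s}-s epoch grid"
        )
    grid = pd.date_range(idx[0], idx[-1], freq=f"{ts.epoch_s}s")
    return replace(ts, data=ts.data.reindex(grid))


def apply_exclusions(
    ts: LightTimeseries, policy: CleaningPolicy | None = None, log_mode: bool = False
) -> LightTimeseries:
    """Apply the plausibility ceiling and, optionally, the dark-floor replacement.

    Samples whose photopic reading reaches ``photopic_ceiling`` are set
    missing in both channels. With ``log_mode=True``, mel-EDI values below
    ``dark_floor`` are replaced by ``dark_replacement`` so that subsequent
    log10 transforms are defined; without it sub-floor readings are kept as
    measured (threshold metrics use raw values).
    """
    policy = policy or CleaningPolicy()
    data = ts.data.copy()
    n_ceiling = 0
    if "photopic" in data.columns:
        over = data["photopic"] >= policy.photopic_ceiling
        n_ceiling = int(over.sum())
        data.loc[over, ["mel_edi", "photopic"]] = np.nan
    n_dark = 0
    if log_mode:
        dark = data["mel_edi"] < policy.dark_floor
        n_dark = int(dark.sum())
        data.loc[dark, "mel_edi"] = policy.dark_replacement
    log.info(
        "exclusions for %s: %d samples at ceiling, %d dark replacements",
        ts.participant_id,
        n_ceiling,
        n_dark,
    )
    return replace(ts, data=data)


def split_valid_days(
    ts: LightTimeseries, policy: CleaningPolicy | None = None
) -> list[DayRecord]:
    """Slice a regularized series into local calendar days and flag validity.

    A day is valid when its missing time is at most ``max_daily_missing_h``
    (the threshold is "more than", so exactly 6 h missing is still valid).
    Returns one DayRecord per local date covered; empty series give [].
    """
    policy = policy or CleaningPolicy()
    if ts.data.empty:
        return []
    tz = ts.data.index.tz
    dates = ts.data.index.tz_convert(tz).date
    records: list[DayRecord] = []
    for day, chunk in ts.data.groupby(dates):
        start, end = local_day_bounds(day, tz)
        # absolute duration (23/24/25 h across DST), not wall-clock difference
        expected = int(round((end.timestamp() - start.timestamp()) / ts.epoch_s))
        n_obs = int(chunk["mel_edi"].notna().sum())
        missing = expected - n_obs
        missing_fraction = missing / expected
        missing_h = missing * ts.epoch_s / 3600.0
        records.append(
            DayRecord(
                participant_id=ts.participant_id,
                local_date=day,
                data=chunk,
                epoch_s=ts.epoch_s,
                expected_epochs=expected,
                missing_fraction=missing_fraction,
                valid=missing_h <= policy.max_daily_missing_h,
            )
        )
    records.sort(key=lambda r: r.local_date)
    return records
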