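"""Civil twilight, photoperiod and day/evening/night segmentation.

Dawn and dusk are the instants at which the solar centre crosses a given
depression angle below the horizon (default 6 degrees, i.e. civil twilight).
The solar position is computed with the NOAA fractional-year / equation-of-time
formulation, which is accurate to about +/-2 minutes at temperate latitudes --
ample for segmenting wearable light-exposure recordings.

All returned datetimes are timezone-aware in the site's IANA zone, so daylight
saving time is handled by the zone database, not by this module.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, time, timedelta
from zoneinfo import ZoneInfo

__all__ = [
    "GeoSite",
    "SolarDay",
    "civil_dawn_dusk",
    "solar_days",
    "segment_timestamp",
    "mean_photoperiod",
    "mean_noon_difference",
    "local_day_bounds",
]


class PolarTwilightError(ValueError):
    """The sun never reaches the requested depression angle on this date."""


@dataclass(frozen=True)
class GeoSite:
    """A study site: coordinates, IANA time zone and twilight depression angle.

    Latitude is restricted to |lat| <= 66 degrees so that civil twilight
    exists on every calendar date.
    """

    name: str
    latitude: float
    longitude: float
    tz: str
    depression_deg: float = 6.0

    def __post_init__(self) -> None:
        if abs(self.latitude) > 66.0:
            raise ValueError(
                f"|latitude| must be <= 66 deg (got {self.latitude}): "
                "civil twilight must exist on every date"
            )
        if self.depression_deg <= 0:
            raise ValueError("depression_deg must be > 0")

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.tz)


@dataclass(frozen=True)
class SolarDay:
    """Civil dawn/dusk and derived segment boundaries for one local date.

    ``centre`` is the midpoint of dawn and dusk expressed as local clock
    hours since midnight; ``evening_length_h`` is the clock duration from
    dusk to the following midnight.
    """

    local_date: Date
    civil_dawn: datetime
    civil_dusk: datetime
    photoperiod_h: float = field(init=False)
    centre: float = field(init=False)
    evening_length_h: float = field(init=False)

    def __post_init__(self) -> None:
        if self.civil_dawn >= self.civil_dusk:
            raise ValueError("civil_dawn must precede civil_dusk")
        # absolute duration: same-zone aware subtraction would be wall-clock
        # and miss a DST transition between dawn and dusk
        object.__setattr__(
            self,
            "photoperiod_h",
            (self.civil_dusk.timestamp() - self.civil_dawn.timestamp()) / 3600.0,
        )
        mid = self.civil_dawn + (self.civil_dusk - self.civil_dawn) / 2
        object.__setattr__(self, "centre", _clock_hours(mid))
        tz = self.civil_dusk.tzinfo
        next_midnight = datetime.combine(
            self.local_date + timedelta(days=1), time.min, tzinfo=tz
        )
        # evening length is deliberately the *clock* duration dusk -> midnight
        # (same-zone naive subtraction), matching the local-time convention
        object.__setattr__(
            self,
            "evening_length_h",
            (next_midnight - self.civil_dusk).total_seconds() / 3600.0,
        )


def _clock_hours(t: datetime) -> float:
    """Local clock time as fractional hours since local midnight."""
    return t.hour + t.minute / 60.0 + (t.second + t.microsecond / 1e6) / 3600.0


def _fractional_year(doy: int, hour: float, year: int) -> float:
    days = 366 if calendar.isleap(year) else 365
    return 2.0 * math.pi / days * (doy - 1 + (hour - 12.0) / 24.0)


def _equation_of_time_min(g: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )


def _solar_declination_rad(g: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )


def _crossing_utc_minutes(
    date: Date, site: GeoSite, rising: bool
) -> float:
    """UTC minutes (from the date's UTC midnight) of the twilight crossing.

    Two-pass evaluation: the fractional year is first taken at 12:00 UTC and
    then refined at the event time found, which brings the equation of time
    and declination to their values at the event.
    """
    zenith = math.radians(90.0 + site.depression_deg)
    lat = math.radians(site.latitude)
    doy = date.timetuple().tm_yday
    minutes = 720.0
    for _ in range(2):
        g = _fractional_year(doy, minutes / 60.0, date.year)
        decl = _solar_declination_rad(g)
        eqtime = _equation_of_time_min(g)
        cos_ha = math.cos(zenith) / (math.cos(lat) * math.cos(decl)) - math.tan(
            lat
        ) * math.tan(decl)
        if not -1.0 <= cos_ha <= 1.0:
            raise PolarTwilightError(
                f"sun does not cross {site.depression_deg} deg depression at "
                f"{site.name} on {date}"
            )
        ha_deg = math.degrees(math.acos(cos_ha))
        if rising:
            minutes = 720.0 - 4.0 * (site.longitude + ha_deg) - eqtime
        else:
            minutes = 720.0 - 4.0 * (site.longitude - ha_deg) - eqtime
    return minutes


def civil_dawn_dusk(date: Date, site: GeoSite) -> SolarDay:
    """Civil dawn and dusk for one local calendar date at a site.

    Raises :class:`PolarTwilightError` if the sun never reaches the site's
    depression angle on that date (cannot happen within |lat| <= 66 for the
    civil 6-degree angle).
    """
    tz = site.tzinfo
    utc = ZoneInfo("UTC")
    midnight_utc = datetime.combine(date, time.min, tzinfo=utc)
    dawn = midnight_utc + timedelta(
        minutes=_crossing_utc_minutes(date, site, rising=True)
    )
    dusk = midnight_utc + timedelta(
        minutes=_crossing_utc_minutes(date, site, rising=False)
    )
    return SolarDay(
        local_date=date,
        civil_dawn=dawn.astimezone(tz),
        civil_dusk=dusk.astimezone(tz),
    )


def solar_days(site: GeoSite, start: Date, end: Date) -> list[SolarDay]:
    """SolarDay for every date in the closed range [start, end]."""
    if end < start:
        raise ValueError("end date precedes start date")
    out = []
    d = start
    while d <= end:
        out.append(civil_dawn_dusk(d, site))
        d += timedelta(days=1)
    return out


def segment_timestamp(t: datetime, sd: SolarDay) -> str:
    """Label a timestamp on sd.local_date as 'day', 'evening' or 'night'.

    Half-open convention: day = [dawn, dusk), evening = [dusk, midnight),
    night = [midnight, dawn).
    """
    if t.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    if sd.civil_dawn <= t < sd.civil_dusk:
        return "day"
    if t >= sd.civil_dusk:
        return "evening"
    return "night"


def mean_photoperiod(site: GeoSite, start: Date, end: Date) -> float:
    """Arithmetic mean of civil-dawn-to-dusk duration (hours) over the range."""
    days = solar_days(site, start, end)
    return sum(sd.photoperiod_h for sd in days) / len(days)


def mean_noon_difference(
    site_a: GeoSite,
    dates_a: tuple[Date, Date],
    site_b: GeoSite,
    dates_b: tuple[Date, Date],
) -> float:
    """|difference| in mean local-clock photoperiod centre between two sites.

    Centres are compared as local clock times of day (hours since local
    midnight), matching the convention that cross-site comparisons are made
    on the local timeline rather than in absolute time.
    """
    mean_a = _mean_centre(site_a, *dates_a)
    mean_b = _mean_centre(site_b, *dates_b)
    return abs(mean_a - mean_b)


def _mean_centre(site: GeoSite, start: Date, end: Date) -> float:
    days = solar_days(site, start, end)
    return sum(sd.centre for sd in days) / len(days)


def local_day_bounds(date: Date, tz: ZoneInfo) -> tuple[datetime, datetime]:
    """Aware [midnight, next-midnight) bounds of a local calendar date.

    On daylight-saving transition days the interval is 23 or 25 clock hours;
    callers use the true duration as the expected-epoch denominator.
    """
    start = datetime.combine(date, time.min, tzinfo=tz)
    end = datetime.combine(date + timedelta(days=1), time.min, tzinfo=tz)
    return start, end
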