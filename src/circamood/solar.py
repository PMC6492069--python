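"""Sunrise/sunset computation and the solar-anchored analysis windows.

All downstream light and activity features are aggregated inside two
timeslots per calendar day:

* ``daytime``  — ``[sunrise(d), sunset(d))``
* ``bedtime``  — the 8-hour interval ending at sunrise, i.e.
  ``[sunrise(d+1) - 8h, sunrise(d+1))`` for the night *following* day ``d``.

Bedtime has a constant 8-hour duration; only its placement moves with the
seasons.  Solar times come from the standard NOAA low-precision solar
position equations (accurate to a few minutes at mid latitudes), or from a
user-supplied override table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta
from typing import Optional

import pandas as pd

__all__ = [
    "SolarTimes",
    "Interval",
    "SolarCalendar",
    "sun_times",
    "UnsupportedSiteError",
]

#: refraction-corrected zenith used for official sunrise/sunset (degrees)
_SUN_ZENITH = 90.833

#: latitudes beyond this may have polar day/night; not supported
MAX_LATITUDE = 66.0

BEDTIME_HOURS = 8.0


class UnsupportedSiteError(ValueError):
    """Raised for sites where sunrise/sunset may not exist (polar latitudes)."""


@dataclass(frozen=True)
class SolarTimes:
    date: Date
    sunrise: datetime  # naive, local civil time
    sunset: datetime

    def __post_init__(self) -> None:
        if not self.sunrise < self.sunset:
            raise ValueError("sunrise must precede sunset")


@dataclass(frozen=True)
class Interval:
    """Half-open time interval ``[start, end)`` in local civil time."""

    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval start must precede end")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    def contains(self, ts: datetime) -> bool:
        return self.start <= ts < self.end


def _julian_day(d: Date) -> float:
    """Julian day number at 00:00 UT of the given Gregorian date."""
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _solar_params(jc: float) -> tuple[float, float]:
    """Return (equation of time [minutes], solar declination [degrees])
    for a Julian century ``jc`` past J2000.0.  NOAA low-precision model."""
    geom_mean_long = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    ma = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(ma) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * ma) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * ma) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - 0.001813 * jc))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    decl = math.degrees(math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long))))
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    gml = math.radians(geom_mean_long)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * gml)
        - 2.0 * ecc * math.sin(ma)
        + 4.0 * ecc * var_y * math.sin(ma) * math.cos(2 * gml)
        - 0.5 * var_y**2 * math.sin(4 * gml)
        - 1.25 * ecc**2 * math.sin(2 * ma)
    )
    return eq_time, decl


def sun_times(d: Date, latitude: float, longitude: float, tz: float) -> SolarTimes:
    """Compute local sunrise and sunset for one date.

    Parameters
    ----------
    d : datetime.date
        Calendar date at the site.
    latitude, longitude : float
        Degrees; east and north positive.
    tz : float
        Fixed UTC offset of local civil time, in hours.

    Raises
    ------
    UnsupportedSiteError
        If ``|latitude| >= 66`` or the sun does not rise/set on that date.
    """
    if abs(latitude) >= MAX_LATITUDE:
        raise UnsupportedSiteError(f"latitude {latitude} not supported (|lat| must be < {MAX_LATITUDE})")
    # evaluate the slowly varying orbital terms at local civil noon
    jd = _julian_day(d) + 0.5 - tz / 24.0
    jc = (jd - 2451545.0) / 36525.0
    eq_time, decl = _solar_params(jc)
    lat_r = math.radians(latitude)
    decl_r = math.radians(decl)
    cos_ha = math.cos(math.radians(_SUN_ZENITH)) / (math.cos(lat_r) * math.cos(decl_r)) - math.tan(lat_r) * math.tan(decl_r)
    if not -1.0 <= cos_ha <= 1.0:
        raise UnsupportedSiteError(f"no sunrise/sunset at latitude {latitude} on {d}")
    ha = math.degrees(math.acos(cos_ha))
    noon_min = 720.0 - 4.0 * longitude - eq_time + tz * 60.0
    sunrise_min = noon_min - 4.0 * ha
    sunset_min = noon_min + 4.0 * ha
    midnight = datetime(d.year, d.month, d.day)
    return SolarTimes(
        date=d,
        sunrise=midnight + timedelta(minutes=sunrise_min),
        sunset=midnight + timedelta(minutes=sunset_min),
    )


def _load_suntimes_table(table: pd.DataFrame) -> dict[Date, tuple[datetime, datetime]]:
    required = {"date", "sunrise", "sunset"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"suntimes table missing columns: {sorted(missing)}")
    out: dict[Date, tuple[datetime, datetime]] = {}
    for _, row in table.iterrows():
        d = pd.Timestamp(row["date"]).date()
        sr = pd.Timestamp(row["sunrise"]).to_pydatetime().replace(tzinfo=None)
        ss = pd.Timestamp(row["sunset"]).to_pydatetime().replace(tzinfo=None)
        out[d] = (sr, ss)
    return out


@dataclass
class SolarCalendar:
    """Per-site solar times with optional verbatim override table.

    An override table (columns ``date,sunrise,sunset``) takes precedence over
    the computed NOAA values for every date it contains.
    """

    latitude: float
    longitude: float
    tz: float
    suntimes: Optional[pd.DataFrame] = None
    _table: dict = field(default_factory=dict, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.suntimes is not None:
            self._table = _load_suntimes_table(self.suntimes)

    def sun_times(self, d: Date) -> SolarTimes:
        d = pd.Timestamp(d).date()
        if d in self._table:
            sr, ss = self._table[d]
            return SolarTimes(date=d, sunrise=sr, sunset=ss)
        if d not in self._cache:
            self._cache[d] = sun_times(d, self.latitude, self.longitude, self.tz)
        return self._cache[d]

    def daytime_window(self, d: Date) -> Interval:
        """``[sunrise(d), sunset(d))`` for calendar day ``d``."""
        st = self.sun_times(d)
        return Interval(st.sunrise, st.sunset)

    def bedtime_window(self, d: Date) -> Interval:
        """The 8-hour window ending at sunrise of day ``d+1`` — the night
        that follows day ``d``.  Duration is exactly 8 h for every date."""
        nxt = pd.Timestamp(d).date() + timedelta(days=1)
        st = self.sun_times(nxt)
        return Interval(st.sunrise - timedelta(hours=BEDTIME_HOURS), st.sunrise)
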