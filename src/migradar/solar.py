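"""Solar events and biological-period segmentation.

Sunrise and sunset are computed with the NOAA solar-position equations
(Meeus-style low-precision series) at the standard refraction-corrected
altitude of -0.833 degrees, with no site-elevation correction.  From these
the four biological periods of a solar cycle are derived:

* ``dawn``  -- 30 min before sunrise to 30 min after sunrise (always 1 h)
* ``day``   -- 30 min after sunrise to 30 min before sunset
* ``dusk``  -- 30 min before sunset to 30 min after sunset (always 1 h)
* ``night`` -- 30 min after sunset to 30 min before the next sunrise

All period intervals are half-open ``[start, end)``.  A night spans local
midnight and is attributed to the calendar date of its dusk, so a
dusk-night-dawn sequence forms one migration night.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PERIODS = ("dawn", "day", "dusk", "night")

#: Solar altitude (degrees) defining sunrise/sunset: 16' solar radius plus
#: 34' standard atmospheric refraction.
SUNRISE_ALTITUDE_DEG = -0.833

_HALF_TRANSITION = dt.timedelta(minutes=30)


class PolarLatitudeError(ValueError):
    """Raised for latitudes where the sun may not rise or set."""


def _julian_day(date: dt.date) -> float:
    # Julian day number at 00:00 UT for a Gregorian calendar date.
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_params(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (degrees) at
    Julian century ``jc`` since J2000.0 (NOAA spreadsheet series)."""
    l0 = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m)
    c = (
        math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    seconds = 21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))
    mean_obliq = 23.0 + (26.0 + seconds / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        var_y * math.sin(2 * l0r)
        - 2.0 * e * math.sin(mr)
        + 4.0 * e * var_y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * var_y * var_y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mr)
    )
    return eot, decl


@dataclass(frozen=True)
class SolarDay:
    """Sunrise/sunset for one civil date plus the derived period bounds.

    ``period_bounds`` maps each period name to its half-open UTC interval.
    The night interval belongs to this date (the date of its dusk) even
    though it ends after the following sunrise.
    """

    date: dt.date
    sunrise: dt.datetime
    sunset: dt.datetime
    period_bounds: dict = field(default_factory=dict)

    @property
    def daylight(self) -> dt.timedelta:
        return self.sunset - self.sunrise

    @property
    def period_durations(self) -> dict:
        """Nominal per-cycle durations keyed by period name.

        These are the conventional bookkeeping durations for one solar
        cycle, computed from this date's sunrise/sunset alone (night =
        24 h - day - 2 h), and sum to exactly 24 h.  The *segmentation*
        bounds in ``period_bounds`` are physical — night ends 30 min
        before the next day's sunrise — and differ from these by the
        day-to-day sunrise drift (< 2 min at temperate latitudes).
        """
        day = self.daylight - dt.timedelta(hours=1)
        hour = dt.timedelta(hours=1)
        return {
            "dawn": hour,
            "day": day,
            "dusk": hour,
            "night": dt.timedelta(hours=24) - day - 2 * hour,
        }


def _sunrise_sunset_utc(
    date: dt.date, latitude_deg: float, longitude_deg: float
) -> tuple[dt.datetime, dt.datetime]:
    if abs(latitude_deg) >= 66.5:
        raise PolarLatitudeError(
            f"latitude {latitude_deg} is inside the polar circles; "
            "polar day/night is not supported"
        )
    jd = _julian_day(date)
    # evaluate the series at local solar noon for ~sub-minute accuracy
    jc = (jd + 0.5 - longitude_deg / 360.0 - 2451545.0) / 36525.0
    eot, decl = _solar_params(jc)
    lat_r = math.radians(latitude_deg)
    decl_r = math.radians(decl)
    cos_h = (
        math.cos(math.radians(90.0 - SUNRISE_ALTITUDE_DEG)) / (math.cos(lat_r) * math.cos(decl_r))
        - math.tan(lat_r) * math.tan(decl_r)
    )
    if not -1.0 < cos_h < 1.0:
        raise PolarLatitudeError(
            f"sun does not rise/set at latitude {latitude_deg} on {date}"
        )
    ha_deg = math.degrees(math.acos(cos_h))
    noon_min = 720.0 - 4.0 * longitude_deg - eot
    midnight = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    sunrise = midnight + dt.timedelta(minutes=noon_min - 4.0 * ha_deg)
    sunset = midnight + dt.timedelta(minutes=noon_min + 4.0 * ha_deg)
    return sunrise, sunset


def solar_times(date: dt.date, latitude_deg: float, longitude_deg: float) -> SolarDay:
    """Sunrise, sunset and biological-period bounds for one civil date.

    Longitude is east-positive decimal degrees (study sites are ~ -86).
    The night bound requires the *next* day's sunrise, so it is computed
    here as well.
    """
    sunrise, sunset = _sunrise_sunset_utc(date, latitude_deg, longitude_deg)
    next_sunrise, _ = _sunrise_sunset_utc(
        date + dt.timedelta(days=1), latitude_deg, longitude_deg
    )
    bounds = {
        "dawn": (sunrise - _HALF_TRANSITION, sunrise + _HALF_TRANSITION),
        "day": (sunrise + _HALF_TRANSITION, sunset - _HALF_TRANSITION),
        "dusk": (sunset - _HALF_TRANSITION, sunset + _HALF_TRANSITION),
        "night": (sunset + _HALF_TRANSITION, next_sunrise - _HALF_TRANSITION),
    }
    return SolarDay(date=date, sunrise=sunrise, sunset=sunset, period_bounds=bounds)


def solar_calendar(
    start: dt.date, end: dt.date, latitude_deg: float, longitude_deg: float
) -> list[SolarDay]:
    """Inclusive sequence of :class:`SolarDay` covering ``[start, end]``."""
    days = []
    d = start
    while d <= end:
        days.append(solar_times(d, latitude_deg, longitude_deg))
        d += dt.timedelta(days=1)
    return days


def _interval_table(calendar: Sequence[SolarDay]) -> pd.DataFrame:
    rows = []
    for day in calendar:
        for period, (lo, hi) in day.period_bounds.items():
            rows.append((lo, hi, period, day.date))
    df = pd.DataFrame(rows, columns=["start", "end", "period", "night_id"])
    return df.sort_values("start").reset_index(drop=True)


def assign_period(
    timestamps: Iterable[dt.datetime] | pd.Series,
    calendar: Sequence[SolarDay],
) -> pd.DataFrame:
    """Assign each UTC timestamp to its biological period.

    Returns a DataFrame with columns ``period`` and ``night_id`` (the local
    civil date of the solar day each period instance belongs to; for night
    this is the date of the night's dusk).  Intervals are half-open
    ``[start, end)``.  Raises ``ValueError`` for timestamps not covered by
    the calendar.
    """
    table = _interval_table(calendar)
    ts = pd.to_datetime(pd.Series(list(timestamps)), utc=True)
    starts = pd.DatetimeIndex(table["start"]).tz_convert("UTC")
    ends = pd.DatetimeIndex(table["end"]).tz_convert("UTC")
    idx = np.searchsorted(starts.values, ts.values, side="right") - 1
    bad = idx < 0
    inside = ~bad & (ts.values < ends.values[np.clip(idx, 0, None)])
    if not inside.all():
        first = ts[~inside].iloc[0]
        raise ValueError(f"timestamp {first} is outside the solar calendar")
    out = pd.DataFrame(
        {
            "period": table["period"].values[idx],
            "night_id": table["night_id"].values[idx],
        },
        index=ts.index,
    )
    return out
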