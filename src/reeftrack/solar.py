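"""Sunrise/sunset computation (NOAA solar-position algorithm).

The standard NOAA formulation: fractional year -> equation of time and
solar declination via truncated Fourier series, then the hour angle for
the standard refraction-corrected zenith of 90.833 degrees.  One
fixed-point refinement (re-evaluating the ephemeris at the provisional
event time) brings event times within ~1 minute of almanac values at
mid-latitudes, well inside the 2-minute accuracy demanded here.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

ZENITH_OFFICIAL = 90.833  # degrees; includes refraction + solar radius


@dataclasses.dataclass(frozen=True)
class SolarEvents:
    """Sunrise and sunset (UTC) for one date at one site."""

    date: dt.date
    sunrise_utc: dt.datetime
    sunset_utc: dt.datetime

    def __post_init__(self) -> None:
        if not self.sunrise_utc < self.sunset_utc:
            raise ValueError("sunrise must precede sunset")


def _solar_params(doy: int, hours_utc: float, leap: bool) -> tuple[float, float]:
    """Equation of time (minutes) and declination (radians)."""
    year_len = 366.0 if leap else 365.0
    g = 2.0 * math.pi / year_len * (doy - 1 + (hours_utc - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    return eqtime, decl


def _hour_angle(lat_rad: float, decl: float, zenith_deg: float) -> float:
    """Sunrise hour angle (radians); raises outside polar limits."""
    zen = math.radians(zenith_deg)
    cos_ha = math.cos(zen) / (math.cos(lat_rad) * math.cos(decl)) - math.tan(
        lat_rad
    ) * math.tan(decl)
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("sun does not cross the horizon on this date (polar day/night)")
    return math.acos(cos_ha)


def sun_times(
    date: dt.date, latitude: float, longitude: float, zenith: float = ZENITH_OFFICIAL
) -> SolarEvents:
    """Sunrise and sunset (UTC) for ``date`` at the given coordinates.

    Longitude is positive east.  Raises ``ValueError`` during polar day
    or night (cannot occur at the study latitude).
    """
    doy = date.timetuple().tm_yday
    leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    lat_rad = math.radians(latitude)

    def event_minutes(rising: bool, guess_hours: float) -> float:
        minutes = guess_hours * 60.0
        for _ in range(2):  # one refinement pass is enough at minute accuracy
            eqtime, decl = _solar_params(doy, minutes / 60.0, leap)
            ha = math.degrees(_hour_angle(lat_rad, decl, zenith))
            if rising:
                minutes = 720.0 - 4.0 * (longitude + ha) - eqtime
            else:
                minutes = 720.0 - 4.0 * (longitude - ha) - eqtime
        return minutes

    sunrise_min = event_minutes(True, 6.0)
    sunset_min = event_minutes(False, 18.0)
    midnight = dt.datetime.combine(date, dt.time(0), tzinfo=None)
    return SolarEvents(
        date=date,
        sunrise_utc=midnight + dt.timedelta(minutes=sunrise_min),
        sunset_utc=midnight + dt.timedelta(minutes=sunset_min),
    )


def day_length_hours(events: SolarEvents) -> float:
    return (events.sunset_utc - events.sunrise_utc).total_seconds() / 3600.0
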