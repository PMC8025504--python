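"""Solar-geometry day partition and resting-by-time-of-day summaries.

The day is split into eight categories anchored on the solar nadir, the two
twilights, the golden hours and solar noon:

1. night after solar nadir   [nadir, astronomical twilight begin)
2. morning twilight          [astronomical twilight begin, dawn)
3. morning                   [dawn, morning golden hour end)
4. day before solar noon     [morning golden hour end, solar noon)
5. day after solar noon      [solar noon, evening golden hour start)
6. evening                   [evening golden hour start, dusk)
7. evening twilight          [dusk, astronomical twilight end)
8. night before solar nadir  [astronomical twilight end, next nadir)

Dawn/dusk are the civil-twilight boundaries (sun 6 degrees below the
horizon); astronomical twilight uses 18 degrees below; the golden-hour
bounds are the 6-degrees-above-horizon crossings.  Event times come from the
NOAA solar-position equations (equation of time + declination + hour-angle
inversion), which are accurate to well under a minute at mid-latitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DielEvents", "solar_events", "classify_diel", "resting_by_category"]

CATEGORY_NAMES = {
    1: "night after solar nadir",
    2: "morning twilight",
    3: "morning",
    4: "day before solar noon",
    5: "day after solar noon",
    6: "evening",
    7: "evening twilight",
    8: "night before solar nadir",
}

ALT_ASTRO = -18.0
ALT_CIVIL = -6.0
ALT_GOLDEN = 6.0


class PolarDayError(ValueError):
    """Raised when a requested sun-altitude crossing does not occur."""


@dataclass(frozen=True)
class DielEvents:
    """Solar event instants for one nadir-anchored day (all tz-aware UTC)."""

    date: pd.Timestamp
    solar_nadir: pd.Timestamp
    astronomical_twilight_begin: pd.Timestamp
    dawn: pd.Timestamp
    morning_golden_hour_end: pd.Timestamp
    solar_noon: pd.Timestamp
    evening_golden_hour_start: pd.Timestamp
    dusk: pd.Timestamp
    astronomical_twilight_end: pd.Timestamp
    next_nadir: pd.Timestamp

    def ordered(self) -> list[pd.Timestamp]:
        return [
            self.solar_nadir, self.astronomical_twilight_begin, self.dawn,
            self.morning_golden_hour_end, self.solar_noon,
            self.evening_golden_hour_start, self.dusk,
            self.astronomical_twilight_end, self.next_nadir,
        ]

    def __post_init__(self):
        ev = self.ordered()
        for a, b in zip(ev, ev[1:]):
            if not a < b:
                raise PolarDayError(
                    f"solar events not strictly ordered on {self.date.date()}"
                )


def _solar_coeffs(frac_year: float):
    """Equation of time (minutes) and declination (radians), NOAA series."""
    g = frac_year
    eqtime = 229.18 * (
        0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g)
    )
    decl = (
        0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g)
    )
    return eqtime, decl


def _frac_year(date: pd.Timestamp, hour_utc: float) -> float:
    doy = date.dayofyear
    ndays = 366 if date.is_leap_year else 365
    return 2 * np.pi / ndays * (doy - 1 + (hour_utc - 12) / 24)


def _noon_utc_minutes(date: pd.Timestamp, lon: float) -> float:
    # refine the equation of time at the estimated noon itself
    mins = 720.0 - 4.0 * lon
    for _ in range(2):
        eqtime, _ = _solar_coeffs(_frac_year(date, mins / 60.0))
        mins = 720.0 - 4.0 * lon - eqtime
    return mins


def _crossing_utc_minutes(date, lat, lon, altitude_deg, evening: bool,
                          noon_mins: float) -> float:
    """UTC minutes of the sun crossing a given altitude, morning or evening."""
    phi = np.deg2rad(lat)
    t = noon_mins
    for _ in range(3):
        _, decl = _solar_coeffs(_frac_year(date, t / 60.0))
        zen = np.deg2rad(90.0 - altitude_deg)
        cos_ha = (np.cos(zen) - np.sin(phi) * np.sin(decl)) / (
            np.cos(phi) * np.cos(decl)
        )
        if not -1.0 < cos_ha < 1.0:
            raise PolarDayError(
                f"sun never crosses altitude {altitude_deg} deg on "
                f"{date.date()} at lat {lat}"
            )
        ha_deg = np.rad2deg(np.arccos(cos_ha))
        t = noon_mins + 4.0 * ha_deg if evening else noon_mins - 4.0 * ha_deg
    return t


def solar_events(date, lat: float, lon: float, zone: str = "UTC") -> DielEvents:
    """Solar event instants for the local calendar date at (lat, lon).

    The nadir-anchored day runs from solar noon minus 12 h to solar noon
    plus 12 h.  Latitudes above 60 degrees are rejected (twilight can
    degenerate there).
    """
    if abs(lat) >= 60:
        raise PolarDayError("latitude beyond +/-60 degrees not supported")
    date = pd.Timestamp(date)
    if date.tz is not None:
        date = date.tz_localize(None)
    date = date.normalize()
    base = date.tz_localize("UTC")

    def at(mins: float) -> pd.Timestamp:
        return (base + pd.Timedelta(minutes=float(mins))).tz_convert(zone)

    noon = _noon_utc_minutes(date, lon)
    ev = {}
    for key, alt, evening in [
        ("astronomical_twilight_begin", ALT_ASTRO, False),
        ("dawn", ALT_CIVIL, False),
        ("morning_golden_hour_end", ALT_GOLDEN, False),
        ("evening_golden_hour_start", ALT_GOLDEN, True),
        ("dusk", ALT_CIVIL, True),
        ("astronomical_twilight_end", ALT_ASTRO, True),
    ]:
        ev[key] = at(_crossing_utc_minutes(date, lat, lon, alt, evening, noon))
    return DielEvents(
        date=base.tz_convert(zone),
        solar_nadir=at(noon - 720.0),
        solar_noon=at(noon),
        next_nadir=at(noon + 720.0),
        **ev,
    )


def classify_diel(timestamp, events: DielEvents) -> int:
    """Category 1..8 for a timestamp inside the events' day window
    (half-open intervals [start, end))."""
    ts = pd.Timestamp(timestamp)
    if ts.tz is None:
        ts = ts.tz_localize(events.solar_nadir.tz)
    bounds = events.ordered()
    if not bounds[0] <= ts < bounds[-1]:
        raise ValueError("timestamp outside the events' day window")
    for k in range(8):
        if bounds[k] <= ts < bounds[k + 1]:
            return k + 1
    raise AssertionError("unreachable: intervals partition the window")


def _events_for(ts: pd.Timestamp, lat, lon, zone, cache: dict) -> DielEvents:
    for offset in (0, -1, 1):
        d = (ts.tz_convert(zone).normalize() + pd.Timedelta(days=offset)).tz_localize(None)
        if d not in cache:
            cache[d] = solar_events(d, lat, lon, zone)
        ev = cache[d]
        if ev.solar_nadir <= ts < ev.next_nadir:
            return ev
    raise ValueError(f"no solar day window found for {ts}")


def resting_by_category(states, series, ref_coord, zone: str = "UTC") -> pd.DataFrame:
    """Proportion of steps assigned resting (s* = 0) per diel category.

    ``ref_coord`` is a (lat, lon) pair for the deployment's study area; one
    reference coordinate serves all steps (solar-time differences across a
    territory are negligible).  Categories with no steps get proportion NaN.
    """
    lat, lon = ref_coord
    ts = pd.DatetimeIndex(series.timestamps)
    if ts.tz is None:
        ts = ts.tz_localize(zone)
    s = np.asarray(states.s_star, int)
    if len(s) != len(ts):
        raise ValueError("states and series are misaligned")
    cache: dict = {}
    n_steps = np.zeros(8, int)
    n_rest = np.zeros(8, int)
    for t, st in zip(ts, s):
        ev = _events_for(t, lat, lon, zone, cache)
        cat = classify_diel(t, ev)
        n_steps[cat - 1] += 1
        n_rest[cat - 1] += st == 0
    with np.errstate(invalid="ignore"):
        prop = np.where(n_steps > 0, n_rest / np.maximum(n_steps, 1), np.nan)
    return pd.DataFrame(
        {
            "category": range(1, 9),
            "name": [CATEGORY_NAMES[k] for k in range(1, 9)],
            "n_steps": n_steps,
            "n_resting": n_rest,
            "proportion_resting": prop,
        }
    )
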