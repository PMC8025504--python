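"""Collar deployment time series: validation, I/O and preprocessing.

A deployment is a regular time series of attempted GPS fixes (projected
easting/northing in meters, missing where the fix failed) paired with a
complete accelerometer-derived *activity* series: the fraction of one-second
samples within each fix interval that exceeded a minimum acceleration
threshold.  Coordinates must already be projected to a metric plane (e.g.
UTM); every model scale downstream (observation error, process error, step
lengths) is in meters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ACTIVITY_LO = 0.005
ACTIVITY_HI = 0.995

#: default mapping from DeploymentSeries field -> CSV column name
DEFAULT_COLUMNS = {
    "deployment_id": "deployment_id",
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "easting": "easting",
    "northing": "northing",
    "activity": "activity",
}


class DeploymentError(ValueError):
    """Raised when a deployment series violates a structural invariant."""


@dataclass(frozen=True)
class DeploymentSeries:
    """One collar deployment on a regular fix-attempt grid.

    Attributes
    ----------
    deployment_id, animal_id : str
    fix_interval : int
        Minutes between scheduled fix attempts (15 or 30).
    timestamps : pandas.DatetimeIndex
        Strictly increasing, constant spacing equal to ``fix_interval``.
    easting, northing : ndarray of float, meters
        NaN exactly where the fix failed.
    activity : ndarray of float
        Complete series in [0.005, 0.995].
    fix_success : ndarray of bool
    """

    deployment_id: str
    animal_id: str
    fix_interval: int
    timestamps: pd.DatetimeIndex
    easting: np.ndarray
    northing: np.ndarray
    activity: np.ndarray
    fix_success: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        ts = pd.DatetimeIndex(self.timestamps)
        e = np.asarray(self.easting, dtype=float)
        n = np.asarray(self.northing, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if self.fix_success is None:
            object.__setattr__(self, "fix_success", ~np.isnan(e))
        fs = np.asarray(self.fix_success, dtype=bool)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "easting", e)
        object.__setattr__(self, "northing", n)
        object.__setattr__(self, "activity", a)
        object.__setattr__(self, "fix_success", fs)
        self._validate()

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        T = len(self.timestamps)
        if T < 4:
            raise DeploymentError(
                f"deployment {self.deployment_id!r}: length {T} < 4 "
                "(need at least one movement step and one transition)"
            )
        for name, arr in (
            ("easting", self.easting),
            ("northing", self.northing),
            ("activity", self.activity),
            ("fix_success", self.fix_success),
        ):
            if len(arr) != T:
                raise DeploymentError(f"{name} length {len(arr)} != {T}")
        if self.fix_interval not in (15, 30):
            raise DeploymentError(
                f"fix_interval must be 15 or 30 min, got {self.fix_interval}"
            )
        deltas = np.diff(self.timestamps.asi8) / (60 * 1_000_000_000)
        bad = np.nonzero(deltas != self.fix_interval)[0]
        if bad.size:
            i = int(bad[0])
            raise DeploymentError(
                f"irregular timestamp spacing at rows {i}->{i + 1}: "
                f"{deltas[i]:g} min (expected {self.fix_interval})"
            )
        e_ok, n_ok = ~np.isnan(self.easting), ~np.isnan(self.northing)
        if np.any(e_ok != n_ok):
            i = int(np.nonzero(e_ok != n_ok)[0][0])
            raise DeploymentError(
                f"row {i}: exactly one of easting/northing is missing"
            )
        if np.any(e_ok != self.fix_success):
            raise DeploymentError("fix_success inconsistent with coordinate presence")
        if np.any(np.isnan(self.activity)):
            i = int(np.nonzero(np.isnan(self.activity))[0][0])
            raise DeploymentError(f"missing activity at row {i}; activity must be complete")
        if np.any((self.activity < 0) | (self.activity > 1)):
            i = int(np.nonzero((self.activity < 0) | (self.activity > 1))[0][0])
            raise DeploymentError(
                f"activity out of [0, 1] at row {i}: {self.activity[i]:g}"
            )
        if np.any((self.activity < ACTIVITY_LO) | (self.activity > ACTIVITY_HI)):
            warnings.warn(
                f"deployment {self.deployment_id!r}: activity outside "
                f"[{ACTIVITY_LO}, {ACTIVITY_HI}] clamped to that range",
                stacklevel=3,
            )
            object.__setattr__(
                self, "activity", np.clip(self.activity, ACTIVITY_LO, ACTIVITY_HI)
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "deployment_id": self.deployment_id,
                "animal_id": self.animal_id,
                "timestamp": self.timestamps,
                "easting": self.easting,
                "northing": self.northing,
                "activity": self.activity,
                "fix_success": self.fix_success,
            }
        )


@dataclass(frozen=True)
class ObservationSeries:
    """HMM-ready observations: activity paired with apparent step lengths.

    ``step_length[t]`` is the Euclidean distance between the fixes at t and
    t+1 when both succeeded, NaN otherwise; the last element is always NaN
    (no successor attempt).  Exact zero steps (identical consecutive fixes)
    are replaced by 1 m and flagged, since zero is inadmissible under a
    lognormal model.
    """

    activity: np.ndarray
    step_length: np.ndarray
    step_missing: np.ndarray
    zero_substituted: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.activity, float)
        sl = np.asarray(self.step_length, float)
        sm = np.asarray(self.step_missing, bool)
        zs = np.asarray(self.zero_substituted, bool)
        if not (len(a) == len(sl) == len(sm) == len(zs)):
            raise DeploymentError("observation series arrays must share length")
        present = ~np.isnan(sl)
        if np.any(present == sm):
            raise DeploymentError("step_missing inconsistent with step_length NaNs")
        if np.any(sl[present] <= 0):
            raise DeploymentError("step lengths must be positive where present")
        object.__setattr__(self, "activity", a)
        object.__setattr__(self, "step_length", sl)
        object.__setattr__(self, "step_missing", sm)
        object.__setattr__(self, "zero_substituted", zs)

    def __len__(self) -> int:
        return len(self.activity)


def read_deployment(
    path,
    column_map: dict | None = None,
    fix_interval: int | None = None,
) -> DeploymentSeries:
    """Read one deployment from a long-format CSV (one row per fix attempt).

    Blank easting/northing marks a failed fix.  ``fix_interval`` is inferred
    from the first timestamp difference when not given.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, parse_dates=[cols["timestamp"]])
    ts = pd.DatetimeIndex(df[cols["timestamp"]])
    if fix_interval is None:
        if len(ts) < 2:
            raise DeploymentError("cannot infer fix interval from fewer than 2 rows")
        fix_interval = int(round((ts[1] - ts[0]).total_seconds() / 60))
    dep = df[cols["deployment_id"]].iloc[0] if cols["deployment_id"] in df else "dep"
    ani = df[cols["animal_id"]].iloc[0] if cols["animal_id"] in df else "animal"
    return DeploymentSeries(
        deployment_id=str(dep),
        animal_id=str(ani),
        fix_interval=fix_interval,
        timestamps=ts,
        easting=df[cols["easting"]].to_numpy(float),
        northing=df[cols["northing"]].to_numpy(float),
        activity=df[cols["activity"]].to_numpy(float),
    )


def read_deployments(path, column_map: dict | None = None) -> list[DeploymentSeries]:
    """Read a multi-deployment CSV, split on deployment_id."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, parse_dates=[cols["timestamp"]])
    out = []
    for _, grp in df.groupby(cols["deployment_id"], sort=False):
        ts = pd.DatetimeIndex(grp[cols["timestamp"]])
        interval = int(round((ts[1] - ts[0]).total_seconds() / 60))
        out.append(
            DeploymentSeries(
                deployment_id=str(grp[cols["deployment_id"]].iloc[0]),
                animal_id=str(grp[cols["animal_id"]].iloc[0]),
                fix_interval=interval,
                timestamps=ts,
                easting=grp[cols["easting"]].to_numpy(float),
                northing=grp[cols["northing"]].to_numpy(float),
                activity=grp[cols["activity"]].to_numpy(float),
            )
        )
    return out


def truncate_trailing_failures(series: DeploymentSeries) -> DeploymentSeries:
    """Drop everything after the last run of >=3 consecutive successful fixes.

    Collar batteries fade toward the end of a deployment, producing long
    trailing stretches of failed fixes; the series is cut immediately after
    the final element of the last window of at least three consecutive
    successes.  Idempotent.  Raises if no such window exists.
    """
    fs = series.fix_success
    run = 0
    last_end = -1
    for i, ok in enumerate(fs):
        run = run + 1 if ok else 0
        if run >= 3:
            last_end = i
    if last_end < 0:
        raise DeploymentError(
            f"deployment {series.deployment_id!r}: no run of 3 consecutive "
            "successful fixes; unusable"
        )
    if last_end == len(fs) - 1:
        return series
    sl = slice(0, last_end + 1)
    return replace(
        series,
        timestamps=series.timestamps[sl],
        easting=series.easting[sl],
        northing=series.northing[sl],
        activity=series.activity[sl],
        fix_success=series.fix_success[sl],
    )


def apparent_step_lengths(series: DeploymentSeries) -> ObservationSeries:
    """Compute apparent step lengths l_t = ||x_{t+1} - x_t|| in meters.

    "Apparent" because each step conflates true movement with GPS
    measurement error.  A step is missing when either endpoint fix failed;
    the last step has no successor attempt.  Exact zeros are replaced by 1 m
    (flagged), keeping them admissible under the lognormal emission.
    """
    T = len(series)
    sl = np.full(T, np.nan)
    zs = np.zeros(T, bool)
    dx = np.diff(series.easting)
    dy = np.diff(series.northing)
    d = np.hypot(dx, dy)
    ok = series.fix_success[:-1] & series.fix_success[1:]
    sl[:-1][ok] = d[ok]
    zero = ok & (d == 0.0)
    sl[:-1][zero] = 1.0
    zs[:-1][zero] = True
    return ObservationSeries(
        activity=series.activity.copy(),
        step_length=sl,
        step_missing=np.isnan(sl),
        zero_substituted=zs,
    )


def activity_seconds(activity: float, fix_interval: int) -> float:
    """Seconds of above-threshold acceleration implied by an activity value.

    Activity is the fraction of one-second accelerometer samples in the fix
    interval exceeding the threshold, so 0.5 at a 15-min interval means 450
    of 900 seconds active.
    """
    return float(activity) * fix_interval * 60.0


def write_observations(series: DeploymentSeries, obs: ObservationSeries, path) -> None:
    """Write the normalized per-step CSV (fix_success, step_length, flags)."""
    df = series.to_frame()
    df["step_length"] = obs.step_length
    df["step_missing"] = obs.step_missing
    df["zero_substituted"] = obs.zero_substituted
    df.to_csv(path, index=False)
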