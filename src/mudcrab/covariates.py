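"""Observation streams and environmental covariates on the regular grid.

From the smoothed regular-interval positions this module derives the three
HMM observation streams — step length (m per interval), turning angle
(radians, 0 = straight ahead, ±π = course reversal) and interval-mean RMS
acceleration — and the time-varying covariates that drive state
transitions: tide height, Δ-tide (backward 15-min difference, + flood /
− ebb), the cyclic hour-of-day harmonics cos(2πt/24) and sin(2πt/24), and
habitat category from buffered polygons. The product is a single
model-ready table with one row per grid interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep
from shapely.validation import explain_validity

from .simulate import TideSeries
from .trackprep import RegularSeries, Track

__all__ = [
    "compute_steps_angles",
    "aggregate_acceleration",
    "build_tide_covariates",
    "cyclic_time",
    "assign_habitat",
    "build_model_table",
    "HABITAT_PRIORITY",
]

DTIDE_LAG_S = 900.0  # Δ-tide is a 15-min backward difference at every grid Δ
HABITAT_PRIORITY = ("seagrass", "mangrove", "saltmarsh")
HABITAT_DEFAULT = "unvegetated"


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]; exact reversals map to +pi."""
    return np.pi - np.mod(np.pi - a, 2.0 * np.pi)


def compute_steps_angles(series: RegularSeries) -> pd.DataFrame:
    """Step lengths and turning angles from regular positions.

    ``step[t]`` is the Euclidean distance from position t to t+1 (missing
    at the final grid point); ``angle[t]`` is the signed heading change
    over (t-1, t, t+1), missing at both ends and wherever a zero-length
    step leaves the heading undefined.
    """
    x, y = series.x, series.y
    T = len(x)
    step = np.full(T, np.nan)
    angle = np.full(T, np.nan)
    if T >= 2:
        dx = np.diff(x)
        dy = np.diff(y)
        step[:-1] = np.hypot(dx, dy)
    if T >= 3:
        heading = np.arctan2(dy, dx)  # heading of step t -> t+1
        dh = heading[1:] - heading[:-1]
        ok = (step[:-2] > 0) & (step[1:-1] > 0)
        angle[1:-1] = np.where(ok, _wrap_angle(dh), np.nan)
    return pd.DataFrame({"time": series.times, "step": step, "angle": angle})


def aggregate_acceleration(track: Track, grid: np.ndarray, interval_min: float) -> np.ndarray:
    """Mean transmitted acceleration per grid interval [t, t+Δ).

    Intervals containing no transmission are missing — those epochs simply
    do not contribute an acceleration factor to the likelihood.
    """
    if track.accel is None:
        return np.full(len(grid), np.nan)
    step = interval_min * 60.0
    t = track.times
    a = np.asarray(track.accel, dtype=float)
    out = np.full(len(grid), np.nan)
    order = np.argsort(t, kind="stable")
    t, a = t[order], a[order]
    lo = np.searchsorted(t, grid, side="left")
    hi = np.searchsorted(t, grid + step, side="left")
    for i, (l, h) in enumerate(zip(lo, hi)):
        vals = a[l:h]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[i] = vals.mean()
    return out


def build_tide_covariates(
    tide: TideSeries, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tide height and Δ-tide at grid times.

    Heights are linearly interpolated; Δ-tide is ``h(t) - h(t - 15 min)``
    so positive values mean flood and negative ebb. Grid times outside the
    tide record give missing values and are flagged.
    """
    grid = np.asarray(grid, dtype=float)
    inside = (grid >= tide.times[0]) & (grid <= tide.times[-1])
    inside_lag = (grid - DTIDE_LAG_S >= tide.times[0]) & inside
    h = np.where(inside, np.interp(grid, tide.times, tide.heights), np.nan)
    h_lag = np.where(
        inside_lag, np.interp(grid - DTIDE_LAG_S, tide.times, tide.heights), np.nan
    )
    return h, h - h_lag, ~(inside & inside_lag)


def cyclic_time(hour) -> tuple[np.ndarray, np.ndarray]:
    """Daily harmonics (cos(2πt/24), sin(2πt/24)); t is reduced mod 24."""
    t = np.mod(np.asarray(hour, dtype=float), 24.0)
    w = 2.0 * np.pi * t / 24.0
    return np.cos(w), np.sin(w)


def assign_habitat(
    positions: np.ndarray,
    polygons: list[tuple[str, object]],
    buffer: float = 1.26,
) -> np.ndarray:
    """Habitat category per position from buffered polygons.

    Each polygon is dilated by ``buffer`` metres (matching the array's
    median positional error, to absorb edge effects); a position inside any
    dilated polygon takes that polygon's category, with overlaps resolved
    by the fixed priority seagrass > mangrove > saltmarsh; anything else is
    unvegetated.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    for cat, geom in polygons:
        if not geom.is_valid:
            raise ValueError(f"invalid {cat} geometry: {explain_validity(geom)}")
    rank = {c: i for i, c in enumerate(HABITAT_PRIORITY)}
    ordered = sorted(polygons, key=lambda cg: rank.get(cg[0], len(rank)))
    prepared = [(cat, prep(geom.buffer(buffer))) for cat, geom in ordered]
    out = np.full(len(positions), HABITAT_DEFAULT, dtype=object)
    undecided = np.ones(len(positions), dtype=bool)
    for cat, pg in prepared:
        for i in np.flatnonzero(undecided):
            if pg.contains(Point(positions[i])):
                out[i] = cat
                undecided[i] = False
    return out


def build_model_table(
    series_list: list[RegularSeries],
    tide: TideSeries | None = None,
    habitat_polygons: list[tuple[str, object]] | None = None,
    habitat_buffer: float = 1.26,
    tz_offset_hours: float = 10.0,
    individuals: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One model-ready row per grid interval across all tracks.

    Columns: track_id, individual, time, x, y, step, angle, accel and the
    requested covariates (tide_height, dtide, hour_cos, hour_sin, habitat).
    ``tz_offset_hours`` converts epoch times (UTC) to the local clock hour
    feeding the daily harmonics — diel behaviour follows solar time.
    """
    frames = []
    for series in series_list:
        df = compute_steps_angles(series)
        df.insert(0, "track_id", series.track_id)
        df["x"] = series.x
        df["y"] = series.y
        df["accel"] = series.accel if series.accel is not None else np.nan
        if tide is not None:
            h, dh, flagged = build_tide_covariates(tide, series.times)
            df["tide_height"] = h
            df["dtide"] = dh
            df["tide_flag"] = flagged
        hour = np.mod(series.times / 3600.0 + tz_offset_hours, 24.0)
        df["hour_cos"], df["hour_sin"] = cyclic_time(hour)
        if habitat_polygons is not None:
            df["habitat"] = assign_habitat(
                np.column_stack([series.x, series.y]), habitat_polygons, habitat_buffer
            )
        tag = series.track_id.rsplit("-", 1)[0]
        df.insert(1, "individual", individuals.get(tag, tag) if individuals else tag)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
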