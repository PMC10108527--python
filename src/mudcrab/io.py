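"""Interchange formats: CSV readers/writers and JSON sidecars.

All timestamps on disk are ISO-8601 with an explicit zone (UTC); in memory
they are seconds since the epoch. Every generated dataset gets a JSON
sidecar recording generator parameters and seed so runs are reproducible
from the artefacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import geo
from .simulate import TideSeries
from .trackprep import RegularSeries

logger = logging.getLogger("mudcrab")

__all__ = [
    "read_detections",
    "write_detections",
    "read_tide",
    "write_tide",
    "write_truth",
    "write_regular",
    "read_regular",
    "write_sidecar",
    "read_habitat_geojson",
    "fit_to_json",
]


def _iso(seconds: np.ndarray) -> pd.Series:
    return pd.to_datetime(np.asarray(seconds, dtype=float), unit="s", utc=True).strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z"
    )


def _epoch(series: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(series, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def write_detections(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "tag_id": df["tag_id"],
            "time": _iso(df["time"].to_numpy()),
            "x_m": df["x"],
            "y_m": df["y"],
            "accel_ms2": df.get("accel", np.nan),
        }
    )
    out.to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    """Validated, time-sorted detections.

    Accepts planar columns (x_m, y_m) or geographic (lon, lat), projecting
    the latter to local metres about the centroid. Malformed rows (bad
    timestamp or coordinates) are skipped with a logged count.
    """
    raw = pd.read_csv(path)
    cols = set(raw.columns)
    if "tag_id" not in cols or "time" not in cols:
        raise ValueError("detections require tag_id and time columns")
    planar = {"x_m", "y_m"} <= cols
    geographic = {"lon", "lat"} <= cols
    if not planar and not geographic:
        raise ValueError("detections require x_m/y_m or lon/lat columns")
    n0 = len(raw)
    t = pd.to_datetime(raw["time"], utc=True, errors="coerce", format="mixed")
    xcol, ycol = ("x_m", "y_m") if planar else ("lon", "lat")
    x = pd.to_numeric(raw[xcol], errors="coerce")
    y = pd.to_numeric(raw[ycol], errors="coerce")
    ok = t.notna() & x.notna() & y.notna()
    if (~ok).sum():
        logger.warning("skipped %d malformed detection rows", int((~ok).sum()))
    df = pd.DataFrame(
        {
            "tag_id": raw["tag_id"][ok].astype(str),
            "time": t[ok].astype("int64") / 1e9,
            "x": x[ok],
            "y": y[ok],
        }
    )
    if "accel_ms2" in cols:
        df["accel"] = pd.to_numeric(raw["accel_ms2"][ok], errors="coerce")
    elif "accel" in cols:
        df["accel"] = pd.to_numeric(raw["accel"][ok], errors="coerce")
    else:
        df["accel"] = np.nan
    if geographic:
        px, py, origin = geo.project_lonlat(df["x"].to_numpy(), df["y"].to_numpy())
        df["x"], df["y"] = px, py
        df.attrs["projection_origin"] = origin
    if not df["time"].is_monotonic_increasing:
        logger.warning("detections were not time-sorted; sorting")
    return df.sort_values(["tag_id", "time"], kind="stable", ignore_index=True)


def write_tide(tide: TideSeries, path) -> None:
    pd.DataFrame({"time": _iso(tide.times), "height_m": tide.heights}).to_csv(path, index=False)


def read_tide(path) -> TideSeries:
    df = pd.read_csv(path)
    return TideSeries(_epoch(df["time"]), df["height_m"].to_numpy(dtype=float))


def write_truth(path_obj, path) -> None:
    """True per-interval states/streams of a simulated path."""
    pd.DataFrame(
        {
            "interval": np.arange(len(path_obj.steps)),
            "state": path_obj.states,
            "step_m": path_obj.steps,
            "angle_rad": path_obj.angles,
            "accel_ms2": path_obj.accels,
        }
    ).to_csv(path, index=False)


def write_regular(series: RegularSeries, path) -> None:
    pd.DataFrame(
        {
            "track_id": series.track_id,
            "time": _iso(series.times),
            "x_m": series.x,
            "y_m": series.y,
            "var_x_m2": series.var_x,
            "var_y_m2": series.var_y,
            "accel_ms2": series.accel if series.accel is not None else np.nan,
        }
    ).to_csv(path, index=False)


def read_regular(path) -> RegularSeries:
    df = pd.read_csv(path)
    times = _epoch(df["time"])
    dts = np.diff(times)
    interval_min = float(dts[0] / 60.0) if len(dts) else 15.0
    accel = df["accel_ms2"].to_numpy(dtype=float)
    return RegularSeries(
        track_id=str(df["track_id"].iloc[0]),
        interval_min=interval_min,
        times=times,
        x=df["x_m"].to_numpy(dtype=float),
        y=df["y_m"].to_numpy(dtype=float),
        var_x=df["var_x_m2"].to_numpy(dtype=float),
        var_y=df["var_y_m2"].to_numpy(dtype=float),
        accel=None if np.all(np.isnan(accel)) else accel,
    )


def write_sidecar(params: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_habitat_geojson(path) -> list[tuple[str, object]]:
    """(category, shapely geometry) pairs from a GeoJSON FeatureCollection.

    Each feature needs a "habitat" property naming its category.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj.get("features", []):
        cat = feat.get("properties", {}).get("habitat")
        if cat is None:
            raise ValueError("habitat GeoJSON features need a 'habitat' property")
        out.append((str(cat), shape(feat["geometry"])))
    return out


def fit_to_json(fit, path) -> None:
    """Serialize a FitResult: natural and working scale plus restart log."""
    em = fit.params.emission
    trans = fit.params.transition
    doc = {
        "n_states": fit.n_states,
        "formula": list(fit.formula),
        "K": fit.K,
        "loglik": fit.loglik,
        "penalized_objective": fit.penalized,
        "aic": fit.aic,
        "n_params": fit.n_params,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "boundary": fit.boundary,
        "emission": {
            "step_mean": em.step_mean,
            "step_sd": em.step_sd,
            "step_zeromass": em.step_zeromass,
            "angle_rho": em.angle_rho,
            "accel_mean": em.accel_mean,
            "accel_sd": em.accel_sd,
            "accel_zeromass": em.accel_zeromass,
        },
        "transition": (
            {"columns": list(trans.columns), "beta": trans.beta}
            if not fit.params.is_mixture
            else {
                "columns": list(trans.columns),
                "weights": trans.weights,
                "betas": trans.betas,
            }
        ),
        "working": fit.working,
        "restarts": fit.restarts,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_jsonable)
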