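"""Acoustic array positioning: sound speed, TDOA multilateration, audits.

A transmitter detected on three or more time-synchronized receivers can be
located from the time-differences-of-arrival: each receiver pair constrains
the source to a hyperbola, and the least-squares intersection is the
position estimate. Arrival times convert to distances via the Coppens
(1981) shallow-water sound-speed polynomial. Receiver clocks drift (up to
seconds per day), so fixed-position synchronization tags are used to
estimate and remove per-receiver linear clock error before solving.

This is a generic re-implementation for simulation and auditing; vendor
positioning systems use proprietary algorithms of the same family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ReceiverArray",
    "coppens_sound_speed",
    "tdoa_solve",
    "simulate_arrival_times",
    "estimate_clock_error",
    "correct_arrivals",
    "audit_reference_tag",
]

SECONDS_PER_DAY = 86400.0


def coppens_sound_speed(temperature: float, salinity: float, depth: float = 0.0) -> float:
    """Speed of sound in seawater (m/s), Coppens (1981).

    ``temperature`` in deg C (valid 0-35), ``salinity`` in psu (0-45),
    ``depth`` in metres. Outside the fitted range a warning is raised and
    the polynomial is still evaluated.
    """
    if not (0.0 <= temperature <= 35.0) or not (0.0 <= salinity <= 45.0):
        warnings.warn(
            "temperature/salinity outside the Coppens fit range; value extrapolated",
            stacklevel=2,
        )
    t = temperature / 10.0
    d = depth / 1000.0  # km
    s = salinity
    c0 = (
        1449.05
        + 45.7 * t
        - 5.21 * t**2
        + 0.23 * t**3
        + (1.333 - 0.126 * t + 0.009 * t**2) * (s - 35.0)
    )
    return (
        c0
        + (16.23 + 0.253 * t) * d
        + (0.213 - 0.1 * t) * d**2
        + (0.016 + 0.0002 * (s - 35.0)) * (s - 35.0) * t * d
    )


@dataclass
class ReceiverArray:
    """Fixed receivers: positions (n, 3) in planar metres (x, y, z).

    ``skew_rates`` are per-receiver clock drifts in seconds per day (used
    by the simulator); ``sound_speed`` in m/s.
    """

    positions: np.ndarray
    skew_rates: np.ndarray | None = None
    sound_speed: float = 1500.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] == 2:  # pad z = 0
            self.positions = np.column_stack([self.positions, np.zeros(len(self.positions))])
        if len(self.positions) < 3:
            raise ValueError("positioning requires at least 3 receivers")
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=2
        )
        if np.any(d[np.triu_indices(len(self.positions), 1)] == 0):
            raise ValueError("receiver positions must be pairwise distinct")
        if self.skew_rates is None:
            self.skew_rates = np.zeros(len(self.positions))
        self.skew_rates = np.asarray(self.skew_rates, dtype=float)
        if self.sound_speed <= 0:
            raise ValueError("sound speed must be positive")

    @property
    def n_receivers(self) -> int:
        return len(self.positions)


def _distances(array: ReceiverArray, xy: np.ndarray, tag_z: float) -> np.ndarray:
    p = np.array([xy[0], xy[1], tag_z])
    return np.linalg.norm(array.positions - p, axis=1)


def simulate_arrival_times(
    array: ReceiverArray,
    tag_position,
    t_emit: float,
    timing_sd: float = 0.0,
    seed=0,
) -> np.ndarray:
    """True propagation arrivals plus clock skew and Gaussian timing noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tag_position = np.asarray(tag_position, dtype=float)
    tag_z = tag_position[2] if tag_position.size == 3 else 0.0
    d = _distances(array, tag_position[:2], tag_z)
    arr = t_emit + d / array.sound_speed
    arr = arr + array.skew_rates * (t_emit / SECONDS_PER_DAY)
    if timing_sd > 0:
        arr = arr + rng.normal(0.0, timing_sd, array.n_receivers)
    return arr


def tdoa_solve(
    array: ReceiverArray,
    arrival_times: np.ndarray,
    tag_z: float = 0.0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Least-squares (x, y) minimizing squared TDOA residuals.

    Residuals are ``(d_i - d_0)/c - (a_i - a_0)`` against the first
    receiver. Returns the estimate and a convergence flag; with noiseless
    arrivals from a tag inside the array the true position is recovered.
    """
    arrival_times = np.asarray(arrival_times, dtype=float)
    if len(arrival_times) < 3:
        raise ValueError("TDOA needs arrivals at 3 or more receivers")
    if len(arrival_times) != array.n_receivers:
        raise ValueError("one arrival time per receiver required")
    c = array.sound_speed
    dt_obs = arrival_times[1:] - arrival_times[0]

    def resid(xy):
        d = _distances(array, xy, tag_z)
        return (d[1:] - d[0]) / c - dt_obs

    if x0 is None:
        x0 = array.positions[:, :2].mean(axis=0)
    sol = least_squares(resid, x0, method="lm")
    return sol.x, bool(sol.success)


def estimate_clock_error(
    emit_times: np.ndarray,
    arrivals: np.ndarray,
    array: ReceiverArray,
    sync_position,
) -> np.ndarray:
    """Per-receiver linear clock error from a fixed sync tag.

    ``arrivals`` is (n_emissions, n_receivers). The expected TDOA of the
    sync tag against receiver 0 is a known constant, so the observed excess
    is pure relative clock error; a straight line (offset, rate/day) is fit
    per receiver. Returns coefficients (n_receivers, 2); receiver 0 is the
    reference with zero error.
    """
    emit_times = np.asarray(emit_times, dtype=float)
    arrivals = np.atleast_2d(np.asarray(arrivals, dtype=float))
    sync_position = np.asarray(sync_position, dtype=float)
    sync_z = sync_position[2] if sync_position.size == 3 else 0.0
    d = _distances(array, sync_position[:2], sync_z)
    expected = (d - d[0]) / array.sound_speed  # constant TDOA vs receiver 0
    excess = (arrivals - arrivals[:, [0]]) - expected  # (n_emissions, n_receivers)
    days = emit_times / SECONDS_PER_DAY
    A = np.column_stack([np.ones(len(days)), days])
    coef, *_ = np.linalg.lstsq(A, excess, rcond=None)
    return coef.T  # (n_receivers, 2): offset, rate per day


def correct_arrivals(arrivals: np.ndarray, emit_times: np.ndarray, clock_coef: np.ndarray) -> np.ndarray:
    """Remove estimated linear clock error from arrival times."""
    emit_times = np.asarray(emit_times, dtype=float)
    arrivals = np.atleast_2d(np.asarray(arrivals, dtype=float))
    drift = clock_coef[:, 0][None, :] + clock_coef[:, 1][None, :] * (
        emit_times[:, None] / SECONDS_PER_DAY
    )
    return arrivals - drift


def audit_reference_tag(estimates: pd.DataFrame, known_position) -> dict:
    """Error summary of a fixed-position reference tag.

    ``estimates`` needs columns x, y. Returns horizontal-error statistics
    (mean, SD, median, IQR, fraction within 5 m) plus the isotropic
    measurement-error covariance handed to the CTCRW error model.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one position estimate")
    kx, ky = float(known_position[0]), float(known_position[1])
    dx = estimates["x"].to_numpy(dtype=float) - kx
    dy = estimates["y"].to_numpy(dtype=float) - ky
    err = np.hypot(dx, dy)
    q25, q75 = np.percentile(err, [25, 75])
    var_iso = float(np.mean(dx**2 + dy**2) / 2.0)
    return {
        "n": int(len(err)),
        "mean_m": float(np.mean(err)),
        "sd_m": float(np.std(err, ddof=1)) if len(err) > 1 else 0.0,
        "median_m": float(np.median(err)),
        "iqr_m": float(q75 - q25),
        "frac_within_5m": float(np.mean(err <= 5.0)),
        "error_cov": [[var_iso, 0.0], [0.0, var_iso]],
    }
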