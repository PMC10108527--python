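"""State-dependent observation distributions.

Two families carry the whole observation model:

* **zero-inflated gamma** for step length and RMS acceleration — a point
  mass at exactly zero (no movement / no dynamic acceleration) mixed with a
  gamma distribution parameterized by its mean and standard deviation;
* **wrapped Cauchy** for turning angles — the Cauchy distribution wrapped
  onto the unit circle, with mean direction fixed at 0 (straight-line
  movement) and concentration ``rho`` in [0, 1) (0 = uniform on the circle).

Both are exposed as log-densities, CDFs and samplers so the same code path
serves simulation, likelihood evaluation and pseudo-residuals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

TWO_PI = 2.0 * np.pi


def _gamma_shape_rate(mean, sd):
    """Mean/SD -> (shape, rate) of the gamma component."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape, rate


def zigamma_logpdf(x, mean, sd, zeromass):
    """Log-density of the zero-inflated gamma distribution.

    ``x == 0`` contributes ``log(zeromass)``; ``x > 0`` contributes
    ``log(1 - zeromass)`` plus the gamma log-density with shape
    ``(mean/sd)**2`` and rate ``mean/sd**2``. Negative ``x`` is a domain
    error.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("zero-inflated gamma is defined on x >= 0")
    mean, sd, zeromass = np.broadcast_arrays(
        np.asarray(mean, float), np.asarray(sd, float), np.asarray(zeromass, float)
    )
    if np.any(mean <= 0) or np.any(sd <= 0):
        raise ValueError("mean and sd must be positive")
    if np.any(zeromass < 0) or np.any(zeromass >= 1):
        raise ValueError("zeromass must lie in [0, 1)")
    shape, rate = _gamma_shape_rate(mean, sd)
    with np.errstate(divide="ignore"):
        out = np.where(
            x == 0,
            np.log(zeromass),
            np.log1p(-zeromass) + stats.gamma.logpdf(np.where(x > 0, x, 1.0), shape, scale=1.0 / rate),
        )
    return out


def zigamma_cdf(x, mean, sd, zeromass):
    """CDF; the atom at zero makes F(0) = zeromass."""
    x = np.asarray(x, dtype=float)
    shape, rate = _gamma_shape_rate(mean, sd)
    cont = stats.gamma.cdf(np.clip(x, 0.0, None), shape, scale=1.0 / rate)
    return np.where(x < 0, 0.0, zeromass + (1.0 - zeromass) * cont)


def zigamma_rvs(mean, sd, zeromass, size, rng):
    """Sample: Bernoulli(zeromass) atom at 0, otherwise gamma."""
    shape, rate = _gamma_shape_rate(mean, sd)
    x = rng.gamma(shape, 1.0 / rate, size=size)
    zero = rng.random(size) < zeromass
    x[zero] = 0.0
    return x


def wrapped_cauchy_logpdf(theta, rho, mu=0.0):
    """Log-density of the wrapped Cauchy on (-pi, pi].

    ``log[(1 - rho^2) / (2 pi (1 + rho^2 - 2 rho cos(theta - mu)))]``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho >= 1):
        raise ValueError("concentration rho must lie in [0, 1)")
    theta = np.asarray(theta, dtype=float)
    return np.log1p(-rho**2) - np.log(TWO_PI) - np.log1p(rho**2 - 2.0 * rho * np.cos(theta - mu))


def wrapped_cauchy_cdf(theta, rho, mu=0.0):
    """CDF on (-pi, pi] for mean direction ``mu`` (closed form).

    The antiderivative of the density is
    ``(1/pi) * arctan(((1+rho)/(1-rho)) * tan((theta-mu)/2))`` which gives
    ``F(theta) = 1/2 + ...`` on the principal branch.
    """
    theta = np.asarray(theta, dtype=float)
    d = np.pi - np.mod(np.pi - (theta - mu), TWO_PI)  # wrap to (-pi, pi]
    # tan is singular at +/-pi; the limit there is F = 1 (or 0).
    half = np.clip(d / 2.0, -np.pi / 2 + 1e-12, np.pi / 2 - 1e-12)
    k = (1.0 + rho) / (1.0 - rho)
    return 0.5 + np.arctan(k * np.tan(half)) / np.pi


def wrapped_cauchy_rvs(rho, size, rng, mu=0.0):
    """Sample via the inverse CDF; exact for rho in [0, 1)."""
    u = rng.random(size)
    theta = 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))
    out = np.mod(theta + mu + np.pi, TWO_PI) - np.pi
    # map -pi -> +pi to keep the half-open (-pi, pi] convention
    out[out == -np.pi] = np.pi
    return out
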