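"""Local planar projection for small acoustic arrays.

Receiver arrays of the kind handled here span a few hundred metres, so
longitude/latitude inputs are projected once to a local transverse-Mercator
plane centred on the data centroid and all downstream geometry is planar
Euclidean. Over such extents the spherical approximation is accurate to well
under a millimetre.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


def project_lonlat(
    lon: np.ndarray,
    lat: np.ndarray,
    lon0: float | None = None,
    lat0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Project geographic coordinates to local planar metres.

    Spherical transverse Mercator centred on ``(lon0, lat0)`` (defaults to
    the centroid of the inputs). Returns ``(x, y, (lon0, lat0))``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    lam = np.radians(lon - lon0)
    phi = np.radians(lat)
    phi0 = np.radians(lat0)
    b = np.cos(phi) * np.sin(lam)
    x = EARTH_RADIUS_M * np.arctanh(np.clip(b, -1 + 1e-15, 1 - 1e-15))
    y = EARTH_RADIUS_M * (np.arctan2(np.tan(phi), np.cos(lam)) - phi0)
    return x, y, (lon0, lat0)
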