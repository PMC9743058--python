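"""Spherical geometry helpers: great-circle distance and a local metric projection.

All functions are vectorised over numpy arrays of coordinates in decimal
degrees (WGS84 lon/lat). The projection used throughout the package is the
azimuthal equidistant projection on the authalic sphere, centred per bird;
within the ~50 km ranges of a breeding shorebird its pairwise-distance
distortion is far below the GPS error scale (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius, metres


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def aeqd_forward(lon, lat, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to metric x/y centred on (lon0, lat0).

    Distances from the origin are preserved exactly; azimuths from the
    origin are preserved exactly (azimuthal equidistant).
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    dlam = lam - lam0
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    # k = c / sin(c), with the removable singularity at c = 0
    sin_c = np.sin(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(sin_c > 1e-12, c / np.where(sin_c > 1e-12, sin_c, 1.0), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_M * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
    return x, y


def aeqd_inverse(x, y, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`aeqd_forward`; returns lon/lat in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    sin_c, cos_c = np.sin(c), np.cos(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_y = np.where(rho > 1e-12, y / np.where(rho > 1e-12, rho, 1.0), 0.0)
        frac_x = np.where(rho > 1e-12, x / np.where(rho > 1e-12, rho, 1.0), 0.0)
    phi = np.arcsin(np.clip(cos_c * np.sin(phi0) + frac_y * sin_c * np.cos(phi0), -1.0, 1.0))
    lam = lam0 + np.arctan2(
        frac_x * sin_c,
        cos_c * np.cos(phi0) - frac_y * sin_c * np.sin(phi0),
    )
    return np.degrees(lam), np.degrees(phi)
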