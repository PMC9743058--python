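"""Solar elevation and day/night classification.

Implements the NOAA general solar-position equations (fractional-year
Fourier expansions for the equation of time and solar declination), which
are accurate to roughly 0.1 degrees over the satellite-tracking era —
ample for a twilight threshold.

Day is defined as the sun being at or above the civil-twilight elevation
of -6 degrees, so the crepuscular dawn and dusk periods count as day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CIVIL_TWILIGHT_DEG = -6.0


def solar_elevation(lon, lat, times) -> np.ndarray:
    """Solar elevation angle in degrees at each (lon, lat, time).

    Parameters
    ----------
    lon, lat
        Position(s) in decimal degrees (east / north positive).
    times
        Datetime-like values; naive values are taken as UTC.
    """
    t = pd.DatetimeIndex(pd.to_datetime(times))
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)

    doy = t.dayofyear.to_numpy(dtype=float)
    hours = (
        t.hour.to_numpy(dtype=float)
        + t.minute.to_numpy(dtype=float) / 60.0
        + t.second.to_numpy(dtype=float) / 3600.0
    )
    year = np.asarray(t.year)
    leap = (year % 4 == 0) & ((year % 100 != 0) | (year % 400 == 0))
    year_len = np.where(leap, 366.0, 365.0)

    gamma = 2.0 * np.pi / year_len * (doy - 1.0 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )

    time_offset = eqtime + 4.0 * lon  # minutes
    tst = hours * 60.0 + time_offset  # true solar time, minutes
    ha = np.radians(tst / 4.0 - 180.0)  # hour angle

    phi = np.radians(lat)
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha)
    zen = np.degrees(np.arccos(np.clip(cos_zen, -1.0, 1.0)))
    return 90.0 - zen


def is_day(lon, lat, times, threshold_deg: float = CIVIL_TWILIGHT_DEG) -> np.ndarray:
    """Boolean day flag: sun elevation at or above ``threshold_deg``."""
    return solar_elevation(lon, lat, times) >= threshold_deg
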