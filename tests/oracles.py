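"""Independent brute-force oracles used by the tests.

Everything here is deliberately written with different algorithms from
the package code paths it checks: dense path resampling instead of
analytic circle crossings, the Astronomical Almanac solar position
instead of the fractional-year expansions, exhaustive partition search
instead of Lloyd iterations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def brute_force_visits(
    times_s: np.ndarray, xy: np.ndarray, radius: float, step: float = 1.0
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Visit counts and entry times by dense 1-s resampling of the path.

    The piecewise-linear trajectory is sampled every ``step`` seconds;
    a visit is a maximal run of inside samples. Entry times are
    accurate to one sample step.
    """
    t_dense = np.arange(times_s[0], times_s[-1] + step / 2, step)
    x = np.interp(t_dense, times_s, xy[:, 0])
    y = np.interp(t_dense, times_s, xy[:, 1])
    counts = np.zeros(len(xy), dtype=int)
    entries: list[np.ndarray] = []
    for j in range(len(xy)):
        inside = (x - xy[j, 0]) ** 2 + (y - xy[j, 1]) ** 2 <= radius**2
        d = np.diff(inside.astype(int))
        starts = list(np.nonzero(d == 1)[0] + 1)
        if inside[0]:
            starts = [0] + starts
        counts[j] = len(starts)
        entries.append(t_dense[np.asarray(starts, dtype=int)])
    return counts, entries


def resolvable_entry_times(stats, times_s: np.ndarray, step: float = 1.0) -> list[np.ndarray]:
    """Entry times of the engine's visits that a ``step``-resolution
    resampling oracle can resolve: exactly those containing one of the
    oracle's sample instants (t0, t0+step, ...). Sub-step grazing
    passes between samples are analytically real but invisible to the
    dense grid."""
    t0 = times_s[0]
    out = []
    for visits in stats.visits:
        kept = [
            v.entry_time
            for v in visits
            if np.ceil((v.entry_time - t0) / step - 1e-9) * step
            <= (v.exit_time - t0) + 1e-9
        ]
        out.append(np.sort(kept))
    return out


def solar_elevation_almanac(lon: float, lat: float, when) -> float:
    """Solar elevation (degrees) via the Astronomical Almanac low-precision
    ephemeris (Michalsky-style), independent of the package's equations."""
    t = pd.Timestamp(when)
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    # days from J2000.0 including the time-of-day fraction
    n = (t - pd.Timestamp("2000-01-01 12:00:00")).total_seconds() / 86400.0
    L = (280.460 + 0.9856474 * n) % 360.0  # mean longitude
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)  # mean anomaly
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))  # ecliptic lon
    eps = np.radians(23.439 - 4e-7 * n)  # obliquity
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    gmst_h = (18.697374558 + 24.06570982441908 * n) % 24.0
    lmst_deg = (gmst_h * 15.0 + lon) % 360.0
    ha = np.radians(lmst_deg) - ra
    phi = np.radians(lat)
    sin_el = np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(ha)
    return float(np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0))))


def exhaustive_two_means(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Globally optimal 2-cluster centroids by enumerating all partitions.

    Only feasible for small point sets; returns (2, 2) centroids sorted
    by x, and the optimal within-cluster sum of squares.
    """
    n = len(xy)
    assert n <= 22, "exhaustive search only for tiny inputs"
    best = None
    for mask_bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster A
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        a, b = xy[~mask], xy[mask]
        if len(a) == 0 or len(b) == 0:
            continue
        wcss = ((a - a.mean(axis=0)) ** 2).sum() + ((b - b.mean(axis=0)) ** 2).sum()
        if best is None or wcss < best[1]:
            centers = np.vstack([a.mean(axis=0), b.mean(axis=0)])
            best = (centers[np.argsort(centers[:, 0])], wcss)
    return best


def geometric_mean_capped(p_fail: float, cap: int, n: int, rng) -> float:
    """Mean observed failure day of geometric failures under a cap."""
    days = rng.geometric(p_fail, size=n)
    return float(days[days <= cap].mean())
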