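"""Foci of activity and nest coordinates from revisitation statistics.

The nest of an incubating wader is, by a wide margin, the most
revisited location in its track. Following the population-clustering
idea, the most-revisited fifth of relocations is clustered with
K-means and the highest-support cluster centroid taken as the nest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import geo
from .io_tracks import Trajectory
from .recursion import RevisitStats, compute_revisits


class InsufficientDataError(ValueError):
    """Too few fixes in the window to locate a site."""


@dataclass
class FocalSite:
    """A cluster of highly revisited relocations."""

    x: float
    y: float
    lon: float | None
    lat: float | None
    support: int
    mean_revisits: float
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None


def top_fraction(stats: RevisitStats, fraction: float = 0.2) -> pd.DataFrame:
    """The ceil(fraction * n) most-revisited relocations.

    Ties on visit count are broken by higher total residence, then by
    earlier timestamp, so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(stats)
    if n == 0:
        return stats.traj.df.iloc[0:0].assign(n_visits=[], total_residence_s=[])
    k = int(np.ceil(fraction * n))
    df = stats.traj.df.copy()
    df["n_visits"] = stats.n_visits
    df["total_residence_s"] = stats.residence_s
    order = df.sort_values(
        ["n_visits", "total_residence_s", "timestamp"],
        ascending=[False, False, True],
        kind="stable",
    )
    return order.head(k)


def cluster_foci(
    points: pd.DataFrame, k: int = 3, seed: int = 0, n_restarts: int = 50
) -> list[FocalSite]:
    """K-means foci of the given relocations, ordered by descending support.

    ``points`` must carry projected x/y (and optionally n_visits).
    k is reduced to the number of points when larger.
    """
    if len(points) == 0:
        raise ValueError("no points to cluster")
    if k < 1:
        raise ValueError("k must be >= 1")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    k = min(k, len(points))
    if k == len(points):
        labels = np.arange(len(points))
        centers = xy
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(xy)
        centers = km.cluster_centers_
    visits = points["n_visits"].to_numpy() if "n_visits" in points.columns else np.ones(len(points))
    sites = []
    for j in range(k):
        member = labels == j
        support = int(member.sum())
        if support == 0:
            continue
        cx, cy = xy[member].mean(axis=0)
        sites.append(
            FocalSite(
                x=float(cx), y=float(cy), lon=None, lat=None,
                support=support, mean_revisits=float(visits[member].mean()),
            )
        )
    sites.sort(key=lambda s: (-s.support, s.x, s.y))
    return sites


def _fill_lonlat(site: FocalSite, traj: Trajectory) -> FocalSite:
    if traj.projection_origin is not None:
        lon, lat = geo.aeqd_inverse(site.x, site.y, *traj.projection_origin)
        site.lon, site.lat = float(lon), float(lat)
    return site


def nest_location(
    traj: Trajectory,
    incubation_window: tuple[pd.Timestamp, pd.Timestamp],
    radius: float = 20.0,
    seed: int = 0,
    fraction: float = 0.2,
    k: int = 3,
) -> FocalSite:
    """Nest coordinates for a window already classified as incubation.

    Pipeline: revisits on the windowed trajectory → most-revisited
    fraction → K-means foci → highest-support focus.
    """
    sub = traj.window(*incubation_window)
    if len(sub) < 10:
        raise InsufficientDataError(
            f"incubation window holds {len(sub)} fixes; at least 10 required"
        )
    stats = compute_revisits(sub, radius)
    points = top_fraction(stats, fraction)
    sites = cluster_foci(points, k=k, seed=seed)
    best = sites[0]
    best.window = tuple(map(pd.Timestamp, incubation_window))
    return _fill_lonlat(best, traj)


def sites_to_frame(sites: list[FocalSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": s.x, "y": s.y, "lon": s.lon, "lat": s.lat,
                "support": s.support, "mean_revisits": s.mean_revisits,
                "window_start": s.window[0] if s.window else None,
                "window_end": s.window[1] if s.window else None,
            }
            for s in sites
        ]
    )


def sites_to_geojson(sites: list[FocalSite]) -> dict:
    """GeoJSON FeatureCollection of focal sites (lon/lat where available)."""
    feats = []
    for s in sites:
        geom = {"type": "Point", "coordinates": [s.lon, s.lat] if s.lon is not None else [s.x, s.y]}
        feats.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {
                    "support": s.support,
                    "mean_revisits": s.mean_revisits,
                    "window_start": str(s.window[0]) if s.window else None,
                    "window_end": str(s.window[1]) if s.window else None,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
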