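"""Reading, cleaning and annotating raw GPS relocation tables.

A raw table is delimited text with one row per GPS fix. A declared
:class:`Dialect` maps its columns onto the canonical fields (tag id, UTC
timestamp, lon/lat, satellite count); a built-in ``MOVEBANK`` dialect
covers the common Movebank export layout.

Cleaning follows the standard shorebird-tracking protocol: duplicate
fixes (the same tag at the same second, as produced by downloads to more
than one base station) are removed, as are fixes computed from fewer
than five satellites. Each retained fix is flagged day/night by civil
twilight and projected to local metric coordinates (azimuthal
equidistant, centred per bird) so that later radius-based analysis can
work in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import geo, solar

#: canonical column order of a trajectory frame
COLUMNS = ["timestamp", "lon", "lat", "n_satellites"]


class ConfigurationError(ValueError):
    """A dialect does not match the file it is applied to."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping from an input table onto canonical fix fields."""

    tag_id: str
    timestamp: str
    lon: str
    lat: str
    n_satellites: str | None = None
    timezone: str = "UTC"
    sep: str = ","


MOVEBANK = Dialect(
    tag_id="individual-local-identifier",
    timestamp="timestamp",
    lon="location-long",
    lat="location-lat",
    sep=",",
)

#: dialect for the package's own track CSVs (and the simulator's output)
NATIVE = Dialect(tag_id="tag_id", timestamp="timestamp", lon="lon", lat="lat",
                 n_satellites="n_satellites")


@dataclass
class Trajectory:
    """Time-ordered GPS fixes for one tagged bird.

    ``df`` holds one row per relocation with columns ``timestamp`` (UTC,
    tz-naive), ``lon``, ``lat``, ``n_satellites`` and, once derived,
    ``x``/``y`` (metres in the local projection) and ``is_day``.
    """

    tag_id: str
    df: pd.DataFrame
    sampling_interval: pd.Timedelta = pd.Timedelta(minutes=15)
    tagging_location: tuple[float, float] | None = None  # (lon, lat)
    projection_origin: tuple[float, float] | None = None  # (lon, lat)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> pd.Series:
        return self.df["timestamp"]

    @property
    def times_s(self) -> np.ndarray:
        """Timestamps as float seconds since the Unix epoch."""
        return self.df["timestamp"].astype("int64").to_numpy() / 1e9

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of projected coordinates; requires project_local."""
        if "x" not in self.df.columns:
            raise ValueError("trajectory has no projected coordinates; call project_local first")
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def span_days(self) -> float:
        if len(self.df) < 2:
            return 0.0
        return float((self.df["timestamp"].iloc[-1] - self.df["timestamp"].iloc[0]).total_seconds()) / 86400.0

    def window(self, start, end) -> "Trajectory":
        """Sub-trajectory with timestamps in the half-open interval [start, end)."""
        start = pd.Timestamp(start)
        end = pd.Timestamp(end)
        m = (self.df["timestamp"] >= start) & (self.df["timestamp"] < end)
        return replace(self, df=self.df.loc[m])


@dataclass
class LoadReport:
    """Row-level accounting of a read_tracks call."""

    n_rows: int = 0
    n_bad_timestamp: int = 0
    n_bad_coords: int = 0
    n_loaded: int = 0
    per_tag: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"rows read:            {self.n_rows}",
            f"bad timestamps:       {self.n_bad_timestamp}",
            f"bad coordinates:      {self.n_bad_coords}",
            f"relocations loaded:   {self.n_loaded}",
        ]
        for tag, n in sorted(self.per_tag.items()):
            lines.append(f"  {tag}: {n}")
        return "\n".join(lines)


def read_tracks(
    path: str | Path,
    dialect: Dialect = NATIVE,
    sampling_interval: pd.Timedelta = pd.Timedelta(minutes=15),
) -> tuple[list[Trajectory], LoadReport]:
    """Read a delimited relocation table into one Trajectory per tag.

    Rows with unparseable timestamps or out-of-range coordinates are
    dropped and counted in the returned :class:`LoadReport`. An empty
    file yields an empty list. A missing mapped column raises
    :class:`ConfigurationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str)
    report = LoadReport(n_rows=len(raw))
    if raw.empty:
        return [], report

    needed = [dialect.tag_id, dialect.timestamp, dialect.lon, dialect.lat]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"input file lacks mapped column(s): {missing}")

    ts = pd.to_datetime(raw[dialect.timestamp], errors="coerce", utc=False, format="mixed")
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    elif dialect.timezone != "UTC":
        ts = ts.dt.tz_localize(dialect.timezone, ambiguous="NaT", nonexistent="NaT")
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    lon = pd.to_numeric(raw[dialect.lon], errors="coerce")
    lat = pd.to_numeric(raw[dialect.lat], errors="coerce")
    if dialect.n_satellites and dialect.n_satellites in raw.columns:
        nsat = pd.to_numeric(raw[dialect.n_satellites], errors="coerce").fillna(0).astype(int)
    else:
        nsat = pd.Series(np.full(len(raw), 99, dtype=int))  # unknown: never filtered

    bad_ts = ts.isna()
    bad_xy = lon.isna() | lat.isna() | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    report.n_bad_timestamp = int(bad_ts.sum())
    report.n_bad_coords = int((bad_xy & ~bad_ts).sum())
    keep = ~(bad_ts | bad_xy)

    frame = pd.DataFrame(
        {
            "tag_id": raw[dialect.tag_id].astype(str),
            "timestamp": ts,
            "lon": lon,
            "lat": lat,
            "n_satellites": nsat,
        }
    ).loc[keep]
    report.n_loaded = len(frame)

    trajectories = []
    for tag, grp in frame.groupby("tag_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        report.per_tag[str(tag)] = len(grp)
        trajectories.append(
            Trajectory(
                tag_id=str(tag),
                df=grp[COLUMNS].copy(),
                sampling_interval=sampling_interval,
                tagging_location=(float(grp["lon"].iloc[0]), float(grp["lat"].iloc[0])),
            )
        )
    return trajectories, report


def clean_fixes(traj: Trajectory, min_satellites: int = 5) -> Trajectory:
    """Remove duplicate fixes and fixes from fewer than ``min_satellites``.

    Duplicates are fixes sharing a timestamp (rounded to whole seconds);
    the one seen by more satellites wins, then first occurrence. The
    operation is idempotent and preserves time order.
    """
    df = traj.df.copy()
    df["timestamp"] = df["timestamp"].dt.round("1s")
    df = df[df["n_satellites"] >= min_satellites]
    df = df.sort_values(["timestamp", "n_satellites"], ascending=[True, False], kind="stable")
    df = df.drop_duplicates(subset="timestamp", keep="first")
    return replace(traj, df=df)


def annotate_day_night(traj: Trajectory) -> Trajectory:
    """Flag every fix day/night by civil twilight at its own position and date."""
    df = traj.df.copy()
    df["is_day"] = solar.is_day(df["lon"].to_numpy(), df["lat"].to_numpy(), df["timestamp"])
    return replace(traj, df=df)


def project_local(traj: Trajectory) -> Trajectory:
    """Fill metric x/y via an azimuthal-equidistant projection.

    The projection is centred on the bird's median lon/lat, so each
    trajectory gets its own origin and spatially anonymised (shifted)
    data project just as well as real coordinates.
    """
    df = traj.df.copy()
    if len(df) == 0:
        df["x"] = np.array([], dtype=float)
        df["y"] = np.array([], dtype=float)
        return replace(traj, df=df)
    lon0 = float(df["lon"].median())
    lat0 = float(df["lat"].median())
    x, y = geo.aeqd_forward(df["lon"].to_numpy(), df["lat"].to_numpy(), lon0, lat0)
    df["x"] = x
    df["y"] = y
    return replace(traj, df=df, projection_origin=(lon0, lat0))


def prepare(traj: Trajectory, min_satellites: int = 5) -> Trajectory:
    """clean_fixes → annotate_day_night → project_local in one call."""
    return project_local(annotate_day_night(clean_fixes(traj, min_satellites)))


def write_tracks(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Write trajectories to a single native-dialect CSV (with any derived columns)."""
    frames = []
    for traj in trajectories:
        df = traj.df.copy()
        df.insert(0, "tag_id", traj.tag_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["tag_id", *COLUMNS])
    out.to_csv(path, index=False)
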