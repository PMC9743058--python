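"""Trajectory revisitation analysis.

For every relocation of a trajectory taken as a focal point, this module
computes the *visits* to the closed disc of radius R around it: maximal
time intervals during which the piecewise-linear trajectory is inside
the disc. Entry and exit instants on a segment that crosses the circle
are obtained analytically (the quadratic in the segment parameter),
which is equivalent to linear time-interpolation of the crossing.

Conventions (configurable where noted):

* the disc is closed — a fix exactly on the boundary is inside;
* a segment tangent to the circle contributes no zero-length visit;
* a time gap longer than ``gap_factor`` times the nominal sampling
  interval breaks a visit, because the bird's position across the gap
  is unknown (no residence is accrued across such a segment);
* the first entry counts as visit 1, so a location seen only once has
  a revisit count of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tracks import Trajectory

DEFAULT_RADIUS_M = 20.0


@dataclass(frozen=True)
class Visit:
    """One maximal interval inside a focal disc."""

    focal_index: int
    entry_time: float  # seconds since epoch
    exit_time: float

    @property
    def duration(self) -> float:
        return self.exit_time - self.entry_time


@dataclass
class RevisitStats:
    """Per-focal visit counts and residence times for one trajectory."""

    traj: Trajectory
    radius: float
    n_visits: np.ndarray  # (n,) int
    residence_s: np.ndarray  # (n,) float
    visits: list[list[Visit]] | None = None  # populated when detailed=True

    def __len__(self) -> int:
        return len(self.n_visits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tag_id": self.traj.tag_id,
                "timestamp": self.traj.df["timestamp"].to_numpy(),
                "n_visits": self.n_visits,
                "total_residence_s": self.residence_s,
            }
        )


@dataclass
class FrequencyProfile:
    """Histogram of per-fix revisit counts within a time window."""

    window: tuple[pd.Timestamp, pd.Timestamp]
    counts: dict[int, int]
    n_fixes: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"window_start": self.window[0], "revisit_count": k, "n_fixes": v}
            for k, v in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["window_start", "revisit_count", "n_fixes"])


def _segment_intervals(
    xy: np.ndarray, focals: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Presence interval of each segment inside each focal disc.

    Returns (s_lo, s_hi, present) of shape (n_segments, n_focals):
    the sub-interval of the segment parameter s in [0, 1] spent inside
    the disc, and whether that interval is non-degenerate (or touches a
    segment endpoint, so that boundary fixes still register).
    """
    seg_a = xy[:-1]  # (m, 2)
    seg_d = xy[1:] - xy[:-1]  # (m, 2)
    # a = seg_a - focal, per (segment, focal)
    ax = seg_a[:, None, 0] - focals[None, :, 0]
    ay = seg_a[:, None, 1] - focals[None, :, 1]
    A = (seg_d**2).sum(axis=1)[:, None]  # (m, 1)
    B = 2.0 * (ax * seg_d[:, None, 0] + ay * seg_d[:, None, 1])
    C = ax**2 + ay**2 - radius**2

    disc = B**2 - 4.0 * A * C
    sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = (-B - sqrt_disc) / (2.0 * A)
        s2 = (-B + sqrt_disc) / (2.0 * A)
    # degenerate (zero-length) segments: inside iff the point is inside
    degen = A[:, 0] < 1e-18
    if degen.any():
        inside_pt = C[degen] <= 0.0
        s1[degen] = np.where(inside_pt, 0.0, 1.0)
        s2[degen] = np.where(inside_pt, 1.0, 0.0)

    s_lo = np.clip(s1, 0.0, 1.0)
    s_hi = np.clip(s2, 0.0, 1.0)
    has_roots = disc >= 0.0
    overlaps = (s1 <= 1.0) & (s2 >= 0.0)
    positive = s_hi > s_lo
    # zero-length intervals still count when they sit on a fix (boundary fix)
    touches_fix = ((s_lo <= 0.0) & (C <= 0.0)) | ((s_hi >= 1.0) & ((A + B + C) <= 0.0))
    present = has_roots & overlaps & (positive | touches_fix)
    s_lo = np.where(present, s_lo, np.nan)
    s_hi = np.where(present, s_hi, np.nan)
    return s_lo, s_hi, present


def compute_revisits(
    traj: Trajectory,
    radius: float = DEFAULT_RADIUS_M,
    gap_factor: float = 4.0,
    detailed: bool = False,
    chunk: int = 512,
) -> RevisitStats:
    """Visit counts and residence time around every relocation.

    Every relocation serves as a focal point; its own fix is inside its
    disc, so any focal that is part of the evaluated trajectory has at
    least one visit.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(traj)
    if n == 0:
        return RevisitStats(traj, radius, np.zeros(0, dtype=int), np.zeros(0), [] if detailed else None)

    xy = traj.xy
    t = traj.times_s
    dt = np.diff(t)  # (m,)
    nominal = traj.sampling_interval.total_seconds()
    valid = dt <= gap_factor * nominal  # segments short enough to interpolate

    n_visits = np.zeros(n, dtype=int)
    residence = np.zeros(n, dtype=float)
    all_visits: list[list[Visit]] | None = [] if detailed else None

    if n == 1:
        n_visits[0] = 1
        if detailed:
            all_visits.append([Visit(0, t[0], t[0])])
        return RevisitStats(traj, radius, n_visits, residence, all_visits)

    for start in range(0, n, chunk):
        focals = xy[start : start + chunk]
        s_lo, s_hi, present = _segment_intervals(xy, focals, radius)
        present = present & valid[:, None]
        s_lo = np.where(present, s_lo, np.nan)
        s_hi = np.where(present, s_hi, np.nan)

        # inside flag for each fix w.r.t. each focal
        diff = xy[:, None, :] - focals[None, :, :]
        inside = (diff**2).sum(axis=2) <= radius**2  # (n, k)

        # component count: presence runs connected through an inside fix
        connect = present[:-1] & present[1:] & inside[1:-1]
        comp = present.sum(axis=0) - connect.sum(axis=0)

        # isolated inside fixes flanked by no valid segment
        left_ok = np.concatenate(([False], valid))  # valid segment ending at fix j
        right_ok = np.concatenate((valid, [False]))  # valid segment starting at fix j
        iso = inside & ~left_ok[:, None] & ~right_ok[:, None]

        n_visits[start : start + chunk] = comp + iso.sum(axis=0)
        residence[start : start + chunk] = np.nansum((s_hi - s_lo) * dt[:, None], axis=0)

        if detailed:
            for j in range(focals.shape[0]):
                all_visits.append(
                    _assemble_visits(start + j, t, dt, valid, s_lo[:, j], s_hi[:, j],
                                     present[:, j], inside[:, j])
                )

    return RevisitStats(traj, radius, n_visits, residence, all_visits)


def _assemble_visits(focal_index, t, dt, valid, s_lo, s_hi, present, inside) -> list[Visit]:
    """Merge per-segment presence intervals into maximal visits for one focal."""
    visits: list[Visit] = []
    entry = exit_ = None
    m = len(dt)
    for i in range(m):
        if not present[i]:
            if entry is not None:
                visits.append(Visit(focal_index, entry, exit_))
                entry = None
            continue
        seg_entry = t[i] + s_lo[i] * dt[i]
        seg_exit = t[i] + s_hi[i] * dt[i]
        if entry is not None and inside[i]:  # continues previous segment's visit
            exit_ = seg_exit
        else:
            if entry is not None:
                visits.append(Visit(focal_index, entry, exit_))
            entry, exit_ = seg_entry, seg_exit
        if s_hi[i] < 1.0:  # leaves the disc before the next fix
            visits.append(Visit(focal_index, entry, exit_))
            entry = None
    if entry is not None:
        visits.append(Visit(focal_index, entry, exit_))
    # isolated inside fixes with no adjacent valid segment
    left_ok = np.concatenate(([False], valid))
    right_ok = np.concatenate((valid, [False]))
    for j in np.nonzero(inside & ~left_ok & ~right_ok)[0]:
        visits.append(Visit(focal_index, t[j], t[j]))
    visits.sort(key=lambda v: v.entry_time)
    return visits


def frequency_profile(
    stats: RevisitStats,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    gap_factor: float = 4.0,
) -> FrequencyProfile:
    """Histogram of revisit counts for focal fixes in a half-open window.

    Counts are recomputed on the windowed sub-trajectory so that
    movement outside the window does not contribute (weekly profiles are
    self-contained).
    """
    traj = stats.traj
    if window is None:
        sub_stats = stats
        start = traj.df["timestamp"].iloc[0] if len(traj) else pd.Timestamp(0)
        end = traj.df["timestamp"].iloc[-1] + pd.Timedelta(seconds=1) if len(traj) else pd.Timestamp(0)
        window = (start, end)
    else:
        sub = traj.window(*window)
        if len(sub) == 0:
            return FrequencyProfile(tuple(map(pd.Timestamp, window)), {}, 0)
        sub_stats = compute_revisits(sub, stats.radius, gap_factor=gap_factor)
    values, freq = np.unique(sub_stats.n_visits, return_counts=True)
    counts = {int(v): int(f) for v, f in zip(values, freq) if v >= 1}
    return FrequencyProfile(tuple(map(pd.Timestamp, window)), counts, int(len(sub_stats)))
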