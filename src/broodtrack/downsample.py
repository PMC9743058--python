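"""Sampling-resolution experiment: thin tracks and find the minimum
window length at which stage classification still matches truth.

Tags are often duty-cycled to save battery; this module asks how much
the stage classifier loses when a 15-min track is reduced to 30-min or
60-min schedules, or to daylight-morning fixes only, and what the
shortest analysis window is under each schedule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .focal_sites import InsufficientDataError
from .io_tracks import Trajectory
from .stage_classifier import ClassifierConfig, classify_window, profile_features
from .stage_labels import NON_BREEDING_LABELS, StageLabel, StageSegment


class SchemeKind(enum.Enum):
    INTERVAL = "interval"
    DAYLIGHT_MORNING = "daylight_morning"


@dataclass(frozen=True)
class SamplingScheme:
    """A reduced GPS schedule: a coarser fixed interval, or morning-only."""

    kind: SchemeKind
    interval_min: float = 15.0
    band_start_hour: int = 8  # UTC, for DAYLIGHT_MORNING
    band_end_hour: int = 14  # exclusive

    def __post_init__(self):
        if self.kind is SchemeKind.INTERVAL and self.interval_min <= 0:
            raise ValueError("interval must be positive")
        if self.band_end_hour <= self.band_start_hour:
            raise ValueError("band end must be after band start")


FULL_15MIN = SamplingScheme(SchemeKind.INTERVAL, 15.0)
HALF_HOURLY = SamplingScheme(SchemeKind.INTERVAL, 30.0)
HOURLY = SamplingScheme(SchemeKind.INTERVAL, 60.0)
MORNINGS = SamplingScheme(SchemeKind.DAYLIGHT_MORNING)


def thin(traj: Trajectory, scheme: SamplingScheme) -> Trajectory:
    """Reduce a trajectory to the given sampling scheme.

    INTERVAL keeps the fix nearest each grid time (grid anchored at the
    first fix, one fix per slot); DAYLIGHT_MORNING keeps fixes whose
    UTC time of day falls in the configured band. Both preserve order
    and are idempotent for a matching scheme.
    """
    from dataclasses import replace

    if len(traj) == 0:
        return traj
    if scheme.kind is SchemeKind.DAYLIGHT_MORNING:
        hours = traj.df["timestamp"].dt.hour
        keep = (hours >= scheme.band_start_hour) & (hours < scheme.band_end_hour)
        return replace(traj, df=traj.df.loc[keep])

    t = traj.times_s
    step = scheme.interval_min * 60.0
    slots = np.round((t - t[0]) / step).astype(int)
    offset = np.abs(t - (t[0] + slots * step))
    n_slots = int((t[-1] - t[0]) // step) + 1  # grid stays within the span
    df = traj.df.copy()
    df["_slot"] = slots
    df["_off"] = offset
    df = df[df["_slot"] < n_slots]
    df = df.sort_values(["_slot", "_off"], kind="stable").drop_duplicates("_slot")
    df = df.sort_values("timestamp", kind="stable").drop(columns=["_slot", "_off"])
    return replace(traj, df=df,
                   sampling_interval=pd.Timedelta(minutes=scheme.interval_min))


def _truth_label_for_window(
    truth: list[StageSegment], start: pd.Timestamp, end: pd.Timestamp
) -> StageLabel | None:
    """The single truth label covering [start, end), or None if mixed."""
    for seg in truth:
        if seg.start <= start and end <= seg.end:
            return seg.label
    return None


def _labels_match(pred: StageLabel, truth: StageLabel) -> bool:
    # pre/post have equivalent profiles; windows are classified out of
    # timeline context here, so either non-breeding label matches
    if pred in NON_BREEDING_LABELS and truth in NON_BREEDING_LABELS:
        return True
    return pred is truth


def min_window_eval(
    traj: Trajectory,
    truth: list[StageSegment],
    scheme: SamplingScheme,
    window_lengths_days: list[int],
    config: ClassifierConfig | None = None,
    agreement_required: float = 0.9,
) -> tuple[int | None, pd.DataFrame]:
    """Smallest window length at which thinned-data labels agree with truth.

    For each candidate length L the span is tiled with consecutive
    L-day windows; windows wholly inside one truth segment are
    classified on the thinned trajectory and compared to the truth
    label. The smallest L reaching the required agreement is returned
    (None if no tested length suffices), together with a per-length
    report frame.
    """
    if not window_lengths_days:
        raise ValueError("window_lengths_days must be non-empty")
    cfg = config or ClassifierConfig()
    thinned = thin(traj, scheme)
    t0 = thinned.df["timestamp"].iloc[0].floor("D")
    t_end = thinned.df["timestamp"].iloc[-1]
    rows = []
    minimal = None
    for length in sorted(window_lengths_days):
        n_match = n_total = 0
        start = t0
        while start + pd.Timedelta(days=length) <= t_end:
            end = start + pd.Timedelta(days=length)
            truth_label = _truth_label_for_window(truth, start, end)
            start = end
            if truth_label is None:
                continue
            n_total += 1
            sub = thinned.window(end - pd.Timedelta(days=length), end)
            try:
                feats = profile_features(sub, cfg.radius_m, cfg)
                pred = classify_window(feats, cfg)
            except InsufficientDataError:
                continue  # counted as a miss via n_total
            if _labels_match(pred, truth_label):
                n_match += 1
        agreement = n_match / n_total if n_total else 0.0
        sufficient = n_total > 0 and agreement >= agreement_required
        rows.append(
            {"scheme": scheme.kind.value, "interval_min": scheme.interval_min,
             "window_length_days": length, "n_windows": n_total,
             "agreement": agreement, "sufficient": sufficient}
        )
        if sufficient and minimal is None:
            minimal = length
    return minimal, pd.DataFrame(rows)
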