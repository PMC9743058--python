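"""Breeding-stage classification from revisitation profiles.

The weekly revisit histogram of a breeding curlew has a recognisable
shape per stage: incubation is bimodal (a foraging peak at one visit
plus a strong nest focus revisited many times), chick guarding is a
sloped mid-range distribution (many places visited a few times, no
single focus, and a slowly drifting activity centre), and non-breeding
movement is dominated by places visited once. This module quantifies
those shapes as five window features, classifies windows by a rule
cascade, and refines the timing of stage changes first with rolling
3-day windows (day resolution) and then with nest-occupancy blocks
(hour resolution).

All thresholds live in :class:`ClassifierConfig` and are deliberate,
tunable operationalisations of qualitative criteria; see
docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .focal_sites import FocalSite, InsufficientDataError, nest_location
from .io_tracks import Trajectory
from .recursion import compute_revisits
from .stage_labels import (
    NON_BREEDING_LABELS,
    StageLabel,
    StageSegment,
    TransitionEvent,
    TransitionKind,
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and window conventions of the stage classifier."""

    radius_m: float = 20.0
    min_window_fixes: int = 10
    gap_factor: float = 4.0
    # rule cascade
    incubation_focus_share: float = 0.30
    incubation_max_visits_norm: float = 0.15
    chick_mid_mass: float = 0.40
    chick_drift_max_m_per_day: float = 500.0
    # refinement
    refine_window_days: int = 3
    occupancy_threshold: float = 0.2
    occupancy_block_hours: float = 6.0
    hatch_drift_max_m_per_day: float = 500.0
    hatch_range_max_m: float = 2000.0
    displacement_jump_m: float = 2000.0
    # plausibility annotations (expected stage lengths, days)
    expected_incubation_days: float = 28.0
    expected_chick_days: float = 35.0


@dataclass(frozen=True)
class ProfileFeatures:
    """Shape features of one windowed revisitation profile."""

    n_fixes: int
    prop_single: float  # fraction of fixes visited exactly once
    dominant_focus_share: float  # largest fraction of fixes within R of one fix
    mid_mass: float  # fraction with 2..10 visits
    max_visits_norm: float  # max visit count / window fix count
    drift_rate: float  # mean daily-centroid displacement, m/day


@dataclass
class Timeline:
    """Output of segment_timeline: tiled segments plus typed transitions."""

    segments: list[StageSegment]
    transitions: list[TransitionEvent]
    nests: dict[int, FocalSite] = field(default_factory=dict)  # attempt_index -> nest
    week_labels: list[tuple[pd.Timestamp, str]] = field(default_factory=list)

    @property
    def is_breeder(self) -> bool:
        return any(s.label is StageLabel.INCUBATION for s in self.segments)

    def label_at(self, when: pd.Timestamp) -> StageLabel | None:
        for seg in self.segments:
            if seg.start <= when < seg.end:
                return seg.label
        return None


def profile_features(
    window_traj: Trajectory,
    radius: float = 20.0,
    config: ClassifierConfig | None = None,
) -> ProfileFeatures:
    """Compute the five profile features on a windowed trajectory."""
    cfg = config or ClassifierConfig(radius_m=radius)
    n = len(window_traj)
    if n < cfg.min_window_fixes:
        raise InsufficientDataError(f"window holds {n} fixes; {cfg.min_window_fixes} required")
    stats = compute_revisits(window_traj, radius, gap_factor=cfg.gap_factor)
    nv = stats.n_visits

    xy = window_traj.xy
    # largest neighbourhood share: max over fixes of within-R fix count
    best = 0
    r2 = radius**2
    for start in range(0, n, 512):
        block = xy[start : start + 512]
        d2 = ((xy[:, None, :] - block[None, :, :]) ** 2).sum(axis=2)
        best = max(best, int((d2 <= r2).sum(axis=0).max()))
    dominant_share = best / n

    days = window_traj.df["timestamp"].dt.floor("D")
    cent = pd.DataFrame({"day": days, "x": xy[:, 0], "y": xy[:, 1]}).groupby("day").mean()
    if len(cent) >= 2:
        day_gaps = np.diff(cent.index.to_numpy()).astype("timedelta64[s]").astype(float) / 86400.0
        steps = np.hypot(np.diff(cent["x"].to_numpy()), np.diff(cent["y"].to_numpy()))
        drift = float(np.mean(steps / day_gaps))
    else:
        drift = 0.0

    return ProfileFeatures(
        n_fixes=n,
        prop_single=float(np.mean(nv == 1)),
        dominant_focus_share=float(dominant_share),
        mid_mass=float(np.mean((nv >= 2) & (nv <= 10))),
        max_visits_norm=float(nv.max() / n),
        drift_rate=drift,
    )


def classify_window(
    features: ProfileFeatures,
    config: ClassifierConfig | None = None,
    after_incubation: bool = False,
) -> StageLabel:
    """Rule cascade mapping profile features to a stage label.

    The cascade is total: whatever does not look like incubation or
    chick guarding is non-breeding movement, split into pre- or
    post-breeding by ``after_incubation`` (their profiles are
    equivalent, so the split is positional).
    """
    cfg = config or ClassifierConfig()
    if (
        features.dominant_focus_share >= cfg.incubation_focus_share
        and features.max_visits_norm >= cfg.incubation_max_visits_norm
    ):
        return StageLabel.INCUBATION
    if (
        features.mid_mass >= cfg.chick_mid_mass
        and features.dominant_focus_share < cfg.incubation_focus_share
        and features.drift_rate <= cfg.chick_drift_max_m_per_day
    ):
        return StageLabel.CHICK_GUARDING
    return StageLabel.POST_BREEDING if after_incubation else StageLabel.PRE_BREEDING


# ---------------------------------------------------------------------------
# timeline segmentation


def _iso_week_starts(first: pd.Timestamp, last: pd.Timestamp) -> list[pd.Timestamp]:
    start = (first - pd.Timedelta(days=int(first.dayofweek))).floor("D")  # Monday
    weeks = []
    w = start
    while w <= last:
        weeks.append(w)
        w = w + pd.Timedelta(days=7)
    return weeks


def _raw_label(traj: Trajectory, start, end, cfg: ClassifierConfig) -> str | None:
    """'INC' / 'CG' / 'NB' for one window, or None when data are too thin."""
    sub = traj.window(start, end)
    if len(sub) < cfg.min_window_fixes:
        return None
    feats = profile_features(sub, cfg.radius_m, cfg)
    label = classify_window(feats, cfg)
    if label is StageLabel.INCUBATION:
        return "INC"
    if label is StageLabel.CHICK_GUARDING:
        return "CG"
    return "NB"


def occupancy_series(
    traj: Trajectory,
    nest_xy: tuple[float, float],
    bracket: tuple[pd.Timestamp, pd.Timestamp],
    radius: float,
    block_hours: float,
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Fraction of fixes within ``radius`` of the nest per time block.

    Blocks with no fixes get NaN occupancy.
    """
    sub = traj.window(*bracket)
    starts = pd.date_range(bracket[0], bracket[1], freq=pd.Timedelta(hours=block_hours),
                           inclusive="left")
    occ = np.full(len(starts), np.nan)
    if len(sub) == 0:
        return starts, occ
    xy = sub.xy
    near = np.hypot(xy[:, 0] - nest_xy[0], xy[:, 1] - nest_xy[1]) <= radius
    idx = ((sub.times - bracket[0]).dt.total_seconds() // (block_hours * 3600.0)).astype(int)
    for b in range(len(starts)):
        m = idx == b
        if m.any():
            occ[b] = float(near[m.to_numpy()].mean())
    return starts, occ


def locate_transition(
    traj: Trajectory,
    nest: FocalSite,
    bracket: tuple[pd.Timestamp, pd.Timestamp],
    radius: float = 20.0,
    config: ClassifierConfig | None = None,
) -> TransitionEvent | None:
    """Hour-level timing (and kind) of the end of incubation.

    The transition is the start of the first occupancy block below the
    threshold with every later non-empty block in the bracket also
    below it. The kind is resolved from post-transition behaviour: a
    slowly drifting activity centre that stays near the nest means a
    hatch (mobile brood); anything else is a failure.
    Returns None when occupancy never drops (caller re-widens).
    """
    cfg = config or ClassifierConfig(radius_m=radius)
    starts, occ = occupancy_series(traj, (nest.x, nest.y), bracket, radius,
                                   cfg.occupancy_block_hours)
    below = occ < cfg.occupancy_threshold  # NaN compares False
    nonempty = ~np.isnan(occ)
    order = np.arange(len(starts))
    t_change = None
    for b in range(len(starts)):
        if not (nonempty[b] and below[b]):
            continue
        if not np.any(~below & nonempty & (order > b)):  # stays below afterwards
            t_change = starts[b]
            break
    if t_change is None:
        return None

    after = traj.window(t_change, t_change + pd.Timedelta(hours=48))
    kind = TransitionKind.NEST_FAIL
    if len(after) >= 4:
        xy = after.xy
        days = after.df["timestamp"].dt.floor("D")
        cent = pd.DataFrame({"day": days, "x": xy[:, 0], "y": xy[:, 1]}).groupby("day").mean()
        dist = np.hypot(cent["x"] - nest.x, cent["y"] - nest.y)
        if len(cent) >= 2:
            drift = float(np.mean(np.hypot(np.diff(cent["x"]), np.diff(cent["y"]))))
        else:
            drift = 0.0
        if drift <= cfg.hatch_drift_max_m_per_day and (dist <= cfg.hatch_range_max_m).all():
            kind = TransitionKind.HATCH
    return TransitionEvent(kind=kind, time=pd.Timestamp(t_change),
                           resolution_s=cfg.occupancy_block_hours * 3600.0)


def _locate_rise(traj, nest_xy, bracket, cfg: ClassifierConfig) -> pd.Timestamp | None:
    """First block from which nest occupancy stays above threshold."""
    starts, occ = occupancy_series(traj, nest_xy, bracket, cfg.radius_m,
                                   cfg.occupancy_block_hours)
    above = occ >= cfg.occupancy_threshold
    nonempty = ~np.isnan(occ)
    for b in range(len(starts)):
        if not (nonempty[b] and above[b]):
            continue
        later = nonempty & (np.arange(len(starts)) > b)
        if not np.any(~above & later):
            return pd.Timestamp(starts[b])
    return None


def _locate_jump(traj, bracket, cfg: ClassifierConfig) -> pd.Timestamp | None:
    """First inter-fix displacement jump inside the bracket (brood loss)."""
    sub = traj.window(*bracket)
    if len(sub) < 2:
        return None
    xy = sub.xy
    step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    idx = np.nonzero(step > cfg.displacement_jump_m)[0]
    if len(idx) == 0:
        return None
    return pd.Timestamp(sub.df["timestamp"].iloc[int(idx[0]) + 1])


def segment_timeline(
    traj: Trajectory,
    radius: float = 20.0,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> Timeline:
    """Full stage timeline for one cleaned, projected trajectory.

    Coarse pass on ISO calendar weeks, then day-level refinement of
    each label change with rolling 3-day windows, then hour-level
    refinement with nest-occupancy blocks. Segments tile the tracked
    span; minimum segment length is one day.
    """
    cfg = config or ClassifierConfig(radius_m=radius)
    if traj.span_days < 3.0:
        raise InsufficientDataError(
            f"trajectory spans {traj.span_days:.1f} days; at least 3 required"
        )
    t_first = traj.df["timestamp"].iloc[0]
    t_last = traj.df["timestamp"].iloc[-1]

    # --- coarse pass: calendar weeks -------------------------------------
    week_starts = _iso_week_starts(t_first, t_last)
    labels: list[str | None] = [
        _raw_label(traj, w, w + pd.Timedelta(days=7), cfg) for w in week_starts
    ]
    # fill data-thin weeks from the nearest classified week
    known = [i for i, l in enumerate(labels) if l is not None]
    if not known:
        raise InsufficientDataError("no week with enough fixes to classify")
    for i in range(len(labels)):
        if labels[i] is None:
            j = min(known, key=lambda k: abs(k - i))
            labels[i] = labels[j]
    week_labels = [(w, l) for w, l in zip(week_starts, labels)]

    # collapse into time-bounded runs
    runs: list[dict] = []
    for i, l in enumerate(labels):
        w0 = week_starts[i]
        w1 = w0 + pd.Timedelta(days=7)
        if runs and runs[-1]["label"] == l:
            runs[-1]["end"] = w1
        else:
            runs.append({"label": l, "start": w0, "end": w1})
    runs[0]["start"] = max(runs[0]["start"], t_first.floor("D"))
    runs[-1]["end"] = min(runs[-1]["end"], t_last + pd.Timedelta(seconds=1))

    # interior scan: stage changes shorter than a week (a failed attempt
    # plus renest, or a short attempt inside wide-ranging movement) can
    # hide inside one coarse run; rolling 3-day windows across each run
    # recover interior blocks of a different label at day resolution
    refine_td = pd.Timedelta(days=cfg.refine_window_days)
    split_runs: list[dict] = []
    for run in runs:
        if run["end"] - run["start"] < 2 * refine_td:
            split_runs.append(run)
            continue
        d = pd.Timestamp(run["start"]).floor("D")
        day_labels: list[tuple[pd.Timestamp, str | None]] = []
        while d + refine_td <= run["end"]:
            day_labels.append((d, _raw_label(traj, d, d + refine_td, cfg)))
            d += pd.Timedelta(days=1)
        # maximal blocks of >= 2 consecutive same-label windows that
        # disagree with the run label, strictly interior to the run
        blocks: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
        cur: list[pd.Timestamp] = []
        cur_lab: str | None = None
        for d, lab in day_labels:
            if lab is not None and lab != run["label"] and lab == cur_lab:
                cur.append(d)
            elif lab is not None and lab != run["label"]:
                if len(cur) >= 2:
                    blocks.append((cur[0], cur[-1] + refine_td, cur_lab))
                cur, cur_lab = [d], lab
            else:
                if len(cur) >= 2:
                    blocks.append((cur[0], cur[-1] + refine_td, cur_lab))
                cur, cur_lab = [], None
        if len(cur) >= 2:
            blocks.append((cur[0], cur[-1] + refine_td, cur_lab))
        pos = run["start"]
        for g0, g1, lab in blocks:
            if g0 <= pos or g1 >= run["end"]:
                continue  # touches the run edge; boundary refinement handles it
            split_runs.append({"label": run["label"], "start": pos, "end": g0})
            split_runs.append({"label": lab, "start": g0, "end": g1})
            pos = g1
        split_runs.append({"label": run["label"], "start": pos, "end": run["end"]})
    runs = [r for r in split_runs if r["end"] > r["start"]]
    merged: list[dict] = []
    for run in runs:
        if merged and merged[-1]["label"] == run["label"]:
            merged[-1]["end"] = run["end"]
        else:
            merged.append(run)
    runs = merged

    # --- day-level refinement of each run boundary -------------------------
    boundaries: list[dict] = []  # {time, old, new, kind, resolution_s}
    for r in range(len(runs) - 1):
        old, new = runs[r]["label"], runs[r + 1]["label"]
        guess = pd.Timestamp(runs[r]["end"]).floor("D")
        day0 = max(pd.Timestamp(runs[r]["start"]).floor("D"),
                   guess - pd.Timedelta(days=4), t_first.floor("D"))
        day1 = min(pd.Timestamp(runs[r + 1]["end"]),
                   guess + pd.Timedelta(days=4),
                   t_last.floor("D") + pd.Timedelta(days=1))
        # first day whose 3-day window (and the next, to ride out one
        # misclassified window) carries the new label
        day_seq: list[tuple[pd.Timestamp, str | None]] = []
        d = day0
        while d + refine_td <= day1:
            day_seq.append((d, _raw_label(traj, d, d + refine_td, cfg)))
            d += pd.Timedelta(days=1)
        change_day = None
        for i, (d, lab) in enumerate(day_seq):
            if lab != new:
                continue
            if i + 1 >= len(day_seq) or day_seq[i + 1][1] == new:
                change_day = d
                break
        if change_day is None:
            for d, lab in day_seq:  # single-window fallback
                if lab == new:
                    change_day = d
                    break
        if change_day is None:
            change_day = guess  # fall back to the coarse boundary
        boundaries.append(
            {"old": old, "new": new, "day": change_day,
             "time": change_day, "resolution_s": 43200.0, "kind": None}
        )

    # --- assign attempts and nests, then hour-level refinement -------------
    run_spans = []
    prev_t = t_first
    for r, run in enumerate(runs):
        end_t = boundaries[r]["day"] if r < len(boundaries) else t_last
        run_spans.append((prev_t, max(end_t, prev_t)))
        prev_t = max(end_t, prev_t)

    nests: dict[int, FocalSite] = {}
    attempt = 0
    run_attempt: dict[int, int] = {}
    for r, run in enumerate(runs):
        if run["label"] != "INC":
            continue
        attempt += 1
        run_attempt[r] = attempt
        start, end = run_spans[r]
        nest_win = (start, min(end, start + pd.Timedelta(days=7)))
        try:
            nests[attempt] = nest_location(traj, nest_win, radius=cfg.radius_m, seed=seed)
        except (InsufficientDataError, ValueError):
            pass

    for r, b in enumerate(boundaries):
        day = b["day"]
        bracket = (day - pd.Timedelta(days=1),
                   day + pd.Timedelta(days=cfg.refine_window_days))
        refined = None
        if b["old"] == "INC" and run_attempt.get(r) in nests:
            ev = locate_transition(traj, nests[run_attempt[r]], bracket, cfg.radius_m, cfg)
            if ev is None:
                wide = (bracket[0] - pd.Timedelta(days=1), bracket[1] + pd.Timedelta(days=1))
                ev = locate_transition(traj, nests[run_attempt[r]], wide, cfg.radius_m, cfg)
            if ev is not None:
                refined = ev.time
                b["kind"] = ev.kind
                b["resolution_s"] = ev.resolution_s
        elif b["new"] == "INC" and run_attempt.get(r + 1) in nests:
            nest = nests[run_attempt[r + 1]]
            t_rise = _locate_rise(traj, (nest.x, nest.y), bracket, cfg)
            if t_rise is None:
                wide = (bracket[0] - pd.Timedelta(days=1), bracket[1] + pd.Timedelta(days=1))
                t_rise = _locate_rise(traj, (nest.x, nest.y), wide, cfg)
            if t_rise is not None:
                refined = t_rise
                b["kind"] = TransitionKind.INCUBATION_START
                b["resolution_s"] = cfg.occupancy_block_hours * 3600.0
        elif b["old"] == "CG":
            # the failure displacement is a sharp, unambiguous signal, so
            # search a wide bracket around the day estimate
            wide = (day - pd.Timedelta(days=4),
                    day + pd.Timedelta(days=4 + cfg.refine_window_days))
            t_jump = _locate_jump(traj, wide, cfg)
            if t_jump is not None:
                refined = t_jump
                b["kind"] = TransitionKind.BROOD_FAIL
                b["resolution_s"] = cfg.occupancy_block_hours * 3600.0
        if refined is not None:
            b["time"] = refined
        if b["kind"] is None:
            b["kind"] = {
                ("NB", "INC"): TransitionKind.INCUBATION_START,
                ("INC", "CG"): TransitionKind.HATCH,
                ("INC", "NB"): TransitionKind.NEST_FAIL,
                ("CG", "NB"): TransitionKind.BROOD_FAIL,
                ("CG", "INC"): TransitionKind.INCUBATION_START,
                ("NB", "CG"): TransitionKind.HATCH,
            }.get((b["old"], b["new"]), TransitionKind.NEST_FAIL)

    # --- build tiled segments ----------------------------------------------
    # enforce increasing boundary times with >= 1 day spacing
    times = [t_first]
    for b in boundaries:
        t = max(pd.Timestamp(b["time"]), times[-1] + pd.Timedelta(days=1))
        times.append(min(t, t_last))
    times.append(t_last)

    segments: list[StageSegment] = []
    seen_inc = False
    attempt = 0
    for r, run in enumerate(runs):
        start, end = times[r], times[r + 1]
        if end <= start:
            continue
        raw = run["label"]
        if raw == "INC":
            seen_inc = True
            attempt += 1
            label = StageLabel.INCUBATION
            idx = attempt
        elif raw == "CG":
            label = StageLabel.CHICK_GUARDING
            idx = None
        else:
            label = StageLabel.POST_BREEDING if seen_inc else StageLabel.PRE_BREEDING
            idx = None
        note = ""
        span_d = (end - start).total_seconds() / 86400.0
        if label is StageLabel.INCUBATION and span_d > 1.5 * cfg.expected_incubation_days:
            note = f"incubation span {span_d:.0f} d exceeds expected ~{cfg.expected_incubation_days:.0f} d"
        if label is StageLabel.CHICK_GUARDING and span_d > 1.5 * cfg.expected_chick_days:
            note = f"chick-guarding span {span_d:.0f} d exceeds expected ~{cfg.expected_chick_days:.0f} d"
        segments.append(StageSegment(label=label, start=start, end=end,
                                     attempt_index=idx, confidence_notes=note))

    transitions = [
        TransitionEvent(kind=b["kind"], time=pd.Timestamp(t), resolution_s=b["resolution_s"])
        for b, t in zip(boundaries, times[1:-1])
    ]
    transitions.append(TransitionEvent(kind=TransitionKind.TAG_END, time=t_last, resolution_s=0.0))
    return Timeline(segments=segments, transitions=transitions, nests=nests,
                    week_labels=week_labels)


def segments_to_frame(segments: list[StageSegment], tag_id: str = "") -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"tag_id": tag_id, "label": s.label.name, "start": s.start, "end": s.end,
             "attempt_index": s.attempt_index, "confidence_notes": s.confidence_notes}
            for s in segments
        ]
    )
    df["attempt_index"] = df["attempt_index"].astype("Int64")
    df["confidence_notes"] = df["confidence_notes"].astype("string")
    return df
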