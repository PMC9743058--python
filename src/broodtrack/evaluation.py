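"""Scoring inferred timelines against simulator ground truth, and the
repeatable end-to-end benchmarks built on those scores."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geo, io_tracks, simulate
from .io_tracks import Trajectory
from .stage_classifier import Timeline
from .stage_labels import StageLabel, StageSegment, TransitionEvent, TransitionKind


def week_agreement(
    timeline: Timeline,
    truth: list[StageSegment],
    traj: Trajectory,
    min_fixes: int = 10,
) -> tuple[int, int]:
    """(matching weeks, scored weeks) over truth-homogeneous calendar weeks.

    A week is scored when it lies wholly inside one truth segment and
    holds enough fixes; its predicted label is the timeline's label at
    the week midpoint. Transition weeks have no single true label and
    are not scored.
    """
    n_match = n_total = 0
    for wk_start, _raw in timeline.week_labels:
        wk_end = wk_start + pd.Timedelta(days=7)
        truth_label = None
        for seg in truth:
            if seg.start <= wk_start and wk_end <= seg.end:
                truth_label = seg.label
                break
        if truth_label is None:
            continue
        if len(traj.window(wk_start, wk_end)) < min_fixes:
            continue
        pred = timeline.label_at(wk_start + pd.Timedelta(days=3, hours=12))
        if pred is None:
            continue
        n_total += 1
        if pred is truth_label:
            n_match += 1
    return n_match, n_total


def transition_errors(
    predicted: list[TransitionEvent],
    truth: list[TransitionEvent],
    unmatched_penalty_s: float = 7 * 86400.0,
) -> list[float]:
    """Absolute timing error (seconds) per true stage change.

    Each true transition (tag-end excluded) is greedily paired with the
    nearest unused predicted transition; a true transition with no
    prediction left scores the penalty, so missed changes are not
    silently dropped from the error distribution.
    """
    truth_ev = [t for t in truth if t.kind is not TransitionKind.TAG_END]
    pred_ev = [p for p in predicted if p.kind is not TransitionKind.TAG_END]
    used = [False] * len(pred_ev)
    errors = []
    for t in sorted(truth_ev, key=lambda e: e.time):
        best_j, best_err = None, None
        for j, p in enumerate(pred_ev):
            if used[j]:
                continue
            err = abs((p.time - t.time).total_seconds())
            if best_err is None or err < best_err:
                best_j, best_err = j, err
        if best_j is None:
            errors.append(unmatched_penalty_s)
        else:
            used[best_j] = True
            errors.append(best_err)
    return errors


# ---------------------------------------------------------------------------
# end-to-end benchmarks on simulated cohorts


def stage_inference_benchmark(n_birds: int = 100, seed: int = 1) -> dict:
    """Classify a simulated cohort and score it against truth.

    Returns week-label agreement over truth-homogeneous weeks and the
    distribution of transition-timing errors (seconds).
    """
    from .stage_classifier import segment_timeline

    outs = simulate.simulate_cohort(simulate.CohortConfig(n_birds=n_birds), seed=seed)
    n_match = n_total = 0
    errors: list[float] = []
    for out in outs:
        traj = io_tracks.prepare(out.trajectory)
        timeline = segment_timeline(traj, seed=seed)
        m, t = week_agreement(timeline, out.truth_segments, traj)
        n_match += m
        n_total += t
        errors.extend(transition_errors(timeline.transitions, out.truth_transitions))
    return {
        "n_birds": n_birds,
        "n_weeks": n_total,
        "agreement": n_match / n_total if n_total else float("nan"),
        "errors_s": errors,
        "median_error_h": float(np.median(errors)) / 3600.0 if errors else float("nan"),
    }


def nest_error_benchmark(n_reps: int = 50, seed: int = 1) -> dict:
    """Median nest-localisation error over simulated incubations."""
    from .focal_sites import nest_location

    errors = []
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**30)
    for rep in range(n_reps):
        cfg = simulate.SimConfig(
            seed=int(base + rep),
            stages=((StageLabel.PRE_BREEDING, 2.0), (StageLabel.INCUBATION, 7.0)),
        )
        out = simulate.simulate_bird(cfg)
        traj = io_tracks.prepare(out.trajectory)
        seg = out.truth_segments[1]
        site = nest_location(traj, (seg.start, seg.end), seed=seed)
        nest = out.truth_nests[0]
        errors.append(float(geo.haversine_m(site.lon, site.lat, nest["lon"], nest["lat"])))
    return {
        "n_reps": n_reps,
        "median_error_m": float(np.median(errors)),
        "gps_noise_sd_m": simulate.SimConfig(seed=0).gps_noise_sd_m,
        "errors_m": errors,
    }


def mayfield_benchmark(
    true_dsr: float = 0.95, n_nests: int = 200, n_reps: int = 500, seed: int = 1
) -> dict:
    """Bias and CI coverage of the daily-survival estimator on simulated
    cohorts with geometric failure days capped at 28."""
    from .outcomes import BreedingAttempt, Fate, mayfield_dsr

    rng = np.random.default_rng(seed)
    estimates, covered = [], 0
    for _ in range(n_reps):
        fail_day = rng.geometric(1.0 - true_dsr, size=n_nests)
        exposure = np.minimum(fail_day, 28)
        failed = fail_day <= 28
        attempts = [
            BreedingAttempt(f"b{i}", 1, None, None, float(e),
                            Fate.FAILED if f else Fate.HATCHED)
            for i, (e, f) in enumerate(zip(exposure, failed))
        ]
        est = mayfield_dsr(attempts)
        estimates.append(est.dsr)
        covered += est.ci_low <= true_dsr <= est.ci_high
    return {
        "true_dsr": true_dsr,
        "mean_estimate": float(np.mean(estimates)),
        "bias": float(np.mean(estimates) - true_dsr),
        "coverage": covered / n_reps,
    }


def downsample_benchmark(seed: int = 1, n_birds: int = 3,
                         lengths: tuple[int, ...] = (3, 6, 9, 10)) -> dict:
    """Minimum sufficient window length per sampling scheme, pooled over
    simulated full-cycle birds (None means no tested length sufficed)."""
    from . import downsample as ds

    schemes = [("15min", ds.FULL_15MIN), ("30min", ds.HALF_HOURLY),
               ("60min", ds.HOURLY), ("morning", ds.MORNINGS)]
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**30)
    per_scheme: dict[str, list] = {name: [] for name, _ in schemes}
    for b in range(n_birds):
        out = simulate.simulate_bird(simulate.SimConfig(seed=int(base + b)))
        traj = io_tracks.prepare(out.trajectory)
        for name, scheme in schemes:
            minimal, _ = ds.min_window_eval(traj, out.truth_segments, scheme, list(lengths))
            per_scheme[name].append(minimal)
    def _worst(vals):
        return None if any(v is None for v in vals) else max(vals)
    return {name: _worst(vals) for name, vals in per_scheme.items()}
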