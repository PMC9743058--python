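import numpy as np
import pandas as pd
import pytest

from broodtrack import io_tracks, simulate
from broodtrack import stage_classifier as sc
from broodtrack.focal_sites import FocalSite, InsufficientDataError
from broodtrack.stage_labels import StageLabel, TransitionKind
from .conftest import make_traj


class TestProfileFeatures:
    def test_point_mass_window(self):
        f = sc.profile_features(make_traj(np.zeros((20, 2)), interval_s=900.0), 20.0)
        assert f.prop_single == 0.0 or f.prop_single == 1.0  # one shared visit each
        assert f.dominant_focus_share == 1.0
        assert f.drift_rate == 0.0

    def test_dispersed_window(self):
        xy = np.c_[np.arange(20.0) * 100.0, np.zeros(20)]
        f = sc.profile_features(make_traj(xy, interval_s=900.0), 20.0)
        assert f.prop_single == 1.0
        assert f.dominant_focus_share == pytest.approx(1 / 20)

    def test_too_few_fixes_raises(self):
        with pytest.raises(InsufficientDataError):
            sc.profile_features(make_traj(np.zeros((5, 2))), 20.0)

    def test_incubation_week_has_stronger_focus_than_nonbreeding(self, sim_bird):
        out, traj = sim_bird
        inc = next(s for s in out.truth_segments if s.label is StageLabel.INCUBATION)
        pre = next(s for s in out.truth_segments if s.label is StageLabel.PRE_BREEDING)
        f_inc = sc.profile_features(
            traj.window(inc.start + pd.Timedelta(days=2),
                        inc.start + pd.Timedelta(days=9)), 20.0)
        f_pre = sc.profile_features(traj.window(pre.start, pre.end), 20.0)
        assert f_inc.dominant_focus_share > f_pre.dominant_focus_share


class TestClassifyWindow:
    def _features(self, **over):
        base = dict(n_fixes=672, prop_single=0.3, dominant_focus_share=0.1,
                    mid_mass=0.2, max_visits_norm=0.05, drift_rate=100.0)
        base.update(over)
        return sc.ProfileFeatures(**base)

    def test_strong_focus_is_incubation(self):
        f = self._features(dominant_focus_share=0.9, max_visits_norm=0.5)
        assert sc.classify_window(f) is StageLabel.INCUBATION

    def test_dispersed_singles_is_nonbreeding(self):
        f = self._features(prop_single=0.8, dominant_focus_share=0.05)
        assert sc.classify_window(f) is StageLabel.PRE_BREEDING
        assert sc.classify_window(f, after_incubation=True) is StageLabel.POST_BREEDING

    def test_mid_heavy_slow_drift_is_chick_guarding(self):
        f = self._features(mid_mass=0.6, dominant_focus_share=0.1, drift_rate=300.0)
        assert sc.classify_window(f) is StageLabel.CHICK_GUARDING

    def test_fast_drift_blocks_chick_guarding(self):
        f = self._features(mid_mass=0.6, dominant_focus_share=0.1, drift_rate=2000.0)
        assert sc.classify_window(f) is StageLabel.PRE_BREEDING


class TestSegmentTimeline:
    def test_full_breeding_cycle_recovered(self, sim_bird):
        out, traj = sim_bird
        tl = sc.segment_timeline(traj)
        assert [s.label for s in tl.segments] == [
            StageLabel.PRE_BREEDING, StageLabel.INCUBATION,
            StageLabel.CHICK_GUARDING, StageLabel.POST_BREEDING,
        ]
        for pred, truth in zip(tl.segments, out.truth_segments):
            assert abs((pred.start - truth.start).total_seconds()) <= 86400.0
        # segments tile the span with no gaps or overlaps
        for a, b in zip(tl.segments, tl.segments[1:]):
            assert a.end == b.start
        assert tl.segments[0].start == traj.df["timestamp"].iloc[0]
        assert tl.segments[-1].end == traj.df["timestamp"].iloc[-1]
        # one transition per internal boundary plus tag end
        assert len(tl.transitions) == len(tl.segments)

    def test_nest_failure_gives_no_chick_guarding(self):
        cfg = simulate.SimConfig(
            seed=77,
            stages=(
                (StageLabel.PRE_BREEDING, 7.0), (StageLabel.INCUBATION, 7.3),
                (StageLabel.POST_BREEDING, 10.0),
            ),
        )
        out = simulate.simulate_bird(cfg)
        traj = io_tracks.prepare(out.trajectory)
        tl = sc.segment_timeline(traj)
        assert [s.label for s in tl.segments] == [
            StageLabel.PRE_BREEDING, StageLabel.INCUBATION, StageLabel.POST_BREEDING,
        ]
        kinds = [t.kind for t in tl.transitions]
        assert TransitionKind.NEST_FAIL in kinds
        assert TransitionKind.HATCH not in kinds

    def test_nonbreeding_track_is_single_segment(self):
        cfg = simulate.SimConfig(seed=5, stages=((StageLabel.PRE_BREEDING, 21.0),))
        out = simulate.simulate_bird(cfg)
        traj = io_tracks.prepare(out.trajectory)
        tl = sc.segment_timeline(traj)
        assert len(tl.segments) == 1
        assert tl.segments[0].label is StageLabel.PRE_BREEDING
        assert not tl.is_breeder
        assert [t.kind for t in tl.transitions] == [TransitionKind.TAG_END]

    def test_short_track_is_insufficient(self):
        cfg = simulate.SimConfig(seed=5, stages=((StageLabel.PRE_BREEDING, 2.0),))
        traj = io_tracks.prepare(simulate.simulate_bird(cfg).trajectory)
        with pytest.raises(InsufficientDataError):
            sc.segment_timeline(traj)

    def test_classification_invariant_to_rigid_motion(self, sim_bird):
        out, traj = sim_bird
        inc = next(s for s in out.truth_segments if s.label is StageLabel.INCUBATION)
        win = traj.window(inc.start + pd.Timedelta(days=2),
                          inc.start + pd.Timedelta(days=9))
        f0 = sc.profile_features(win, 20.0)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        df = win.df.copy()
        xy = df[["x", "y"]].to_numpy() @ rot.T + np.array([5000.0, -3000.0])
        df["x"], df["y"] = xy[:, 0], xy[:, 1]
        moved = io_tracks.Trajectory(win.tag_id, df, win.sampling_interval)
        f1 = sc.profile_features(moved, 20.0)
        assert f1.dominant_focus_share == pytest.approx(f0.dominant_focus_share)
        assert f1.max_visits_norm == pytest.approx(f0.max_visits_norm)
        assert f1.drift_rate == pytest.approx(f0.drift_rate, rel=1e-9)
        assert sc.classify_window(f1) is sc.classify_window(f0)


class TestLocateTransition:
    def test_bird_never_leaving_nest_yields_no_transition(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(0.0, 5.0, (96 * 3, 2))
        traj = make_traj(xy, interval_s=900.0)
        nest = FocalSite(0.0, 0.0, None, None, support=10, mean_revisits=50.0)
        bracket = (traj.df["timestamp"].iloc[0],
                   traj.df["timestamp"].iloc[-1] + pd.Timedelta(seconds=1))
        assert sc.locate_transition(traj, nest, bracket) is None

    def test_hatch_detected_within_half_day(self):
        errors = []
        for seed in range(10):
            cfg = simulate.SimConfig(seed=200 + seed)
            out = simulate.simulate_bird(cfg)
            traj = io_tracks.prepare(out.trajectory)
            tl = sc.segment_timeline(traj)
            truth_hatch = next(t for t in out.truth_transitions
                               if t.kind is TransitionKind.HATCH)
            pred = [t for t in tl.transitions if t.kind is TransitionKind.HATCH]
            assert pred, f"seed {seed}: hatch not detected"
            errors.append(abs((pred[0].time - truth_hatch.time).total_seconds()))
        assert np.median(errors) <= 12 * 3600.0

    def test_abandonment_displacement_found_at_the_hour(self):
        cfg = simulate.SimConfig(
            seed=300, failure_displacement_km=10.0,
            stages=(
                (StageLabel.PRE_BREEDING, 7.0), (StageLabel.INCUBATION, 10.2),
                (StageLabel.POST_BREEDING, 9.0),
            ),
        )
        out = simulate.simulate_bird(cfg)
        traj = io_tracks.prepare(out.trajectory)
        tl = sc.segment_timeline(traj)
        truth_fail = next(t for t in out.truth_transitions
                          if t.kind is TransitionKind.NEST_FAIL)
        pred = [t for t in tl.transitions if t.kind is TransitionKind.NEST_FAIL]
        assert pred
        assert abs((pred[0].time - truth_fail.time).total_seconds()) <= 6 * 3600.0
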