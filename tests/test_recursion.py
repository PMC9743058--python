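import numpy as np
import pandas as pd
import pytest

from broodtrack import recursion
from .conftest import make_traj
from .oracles import brute_force_visits, resolvable_entry_times


def random_walk_traj(seed: int, n: int = 200, step_mean: float = 30.0,
                     interval_s: float = 60.0):
    rng = np.random.default_rng(seed)
    steps = rng.gamma(2.0, step_mean / 2.0, n - 1)
    ang = np.cumsum(rng.normal(0.0, 0.8, n - 1))
    xy = np.vstack(
        [[0.0, 0.0],
         np.cumsum(steps[:, None] * np.c_[np.cos(ang), np.sin(ang)], axis=0)]
    )
    return make_traj(xy, interval_s=interval_s)


class TestComputeRevisits:
    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            recursion.compute_revisits(random_walk_traj(0), radius=0.0)

    def test_never_exiting_trajectory_is_one_visit(self):
        rng = np.random.default_rng(1)
        xy = rng.normal(0.0, 5.0, (20, 2))  # everything within 20 m of fix 0
        traj = make_traj(xy)
        stats = recursion.compute_revisits(traj, 20.0 + 25.0)
        assert stats.n_visits[0] == 1
        span = traj.times_s[-1] - traj.times_s[0]
        assert stats.residence_s[0] == pytest.approx(span)

    def test_single_fix_has_one_zero_length_visit(self):
        stats = recursion.compute_revisits(make_traj([[0.0, 0.0]]), 20.0)
        assert stats.n_visits[0] == 1
        assert stats.residence_s[0] == 0.0

    def test_square_loop_corner_counts_match_oracle(self):
        """Two laps of a 100 m square at one fix per minute: the engine's
        per-corner visit counts and crossing times match dense resampling."""
        side = np.linspace(0.0, 100.0, 5)[:-1]
        lap = np.vstack([np.c_[side, np.zeros(4)],
                         np.c_[np.full(4, 100.0), side],
                         np.c_[100.0 - side, np.full(4, 100.0)],
                         np.c_[np.zeros(4), 100.0 - side]])
        xy = np.vstack([lap, lap, [[0.0, 0.0]]])
        traj = make_traj(xy, interval_s=60.0)
        stats = recursion.compute_revisits(traj, 20.0, detailed=True)
        counts, entries = brute_force_visits(traj.times_s, xy, 20.0)
        np.testing.assert_array_equal(stats.n_visits, counts)
        # each lap passes each corner once; the closing fix revisits corner 0
        assert stats.n_visits[0] == 3
        for j, ent in enumerate(entries):
            ours = np.sort([v.entry_time for v in stats.visits[j]])
            np.testing.assert_allclose(ours, np.sort(ent), atol=2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_resampling_oracle(self, seed):
        traj = random_walk_traj(seed)
        stats = recursion.compute_revisits(traj, 20.0, detailed=True)
        counts, entries = brute_force_visits(traj.times_s, traj.xy, 20.0)
        ours_all = resolvable_entry_times(stats, traj.times_s, step=1.0)
        for j, ent in enumerate(entries):
            assert len(ours_all[j]) == counts[j]
            np.testing.assert_allclose(ours_all[j], np.sort(ent), atol=2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_residence_monotone_in_radius(self, seed):
        traj = random_walk_traj(seed, n=100)
        prev = None
        for radius in (10.0, 20.0, 40.0, 80.0):
            res = recursion.compute_revisits(traj, radius).residence_s
            if prev is not None:
                assert np.all(res >= prev - 1e-9)
            prev = res

    def test_gap_breaks_visit(self):
        # stationary bird with a 3-h outage: the visit splits in two and
        # no residence is accrued across the gap
        times = np.array([0.0, 60.0, 120.0, 3 * 3600.0, 3 * 3600.0 + 60.0])
        xy = np.zeros((5, 2))
        traj = make_traj(xy, times_s=times, interval_s=60.0)
        stats = recursion.compute_revisits(traj, 20.0)
        assert stats.n_visits[0] == 2
        assert stats.residence_s[0] == pytest.approx(180.0)

    def test_visits_invariants(self):
        stats = recursion.compute_revisits(random_walk_traj(11), 20.0, detailed=True)
        span = stats.traj.times_s[-1] - stats.traj.times_s[0]
        for j, visits in enumerate(stats.visits):
            assert len(visits) == stats.n_visits[j]
            assert stats.n_visits[j] >= 1  # focal fix is inside its own disc
            for v in visits:
                assert v.entry_time <= v.exit_time
            for a, b in zip(visits, visits[1:]):
                assert a.exit_time <= b.entry_time  # disjoint, ordered
            assert sum(v.duration for v in visits) <= span + 1e-6


class TestFrequencyProfile:
    def test_dispersed_fixes_all_single_visits(self):
        xy = np.c_[np.arange(10) * 100.0, np.zeros(10)]  # all > 2R apart
        stats = recursion.compute_revisits(make_traj(xy), 20.0)
        prof = recursion.frequency_profile(stats)
        assert prof.counts == {1: 10}
        assert prof.n_fixes == 10

    def test_stationary_fixes_share_one_focus(self):
        xy = np.zeros((8, 2))
        stats = recursion.compute_revisits(make_traj(xy), 20.0)
        prof = recursion.frequency_profile(stats)
        assert prof.counts == {1: 8}  # never leaves: one visit each

    def test_empty_window_is_empty_profile(self):
        stats = recursion.compute_revisits(random_walk_traj(2), 20.0)
        prof = recursion.frequency_profile(
            stats, (pd.Timestamp("2030-01-01"), pd.Timestamp("2030-01-02"))
        )
        assert prof.counts == {} and prof.n_fixes == 0

    def test_windowed_profile_matches_direct_subtrajectory(self):
        traj = random_walk_traj(3)
        stats = recursion.compute_revisits(traj, 20.0)
        t0 = traj.df["timestamp"].iloc[0]
        window = (t0, t0 + pd.Timedelta(minutes=100))
        prof = recursion.frequency_profile(stats, window)
        sub = traj.window(*window)
        direct = recursion.compute_revisits(sub, 20.0)
        values, freq = np.unique(direct.n_visits, return_counts=True)
        assert prof.counts == {int(v): int(f) for v, f in zip(values, freq)}
        assert sum(prof.counts.values()) == prof.n_fixes == len(sub)
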