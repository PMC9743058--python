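import numpy as np
import pandas as pd
import pytest

from broodtrack import outcomes, summaries
from broodtrack.outcomes import BreedingAttempt, Fate
from broodtrack.stage_labels import StageLabel, StageSegment


def _segs(*plan):
    """plan: (label, days) tuples laid end to end from a fixed origin."""
    t = pd.Timestamp("2019-04-20")
    out = []
    for label, days in plan:
        end = t + pd.Timedelta(days=days)
        out.append(StageSegment(label=label, start=t, end=end))
        t = end
    return out


def _attempt(tag, idx, exposure, fate):
    return BreedingAttempt(tag, idx, None, None, float(exposure), fate)


class TestAssembleAttempts:
    def test_incubation_then_chick_guarding_is_hatched(self):
        segs = _segs((StageLabel.PRE_BREEDING, 5), (StageLabel.INCUBATION, 30),
                     (StageLabel.CHICK_GUARDING, 10), (StageLabel.POST_BREEDING, 5))
        (a,) = outcomes.assemble_attempts(segs, tag_id="339O_OW")
        assert a.fate is Fate.HATCHED
        assert a.exposure_days == pytest.approx(30.0)

    def test_short_incubation_then_postbreeding_failed(self):
        segs = _segs((StageLabel.INCUBATION, 6), (StageLabel.POST_BREEDING, 5))
        (a,) = outcomes.assemble_attempts(segs)
        assert a.fate is Fate.FAILED and a.exposure_days == pytest.approx(6.0)

    def test_incubation_at_tag_end_censored(self):
        segs = _segs((StageLabel.PRE_BREEDING, 3), (StageLabel.INCUBATION, 17))
        (a,) = outcomes.assemble_attempts(segs, tag_id="211O_OW")
        assert a.fate is Fate.CENSORED and a.exposure_days == pytest.approx(17.0)

    def test_renesting_gives_two_attempts(self):
        segs = _segs((StageLabel.INCUBATION, 6), (StageLabel.POST_BREEDING, 5),
                     (StageLabel.INCUBATION, 17), (StageLabel.POST_BREEDING, 4))
        attempts = outcomes.assemble_attempts(segs)
        assert [a.fate for a in attempts] == [Fate.FAILED, Fate.FAILED]
        assert [a.attempt_index for a in attempts] == [1, 2]

    def test_overlapping_incubations_rejected(self):
        t = pd.Timestamp("2019-04-20")
        segs = [
            StageSegment(StageLabel.INCUBATION, t, t + pd.Timedelta(days=10)),
            StageSegment(StageLabel.INCUBATION, t + pd.Timedelta(days=5),
                         t + pd.Timedelta(days=15)),
        ]
        with pytest.raises(outcomes.ConsistencyError):
            outcomes.assemble_attempts(segs)


class TestPopulationSummary:
    def test_study_cohort_proportions(self):
        """The transcribed 23-bird / 25-attempt cohort reproduces the
        published bookkeeping exactly."""
        atts = summaries.attempts_from_table2()
        s = outcomes.population_summary(atts, n_birds=23)
        assert s["n_nonbreeders"] == 6 and s["pct_nonbreeders"] == 26
        assert s["n_breeders"] == 17 and s["pct_breeders"] == 74
        assert s["n_attempts"] == 25
        assert s["n_two_attempt_birds"] == 7 and s["pct_two_attempt_birds"] == 30
        assert s["n_three_attempt_birds"] == 1 and s["pct_three_attempt_birds"] == 4
        assert s["n_incubation_failures"] == 16 and s["pct_incubation_failures"] == 64
        assert s["n_hatched_birds"] == 3
        assert s["pct_hatched_of_breeders"] == 18
        assert s["pct_hatched_of_all"] == 13

    def test_all_nonbreeders(self):
        s = outcomes.population_summary([], n_birds=5)
        assert s["pct_nonbreeders"] == 100 and s["n_attempts"] == 0

    def test_single_hatched_bird(self):
        s = outcomes.population_summary([_attempt("A", 1, 28, Fate.HATCHED)], n_birds=1)
        assert s["pct_breeders"] == 100
        assert s["pct_hatched_of_breeders"] == 100
        assert s["pct_hatched_of_all"] == 100

    def test_zero_birds_rejected(self):
        with pytest.raises(ValueError):
            outcomes.population_summary([], 0)


class TestMayfieldDsr:
    def test_no_failures_is_certain_survival(self):
        atts = [_attempt("A", 1, 100.0, Fate.HATCHED)]
        est = outcomes.mayfield_dsr(atts)
        assert est.dsr == 1.0 and est.ci_high == 1.0

    def test_one_failure_in_two_days(self):
        atts = [_attempt("A", 1, 2.0, Fate.FAILED)]
        est = outcomes.mayfield_dsr(atts)
        assert est.dsr == pytest.approx(0.5)

    def test_study_fixture_exposure_ledger(self):
        """Summing the transcribed nesting intervals gives 294 exposure days
        and 16 failures, hence a closed-form daily survival of 1 - 16/294."""
        atts = summaries.attempts_from_table2()
        est = outcomes.mayfield_dsr(atts)
        assert est.total_exposure == pytest.approx(294.0)
        assert est.n_failures == 16
        assert est.dsr == pytest.approx(1.0 - 16.0 / 294.0)
        assert est.ci_low < est.dsr < est.ci_high

    @pytest.mark.parametrize("f,E", [(1, 10.0), (5, 40.0), (16, 294.0), (0, 50.0)])
    def test_equals_closed_form(self, f, E):
        atts = [_attempt("X", 1, E - f, Fate.HATCHED)] + [
            _attempt(f"F{i}", 1, 1.0, Fate.FAILED) for i in range(f)
        ]
        est = outcomes.mayfield_dsr(atts)
        assert est.dsr == pytest.approx(1.0 - f / E)

    def test_censored_contributes_exposure_only(self):
        atts = [_attempt("A", 1, 10.0, Fate.CENSORED),
                _attempt("B", 1, 10.0, Fate.FAILED)]
        est = outcomes.mayfield_dsr(atts)
        assert est.dsr == pytest.approx(1.0 - 1.0 / 20.0)

    def test_midpoint_mode_reduces_exposure(self):
        atts = [_attempt("A", 1, 10.0, Fate.FAILED)]
        est = outcomes.mayfield_dsr(atts, midpoint=True)
        assert est.total_exposure == pytest.approx(9.5)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            outcomes.mayfield_dsr([])

    def test_parameter_recovery_and_coverage(self):
        """Simulated cohorts (geometric failure days, 28-day cap): the
        estimator is nearly unbiased and the profile CI covers ~95%."""
        rng = np.random.default_rng(2024)
        for p in (0.90, 0.95, 0.99):
            ests, cover = [], 0
            for _ in range(200):
                fail_day = rng.geometric(1 - p, size=200)
                exposure = np.minimum(fail_day, 28)
                failed = fail_day <= 28
                atts = [
                    _attempt(f"b{i}", 1, float(e), Fate.FAILED if fl else Fate.HATCHED)
                    for i, (e, fl) in enumerate(zip(exposure, failed))
                ]
                est = outcomes.mayfield_dsr(atts)
                ests.append(est.dsr)
                cover += est.ci_low <= p <= est.ci_high
            assert abs(np.mean(ests) - p) <= 0.01
            assert 0.90 <= cover / 200 <= 0.99


class TestPeriodSuccess:
    def test_certainty(self):
        assert outcomes.period_success(1.0, 28) == 1.0

    def test_absorbing_zero(self):
        assert outcomes.period_success(0.0, 28) == 0.0

    def test_published_point_estimate_scale(self):
        # a daily rate of 0.935 over a 28-day incubation gives ~15.2%
        assert outcomes.period_success(0.935, 28) == pytest.approx(0.1523, abs=1e-4)

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            outcomes.period_success(1.2)
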