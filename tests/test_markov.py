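"""Transition arithmetic, matrix construction, and cohort iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trastuzumab_cea.markov import (HealthState, Strategy,
                                    annual_event_prob_from_cumulative_survival,
                                    apply_hazard_ratio, build_matrix,
                                    overall_survival, prob_to_rate,
                                    rate_to_prob, recurrence_prob, run_cohort)
from trastuzumab_cea.parameters import LifeTable, ParameterSet

S = HealthState


def hazard_free(params: ParameterSet) -> ParameterSet:
    """Switch off every disease transition (recurrence in all bands,
    metastatic death) so the cohort stays disease-free."""
    for path, value in (("clinical.p_dfs_5y_act", 1.0),
                        ("clinical.recur_rate_y5_9", 0.0),
                        ("clinical.recur_rate_y10_14", 0.0),
                        ("clinical.recur_rate_y15plus", 0.0),
                        ("clinical.metastatic_death_rate", 0.0),
                        ("clinical.local_to_metastatic_annual", 0.0)):
        params = params.with_override(path, value)
    return params


class TestConversions:
    def test_annual_prob_from_cumulative_survival(self):
        assert annual_event_prob_from_cumulative_survival(1.0, 5) == 0.0
        p = annual_event_prob_from_cumulative_survival(0.75, 5)
        assert p == pytest.approx(0.05591, abs=5e-6)
        assert (1 - p) ** 5 == pytest.approx(0.75)
        assert annual_event_prob_from_cumulative_survival(0.25, 1) == 0.75

    def test_zero_survival_rejected(self):
        with pytest.raises(ValueError):
            annual_event_prob_from_cumulative_survival(0.0, 5)

    def test_hazard_ratio_on_hazard_scale(self):
        p = annual_event_prob_from_cumulative_survival(0.75, 5)
        p_h = apply_hazard_ratio(p, 0.64)
        assert p_h == pytest.approx(0.036154, abs=5e-6)
        # 5-year survival consistent with the trial's ~84% trastuzumab DFS
        assert (1 - p_h) ** 5 == pytest.approx(0.75 ** 0.64)
        assert apply_hazard_ratio(0.0, 0.64) == 0.0

    @given(st.floats(0, 0.999), st.floats(0.01, 5))
    @settings(max_examples=100, derandomize=True)
    def test_hazard_ratio_properties(self, p, hr):
        out = apply_hazard_ratio(p, hr)
        assert 0 <= out < 1
        assert apply_hazard_ratio(p, 1.0) == pytest.approx(p)
        if hr < 1:
            assert out <= p + 1e-15

    def test_prob_rate_inverse_pair(self):
        assert rate_to_prob(0.0) == 0.0
        assert rate_to_prob(0.328) == pytest.approx(0.2796, abs=5e-5)
        assert prob_to_rate(rate_to_prob(0.5)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            prob_to_rate(1.0)


class TestRecurrenceSchedule:
    def test_first_five_cycles_trial_derived(self, default_params):
        clin = default_params.clinical
        for c in (1, 3, 5):
            assert recurrence_prob(c, Strategy.ACT, clin) == \
                pytest.approx(0.05591, abs=5e-6)
            assert recurrence_prob(c, Strategy.ACTH, clin) == \
                pytest.approx(0.036154, abs=5e-6)

    @pytest.mark.parametrize("cycle,expected", [
        (6, 0.0489), (9, 0.0489), (10, 0.0354), (12, 0.0354), (14, 0.0354),
        (15, 0.0266), (20, 0.0266),
    ])
    def test_later_cycles_use_pooled_rates_both_arms(self, cycle, expected,
                                                     default_params):
        clin = default_params.clinical
        assert recurrence_prob(cycle, Strategy.ACT, clin) == expected
        # post-benefit hazard ratio defaults to 1: identical in both arms
        assert recurrence_prob(cycle, Strategy.ACTH, clin) == expected

    def test_cycle_out_of_range(self, default_params):
        for cycle in (0, 21):
            with pytest.raises(ValueError):
                recurrence_prob(cycle, Strategy.ACT, default_params.clinical)


class TestBuildMatrix:
    def test_all_hazards_off_freezes_every_durable_state(self, zero_life_table):
        params = hazard_free(ParameterSet())
        m = build_matrix(3, Strategy.ACT, params, zero_life_table)
        np.testing.assert_array_equal(m[S.DFS], [1, 0, 0, 0])
        np.testing.assert_array_equal(m[S.METASTATIC], [0, 0, 1, 0])
        np.testing.assert_array_equal(m[S.DEAD], [0, 0, 0, 1])
        # LOCAL is an episode state: even with all hazards off its occupants
        # return to DFS after one cycle
        np.testing.assert_array_equal(m[S.LOCAL], [1, 0, 0, 0])

    def test_dfs_row_hand_computed(self, flat_life_table):
        # q = 0.01, p_rec = 0.05591, frac local = 0.25:
        # LOCAL = 0.99*0.05591*0.25, MET = 3x that, DFS = remainder
        m = build_matrix(3, Strategy.ACT, ParameterSet(), flat_life_table)
        assert m[S.DFS, S.DEAD] == pytest.approx(0.01)
        assert m[S.DFS, S.LOCAL] == pytest.approx(0.99 * 0.0559125 * 0.25)
        assert m[S.DFS, S.METASTATIC] == pytest.approx(0.99 * 0.0559125 * 0.75)
        assert m[S.DFS, S.DFS] == pytest.approx(0.9346466, abs=1e-6)
        assert m[S.DFS].sum() == pytest.approx(1.0, abs=1e-15)

    def test_structural_zeros_and_absorbing_death(self, flat_life_table):
        m = build_matrix(7, Strategy.ACTH, ParameterSet(), flat_life_table)
        assert m[S.METASTATIC, S.DFS] == 0
        assert m[S.METASTATIC, S.LOCAL] == 0
        assert m[S.LOCAL, S.LOCAL] == 0  # one-cycle episode state
        np.testing.assert_array_equal(m[S.DEAD], [0, 0, 0, 1])

    @given(
        p_dfs=st.floats(0.05, 1.0),
        hr=st.floats(0.05, 1.0),
        frac=st.floats(0, 1),
        l2m=st.floats(0, 1),
        met_death=st.floats(0, 1),
        q=st.floats(0, 0.5),
        cycle=st.integers(1, 20),
    )
    @settings(max_examples=200, derandomize=True)
    def test_rows_stochastic_for_random_valid_parameters(
            self, p_dfs, hr, frac, l2m, met_death, q, cycle):
        params = (ParameterSet()
                  .with_override("clinical.p_dfs_5y_act", p_dfs)
                  .with_override("clinical.hr_dfs", hr)
                  .with_override("clinical.frac_locoregional", frac)
                  .with_override("clinical.local_to_metastatic_annual", l2m)
                  .with_override("clinical.metastatic_death_rate", met_death))
        lt = LifeTable(range(50, 71), [q] * 21)
        for strategy in Strategy:
            m = build_matrix(cycle, strategy, params, lt)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(m >= 0) and np.all(m <= 1)


class TestCohort:
    def test_no_transitions_keeps_initial_distribution(self, zero_life_table):
        trace = run_cohort(Strategy.ACT, hazard_free(ParameterSet()),
                           zero_life_table)
        np.testing.assert_array_equal(trace.occupancy,
                                      np.tile([1.0, 0, 0, 0], (21, 1)))

    def test_occupancy_simplex_and_death_monotone(self, profile):
        params, lt = profile
        for strategy in Strategy:
            trace = run_cohort(strategy, params, lt)
            np.testing.assert_array_equal(trace.occupancy[0], [1, 0, 0, 0])
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                       atol=1e-10)
            assert np.all(trace.occupancy >= 0)
            assert np.all(np.diff(trace.occupancy[:, S.DEAD]) >= -1e-15)

    def test_trastuzumab_arm_keeps_more_patients_disease_free(
            self, default_params, flat_life_table):
        act = run_cohort(Strategy.ACT, default_params, flat_life_table)
        acth = run_cohort(Strategy.ACTH, default_params, flat_life_table)
        assert np.all(acth.occupancy[1:6, S.DFS] >= act.occupancy[1:6, S.DFS])

    def test_equal_arms_when_hazard_ratio_one_and_chf_equalised(
            self, flat_life_table):
        params = (ParameterSet()
                  .with_override("clinical.hr_dfs", 1.0)
                  .with_override("clinical.chf_incidence_acth", 0.007))
        act = run_cohort(Strategy.ACT, params, flat_life_table)
        acth = run_cohort(Strategy.ACTH, params, flat_life_table)
        np.testing.assert_array_equal(act.occupancy, acth.occupancy)
        assert act.chf_fraction == acth.chf_fraction

    def test_chf_fraction_is_strategy_specific(self, default_params,
                                               flat_life_table):
        assert run_cohort(Strategy.ACT, default_params,
                          flat_life_table).chf_fraction == 0.007
        assert run_cohort(Strategy.ACTH, default_params,
                          flat_life_table).chf_fraction == 0.02


class TestOverallSurvival:
    def test_starts_at_one_and_declines(self, profile):
        params, lt = profile
        trace = run_cohort(Strategy.ACT, params, lt)
        assert overall_survival(trace, 0) == 1.0
        os_path = [overall_survival(trace, y) for y in range(21)]
        assert all(a >= b for a, b in zip(os_path, os_path[1:]))
        with pytest.raises(ValueError):
            overall_survival(trace, 21)

    def test_five_year_survival_near_trial_band(self, profile):
        """Calibrated model OS at year 5 should sit around the trial's
        reported 87-93% range for both arms."""
        params, lt = profile
        for strategy in Strategy:
            os5 = overall_survival(run_cohort(strategy, params, lt), 5)
            assert 0.85 <= os5 <= 0.95
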