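"""Cohort engine: transition composition, schedules, accrual and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from varscreen.decision_tree import HealthState, Strategy
from varscreen.markov_engine import (
    STATE_INDEX,
    STATES,
    build_transition_matrix,
    compose_cycle,
    cycle_cost,
    cycle_qaly,
    run_cohort,
)
from varscreen.parameters import deserialize, with_value

S = HealthState


def occupancy(**kwargs):
    v = np.zeros(len(STATES))
    for name, count in kwargs.items():
        v[STATE_INDEX[S[name]]] = count
    return v


ZERO_EVENTS = {
    "p_bleed_missed_hrv": 0,
    "p_bleed_nsbb": 0,
    "p_bleed_ligation": 0,
    "p_death_after_bleed": 0,
    "p_death_other": 0,
}


class TestTransitionMatrix:
    def test_nsbb_row_composition(self, params):
        """Other-cause death first, then bleeding among survivors, then the
        fatal/survived bleed split."""
        m = build_transition_matrix(Strategy.UNIVERSAL, params, 1)
        i = STATE_INDEX[S.HRV_NSBB]
        stay = (1 - 0.034) * (1 - 0.068)
        to_pb = (1 - 0.034) * 0.068 * (1 - 0.022)
        to_db = (1 - 0.034) * 0.068 * 0.022
        assert m[i, i] == pytest.approx(stay)
        assert m[i, STATE_INDEX[S.POST_BLEED]] == pytest.approx(to_pb)
        assert m[i, STATE_INDEX[S.DEAD_BLEED]] == pytest.approx(to_db)
        assert m[i, STATE_INDEX[S.DEAD_OTHER]] == pytest.approx(0.034)
        assert m[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_probabilities_give_identity(self, params):
        p = deserialize(ZERO_EVENTS)
        m = build_transition_matrix(Strategy.UNIVERSAL, p, 1)
        assert np.allclose(m, np.eye(len(STATES)))

    def test_dead_states_absorbing(self, params):
        m = build_transition_matrix(Strategy.SELECTIVE, params, 2)
        for dead in (S.DEAD_BLEED, S.DEAD_OTHER):
            i = STATE_INDEX[dead]
            assert m[i, i] == 1.0
            assert m[i].sum() == 1.0

    def test_post_bleed_cannot_bleed_again(self, params):
        m = build_transition_matrix(Strategy.UNIVERSAL, params, 1)
        i = STATE_INDEX[S.POST_BLEED]
        assert m[i, STATE_INDEX[S.DEAD_BLEED]] == 0.0
        # only other-cause death leaves the post-bleed state
        assert m[i, i] == pytest.approx(1 - 0.034)

    def test_cycle_index_bounds(self, params):
        with pytest.raises(ValueError, match="cycle_index"):
            build_transition_matrix(Strategy.UNIVERSAL, params, 6)

    @given(
        p_do=st.floats(0, 1),
        p_b=st.floats(0, 1),
        p_db=st.floats(0, 1),
    )
    def test_composition_is_a_probability_split(self, p_do, p_b, p_db):
        parts = compose_cycle(p_do, p_b, p_db)
        assert all(0 <= v <= 1 for v in parts.values())
        assert sum(parts.values()) == pytest.approx(1.0, abs=1e-12)

    @given(
        p_do=st.floats(0, 1),
        p_miss=st.floats(0, 1),
        p_nsbb=st.floats(0, 1),
        p_lig=st.floats(0, 1),
        p_db=st.floats(0, 1),
    )
    def test_rows_always_stochastic(self, p_do, p_miss, p_nsbb, p_lig, p_db):
        p = deserialize(
            {
                "p_death_other": p_do,
                "p_bleed_missed_hrv": p_miss,
                "p_bleed_nsbb": p_nsbb,
                "p_bleed_ligation": p_lig,
                "p_death_after_bleed": p_db,
            }
        )
        m = build_transition_matrix(Strategy.SELECTIVE, p, 1)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert m.min() >= 0.0


class TestCycleAccrual:
    def test_qaly_single_state(self, params):
        occ = occupancy(NO_HRV_SURVEILLANCE=1000)
        assert cycle_qaly(params, occ) == pytest.approx(760.0)

    def test_qaly_all_dead_is_zero(self, params):
        occ = occupancy(DEAD_OTHER=600, DEAD_BLEED=400)
        assert cycle_qaly(params, occ) == 0.0

    def test_qaly_linearity(self, params):
        occ = occupancy(HRV_NSBB=100, HRV_LIGATION=50, POST_BLEED=10, HRV_MISSED=5)
        hand = 100 * 0.65 + 50 * 0.67 + 10 * 0.54 + 5 * 0.72
        assert cycle_qaly(params, occ) == pytest.approx(hand)

    def test_ligation_schedule_cycles_1_3_5(self, params):
        occ = occupancy(HRV_LIGATION=100)
        on = 100 * (96.73 + 744.05)
        off = 100 * 96.73
        for t, expected in [(1, on), (2, off), (3, on), (4, off), (5, on)]:
            assert cycle_cost(Strategy.UNIVERSAL, params, t, occ) == pytest.approx(
                expected
            )

    def test_follow_up_endoscopy_biennial_from_cycle_3(self, params):
        occ = occupancy(NO_HRV_ENDO_FOLLOWUP=800)
        for t, expected in [(1, 0.0), (2, 0.0), (3, 800 * 96.73), (4, 0.0), (5, 800 * 96.73)]:
            assert cycle_cost(Strategy.UNIVERSAL, params, t, occ) == pytest.approx(
                expected
            )

    def test_monitoring_cost_every_cycle(self, params):
        occ = occupancy(NO_HRV_SURVEILLANCE=200, HRV_MISSED=6)
        for t in range(1, 6):
            assert cycle_cost(Strategy.SELECTIVE, params, t, occ) == pytest.approx(
                206 * (18.60 + 2.68)
            )

    def test_dead_cohort_costs_nothing(self, params):
        occ = occupancy(DEAD_OTHER=1000)
        assert cycle_cost(Strategy.UNIVERSAL, params, 3, occ) == 0.0

    def test_bleed_event_cost(self, params):
        occ = occupancy(HRV_NSBB=100)
        base = cycle_cost(Strategy.UNIVERSAL, params, 2, occ)
        with_bleeds = cycle_cost(Strategy.UNIVERSAL, params, 2, occ, bleeds=3.0)
        assert with_bleeds - base == pytest.approx(3.0 * 1934.52)

    def test_negative_occupancy_rejected(self, params):
        occ = occupancy(HRV_NSBB=-1)
        with pytest.raises(ValueError, match="negative"):
            cycle_cost(Strategy.UNIVERSAL, params, 1, occ)


class TestRunCohort:
    def test_mass_conserved_every_cycle(self, params):
        for strat in Strategy:
            tr = run_cohort(strat, params)
            assert np.allclose(tr.occupancy.sum(axis=1), 1000.0, atol=1e-9)

    def test_one_bleed_maximum(self, params):
        tr = run_cohort(Strategy.SELECTIVE, params)
        assert tr.tally.bleeds <= 1000.0
        assert tr.tally.deaths_bleed <= tr.tally.bleeds

    def test_zero_probability_annuity_limit(self):
        """With no events and a single 0.76-utility state, discounted QALYs
        equal the closed-form annuity 0.76 x sum_t 1.035^-t."""
        p = deserialize(
            {
                **ZERO_EVENTS,
                "prevalence_hrv": 0.0,
                "endoscopy": 0,
                "blood_routine": 0,
                "elastography": 0,
                "nsbb_annual": 0,
                "band_ligation": 0,
                "bleed_hospitalization": 0,
            }
        )
        tr = run_cohort(Strategy.UNIVERSAL, p)
        annuity = sum(1.035 ** -t for t in range(1, 6))
        assert tr.per_capita_qaly == pytest.approx(0.76 * annuity, abs=1e-12)
        assert tr.per_capita_cost == 0.0

    def test_discount_rate_monotonicity(self, params):
        rates = [0.0, 0.02, 0.035, 0.06, 0.10]
        costs, qalys = [], []
        for r in rates:
            tr = run_cohort(Strategy.UNIVERSAL, with_value(params, "econ.discount_rate", r))
            costs.append(tr.per_capita_cost)
            qalys.append(tr.per_capita_qaly)
        assert all(a >= b for a, b in zip(costs, costs[1:]))
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))

    def test_missed_detection_flag_moves_patients_into_treatment(self, params):
        p = deserialize({"detect_missed_hrv": True})
        tr = run_cohort(Strategy.SELECTIVE, p)
        base = run_cohort(Strategy.SELECTIVE, params)
        i = STATE_INDEX[S.HRV_MISSED]
        assert tr.occupancy[2, i] == pytest.approx(0.0, abs=1e-9)
        assert base.occupancy[2, i] > 4.0  # untreated patients persist by default

    def test_trace_frame_shape(self, params):
        frame = run_cohort(Strategy.UNIVERSAL, params).to_frame()
        assert set(frame["cycle"]) == {0, 1, 2, 3, 4, 5}
        assert len(frame) == 6 * len(STATES)
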