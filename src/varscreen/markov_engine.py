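"""Deterministic Markov cohort engine.

Runs the expected-value state-transition simulation over annual cycles,
accumulating discounted costs, discounted QALYs and event counts.

Within-cycle event composition (shared verbatim with the individual-level
microsimulation in :mod:`varscreen.synthetic_cohort`):

1. other-cause death strikes first with probability ``p_death_other``;
2. survivors in a bleed-risk state bleed with the state's annual probability;
3. a bleed is fatal with probability ``p_death_after_bleed``, otherwise the
   patient moves to the post-bleed state (absorbing for bleeding: at most one
   bleed per patient);
4. everyone else stays in state.

Discounting is end-of-cycle: cycle ``t`` costs and QALYs (t = 1..horizon) are
multiplied by ``(1 + r)^-t``; no half-cycle correction.  Accrual uses the
post-transition occupancy of each cycle, so deaths during a cycle accrue
nothing for it.  The decision-tree screening costs are charged at cycle 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision_tree import (
    ALIVE_STATES,
    DEAD_STATES,
    HealthState,
    InitialDistribution,
    Strategy,
    allocate_cohort,
)
from .parameters import ModelParameters

__all__ = [
    "STATES",
    "STATE_INDEX",
    "EventTally",
    "StateTrace",
    "compose_cycle",
    "bleed_probability",
    "state_utility",
    "state_cycle_cost",
    "build_transition_matrix",
    "cycle_cost",
    "cycle_qaly",
    "run_cohort",
]

STATES: tuple[HealthState, ...] = tuple(HealthState)
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}
_N = len(STATES)

#: states whose occupants are on NSBB therapy (annual drug cost)
_NSBB_STATES = (
    HealthState.HRV_NSBB,
    HealthState.NSBB_NO_HRV_CSPH,
    HealthState.NSBB_NO_CSPH,
)
#: states under annual non-invasive monitoring (elastography + platelets)
_MONITORED_STATES = (HealthState.NO_HRV_SURVEILLANCE, HealthState.HRV_MISSED)


def compose_cycle(
    p_death_other: float, p_bleed: float, p_death_after_bleed: float
) -> dict[str, float]:
    """One-cycle competing-risk composition for a single alive state.

    Returns the probability mass sent to ``dead_other``, ``dead_bleed``,
    ``post_bleed`` and ``stay``; the four always sum to 1.  This function is
    the single definition of the within-cycle event ordering; the cohort
    matrix and the microsimulation both call it.
    """
    dead_other = p_death_other
    survive = 1.0 - p_death_other
    bleed = survive * p_bleed
    return {
        "dead_other": dead_other,
        "dead_bleed": bleed * p_death_after_bleed,
        "post_bleed": bleed * (1.0 - p_death_after_bleed),
        "stay": survive - bleed,
    }


def bleed_probability(state: HealthState, params: ModelParameters) -> float:
    """Annual variceal-bleed probability while occupying ``state``."""
    tr = params.transitions
    if state is HealthState.HRV_MISSED:
        return tr.p_bleed_missed_hrv
    if state is HealthState.HRV_NSBB:
        return tr.p_bleed_nsbb
    if state is HealthState.HRV_LIGATION:
        return tr.p_bleed_ligation
    if state in (
        HealthState.NO_HRV_SURVEILLANCE,
        HealthState.NO_HRV_ENDO_FOLLOWUP,
        HealthState.NSBB_NO_HRV_CSPH,
        HealthState.NSBB_NO_CSPH,
    ):
        return tr.p_bleed_background
    return 0.0  # post-bleed (one-bleed maximum) and dead states


def state_utility(state: HealthState, params: ModelParameters) -> float:
    """Annual utility weight of ``state`` (0 for dead states)."""
    u = params.utilities
    return {
        HealthState.NO_HRV_SURVEILLANCE: u.u_no_hrv,
        HealthState.NO_HRV_ENDO_FOLLOWUP: u.u_no_hrv,
        HealthState.HRV_NSBB: u.u_nsbb,
        HealthState.HRV_LIGATION: u.u_ligation,
        HealthState.HRV_MISSED: u.u_hrv_untreated,
        HealthState.NSBB_NO_HRV_CSPH: u.u_nsbb,
        HealthState.NSBB_NO_CSPH: params.scenario.u_nsbb_no_csph,
        HealthState.POST_BLEED: u.u_post_bleed,
        HealthState.DEAD_BLEED: 0.0,
        HealthState.DEAD_OTHER: 0.0,
    }[state]


def _on_biennial_schedule(cycle_index: int, first_cycle: int) -> bool:
    """True when ``cycle_index`` falls on a biennial schedule anchored at
    ``first_cycle`` (e.g. anchor 1 -> cycles 1, 3, 5...)."""
    return cycle_index >= first_cycle and (cycle_index - first_cycle) % 2 == 0


def state_cycle_cost(
    state: HealthState, params: ModelParameters, cycle_index: int
) -> float:
    """Per-person scheduled cost of occupying ``state`` during one cycle.

    Schedules: NSBB states pay the annual drug cost every cycle; the ligation
    state pays an annual endoscopy plus the ligation procedure biennially from
    initiation (cycles 1, 3, 5); endoscopy-negative follow-up repeats
    endoscopy every two years after the initial cycle-1 exam (cycles 3, 5);
    monitored states pay elastography + platelet count every cycle.  The bleed
    hospitalisation fee is an event cost handled by :func:`cycle_cost`; dead
    states cost nothing.
    """
    c = params.costs
    if state in _NSBB_STATES:
        return c.nsbb_annual
    if state is HealthState.HRV_LIGATION:
        cost = c.endoscopy
        if _on_biennial_schedule(cycle_index, 1):
            cost += c.band_ligation
        return cost
    if state is HealthState.NO_HRV_ENDO_FOLLOWUP:
        return c.endoscopy if _on_biennial_schedule(cycle_index, 3) else 0.0
    if state in _MONITORED_STATES:
        return c.elastography + c.blood_routine
    return 0.0


def build_transition_matrix(
    strategy: Strategy, params: ModelParameters, cycle_index: int
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix over the full state space.

    Raises an internal consistency error if any row fails to sum to 1 within
    1e-12.
    """
    horizon = params.econ.horizon_cycles
    if not 1 <= cycle_index <= horizon:
        raise ValueError(f"cycle_index {cycle_index} outside 1..{horizon}")
    tr = params.transitions
    m = np.zeros((_N, _N))
    i_pb = STATE_INDEX[HealthState.POST_BLEED]
    i_db = STATE_INDEX[HealthState.DEAD_BLEED]
    i_do = STATE_INDEX[HealthState.DEAD_OTHER]
    for state in ALIVE_STATES:
        i = STATE_INDEX[state]
        parts = compose_cycle(
            tr.p_death_other, bleed_probability(state, params), tr.p_death_after_bleed
        )
        m[i, i_do] += parts["dead_other"]
        m[i, i_db] += parts["dead_bleed"]
        m[i, i_pb] += parts["post_bleed"]
        if state is HealthState.HRV_MISSED and params.detect_missed_hrv:
            # optional exploration flag: missed HRV detected at the next cycle
            m[i, STATE_INDEX[HealthState.HRV_NSBB]] += (
                parts["stay"] * tr.p_nsbb_treatment
            )
            m[i, STATE_INDEX[HealthState.HRV_LIGATION]] += parts["stay"] * (
                1.0 - tr.p_nsbb_treatment
            )
        else:
            m[i, i] += parts["stay"]
    for state in DEAD_STATES:
        i = STATE_INDEX[state]
        m[i, i] = 1.0
    rows = m.sum(axis=1)
    if not np.allclose(rows, 1.0, rtol=0.0, atol=1e-12):
        raise AssertionError(f"transition rows do not sum to 1: {rows}")
    return m


def cycle_cost(
    strategy: Strategy,
    params: ModelParameters,
    cycle_index: int,
    occupancy: np.ndarray | dict[HealthState, float],
    bleeds: float = 0.0,
) -> float:
    """Total cohort cost accrued in one cycle from scheduled care plus the
    hospitalisation cost of the cycle's expected bleed events."""
    occ = _as_vector(occupancy)
    if np.any(occ < -1e-9):
        raise ValueError("negative occupancy")
    total = sum(
        occ[STATE_INDEX[s]] * state_cycle_cost(s, params, cycle_index)
        for s in ALIVE_STATES
    )
    return total + bleeds * params.costs.bleed_hospitalization


def cycle_qaly(
    params: ModelParameters, occupancy: np.ndarray | dict[HealthState, float]
) -> float:
    """Cohort QALYs accrued in one cycle (undiscounted)."""
    occ = _as_vector(occupancy)
    if np.any(occ < -1e-9):
        raise ValueError("negative occupancy")
    dt = params.econ.cycle_length_years
    return dt * sum(
        occ[STATE_INDEX[s]] * state_utility(s, params) for s in ALIVE_STATES
    )


def _as_vector(occupancy: np.ndarray | dict[HealthState, float]) -> np.ndarray:
    if isinstance(occupancy, dict):
        v = np.zeros(_N)
        for s, x in occupancy.items():
            v[STATE_INDEX[HealthState(s)]] = x
        return v
    return np.asarray(occupancy, dtype=float)


@dataclass
class EventTally:
    """Expected event counts over the horizon."""

    bleeds: float = 0.0
    deaths_bleed: float = 0.0
    deaths_other: float = 0.0
    endoscopies: float = 0.0
    ligations: float = 0.0
    nsbb_person_years: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class StateTrace:
    """Full cohort trace of one strategy arm."""

    strategy: Strategy
    occupancy: np.ndarray  # (horizon + 1, n_states); row 0 = initial
    cycle_costs: np.ndarray  # undiscounted, cycle 1..horizon
    cycle_qalys: np.ndarray
    discount_factors: np.ndarray
    discounted_cost: float
    discounted_qaly: float
    tally: EventTally
    initial: InitialDistribution

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    @property
    def per_capita_cost(self) -> float:
        return self.discounted_cost / self.cohort_size

    @property
    def per_capita_qaly(self) -> float:
        return self.discounted_qaly / self.cohort_size

    def to_frame(self) -> pd.DataFrame:
        """Long-format trace: one row per (cycle, state)."""
        rows = []
        for t in range(self.occupancy.shape[0]):
            for s in STATES:
                rows.append(
                    {
                        "cycle": t,
                        "state": s.value,
                        "occupancy": self.occupancy[t, STATE_INDEX[s]],
                        "cycle_cost": self.cycle_costs[t - 1] if t >= 1 else 0.0,
                        "cycle_qaly": self.cycle_qalys[t - 1] if t >= 1 else 0.0,
                        "discount_factor": (
                            self.discount_factors[t - 1] if t >= 1 else 1.0
                        ),
                    }
                )
        return pd.DataFrame(rows)


def run_cohort(strategy: Strategy, params: ModelParameters) -> StateTrace:
    """Run the deterministic cohort simulation for one strategy arm.

    Starts from the decision-tree allocation, applies the cycle transition
    matrix for each cycle, then accrues that cycle's costs (decision-tree test
    costs at cycle 1) and QALYs with end-of-cycle discounting.
    """
    strategy = Strategy(strategy)
    init = allocate_cohort(strategy, params)
    horizon = params.econ.horizon_cycles
    r = params.econ.discount_rate
    tr = params.transitions
    n = float(params.econ.cohort_size)

    occ = _as_vector(init.occupancy)
    trace = np.zeros((horizon + 1, _N))
    trace[0] = occ
    costs = np.zeros(horizon)
    qalys = np.zeros(horizon)
    dfs = np.zeros(horizon)
    tally = EventTally(endoscopies=init.endoscopies)
    disc_cost = 0.0
    disc_qaly = 0.0

    for t in range(1, horizon + 1):
        m = build_transition_matrix(strategy, params, t)
        prev = occ
        bleeds_t = sum(
            prev[STATE_INDEX[s]]
            * (1.0 - tr.p_death_other)
            * bleed_probability(s, params)
            for s in ALIVE_STATES
        )
        occ = prev @ m
        if abs(occ.sum() - n) > 1e-9:
            raise AssertionError(f"cohort mass not conserved at cycle {t}")
        trace[t] = occ

        cost_t = cycle_cost(strategy, params, t, occ, bleeds_t)
        if t == 1:
            cost_t += init.first_cycle_cost
        qaly_t = cycle_qaly(params, occ)
        d = (1.0 + r) ** (-t)
        costs[t - 1], qalys[t - 1], dfs[t - 1] = cost_t, qaly_t, d
        disc_cost += d * cost_t
        disc_qaly += d * qaly_t

        tally.bleeds += bleeds_t
        tally.deaths_bleed += bleeds_t * tr.p_death_after_bleed
        tally.deaths_other += sum(
            prev[STATE_INDEX[s]] * tr.p_death_other for s in ALIVE_STATES
        )
        i_lig = STATE_INDEX[HealthState.HRV_LIGATION]
        i_fu = STATE_INDEX[HealthState.NO_HRV_ENDO_FOLLOWUP]
        tally.endoscopies += occ[i_lig]
        if _on_biennial_schedule(t, 3):
            tally.endoscopies += occ[i_fu]
        if _on_biennial_schedule(t, 1):
            tally.ligations += occ[i_lig]
        tally.nsbb_person_years += sum(occ[STATE_INDEX[s]] for s in _NSBB_STATES)

    return StateTrace(
        strategy=strategy,
        occupancy=trace,
        cycle_costs=costs,
        cycle_qalys=qalys,
        discount_factors=dfs,
        discounted_cost=disc_cost,
        discounted_qaly=disc_qaly,
        tally=tally,
        initial=init,
    )
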