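"""Individual-level microsimulation: the stochastic oracle for the cohort engine.

Simulates synthetic patient trajectories by drawing every screening and
disease event as a Bernoulli trial at exactly the model probabilities, using
the same within-cycle composition rule, cost schedules, utilities and
discounting as the deterministic engine.  By construction the per-capita
expectations of the two modules coincide, so microsimulation means at large
``n`` validate the cohort arithmetic (and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decision_tree import HealthState, Strategy
from .markov_engine import (
    STATE_INDEX,
    STATES,
    state_cycle_cost,
    state_utility,
    bleed_probability,
)
from .parameters import ModelParameters, derive_classification

__all__ = ["CohortSample", "simulate_patients", "export_fixture", "read_fixture"]

FIXTURE_COLUMNS = [
    "patient_id",
    "cycle",
    "state",
    "bleed_flag",
    "death_flag",
    "cost",
    "utility",
    "discount_factor",
]

_I = STATE_INDEX
_DEAD_CODES = (_I[HealthState.DEAD_BLEED], _I[HealthState.DEAD_OTHER])


@dataclass
class CohortSample:
    """A simulated patient sample with per-patient totals and aggregates."""

    strategy: Strategy
    seed: int
    per_patient: pd.DataFrame
    trajectories: pd.DataFrame | None
    summary: dict[str, float]


def _allocate_patients(
    strategy: Strategy, params: ModelParameters, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Individual allocation: returns (state_code, true_hrv, spared_endoscopy,
    tree_cost) arrays of length ``n``."""
    acc = params.accuracy
    tr = params.transitions
    c = params.costs
    state = np.empty(n, dtype=np.int64)
    tree_cost = np.zeros(n)

    if strategy in (Strategy.UNIVERSAL, Strategy.SELECTIVE):
        true_hrv = rng.random(n) < acc.prevalence_hrv
        u_meet = rng.random(n)
        # P(criteria met): 1 - sensitivity for HRV, specificity otherwise
        meets = np.where(
            true_hrv, u_meet < 1.0 - acc.sensitivity, u_meet < acc.specificity
        )
        u_split = rng.random(n)
        nsbb = u_split < tr.p_nsbb_treatment
        if strategy is Strategy.UNIVERSAL:
            spared = np.zeros(n, dtype=bool)
            state[:] = _I[HealthState.NO_HRV_ENDO_FOLLOWUP]
            state[true_hrv & nsbb] = _I[HealthState.HRV_NSBB]
            state[true_hrv & ~nsbb] = _I[HealthState.HRV_LIGATION]
            tree_cost[:] = c.endoscopy
        else:
            spared = meets
            state[:] = _I[HealthState.NO_HRV_ENDO_FOLLOWUP]
            state[~true_hrv & meets] = _I[HealthState.NO_HRV_SURVEILLANCE]
            state[true_hrv & meets] = _I[HealthState.HRV_MISSED]
            scoped_hrv = true_hrv & ~meets
            state[scoped_hrv & nsbb] = _I[HealthState.HRV_NSBB]
            state[scoped_hrv & ~nsbb] = _I[HealthState.HRV_LIGATION]
            tree_cost[:] = c.elastography + c.blood_routine
            tree_cost[~meets] += c.endoscopy
        return state, true_hrv, spared, tree_cost

    if strategy is Strategy.BAVENO7:
        params.validate_scenario_stratification()
        sc = params.scenario
        hi = rng.random(n) < sc.p_lsm_ge_25
        u_cat = rng.random(n)
        u_split = rng.random(n) < tr.p_nsbb_treatment
        true_hrv = np.zeros(n, dtype=bool)
        # high-stiffness stratum: HRV / misclassified / CSPH-without-HRV
        hrv_hi = hi & (u_cat < sc.prev_hrv_in_csph)
        mis = hi & ~hrv_hi & (u_cat < sc.prev_hrv_in_csph + sc.p_misclassified_nsbb)
        state[:] = _I[HealthState.NSBB_NO_HRV_CSPH]
        state[hrv_hi] = _I[HealthState.HRV_NSBB]
        state[mis] = _I[HealthState.NSBB_NO_CSPH]
        true_hrv |= hrv_hi
        # low-stiffness stratum: endoscopic screening
        prev_lo = params.prev_hrv_below_25
        lo = ~hi
        hrv_lo = lo & (u_cat < prev_lo)
        state[lo] = _I[HealthState.NO_HRV_ENDO_FOLLOWUP]
        state[hrv_lo & u_split] = _I[HealthState.HRV_NSBB]
        state[hrv_lo & ~u_split] = _I[HealthState.HRV_LIGATION]
        true_hrv |= hrv_lo
        tree_cost[:] = c.elastography
        tree_cost[lo] += c.endoscopy
        return state, true_hrv, hi, tree_cost

    raise ValueError(f"unknown strategy: {strategy!r}")  # pragma: no cover


def simulate_patients(
    strategy: Strategy,
    params: ModelParameters,
    n_patients: int,
    seed: int = 0,
    keep_trajectories: bool = True,
) -> CohortSample:
    """Simulate ``n_patients`` individual trajectories under one strategy.

    Each patient's HRV status, triage result, prophylaxis assignment and
    per-cycle death/bleed events are independent Bernoulli draws at the model
    probabilities.  Costs, utilities and discounting mirror the cohort engine
    cycle for cycle.  Set ``keep_trajectories=False`` for large ``n`` to skip
    materialising the long-format trajectory table.
    """
    strategy = Strategy(strategy)
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    horizon = params.econ.horizon_cycles
    r = params.econ.discount_rate
    tr = params.transitions

    state, true_hrv, spared, tree_cost = _allocate_patients(
        strategy, params, n_patients, rng
    )
    initial_state = state.copy()

    # per-state lookup tables
    utility = np.array([state_utility(s, params) for s in STATES])
    bleed_p = np.array([bleed_probability(s, params) for s in STATES])
    cost_by_cycle = np.array(
        [
            [state_cycle_cost(s, params, t) for s in STATES]
            for t in range(1, horizon + 1)
        ]
    )

    disc_cost = np.zeros(n_patients)
    disc_qaly = np.zeros(n_patients)
    ever_bled = np.zeros(n_patients, dtype=bool)
    bleed_count = np.zeros(n_patients, dtype=np.int64)
    traj: list[pd.DataFrame] | None = [] if keep_trajectories else None

    i_pb = _I[HealthState.POST_BLEED]
    i_db = _I[HealthState.DEAD_BLEED]
    i_do = _I[HealthState.DEAD_OTHER]

    for t in range(1, horizon + 1):
        d = (1.0 + r) ** (-t)
        u_death = rng.random(n_patients)
        u_bleed = rng.random(n_patients)
        u_fatal = rng.random(n_patients)
        u_split = rng.random(n_patients)

        alive = ~np.isin(state, _DEAD_CODES)
        dies_other = alive & (u_death < tr.p_death_other)
        at_risk = alive & ~dies_other
        bleeds = at_risk & (u_bleed < bleed_p[state])
        fatal = bleeds & (u_fatal < tr.p_death_after_bleed)

        new_state = state.copy()
        new_state[dies_other] = i_do
        new_state[bleeds & ~fatal] = i_pb
        new_state[fatal] = i_db
        if params.detect_missed_hrv:
            stayed_missed = (
                at_risk & ~bleeds & (state == _I[HealthState.HRV_MISSED])
            )
            to_nsbb = stayed_missed & (u_split < tr.p_nsbb_treatment)
            new_state[to_nsbb] = _I[HealthState.HRV_NSBB]
            new_state[stayed_missed & ~to_nsbb] = _I[HealthState.HRV_LIGATION]
        state = new_state

        cost_t = cost_by_cycle[t - 1][state]
        cost_t = np.where(np.isin(state, _DEAD_CODES), 0.0, cost_t)
        cost_t = cost_t + bleeds * params.costs.bleed_hospitalization
        if t == 1:
            cost_t = cost_t + tree_cost
        qaly_t = utility[state] * params.econ.cycle_length_years

        disc_cost += d * cost_t
        disc_qaly += d * qaly_t
        ever_bled |= bleeds
        bleed_count += bleeds

        if traj is not None:
            traj.append(
                pd.DataFrame(
                    {
                        "patient_id": np.arange(n_patients),
                        "cycle": t,
                        "state": [STATES[i].value for i in state],
                        "bleed_flag": bleeds.astype(int),
                        "death_flag": (dies_other | fatal).astype(int),
                        "cost": cost_t,
                        "utility": qaly_t,
                        "discount_factor": d,
                    }
                )
            )

    per_patient = pd.DataFrame(
        {
            "patient_id": np.arange(n_patients),
            "true_hrv": true_hrv.astype(int),
            "meets_baveno": spared.astype(int),
            "initial_state": [STATES[i].value for i in initial_state],
            "total_discounted_cost": disc_cost,
            "total_discounted_qaly": disc_qaly,
            "bled": ever_bled.astype(int),
        }
    )
    n = float(n_patients)
    summary = {
        "n_patients": n_patients,
        "mean_cost": float(disc_cost.mean()),
        "se_cost": float(disc_cost.std(ddof=1) / np.sqrt(n)) if n_patients > 1 else 0.0,
        "mean_qaly": float(disc_qaly.mean()),
        "se_qaly": float(disc_qaly.std(ddof=1) / np.sqrt(n)) if n_patients > 1 else 0.0,
        "bleeds": int(ever_bled.sum()),
        "bleed_rate": float(ever_bled.mean()),
        "deaths": int(np.isin(state, _DEAD_CODES).sum()),
        "missed_hrv": int((initial_state == _I[HealthState.HRV_MISSED]).sum()),
    }
    trajectories = (
        pd.concat(traj, ignore_index=True)[FIXTURE_COLUMNS] if traj is not None else None
    )
    return CohortSample(
        strategy=strategy,
        seed=seed,
        per_patient=per_patient,
        trajectories=trajectories,
        summary=summary,
    )


def export_fixture(trajectories: pd.DataFrame, path: str | Path) -> Path:
    """Write a trajectory table to the documented CSV schema (lossless)."""
    path = Path(path)
    frame = (
        trajectories[FIXTURE_COLUMNS]
        if len(trajectories)
        else pd.DataFrame(columns=FIXTURE_COLUMNS)
    )
    frame.to_csv(path, index=False)
    return path


def read_fixture(path: str | Path) -> pd.DataFrame:
    """Read a trajectory fixture written by :func:`export_fixture`."""
    frame = pd.read_csv(path)
    missing = set(FIXTURE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"fixture missing column(s): {sorted(missing)}")
    return frame[FIXTURE_COLUMNS]
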