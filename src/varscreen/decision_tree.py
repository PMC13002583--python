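"""First-cycle decision tree: strategy arms, health states, cohort allocation.

The decision tree resolves within the first model cycle.  It performs the
screening tests of each strategy, counts their costs, and distributes the
cohort over the initial Markov health states:

* **universal** — every patient undergoes endoscopy; confirmed HRV patients
  start prophylaxis (NSBB or band ligation), the rest enter a biennial
  endoscopic follow-up programme.
* **selective** — every patient receives elastography plus a platelet count;
  those meeting the Baveno low-risk criteria enter annual non-invasive
  surveillance (false negatives remain untreated with HRV), the rest undergo
  endoscopy as in the universal arm.
* **baveno7_scenario** — patients with liver stiffness >= 25 kPa start NSBBs
  without endoscopy; only the < 25 kPa stratum is screened endoscopically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .parameters import ModelParameters, derive_classification

__all__ = [
    "Strategy",
    "HealthState",
    "ALIVE_STATES",
    "DEAD_STATES",
    "BASE_STATES",
    "InitialDistribution",
    "allocate_cohort",
    "first_cycle_costs",
]


class Strategy(str, enum.Enum):
    UNIVERSAL = "universal"
    SELECTIVE = "selective"
    BAVENO7 = "baveno7_scenario"


class HealthState(str, enum.Enum):
    #: criteria met, truly no HRV; annual non-invasive monitoring (selective arm)
    NO_HRV_SURVEILLANCE = "NO_HRV_SURVEILLANCE"
    #: endoscopy-negative; repeat endoscopy every two years
    NO_HRV_ENDO_FOLLOWUP = "NO_HRV_ENDO_FOLLOWUP"
    #: HRV on NSBB prophylaxis
    HRV_NSBB = "HRV_NSBB"
    #: HRV on band ligation (biennial procedure, annual endoscopy)
    HRV_LIGATION = "HRV_LIGATION"
    #: criteria met but HRV present; untreated (false negative)
    HRV_MISSED = "HRV_MISSED"
    #: scenario arm: LSM >= 25, true CSPH without HRV, on NSBBs
    NSBB_NO_HRV_CSPH = "NSBB_NO_HRV_CSPH"
    #: scenario arm: LSM >= 25 misclassified (no CSPH), on NSBBs
    NSBB_NO_CSPH = "NSBB_NO_CSPH"
    #: survived a variceal bleed (at most one bleed per patient)
    POST_BLEED = "POST_BLEED"
    DEAD_BLEED = "DEAD_BLEED"
    DEAD_OTHER = "DEAD_OTHER"


DEAD_STATES = (HealthState.DEAD_BLEED, HealthState.DEAD_OTHER)
ALIVE_STATES = tuple(s for s in HealthState if s not in DEAD_STATES)
#: the state space of the two base-case arms (scenario states unoccupied)
BASE_STATES = tuple(
    s
    for s in HealthState
    if s not in (HealthState.NSBB_NO_HRV_CSPH, HealthState.NSBB_NO_CSPH)
)


@dataclass
class InitialDistribution:
    """Expected occupancy and first-cycle screening costs of one arm."""

    strategy: Strategy
    occupancy: dict[HealthState, float]
    first_cycle_cost: float
    #: screening procedures performed in the first cycle
    endoscopies: float = 0.0
    noninvasive_panels: float = 0.0
    elastography_only: float = 0.0

    @property
    def total(self) -> float:
        return sum(self.occupancy.values())

    def fraction(self, state: HealthState) -> float:
        return self.occupancy.get(state, 0.0) / self.total


def _empty_occupancy() -> dict[HealthState, float]:
    return {s: 0.0 for s in HealthState}


def allocate_cohort(strategy: Strategy, params: ModelParameters) -> InitialDistribution:
    """Distribute the cohort over initial health states and count test costs.

    Occupancy is expected (fractional) patient counts; it always sums to the
    cohort size, and no patient starts post-bleed or dead.
    """
    strategy = Strategy(strategy)
    n = float(params.econ.cohort_size)
    prev = params.accuracy.prevalence_hrv
    p_nsbb = params.transitions.p_nsbb_treatment
    c = params.costs
    occ = _empty_occupancy()

    if strategy is Strategy.UNIVERSAL:
        hrv = n * prev
        occ[HealthState.HRV_NSBB] = hrv * p_nsbb
        occ[HealthState.HRV_LIGATION] = hrv * (1.0 - p_nsbb)
        occ[HealthState.NO_HRV_ENDO_FOLLOWUP] = n - hrv
        return InitialDistribution(
            strategy, occ, first_cycle_cost=n * c.endoscopy, endoscopies=n
        )

    if strategy is Strategy.SELECTIVE:
        cls = derive_classification(params.accuracy)
        meet = n * cls.p_meet
        occ[HealthState.HRV_MISSED] = meet * (1.0 - cls.npv)
        occ[HealthState.NO_HRV_SURVEILLANCE] = meet * cls.npv
        scoped = n - meet  # proceed to endoscopy
        hrv = scoped * cls.ppv
        occ[HealthState.HRV_NSBB] = hrv * p_nsbb
        occ[HealthState.HRV_LIGATION] = hrv * (1.0 - p_nsbb)
        occ[HealthState.NO_HRV_ENDO_FOLLOWUP] = scoped - hrv
        cost = n * (c.elastography + c.blood_routine) + scoped * c.endoscopy
        return InitialDistribution(
            strategy,
            occ,
            first_cycle_cost=cost,
            endoscopies=scoped,
            noninvasive_panels=n,
        )

    if strategy is Strategy.BAVENO7:
        params.validate_scenario_stratification()
        sc = params.scenario
        n_hi = n * sc.p_lsm_ge_25
        n_lo = n - n_hi
        # LSM >= 25 stratum: all start NSBBs, no endoscopy
        hrv_hi = n_hi * sc.prev_hrv_in_csph
        mis = n_hi * sc.p_misclassified_nsbb
        occ[HealthState.HRV_NSBB] = hrv_hi
        occ[HealthState.NSBB_NO_CSPH] = mis
        occ[HealthState.NSBB_NO_HRV_CSPH] = n_hi - hrv_hi - mis
        # LSM < 25 stratum: endoscopic screening as in the universal arm
        hrv_lo = n_lo * params.prev_hrv_below_25
        occ[HealthState.HRV_NSBB] += hrv_lo * p_nsbb
        occ[HealthState.HRV_LIGATION] = hrv_lo * (1.0 - p_nsbb)
        occ[HealthState.NO_HRV_ENDO_FOLLOWUP] = n_lo - hrv_lo
        cost = n * c.elastography + n_lo * c.endoscopy
        return InitialDistribution(
            strategy,
            occ,
            first_cycle_cost=cost,
            endoscopies=n_lo,
            elastography_only=n,
        )

    raise ValueError(f"unknown strategy: {strategy!r}")  # pragma: no cover


def first_cycle_costs(strategy: Strategy, params: ModelParameters) -> float:
    """Total screening-test cost of the decision tree (charged in cycle 1).

    Treatment-initiation costs (first-year NSBB, first ligation) are charged
    by the Markov engine at cycle 1, not here.
    """
    return allocate_cohort(strategy, params).first_cycle_cost
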