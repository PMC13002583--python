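"""LSM >= 25 kPa scenario: NSBB initiation without endoscopy.

Patients whose liver stiffness rules in clinically significant portal
hypertension (CSPH, LSM >= 25 kPa) start NSBB prophylaxis directly; only the
"grey zone" below 25 kPa undergoes endoscopic screening.  A configurable
fraction of the high-stiffness stratum is misclassified (no true CSPH) and
receives NSBBs without benefit, at a reduced utility.

The published analysis reports scenario outputs but not the stratum-level
inputs behind them; the defaults in
:class:`varscreen.parameters.ScenarioParameters` are documented illustrative
values, so scenario outputs are exploratory rather than reproduction targets.
"""

from __future__ import annotations

from .cea_metrics import CEAResult, compare_strategies
from .decision_tree import Strategy
from .parameters import ModelParameters
from .sensitivity import ThresholdResult, threshold_search

__all__ = ["run_scenario", "scenario_threshold"]


def run_scenario(params: ModelParameters, wtp: float | None = None) -> CEAResult:
    """Compare the LSM-stratified NSBB scenario against universal screening."""
    return compare_strategies(
        params, reference=Strategy.UNIVERSAL, comparator=Strategy.BAVENO7, wtp=wtp
    )


def _margin_scenario_nmb(params: ModelParameters) -> float:
    """scenario NMB >= universal NMB at the configured WTP."""
    return run_scenario(params).nmb_difference


def scenario_threshold(
    params: ModelParameters,
    bracket: tuple[float, float] = (0.05, 0.65),
    tol: float = 0.001,
) -> ThresholdResult:
    """HRV prevalence among CSPH patients at which the scenario's net benefit
    breaks even with universal screening (bisection over the bracket).

    The bracket must keep the stratification feasible: with the default 30%
    CSPH share and 20% overall prevalence, the CSPH-stratum prevalence cannot
    exceed 2/3 without driving the low-stratum prevalence negative.
    """
    return threshold_search(
        "scenario.prev_hrv_in_csph",
        _margin_scenario_nmb,
        bracket,
        params,
        tol=tol,
    )
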