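"""Deterministic sensitivity machinery.

One-way parameter sweeps, tornado ranking, threshold (break-even) bisection
and two-way grids, all re-running the full decision tree + cohort engine at
each evaluated point.  Derived triage quantities (probability of meeting
criteria, NPV, PPV) cannot be swept directly; sweeping prevalence,
sensitivity or specificity recomputes them automatically.

Dominance outcomes inside sweeps are kept as explicit flags; tornado ranking
uses net-monetary-benefit spans rather than signed ICERs to avoid ratio
pathologies near zero incremental effectiveness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cea_metrics import CEAResult, compare_strategies
from .decision_tree import Strategy
from .parameters import (
    PARAMETER_METADATA,
    ModelParameters,
    get_by_path,
    with_value,
)

__all__ = [
    "SweepSpec",
    "ThresholdResult",
    "CRITERIA",
    "one_way_sweep",
    "tornado",
    "threshold_search",
    "two_way_grid",
    "default_sweep_specs",
]


@dataclass(frozen=True)
class SweepSpec:
    """A one-way sweep: parameter path, range and grid resolution."""

    parameter_path: str
    low: float
    high: float
    n_points: int = 50

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")
        if self.n_points < 1:
            raise ValueError("n_points must be positive")

    def grid(self) -> np.ndarray:
        if self.low == self.high:
            return np.full(self.n_points, self.low)
        return np.linspace(self.low, self.high, self.n_points)


@dataclass
class ThresholdResult:
    """Break-even point of a named criterion along one parameter."""

    parameter_path: str
    criterion: str
    threshold_value: float
    bracket: tuple[float, float]
    tolerance: float


# ---------------------------------------------------------------------------
# Criteria: signed margins, positive where the criterion holds.
# ---------------------------------------------------------------------------


def _margin_cost(params: ModelParameters) -> float:
    """selective per-capita cost <= universal per-capita cost."""
    res = compare_strategies(params)
    return -res.incremental_cost


def _margin_nmb(params: ModelParameters) -> float:
    """selective cost-effective at the configured WTP (ICER <= WTP, including
    dominance), expressed as the NMB difference selective - universal."""
    res = compare_strategies(params)
    return res.nmb_difference


CRITERIA: dict[str, Callable[[ModelParameters], float]] = {
    "selective_cost_le_universal": _margin_cost,
    "icer_le_wtp": _margin_nmb,
}


def _evaluate(params: ModelParameters) -> CEAResult:
    return compare_strategies(
        params, Strategy.UNIVERSAL, Strategy.SELECTIVE, wtp=params.econ.wtp_per_qaly
    )


def one_way_sweep(
    spec: SweepSpec, params: ModelParameters
) -> list[tuple[float, CEAResult]]:
    """Re-run the base comparison at each grid point of one parameter."""
    out = []
    for value in spec.grid():
        out.append((float(value), _evaluate(with_value(params, spec.parameter_path, value))))
    return out


def default_sweep_specs(params: ModelParameters) -> list[SweepSpec]:
    """Sweep specs for every tabulated parameter at its published range."""
    return [
        SweepSpec(meta.path, meta.low, meta.high, n_points=2)
        for meta in PARAMETER_METADATA.values()
    ]


def tornado(params: ModelParameters, specs: list[SweepSpec]) -> pd.DataFrame:
    """Evaluate each parameter at its range endpoints, others at base.

    Returns a frame ranked by the absolute span of the NMB difference
    (selective minus universal); ICERs at the endpoints are reported where
    defined, dominance flags otherwise.
    """
    if not specs:
        raise ValueError("tornado requires at least one sweep spec")
    base = _evaluate(params)
    rows = []
    for spec in specs:
        lo = _evaluate(with_value(params, spec.parameter_path, spec.low))
        hi = _evaluate(with_value(params, spec.parameter_path, spec.high))
        rows.append(
            {
                "parameter": spec.parameter_path,
                "low": spec.low,
                "high": spec.high,
                "nmb_diff_low": lo.nmb_difference,
                "nmb_diff_high": hi.nmb_difference,
                "icer_low": lo.icer,
                "icer_high": hi.icer,
                "flag_low": lo.dominance,
                "flag_high": hi.dominance,
                "span": abs(hi.nmb_difference - lo.nmb_difference),
            }
        )
    frame = pd.DataFrame(rows).sort_values("span", ascending=False, ignore_index=True)
    frame.attrs["base_nmb_diff"] = base.nmb_difference
    return frame


def threshold_search(
    parameter_path: str,
    criterion: str | Callable[[ModelParameters], float],
    bracket: tuple[float, float],
    params: ModelParameters,
    tol: float | None = None,
) -> ThresholdResult:
    """Bisection for the parameter value where a criterion flips.

    ``criterion`` is a registered name (:data:`CRITERIA`) or a callable
    returning a signed margin (positive where the criterion holds).  The
    margin must change sign across the bracket.  Absolute tolerance defaults
    to 0.01 for cost parameters and 0.001 for probabilities.
    """
    name = criterion if isinstance(criterion, str) else getattr(criterion, "__name__", "custom")
    fn = CRITERIA[criterion] if isinstance(criterion, str) else criterion
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy low < high")
    if tol is None:
        tol = 0.01 if parameter_path.startswith("costs.") else 0.001
    f_lo = fn(with_value(params, parameter_path, lo))
    f_hi = fn(with_value(params, parameter_path, hi))
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"criterion '{name}' is monotone over bracket ({lo}, {hi}): "
            f"margins {f_lo:.4g} and {f_hi:.4g} share a sign"
        )
    a, b, f_a = lo, hi, f_lo
    while (b - a) > tol:
        mid = 0.5 * (a + b)
        f_mid = fn(with_value(params, parameter_path, mid))
        if np.sign(f_mid) == np.sign(f_a):
            a, f_a = mid, f_mid
        else:
            b = mid
    return ThresholdResult(
        parameter_path=parameter_path,
        criterion=name,
        threshold_value=0.5 * (a + b),
        bracket=(lo, hi),
        tolerance=tol,
    )


def two_way_grid(
    param_a: str,
    param_b: str,
    grid_a: np.ndarray,
    grid_b: np.ndarray,
    params: ModelParameters,
    criterion: str | Callable[[ModelParameters], float] = "icer_le_wtp",
) -> pd.DataFrame:
    """Boolean cost-effectiveness indicator over a two-parameter grid.

    Returns a frame indexed by ``param_a`` values with ``param_b`` values as
    columns; each cell is True where the criterion holds (by default:
    selective cost-effective at the configured WTP).
    """
    fn = CRITERIA[criterion] if isinstance(criterion, str) else criterion
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    cells = np.zeros((grid_a.size, grid_b.size), dtype=bool)
    for i, a in enumerate(grid_a):
        pa = with_value(params, param_a, float(a))
        for j, b in enumerate(grid_b):
            cells[i, j] = fn(with_value(pa, param_b, float(b))) >= 0.0
    frame = pd.DataFrame(cells, index=grid_a, columns=grid_b)
    frame.index.name = param_a
    frame.columns.name = param_b
    return frame
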