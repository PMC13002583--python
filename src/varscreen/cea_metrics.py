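"""Incremental cost-effectiveness metrics: ICER, dominance, net monetary benefit.

Currency results are conventionally reported to 2 decimals and QALYs to 4;
internal precision is always full.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .decision_tree import Strategy
from .markov_engine import run_cohort
from .parameters import ModelParameters

__all__ = [
    "CEAResult",
    "compute_icer",
    "compute_nmb",
    "compare_strategies",
    "efficiency_frontier",
]

#: dominance / degeneracy flags used instead of a numeric ICER
COMPARATOR_DOMINANT = "comparator dominant"
REFERENCE_DOMINANT = "reference dominant"
UNDEFINED_EQUAL_EFFECT = "undefined ICER (equal effectiveness)"


@dataclass
class CEAResult:
    """Pairwise cost-effectiveness comparison (comparator minus reference)."""

    reference: tuple[float, float]  # (per-capita cost, per-capita QALY)
    comparator: tuple[float, float]
    incremental_cost: float
    incremental_qaly: float
    icer: float | None
    dominance: str | None
    wtp: float | None = None
    nmb: dict[str, float] = field(default_factory=dict)

    @property
    def comparator_cost_effective(self) -> bool:
        """True when the comparator is preferred at the stored WTP (higher NMB)."""
        if self.wtp is None:
            raise ValueError("no WTP stored on this result")
        return self.nmb["comparator"] > self.nmb["reference"]

    @property
    def nmb_difference(self) -> float:
        """NMB(comparator) - NMB(reference) at the stored WTP."""
        if self.wtp is None:
            raise ValueError("no WTP stored on this result")
        return self.nmb["comparator"] - self.nmb["reference"]

    def summary(self) -> dict[str, object]:
        return {
            "reference_cost": round(float(self.reference[0]), 2),
            "reference_qaly": round(float(self.reference[1]), 4),
            "comparator_cost": round(float(self.comparator[0]), 2),
            "comparator_qaly": round(float(self.comparator[1]), 4),
            "incremental_cost": round(float(self.incremental_cost), 2),
            "incremental_qaly": round(float(self.incremental_qaly), 4),
            "icer": None if self.icer is None else round(float(self.icer), 2),
            "dominance": self.dominance,
        }


def compute_nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("WTP must be nonnegative")
    return qaly * wtp - cost


def compute_icer(
    reference: tuple[float, float],
    comparator: tuple[float, float],
    wtp: float | None = None,
) -> CEAResult:
    """Incremental comparison of two (cost, QALY) pairs.

    Incremental values are comparator minus reference.  A cheaper-and-more-
    effective comparator is flagged dominant (no ratio reported); equal
    effectiveness with unequal cost yields an undefined-ICER flag rather than
    a division by zero.
    """
    d_cost = comparator[0] - reference[0]
    d_qaly = comparator[1] - reference[1]
    icer: float | None = None
    dominance: str | None = None
    if d_qaly == 0.0:
        if d_cost != 0.0:
            dominance = UNDEFINED_EQUAL_EFFECT
    elif d_cost <= 0.0 and d_qaly > 0.0:
        dominance = COMPARATOR_DOMINANT if d_cost < 0.0 else None
        if dominance is None:
            icer = 0.0
    elif d_cost >= 0.0 and d_qaly < 0.0:
        dominance = REFERENCE_DOMINANT if d_cost > 0.0 else None
        if dominance is None:
            icer = 0.0
    if icer is None and dominance is None and d_qaly != 0.0:
        icer = d_cost / d_qaly
    nmb: dict[str, float] = {}
    if wtp is not None:
        nmb = {
            "reference": compute_nmb(*reference, wtp),
            "comparator": compute_nmb(*comparator, wtp),
        }
    return CEAResult(
        reference=reference,
        comparator=comparator,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        dominance=dominance,
        wtp=wtp,
        nmb=nmb,
    )


def compare_strategies(
    params: ModelParameters,
    reference: Strategy = Strategy.UNIVERSAL,
    comparator: Strategy = Strategy.SELECTIVE,
    wtp: float | None = None,
) -> CEAResult:
    """Run both arms through the cohort engine and compare them."""
    if wtp is None:
        wtp = params.econ.wtp_per_qaly
    ref = run_cohort(reference, params)
    cmp_ = run_cohort(comparator, params)
    return compute_icer(
        (ref.per_capita_cost, ref.per_capita_qaly),
        (cmp_.per_capita_cost, cmp_.per_capita_qaly),
        wtp=wtp,
    )


def efficiency_frontier(
    results: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Multi-strategy frontier with simple and extended dominance.

    Strategies are sorted by cost; a strategy is simply dominated if another
    is cheaper and at least as effective, and extendedly dominated if the
    ICER to the next frontier strategy is not monotonically increasing.
    Returns one row per strategy with status and the frontier ICER versus the
    previous non-dominated strategy.
    """
    items = sorted(results.items(), key=lambda kv: (kv[1][0], -kv[1][1]))
    status = {name: "on frontier" for name, _ in items}
    # simple dominance
    for i, (name, (c, q)) in enumerate(items):
        for other, (c2, q2) in items[:i]:
            if status[other] != "on frontier":
                continue
            if q2 >= q and c2 <= c:
                status[name] = "dominated"
                break
    # extended dominance: ICERs along the frontier must increase
    changed = True
    while changed:
        changed = False
        frontier = [kv for kv in items if status[kv[0]] == "on frontier"]
        for i in range(1, len(frontier) - 1):
            (n0, (c0, q0)), (n1, (c1, q1)), (n2, (c2, q2)) = frontier[i - 1 : i + 2]
            icer_01 = (c1 - c0) / (q1 - q0) if q1 != q0 else float("inf")
            icer_12 = (c2 - c1) / (q2 - q1) if q2 != q1 else float("inf")
            if icer_01 >= icer_12:
                status[n1] = "extendedly dominated"
                changed = True
                break
    rows = []
    prev: tuple[float, float] | None = None
    for name, (c, q) in items:
        icer = None
        if status[name] == "on frontier":
            if prev is not None and q != prev[1]:
                icer = (c - prev[0]) / (q - prev[1])
            prev = (c, q)
        rows.append(
            {"strategy": name, "cost": c, "qaly": q, "status": status[name], "icer": icer}
        )
    return pd.DataFrame(rows)
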