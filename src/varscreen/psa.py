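"""Probabilistic sensitivity analysis.

Distribution fitting by method of moments from a point estimate and its
published range, joint Monte Carlo parameter sampling, cost-effectiveness
plane draws, probability of cost-effectiveness at a willingness-to-pay
threshold, and the acceptability curve (CEAC).

Fitting convention: the published range is treated as a 95% interval, so the
standard error is (high - low) / (2 * 1.96).  Probabilities and utilities are
beta, costs gamma, and a triangular family is available for parameters that
resist moment fitting.  Parameters whose printed range is the entire [0, 1]
support carry no distributional information and fall back to a +/-20%
interval around the mean (the model's default variation rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision_tree import Strategy
from .markov_engine import run_cohort
from .parameters import (
    PARAMETER_METADATA,
    ModelParameters,
    ParamMeta,
    get_by_path,
    serialize,
    deserialize,
)

__all__ = [
    "DistributionSpec",
    "PSAOutput",
    "fit_distribution",
    "default_psa_specs",
    "sample_parameter_set",
    "run_psa",
]

_Z95 = 2.0 * 1.959963984540054  # width of a 95% normal interval in SE units


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter."""

    family: str  # "beta" | "gamma" | "triangular" | "point"
    mean: float
    low: float
    high: float
    shape: dict[str, float] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "point":
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(self.shape["alpha"], self.shape["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape["k"], self.shape["theta"], size=size)
        if self.family == "triangular":
            return rng.triangular(self.low, self.shape["mode"], self.high, size=size)
        raise ValueError(f"unknown family: {self.family}")  # pragma: no cover


def fit_distribution(
    family: str, mean: float, low: float, high: float
) -> DistributionSpec:
    """Method-of-moments fit treating (low, high) as a 95% interval.

    A degenerate range (low == high) yields a point mass.  Beta fitting fails
    with an explicit error when the implied variance is too large for the
    mean (s^2 >= m(1-m)).
    """
    if low > high:
        raise ValueError("low must be <= high")
    if low == high:
        return DistributionSpec("point", mean, low, high)
    s = (high - low) / _Z95
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError("beta mean must be inside (0, 1)")
        var = s * s
        if var >= mean * (1.0 - mean):
            raise ValueError(
                f"range too wide for beta at mean {mean}: "
                f"s^2 = {var:.4g} >= m(1-m) = {mean * (1 - mean):.4g}"
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return DistributionSpec(
            family, mean, low, high, {"alpha": mean * nu, "beta": (1.0 - mean) * nu}
        )
    if family == "gamma":
        if mean <= 0.0:
            raise ValueError("gamma mean must be positive")
        return DistributionSpec(
            family, mean, low, high, {"k": mean**2 / s**2, "theta": s**2 / mean}
        )
    if family == "triangular":
        mode = 3.0 * mean - low - high  # mean-consistent mode
        if not low <= mode <= high:
            raise ValueError(
                f"triangular mode {mode:.4g} outside [{low}, {high}] "
                f"for mean {mean}"
            )
        return DistributionSpec(family, mean, low, high, {"mode": mode})
    raise ValueError(f"unknown family: {family}")


def _effective_range(meta: ParamMeta, mean: float) -> tuple[float, float]:
    if meta.full_support:
        return 0.8 * mean, 1.2 * mean
    return meta.low, meta.high


def default_psa_specs(params: ModelParameters) -> dict[str, DistributionSpec]:
    """Fitted distributions for every tabulated parameter, keyed by path.

    Means come from the current parameter set, so PSA around a swept or
    overridden base case is supported.
    """
    specs = {}
    for path, meta in PARAMETER_METADATA.items():
        mean = get_by_path(params, path)
        low, high = _effective_range(meta, mean)
        specs[path] = fit_distribution(meta.family, mean, low, high)
    return specs


_MAX_REJECTION = 1000


def sample_parameter_set(
    rng: np.random.Generator,
    params: ModelParameters,
    specs: dict[str, DistributionSpec] | None = None,
) -> ModelParameters:
    """Draw one joint parameter set (all parameters independent).

    Derived triage quantities are recomputed downstream from the drawn
    prevalence/sensitivity/specificity; the NSBB/ligation treatment split
    stays normalised because the ligation share is the complement of the
    drawn NSBB share.  Draws outside a parameter's validity domain are
    rejected and redrawn, capped at 1,000 attempts.
    """
    if specs is None:
        specs = default_psa_specs(params)
    flat = serialize(params)
    for path, spec in specs.items():
        leaf = path.rsplit(".", 1)[-1]
        for _ in range(_MAX_REJECTION):
            value = float(spec.sample(rng))
            if _in_domain(leaf, value):
                flat[leaf] = value
                break
        else:
            raise RuntimeError(
                f"rejection sampling for '{path}' exhausted {_MAX_REJECTION} attempts"
            )
    return deserialize(flat)


def _in_domain(leaf: str, value: float) -> bool:
    if leaf.startswith(("p_", "u_")) or leaf in (
        "prevalence_hrv",
        "sensitivity",
        "specificity",
    ):
        return 0.0 <= value <= 1.0
    return value >= 0.0


@dataclass
class PSAOutput:
    """Paired Monte Carlo draws and derived acceptability results."""

    draws: pd.DataFrame  # per-iteration costs/QALYs and incrementals
    seed: int
    wtp: float
    strategies: tuple[str, str] = ("universal", "selective")

    @property
    def n_iterations(self) -> int:
        return len(self.draws)

    def p_ce_at_wtp(self, wtp: float | None = None) -> float:
        """Fraction of iterations where the comparator (selective) has the
        higher net monetary benefit."""
        if wtp is None:
            wtp = self.wtp
        d = self.draws
        return float((d["dqaly"] * wtp - d["dcost"] > 0.0).mean())

    def ceac(self, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
        """Acceptability curve: P(optimal) per strategy over a WTP grid.

        Defaults to 0..3x the stored WTP in 200 steps.  The two
        probabilities sum to 1 at every threshold (ties go to the reference).
        """
        if wtp_grid is None:
            wtp_grid = np.linspace(0.0, 3.0 * self.wtp, 201)
        d = self.draws
        rows = []
        for w in np.asarray(wtp_grid, dtype=float):
            p_sel = float((d["dqaly"] * w - d["dcost"] > 0.0).mean())
            rows.append(
                {"wtp": w, "p_universal": 1.0 - p_sel, "p_selective": p_sel}
            )
        return pd.DataFrame(rows)

    def ceac_crossover(self, wtp_grid: np.ndarray | None = None) -> float | None:
        """WTP where the selective strategy first overtakes 50% acceptability
        (linear interpolation on the CEAC grid); None if it never crosses."""
        curve = self.ceac(wtp_grid)
        p = curve["p_selective"].to_numpy()
        w = curve["wtp"].to_numpy()
        if p[0] >= 0.5:
            return 0.0
        above = np.nonzero(p >= 0.5)[0]
        if above.size == 0:
            return None
        i = above[0]
        w0, w1, p0, p1 = w[i - 1], w[i], p[i - 1], p[i]
        return float(w0 + (0.5 - p0) * (w1 - w0) / (p1 - p0)) if p1 != p0 else float(w1)


def run_psa(
    params: ModelParameters,
    n_iter: int | None = None,
    seed: int = 0,
    specs: dict[str, DistributionSpec] | None = None,
    reference: Strategy = Strategy.UNIVERSAL,
    comparator: Strategy = Strategy.SELECTIVE,
) -> PSAOutput:
    """Monte Carlo PSA: per iteration, draw a joint parameter set and run both
    strategy arms deterministically.

    Identical ``seed`` and ``n_iter`` give bit-identical output.
    """
    if n_iter is None:
        n_iter = params.econ.psa_iterations
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if specs is None:
        specs = default_psa_specs(params)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_iter):
        try:
            draw = sample_parameter_set(rng, params, specs)
            ref = run_cohort(reference, draw)
            cmp_ = run_cohort(comparator, draw)
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        records.append(
            (
                i,
                ref.per_capita_cost,
                ref.per_capita_qaly,
                cmp_.per_capita_cost,
                cmp_.per_capita_qaly,
            )
        )
    draws = pd.DataFrame(
        records,
        columns=[
            "iteration",
            "cost_reference",
            "qaly_reference",
            "cost_comparator",
            "qaly_comparator",
        ],
    )
    draws["dcost"] = draws["cost_comparator"] - draws["cost_reference"]
    draws["dqaly"] = draws["qaly_comparator"] - draws["qaly_reference"]
    return PSAOutput(
        draws=draws,
        seed=seed,
        wtp=params.econ.wtp_per_qaly,
        strategies=(Strategy(reference).value, Strategy(comparator).value),
    )
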