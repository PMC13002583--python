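"""Model inputs: diagnostic accuracy, transition probabilities, costs, utilities.

All point estimates, deterministic-sensitivity ranges and probabilistic
distribution families for the screening model live here, together with the
Bayesian derivation of the triage classification probabilities (probability of
meeting the Baveno low-risk criteria, NPV, PPV) from prevalence, sensitivity
and specificity.

Conventions
-----------
* "Sensitivity" is the probability that a patient who truly has high-risk
  varices (HRV) does *not* meet the low-risk criteria, i.e. is correctly
  flagged for endoscopy.  "Specificity" is the probability that a patient
  without HRV meets the criteria and is spared endoscopy.
* All currency amounts are 2022 USD; all probabilities are per one-year cycle.
* Reported rounded values (e.g. a 0.26 probability of meeting criteria) are
  outputs of :func:`derive_classification`; the engine always works with the
  full-precision derived values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "DiagnosticAccuracy",
    "ClassificationProbabilities",
    "TransitionProbabilities",
    "CostSet",
    "UtilitySet",
    "EconSettings",
    "ScenarioParameters",
    "ModelParameters",
    "ParamMeta",
    "PARAMETER_METADATA",
    "derive_classification",
    "load_parameters",
    "save_parameters",
    "serialize",
    "deserialize",
    "get_by_path",
    "with_value",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DiagnosticAccuracy(_StrictModel):
    """Accuracy of the non-invasive triage (liver stiffness + platelet count)."""

    prevalence_hrv: float = Field(0.20, ge=0.0, le=1.0)
    #: P(criteria NOT met | HRV): a true HRV patient is flagged for endoscopy.
    sensitivity: float = Field(0.97, ge=0.0, le=1.0)
    #: P(criteria met | no HRV): a non-HRV patient is spared endoscopy.
    specificity: float = Field(0.32, ge=0.0, le=1.0)


class ClassificationProbabilities(_StrictModel):
    """Cohort-level triage outcome probabilities, derived from accuracy."""

    p_meet: float = Field(..., ge=0.0, le=1.0)
    npv: float = Field(..., ge=0.0, le=1.0)
    ppv: float = Field(..., ge=0.0, le=1.0)


class TransitionProbabilities(_StrictModel):
    """Annual event probabilities of the state-transition model."""

    p_nsbb_treatment: float = Field(0.8, ge=0.0, le=1.0)
    p_bleed_missed_hrv: float = Field(0.10, ge=0.0, le=1.0)
    p_bleed_nsbb: float = Field(0.068, ge=0.0, le=1.0)
    p_bleed_ligation: float = Field(0.043, ge=0.0, le=1.0)
    p_death_after_bleed: float = Field(0.022, ge=0.0, le=1.0)
    p_death_other: float = Field(0.034, ge=0.0, le=1.0)
    #: Optional annual bleed probability in states without known HRV
    #: (structural exploration knob; the base case sets it to zero).
    p_bleed_background: float = Field(0.0, ge=0.0, le=1.0)

    @property
    def p_ligation_treatment(self) -> float:
        """Complement of the NSBB treatment split (the two always sum to 1)."""
        return 1.0 - self.p_nsbb_treatment


class CostSet(_StrictModel):
    """Unit costs in 2022 USD."""

    endoscopy: float = Field(96.73, ge=0.0)
    blood_routine: float = Field(2.68, ge=0.0)
    elastography: float = Field(18.60, ge=0.0)
    nsbb_annual: float = Field(52.68, ge=0.0)
    band_ligation: float = Field(744.05, ge=0.0)
    bleed_hospitalization: float = Field(1934.52, ge=0.0)


class UtilitySet(_StrictModel):
    """Health-state utility weights (QALY per year in state)."""

    u_nsbb: float = Field(0.65, ge=0.0, le=1.0)
    u_ligation: float = Field(0.67, ge=0.0, le=1.0)
    u_no_hrv: float = Field(0.76, ge=0.0, le=1.0)
    u_hrv_untreated: float = Field(0.72, ge=0.0, le=1.0)
    u_post_bleed: float = Field(0.54, ge=0.0, le=1.0)


class EconSettings(_StrictModel):
    """Economic evaluation settings."""

    discount_rate: float = Field(0.035, ge=0.0)
    horizon_cycles: int = Field(5, ge=1)
    cycle_length_years: float = Field(1.0, gt=0.0)
    cohort_size: int = Field(1000, ge=1)
    wtp_per_qaly: float = Field(12714.11, ge=0.0)
    psa_iterations: int = Field(10000, ge=1)


class ScenarioParameters(_StrictModel):
    """Inputs of the LSM >= 25 kPa (clinically significant portal hypertension)
    scenario, in which that stratum starts NSBBs without endoscopy.

    The published analysis does not print these stratum-level inputs; the
    defaults are documented illustrative values (see docs/methods.md).
    """

    p_lsm_ge_25: float = Field(0.30, ge=0.0, le=1.0)
    prev_hrv_in_csph: float = Field(0.40, ge=0.0, le=1.0)
    p_misclassified_nsbb: float = Field(0.075, ge=0.0, le=1.0)
    u_nsbb_no_csph: float = Field(0.73, ge=0.0, le=1.0)


class ModelParameters(_StrictModel):
    """The full, validated input set of the model."""

    accuracy: DiagnosticAccuracy = Field(default_factory=DiagnosticAccuracy)
    transitions: TransitionProbabilities = Field(default_factory=TransitionProbabilities)
    costs: CostSet = Field(default_factory=CostSet)
    utilities: UtilitySet = Field(default_factory=UtilitySet)
    econ: EconSettings = Field(default_factory=EconSettings)
    scenario: ScenarioParameters = Field(default_factory=ScenarioParameters)
    #: Structural flag: if True, untreated missed-HRV patients are detected and
    #: start treatment at the next cycle instead of remaining untreated.
    detect_missed_hrv: bool = False

    def validate_scenario_stratification(self) -> None:
        """Check that HRV mass is partitionable across the two LSM strata.

        Called before any scenario-arm allocation or run; base-arm analyses do
        not require the scenario stratification to be feasible.
        """
        p_hi = self.scenario.p_lsm_ge_25
        if p_hi >= 1.0:
            raise ValueError("p_lsm_ge_25 must be < 1 (some patients below 25 kPa)")
        prev_lo = self.prev_hrv_below_25
        if not 0.0 <= prev_lo <= 1.0:
            raise ValueError(
                "scenario stratification violates HRV mass conservation: "
                f"implied HRV prevalence below 25 kPa = {prev_lo:.4f} is outside [0, 1]"
            )
        hrv_hi = p_hi * self.scenario.prev_hrv_in_csph
        if hrv_hi > p_hi * (1.0 - self.scenario.p_misclassified_nsbb) + 1e-12:
            raise ValueError(
                "scenario misclassified fraction exceeds the non-HRV share of "
                "the LSM >= 25 stratum"
            )

    @property
    def prev_hrv_below_25(self) -> float:
        """HRV prevalence in the LSM < 25 kPa stratum, derived so that the two
        strata average to the overall prevalence."""
        p_hi = self.scenario.p_lsm_ge_25
        if p_hi == 0.0:
            return self.accuracy.prevalence_hrv
        return (
            self.accuracy.prevalence_hrv - p_hi * self.scenario.prev_hrv_in_csph
        ) / (1.0 - p_hi)


def derive_classification(accuracy: DiagnosticAccuracy) -> ClassificationProbabilities:
    """Derive triage outcome probabilities from prevalence/sensitivity/specificity.

    ``p_meet`` is the probability of meeting the low-risk criteria (spared
    endoscopy); ``npv`` the probability of truly having no HRV given the
    criteria are met; ``ppv`` the probability of HRV given they are not met.

    Raises
    ------
    ValueError
        If ``p_meet`` is 0 or 1, which makes NPV or PPV undefined.
    """
    prev = accuracy.prevalence_hrv
    sens = accuracy.sensitivity
    spec = accuracy.specificity
    p_meet = prev * (1.0 - sens) + (1.0 - prev) * spec
    if p_meet <= 0.0 or p_meet >= 1.0:
        raise ValueError(
            f"degenerate triage configuration: p_meet = {p_meet:.4f}; "
            "NPV/PPV are undefined"
        )
    # clamp float round-off just past the unit interval
    npv = min(1.0, max(0.0, (1.0 - prev) * spec / p_meet))
    ppv = min(1.0, max(0.0, prev * sens / (1.0 - p_meet)))
    return ClassificationProbabilities(p_meet=p_meet, npv=npv, ppv=ppv)


# --------------------------------------------------------------------------
# Sensitivity / PSA metadata (deterministic ranges and distribution families)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamMeta:
    """Deterministic-sensitivity range and PSA distribution family of a leaf
    parameter, addressed by its dotted path in :class:`ModelParameters`."""

    path: str
    low: float
    high: float
    family: str  # "beta" | "gamma" | "triangular"
    #: True when the printed range is the entire support [0, 1], which carries
    #: no distributional information; the PSA then falls back to a +/-20%
    #: interval around the mean.
    full_support: bool = False


_METADATA = [
    ParamMeta("accuracy.prevalence_hrv", 0.10, 0.30, "beta"),
    ParamMeta("accuracy.sensitivity", 0.95, 0.98, "beta"),
    ParamMeta("accuracy.specificity", 0.26, 0.39, "beta"),
    ParamMeta("transitions.p_nsbb_treatment", 0.0, 1.0, "beta", full_support=True),
    ParamMeta("transitions.p_bleed_missed_hrv", 0.08, 0.12, "beta"),
    ParamMeta("transitions.p_bleed_nsbb", 0.0, 0.1, "beta"),
    ParamMeta("transitions.p_bleed_ligation", 0.0, 0.1, "beta"),
    ParamMeta("transitions.p_death_after_bleed", 0.01, 0.04, "beta"),
    ParamMeta("transitions.p_death_other", 0.0, 1.0, "beta", full_support=True),
    ParamMeta("costs.endoscopy", 44.64, 178.57, "gamma"),
    ParamMeta("costs.blood_routine", 2.23, 3.72, "gamma"),
    ParamMeta("costs.elastography", 12.65, 24.55, "gamma"),
    ParamMeta("costs.nsbb_annual", 26.34, 79.02, "gamma"),
    ParamMeta("costs.band_ligation", 446.43, 1026.79, "gamma"),
    ParamMeta("costs.bleed_hospitalization", 758.93, 2976.19, "gamma"),
    ParamMeta("utilities.u_nsbb", 0.52, 0.95, "beta"),
    ParamMeta("utilities.u_ligation", 0.52, 0.95, "beta"),
    ParamMeta("utilities.u_no_hrv", 0.52, 0.95, "beta"),
    # NB: the published range of the untreated-HRV utility (0.75-0.90) does not
    # contain its own point estimate 0.72; both are used exactly as printed.
    ParamMeta("utilities.u_hrv_untreated", 0.75, 0.90, "beta"),
    ParamMeta("utilities.u_post_bleed", 0.26, 0.66, "beta"),
]

PARAMETER_METADATA: dict[str, ParamMeta] = {m.path: m for m in _METADATA}

#: Derived triage quantities that must be varied through their parent inputs.
DERIVED_QUANTITIES = frozenset({"p_meet", "npv", "ppv", "meeting_baveno_criteria"})

_GROUPS: dict[str, type[_StrictModel]] = {
    "accuracy": DiagnosticAccuracy,
    "transitions": TransitionProbabilities,
    "costs": CostSet,
    "utilities": UtilitySet,
    "econ": EconSettings,
    "scenario": ScenarioParameters,
}


def _flat_fields() -> Iterator[tuple[str, str, str]]:
    """Yield (flat_key, group, field). Flat keys are globally unique."""
    for group, model in _GROUPS.items():
        for field in model.model_fields:
            yield field, group, field
    yield "detect_missed_hrv", "", "detect_missed_hrv"


_FLAT_MAP: dict[str, tuple[str, str]] = {}
for _key, _group, _field in _flat_fields():
    if _key in _FLAT_MAP:  # pragma: no cover - guarded by construction
        raise RuntimeError(f"duplicate flat config key: {_key}")
    _FLAT_MAP[_key] = (_group, _field)


def serialize(params: ModelParameters) -> dict[str, float | int | bool]:
    """Flatten a parameter set into the flat key-value config mapping."""
    out: dict[str, float | int | bool] = {}
    for key, (group, field) in _FLAT_MAP.items():
        obj = getattr(params, group) if group else params
        out[key] = getattr(obj, field)
    return out


def deserialize(flat: dict[str, object]) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from a flat mapping.

    Unknown keys and out-of-range values raise ``ValueError`` naming the
    offending key; omitted keys take the published point estimates.
    """
    grouped: dict[str, dict[str, object]] = {g: {} for g in _GROUPS}
    top: dict[str, object] = {}
    unknown = []
    for key, value in flat.items():
        if key in DERIVED_QUANTITIES:
            raise ValueError(
                f"'{key}' is a derived quantity; set prevalence_hrv, "
                "sensitivity and specificity instead"
            )
        if key not in _FLAT_MAP:
            unknown.append(key)
            continue
        group, field = _FLAT_MAP[key]
        if group:
            grouped[group][field] = value
        else:
            top[field] = value
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    payload: dict[str, object] = {g: v for g, v in grouped.items() if v}
    payload.update(top)
    try:
        return ModelParameters.model_validate(payload)
    except Exception as exc:  # re-raise with a uniform error type
        raise ValueError(str(exc)) from exc


def load_parameters(config_path: str | Path | None = None) -> ModelParameters:
    """Load parameters from a flat YAML config file (or defaults if ``None``).

    An empty or absent config returns the full published default input set.
    """
    if config_path is None:
        return ModelParameters()
    text = Path(config_path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return ModelParameters()
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key: value mapping")
    return deserialize(data)


def save_parameters(params: ModelParameters, config_path: str | Path) -> None:
    """Write a parameter set as a flat YAML config (lossless round-trip)."""
    Path(config_path).write_text(
        yaml.safe_dump(serialize(params), sort_keys=True, default_flow_style=False)
    )


def get_by_path(params: ModelParameters, path: str) -> float:
    """Read a leaf value by dotted path, e.g. ``costs.endoscopy``."""
    obj: object = params
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj  # type: ignore[return-value]


def with_value(params: ModelParameters, path: str, value: float) -> ModelParameters:
    """Return a new validated parameter set with one leaf replaced."""
    leaf = path.rsplit(".", 1)[-1]
    if leaf in DERIVED_QUANTITIES:
        raise ValueError(
            f"'{leaf}' is derived from prevalence/sensitivity/specificity; "
            "sweep those parents instead"
        )
    flat = serialize(params)
    key = leaf
    if key not in flat:
        raise ValueError(f"unknown parameter path: {path}")
    flat[key] = value
    return deserialize(flat)
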