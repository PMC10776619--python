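"""Model parameters: prevalences, test performance, surgery uptake, cancer
risks, unit costs and the model timeline, in three scenario columns
(central / best / worst).

All probabilities are stored as fractions in [0, 1]; costs are euros; ages
and durations are years. The three built-in scenarios carry the Italian
input data the model was calibrated to: a steady-state cohort of 274,000
eighteen-year-old women, a population carrier prevalence of 0.67 %
(central), clinical/family-history testing eligibility of 0.98 % with a
10 % positivity among the eligible, and lifetime cancer-risk tables per
prophylactic-surgery stratum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

logger = logging.getLogger("brcascreen")

SCENARIO_LABELS = ("central", "best", "worst")
SURGERY_STRATA = ("none", "rrm_only", "rrso_only", "both")

#: Relative slack within which a probability block that should sum to 1 is
#: silently renormalized (with a WARN); larger deviations are errors. The
#: best-case no-surgery cancer block sums to 1.0002 as printed.
RENORM_TOLERANCE = 1e-3
_SUM_TOLERANCE = 1e-9


class ParameterError(ValueError):
    """Raised when a parameter set fails validation."""


def _check_probability(name: str, value: Any) -> float:
    try:
        p = float(value)
    except (TypeError, ValueError):
        raise ParameterError(f"{name} must be a number, got {value!r}") from None
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"{name} must be a probability in [0, 1], got {p}")
    return p


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity of the radiogenomic ultrasound classifier.

    Model 2 uses the published performance (49 % / 87 %); model 3 the
    projected improved performance (80 % / 95 %). Model 1 has no screening
    test at all (``screening=None`` in :class:`ModelConfig`).
    """

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_probability("sensitivity", self.sensitivity)
        _check_probability("specificity", self.specificity)


@dataclass(frozen=True)
class SurgeryMix:
    """Risk-reducing surgery uptake among carriers who know their status."""

    p_both: float
    p_rrso_only: float
    p_rrm_only: float
    p_none: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_probability(f.name, getattr(self, f.name))
        total = self.p_both + self.p_rrso_only + self.p_rrm_only + self.p_none
        if abs(total - 1.0) > _SUM_TOLERANCE:
            raise ParameterError(
                f"surgery mix probabilities must sum to 1, got {total!r}"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "both": self.p_both,
            "rrso_only": self.p_rrso_only,
            "rrm_only": self.p_rrm_only,
            "none": self.p_none,
        }


@dataclass(frozen=True)
class StratumRisks:
    """Lifetime cancer probabilities for one prophylactic-surgery stratum."""

    p_breast_only: float
    p_ovarian_only: float
    p_both_cancers: float
    p_no_cancer: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_probability(f.name, getattr(self, f.name))
        total = sum(getattr(self, f.name) for f in fields(self))
        if abs(total - 1.0) > _SUM_TOLERANCE:
            raise ParameterError(
                f"stratum probabilities must sum to 1, got {total!r}"
            )

    @property
    def p_any_cancer(self) -> float:
        return self.p_breast_only + self.p_ovarian_only + self.p_both_cancers

    @property
    def p_breast_involved(self) -> float:
        return self.p_breast_only + self.p_both_cancers

    @property
    def p_ovarian_involved(self) -> float:
        return self.p_ovarian_only + self.p_both_cancers

    @classmethod
    def from_raw(cls, stratum: str, raw: Mapping[str, Any]) -> "StratumRisks":
        """Build from possibly-unnormalized values, renormalizing within
        :data:`RENORM_TOLERANCE` (the printed tables round to 0.01 %)."""
        keys = ("breast_only", "ovarian_only", "both_cancers", "no_cancer")
        vals = []
        for key in keys:
            if key not in raw:
                raise ParameterError(
                    f"cancer_risks[{stratum}] is missing field {key!r}"
                )
            vals.append(_check_probability(f"cancer_risks[{stratum}].{key}", raw[key]))
        total = sum(vals)
        if abs(total - 1.0) > RENORM_TOLERANCE:
            raise ParameterError(
                f"cancer_risks[{stratum}] probabilities sum to {total}, not 1"
            )
        if abs(total - 1.0) > _SUM_TOLERANCE:
            logger.warning(
                "cancer_risks[%s] sums to %.6f; renormalizing to 1", stratum, total
            )
            vals = [v / total for v in vals]
        return cls(*vals)


@dataclass(frozen=True)
class CancerRiskTable:
    """Per-surgery-stratum lifetime cancer-risk rows."""

    none: StratumRisks
    rrm_only: StratumRisks
    rrso_only: StratumRisks
    both: StratumRisks

    def stratum(self, name: str) -> StratumRisks:
        if name not in SURGERY_STRATA:
            raise ParameterError(
                f"unknown surgery stratum {name!r}; expected one of {SURGERY_STRATA}"
            )
        return getattr(self, name)

    def items(self) -> Iterator[tuple[str, StratumRisks]]:
        for name in SURGERY_STRATA:
            yield name, getattr(self, name)


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs to the health service (euros, Italian DRG tariffs)."""

    gyn_visit_us: float
    genetic_counselling_testing: float
    rrso: float
    rrm: float
    ovarian_cancer_surgery: float
    breast_cancer_mastectomy: float
    chemotherapy: float
    parp_inhibitor: float
    radiotherapy: float
    fu_brca_positive_per_year: float
    fu_brca_negative_or_unknown_per_year: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or v < 0:
                raise ParameterError(f"cost {f.name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class Timeline:
    """Model timeline in years (consent at 18, exit at 80, 62-year cycle).

    Follow-up splits at the scenario's average cancer-onset age: step 1 runs
    from consent to onset, step 2 from onset to exit.
    """

    age_consent: float
    cancer_onset_age: float
    fu_step1_years: float
    fu_step2_years: float
    exit_age: float
    cycle_years: float
    prophylactic_surgery_age: float

    def __post_init__(self) -> None:
        checks = [
            ("fu_step1_years", self.fu_step1_years,
             self.cancer_onset_age - self.age_consent),
            ("fu_step2_years", self.fu_step2_years,
             self.exit_age - self.cancer_onset_age),
            ("cycle_years", self.cycle_years, self.exit_age - self.age_consent),
        ]
        for name, got, expected in checks:
            if abs(got - expected) > 1e-9:
                raise ParameterError(
                    f"timeline inconsistency: {name}={got} but ages imply {expected}"
                )


@dataclass(frozen=True)
class ScenarioParameters:
    """One full Table-of-inputs column: everything the cohort engine needs."""

    scenario_label: str
    population_size: float
    prevalence_carriers: float
    clinical_eligibility_rate: float
    positivity_among_eligible: float
    prevalence_in_not_eligible: float
    surgery_mix: SurgeryMix
    cancer_risks: CancerRiskTable
    costs: CostSchedule
    timeline: Timeline

    def __post_init__(self) -> None:
        if self.scenario_label not in SCENARIO_LABELS:
            raise ParameterError(
                f"unknown scenario label {self.scenario_label!r}; "
                f"expected one of {SCENARIO_LABELS}"
            )
        if self.population_size <= 0:
            raise ParameterError(
                f"population_size must be > 0, got {self.population_size}"
            )
        for name in (
            "prevalence_carriers",
            "clinical_eligibility_rate",
            "positivity_among_eligible",
            "prevalence_in_not_eligible",
        ):
            _check_probability(name, getattr(self, name))
        # Internal consistency: eligibility x positivity + complement x
        # not-eligible prevalence should recover the marginal prevalence.
        implied = (
            self.clinical_eligibility_rate * self.positivity_among_eligible
            + (1.0 - self.clinical_eligibility_rate) * self.prevalence_in_not_eligible
        )
        if abs(implied - self.prevalence_carriers) > 1e-3:
            logger.warning(
                "scenario %s: implied carrier prevalence %.5f differs from "
                "stated %.5f by more than 0.001",
                self.scenario_label, implied, self.prevalence_carriers,
            )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        risks = {
            stratum: {
                "breast_only": r.p_breast_only,
                "ovarian_only": r.p_ovarian_only,
                "both_cancers": r.p_both_cancers,
                "no_cancer": r.p_no_cancer,
            }
            for stratum, r in self.cancer_risks.items()
        }
        return {
            "scenario_label": self.scenario_label,
            "population_size": self.population_size,
            "prevalence_carriers": self.prevalence_carriers,
            "clinical_eligibility_rate": self.clinical_eligibility_rate,
            "positivity_among_eligible": self.positivity_among_eligible,
            "prevalence_in_not_eligible": self.prevalence_in_not_eligible,
            "surgery_mix": self.surgery_mix.as_dict(),
            "cancer_risks": risks,
            "costs": {f.name: getattr(self.costs, f.name)
                      for f in fields(CostSchedule)},
            "timeline": {f.name: getattr(self.timeline, f.name)
                         for f in fields(Timeline)},
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ScenarioParameters":
        def require(section: Mapping[str, Any], key: str, where: str = "") -> Any:
            if key not in section:
                raise ParameterError(f"missing field {where}{key!r}")
            return section[key]

        for top in (
            "scenario_label", "population_size", "prevalence_carriers",
            "clinical_eligibility_rate", "positivity_among_eligible",
            "prevalence_in_not_eligible", "surgery_mix", "cancer_risks",
            "costs", "timeline",
        ):
            require(data, top)

        mix_raw = data["surgery_mix"]
        mix = SurgeryMix(
            p_both=require(mix_raw, "both", "surgery_mix."),
            p_rrso_only=require(mix_raw, "rrso_only", "surgery_mix."),
            p_rrm_only=require(mix_raw, "rrm_only", "surgery_mix."),
            p_none=require(mix_raw, "none", "surgery_mix."),
        )
        risks_raw = data["cancer_risks"]
        risks = CancerRiskTable(**{
            stratum: StratumRisks.from_raw(
                stratum, require(risks_raw, stratum, "cancer_risks.")
            )
            for stratum in SURGERY_STRATA
        })
        costs_raw = data["costs"]
        costs = CostSchedule(**{
            f.name: require(costs_raw, f.name, "costs.")
            for f in fields(CostSchedule)
        })
        tl_raw = data["timeline"]
        timeline = Timeline(**{
            f.name: require(tl_raw, f.name, "timeline.")
            for f in fields(Timeline)
        })
        return cls(
            scenario_label=data["scenario_label"],
            population_size=float(data["population_size"]),
            prevalence_carriers=float(data["prevalence_carriers"]),
            clinical_eligibility_rate=float(data["clinical_eligibility_rate"]),
            positivity_among_eligible=float(data["positivity_among_eligible"]),
            prevalence_in_not_eligible=float(data["prevalence_in_not_eligible"]),
            surgery_mix=mix,
            cancer_risks=risks,
            costs=costs,
            timeline=timeline,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Which carrier-selection strategy to run and for how many generations.

    model 1: clinical criteria / family history only (standard of care).
    model 2: model 1 plus the radiogenomic screen at 49 % / 87 %.
    model 3: model 1 plus the improved screen at 80 % / 95 %.

    Screening is active in generations 1 and 2 by default and withdrawn in
    generation 3, when cascade testing of relatives carries detection.

    ``gen1_rule`` selects how screening and clinical detection combine in
    generation 1 ("union": clinical criteria add only screen-negative
    eligible carriers). ``residual_rule_active`` / ``residual_rule_inactive``
    select how carriers from still-unaware families are picked up in
    generations >= 2 with screening on / off: "additive" adds the clinical
    detection rate to the screen sensitivity without overlap deduction (the
    source tables are only reproduced this way); "cascade_only" leaves the
    residual undetected once screening is withdrawn.
    """

    model_id: int
    screening: TestPerformance | None = None
    generations: int = 3
    screening_active_generations: frozenset[int] = field(default=None)  # type: ignore[assignment]
    gen1_rule: str = "union"
    residual_rule_active: str = "additive"
    residual_rule_inactive: str = "cascade_only"
    model1_cascade: bool = False

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ParameterError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        if self.model_id == 1 and self.screening is not None:
            raise ParameterError("model 1 has no screening test")
        if self.model_id in (2, 3) and self.screening is None:
            raise ParameterError(f"model {self.model_id} requires screening performance")
        if self.generations < 1:
            raise ParameterError("generations must be >= 1")
        if self.screening_active_generations is None:
            default = frozenset({1, 2}) if self.screening else frozenset()
            object.__setattr__(self, "screening_active_generations", default)
        else:
            object.__setattr__(
                self,
                "screening_active_generations",
                frozenset(self.screening_active_generations),
            )
        if self.gen1_rule not in ("union", "additive"):
            raise ParameterError(f"unknown gen1_rule {self.gen1_rule!r}")
        if self.residual_rule_active not in ("additive", "union"):
            raise ParameterError(
                f"unknown residual_rule_active {self.residual_rule_active!r}"
            )
        if self.residual_rule_inactive not in ("cascade_only", "clinical"):
            raise ParameterError(
                f"unknown residual_rule_inactive {self.residual_rule_inactive!r}"
            )

    def screening_active(self, generation_index: int) -> bool:
        return (
            self.screening is not None
            and generation_index in self.screening_active_generations
        )


#: Published classifier performance per model variant.
MODEL_SCREENING: dict[int, TestPerformance | None] = {
    1: None,
    2: TestPerformance(sensitivity=0.49, specificity=0.87),
    3: TestPerformance(sensitivity=0.80, specificity=0.95),
}


def default_config(model_id: int, generations: int = 3, **kwargs: Any) -> ModelConfig:
    """Standard configuration for one of the three published model variants."""
    if model_id not in MODEL_SCREENING:
        raise ParameterError(f"model_id must be 1, 2 or 3, got {model_id}")
    return ModelConfig(
        model_id=model_id,
        screening=MODEL_SCREENING[model_id],
        generations=generations,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Built-in scenario columns
# ---------------------------------------------------------------------------

_COSTS = {
    "gyn_visit_us": 51.65,
    "genetic_counselling_testing": 1099.48,
    "rrso": 1436.00,
    "rrm": 1960.00,
    "ovarian_cancer_surgery": 6791.00,
    "breast_cancer_mastectomy": 3524.45,
    "chemotherapy": 2226.00,
    "parp_inhibitor": 82344.00,
    "radiotherapy": 6000.00,
    "fu_brca_positive_per_year": 198.20,
    "fu_brca_negative_or_unknown_per_year": 69.60,
}

_SCENARIO_TABLE: dict[str, dict[str, Any]] = {
    "central": {
        "scenario_label": "central",
        "population_size": 274000,
        "prevalence_carriers": 0.0067,
        "clinical_eligibility_rate": 0.0098,
        "positivity_among_eligible": 0.10,
        "prevalence_in_not_eligible": 0.0058,
        "surgery_mix": {"both": 0.2585, "rrso_only": 0.2915,
                        "rrm_only": 0.2115, "none": 0.2385},
        "cancer_risks": {
            "none": {"breast_only": 0.4900, "ovarian_only": 0.0900,
                     "both_cancers": 0.2150, "no_cancer": 0.2050},
            "rrm_only": {"breast_only": 0.0441, "ovarian_only": 0.2856,
                         "both_cancers": 0.0194, "no_cancer": 0.6509},
            "rrso_only": {"breast_only": 0.3413, "ovarian_only": 0.0080,
                          "both_cancers": 0.0042, "no_cancer": 0.6465},
            "both": {"breast_only": 0.0349, "ovarian_only": 0.0118,
                     "both_cancers": 0.0004, "no_cancer": 0.9529},
        },
        "costs": _COSTS,
        "timeline": {"age_consent": 18, "cancer_onset_age": 45,
                     "fu_step1_years": 27, "fu_step2_years": 35,
                     "exit_age": 80, "cycle_years": 62,
                     "prophylactic_surgery_age": 40},
    },
    "best": {
        "scenario_label": "best",
        "population_size": 274000,
        "prevalence_carriers": 0.0059,
        "clinical_eligibility_rate": 0.0047,
        "positivity_among_eligible": 0.10,
        "prevalence_in_not_eligible": 0.0051,
        "surgery_mix": {"both": 0.3584, "rrso_only": 0.2816,
                        "rrm_only": 0.2016, "none": 0.1584},
        "cancer_risks": {
            # As printed this block sums to 1.0002; renormalized on load.
            "none": {"breast_only": 0.4820, "ovarian_only": 0.0870,
                     "both_cancers": 0.1481, "no_cancer": 0.2831},
            "rrm_only": {"breast_only": 0.0096, "ovarian_only": 0.2320,
                         "both_cancers": 0.0030, "no_cancer": 0.7554},
            "rrso_only": {"breast_only": 0.2309, "ovarian_only": 0.0072,
                          "both_cancers": 0.0022, "no_cancer": 0.7597},
            "both": {"breast_only": 0.0062, "ovarian_only": 0.0093,
                     "both_cancers": 0.0001, "no_cancer": 0.9844},
        },
        "costs": _COSTS,
        "timeline": {"age_consent": 18, "cancer_onset_age": 60,
                     "fu_step1_years": 42, "fu_step2_years": 20,
                     "exit_age": 80, "cycle_years": 62,
                     "prophylactic_surgery_age": 45},
    },
    "worst": {
        "scenario_label": "worst",
        "population_size": 274000,
        "prevalence_carriers": 0.0077,
        "clinical_eligibility_rate": 0.0179,
        "positivity_among_eligible": 0.10,
        "prevalence_in_not_eligible": 0.0068,
        "surgery_mix": {"both": 0.1530, "rrso_only": 0.2970,
                        "rrm_only": 0.1870, "none": 0.3630},
        "cancer_risks": {
            "none": {"breast_only": 0.4758, "ovarian_only": 0.0858,
                     "both_cancers": 0.3042, "no_cancer": 0.1342},
            "rrm_only": {"breast_only": 0.1808, "ovarian_only": 0.2744,
                         "both_cancers": 0.1156, "no_cancer": 0.4292},
            "rrso_only": {"breast_only": 0.4675, "ovarian_only": 0.0385,
                          "both_cancers": 0.0395, "no_cancer": 0.4545},
            "both": {"breast_only": 0.1582, "ovarian_only": 0.0646,
                     "both_cancers": 0.0134, "no_cancer": 0.7638},
        },
        "costs": _COSTS,
        "timeline": {"age_consent": 18, "cancer_onset_age": 35,
                     "fu_step1_years": 17, "fu_step2_years": 45,
                     "exit_age": 80, "cycle_years": 62,
                     "prophylactic_surgery_age": 35},
    },
}


def builtin_scenario(label: str) -> ScenarioParameters:
    """Return the fully populated built-in parameter set for one scenario.

    Pure and deterministic: repeated calls with the same label give equal
    objects. Costs are identical across scenarios (a single tariff per
    cost item).
    """
    if label not in _SCENARIO_TABLE:
        raise ParameterError(
            f"unknown scenario label {label!r}; valid labels: "
            + ", ".join(SCENARIO_LABELS)
        )
    return ScenarioParameters.from_dict(_SCENARIO_TABLE[label])


def load_parameters(path: str | Path) -> ScenarioParameters:
    """Load and validate a scenario parameter file (YAML).

    The file mirrors :meth:`ScenarioParameters.to_dict`; see the packaged
    ``data/central.yaml`` for a template. Raises :class:`ParameterError`
    naming the offending field on any validation failure.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ParameterError(f"{path} does not contain a parameter mapping")
    return ScenarioParameters.from_dict(data)


def save_parameters(params: ScenarioParameters, path: str | Path) -> None:
    """Write a parameter set as YAML; ``load_parameters`` round-trips it."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def packaged_scenario_path(label: str) -> Path:
    """Path of the packaged YAML fixture for one scenario column."""
    if label not in SCENARIO_LABELS:
        raise ParameterError(
            f"unknown scenario label {label!r}; valid labels: "
            + ", ".join(SCENARIO_LABELS)
        )
    return Path(__file__).parent / "data" / f"{label}.yaml"


def carriers_expected(params: ScenarioParameters) -> float:
    """Expected carrier count N x prevalence (kept unrounded)."""
    return params.population_size * params.prevalence_carriers


def is_close(a: float, b: float, tol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=tol)
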