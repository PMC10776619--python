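"""Direct costs to the health service over the 62-year cycle.

Five components per model x generation:

* **testing** — genetic counselling + testing for every woman eligible
  for testing (1099.48 EUR each);
* **screening** — the gynaecological visit + ultrasound (51.65 EUR)
  billed per screened woman in screening-active generations (models 2/3;
  switch off via :class:`CostRules` to treat it as part of routine care);
* **prophylactic surgery** — RRSO/RRM tariffs weighted by the surgery mix
  for every detected carrier;
* **cancer treatment** — per involvement: ovarian-involved cases receive
  surgery + chemotherapy + PARP-inhibitor therapy, breast-involved cases
  mastectomy + chemotherapy + radiotherapy; a both-cancers patient incurs
  both bundles;
* **follow-up** — yearly surveillance: 198.20 EUR for known carriers,
  69.60 EUR for everyone else; carriers diagnosed at cancer onset switch
  from the unknown to the carrier rate at the onset age.

The treatment/follow-up assignment rules are an explicit, configurable
rule ledger (:class:`CostRules`); the defaults reproduce the published
cost levels within the stated tolerances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .detection import DetectionResult
from .outcomes import CancerOutcome
from .parameters import (
    CostSchedule,
    ParameterError,
    ScenarioParameters,
    SurgeryMix,
)

logger = logging.getLogger("brcascreen")


@dataclass(frozen=True)
class CostRules:
    """The configurable cost-assignment rule ledger.

    parp_fraction: fraction of ovarian-involved cancers receiving
        PARP-inhibitor therapy (default: all of them).
    bill_screening_visit: bill the gyn visit + US per screened woman in
        screening-active generations (default True; False treats the
        screen as embedded in routine care at zero marginal cost).
    """

    parp_fraction: float = 1.0
    bill_screening_visit: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.parp_fraction <= 1.0:
            raise ParameterError(
                f"parp_fraction must be in [0, 1], got {self.parp_fraction}"
            )


@dataclass(frozen=True)
class CostBreakdown:
    """Total direct cost and its components for one model x generation."""

    testing: float
    screening: float
    prophylactic_surgery: float
    cancer_treatment: float
    follow_up: float
    total: float
    per_year_per_person: float

    def __post_init__(self) -> None:
        parts = (
            self.testing + self.screening + self.prophylactic_surgery
            + self.cancer_treatment + self.follow_up
        )
        if abs(parts - self.total) > 0.01:
            raise ParameterError(f"cost components sum to {parts}, not {self.total}")


def testing_cost(eligible: float, costs: CostSchedule) -> float:
    """Genetic counselling + testing for all eligible women."""
    if eligible < 0:
        raise ParameterError(f"eligible must be >= 0, got {eligible}")
    return eligible * costs.genetic_counselling_testing


def surgery_cost(detected: float, mix: SurgeryMix, costs: CostSchedule) -> float:
    """Prophylactic-surgery cost for detected carriers: mix-weighted
    RRSO/RRM tariffs (central expectation: 1711.00 EUR per carrier)."""
    if detected < 0:
        raise ParameterError(f"detected must be >= 0, got {detected}")
    per_carrier = (
        mix.p_both * (costs.rrso + costs.rrm)
        + mix.p_rrso_only * costs.rrso
        + mix.p_rrm_only * costs.rrm
    )
    return detected * per_carrier


def treatment_cost(
    outcome: CancerOutcome,
    costs: CostSchedule,
    rules: CostRules | None = None,
) -> float:
    """Cancer-treatment cost by involvement.

    Ovarian bundle: 6791 + 2226 + 82344 EUR (surgery, chemo, PARP);
    breast bundle: 3524.45 + 2226 + 6000 EUR (mastectomy, chemo,
    radiotherapy). Both-cancer patients incur both bundles.
    """
    rules = rules or CostRules()
    ovarian_bundle = (
        costs.ovarian_cancer_surgery
        + costs.chemotherapy
        + rules.parp_fraction * costs.parp_inhibitor
    )
    breast_bundle = (
        costs.breast_cancer_mastectomy + costs.chemotherapy + costs.radiotherapy
    )
    return (
        outcome.ovarian_involved * ovarian_bundle
        + outcome.breast_involved * breast_bundle
    )


def follow_up_cost(
    detection: DetectionResult,
    outcome: CancerOutcome,
    params: ScenarioParameters,
    rules: CostRules | None = None,
) -> float:
    """Lifetime surveillance cost over the cycle.

    Detected carriers: carrier rate for the whole cycle. Carriers
    diagnosed at cancer onset: unknown rate until onset, carrier rate
    after. Everyone else: unknown rate for the whole cycle.
    """
    costs, tl = params.costs, params.timeline
    pos, neg = (
        costs.fu_brca_positive_per_year,
        costs.fu_brca_negative_or_unknown_per_year,
    )
    detected = detection.carriers_detected
    late_diagnosed = outcome.cancers_unaware
    rest = params.population_size - detected - late_diagnosed
    if rest < 0:
        raise ParameterError("follow-up compartments exceed the population")
    return (
        detected * pos * tl.cycle_years
        + late_diagnosed * (neg * tl.fu_step1_years + pos * tl.fu_step2_years)
        + rest * neg * tl.cycle_years
    )


def screening_visit_cost(
    params: ScenarioParameters,
    screening_active: bool,
    rules: CostRules | None = None,
) -> float:
    """Gyn visit + US billed per screened woman while screening is active.

    The screen is offered to women not already eligible on clinical
    criteria (those proceed straight to testing).
    """
    rules = rules or CostRules()
    if not (screening_active and rules.bill_screening_visit):
        return 0.0
    screened = params.population_size * (1.0 - params.clinical_eligibility_rate)
    return screened * params.costs.gyn_visit_us


def total_cost(
    detection: DetectionResult,
    outcome: CancerOutcome,
    params: ScenarioParameters,
    screening_active: bool,
    rules: CostRules | None = None,
) -> CostBreakdown:
    """Assemble the full cost breakdown for one model x generation."""
    rules = rules or CostRules()
    if params.population_size <= 0:
        raise ParameterError("population_size must be > 0")
    testing = testing_cost(detection.eligible_for_testing, params.costs)
    screening = screening_visit_cost(params, screening_active, rules)
    surgery = surgery_cost(
        detection.carriers_detected, params.surgery_mix, params.costs
    )
    treatment = treatment_cost(outcome, params.costs, rules)
    follow_up = follow_up_cost(detection, outcome, params, rules)
    total = testing + screening + surgery + treatment + follow_up
    per_year_per_person = total / (
        params.timeline.cycle_years * params.population_size
    )
    logger.debug(
        "cost components (EUR): testing %.0f screening %.0f surgery %.0f "
        "treatment %.0f follow-up %.0f total %.0f",
        testing, screening, surgery, treatment, follow_up, total,
    )
    return CostBreakdown(
        testing=testing,
        screening=screening,
        prophylactic_surgery=surgery,
        cancer_treatment=treatment,
        follow_up=follow_up,
        total=total,
        per_year_per_person=per_year_per_person,
    )
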