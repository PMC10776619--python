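"""Carrier detection per model and generation.

The cohort engine works in expected counts, never rounding internally:
``C = N x prevalence`` carriers, of whom a fraction are identified before
cancer onset through three routes:

* **clinical** — established criteria / family history select
  ``N x eligibility_rate`` women; 10 % of them are carriers, so a carrier's
  probability of clinical detection is
  ``r_clin = N x e x positivity / C``;
* **screening** — the radiogenomic ultrasound classifier flags carriers
  with probability ``sensitivity`` (models 2 and 3, while active);
* **cascade** — in generations >= 2, carriers whose family became aware of
  the variant in the previous generation are tested on family history
  alone; the awareness fraction is the state carried between generations.

Generation 1 combines screening and clinical criteria with a union rule
(clinical criteria add only the screen-negative eligible carriers).
Later generations combine the residual channels additively, without
overlap deduction, which is how the source results are constructed; once
screening is withdrawn the default leaves residual carriers to cascade
alone (see :class:`~brcascreen.parameters.ModelConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    ModelConfig,
    ParameterError,
    ScenarioParameters,
    carriers_expected,
)

_TOL = 1e-9


@dataclass(frozen=True)
class DetectionResult:
    """Expected detection compartments for one model x generation."""

    generation_index: int
    carriers_total: float
    eligible_for_testing: float
    carriers_detected: float
    carriers_detected_by_screening: float
    carriers_detected_by_clinical: float
    carriers_detected_by_cascade: float
    carriers_undetected: float

    def __post_init__(self) -> None:
        if self.generation_index < 1:
            raise ParameterError("generation_index must be >= 1")
        routes = (
            self.carriers_detected_by_screening
            + self.carriers_detected_by_clinical
            + self.carriers_detected_by_cascade
        )
        if abs(routes - self.carriers_detected) > 1e-6:
            raise ParameterError(
                "detection routes do not sum to carriers_detected: "
                f"{routes} vs {self.carriers_detected}"
            )
        if not -_TOL <= self.carriers_detected <= self.carriers_total + 1e-6:
            raise ParameterError(
                f"carriers_detected {self.carriers_detected} outside "
                f"[0, {self.carriers_total}]"
            )
        if abs(
            self.carriers_undetected
            - (self.carriers_total - self.carriers_detected)
        ) > 1e-6:
            raise ParameterError("carriers_undetected != total - detected")

    @property
    def detection_rate(self) -> float:
        return (
            self.carriers_detected / self.carriers_total
            if self.carriers_total > 0
            else 0.0
        )


def carriers_total(params: ScenarioParameters) -> float:
    """Expected carriers ``C = N x prevalence``, unrounded (central: 1835.8)."""
    return carriers_expected(params)


def clinical_detection_rate(params: ScenarioParameters) -> float:
    """P(detected via clinical criteria | carrier).

    ``r_clin = N x eligibility x positivity / C`` — the clinically
    detected carriers as a fraction of all carriers (central: 0.14627).
    """
    c = carriers_total(params)
    if c == 0:
        raise ParameterError(
            "clinical detection rate undefined: zero expected carriers"
        )
    detected = (
        params.population_size
        * params.clinical_eligibility_rate
        * params.positivity_among_eligible
    )
    return detected / c


def _clinical_compartments(params: ScenarioParameters) -> tuple[float, float, float]:
    """(clinically eligible women, clinically detected carriers, r_clin).

    With zero expected carriers there is nothing to detect; the rate is
    taken as 0 here (``clinical_detection_rate`` itself raises).
    """
    n_eligible = params.population_size * params.clinical_eligibility_rate
    if carriers_total(params) == 0:
        return n_eligible, 0.0, 0.0
    r_clin = clinical_detection_rate(params)
    return n_eligible, r_clin * carriers_total(params), r_clin


def detect_generation1(
    params: ScenarioParameters, config: ModelConfig
) -> DetectionResult:
    """Generation-1 detection for any of the three models.

    Model 1: clinical route only. Models 2/3 (union rule, default):
    screening detects ``C x sens``; clinical criteria add the
    screen-negative eligible carriers ``r_clin x C x (1 - sens)``.
    Eligible-for-testing counts the screen positives (true and false) plus
    the screen-negative clinically eligible women; this count is
    structurally derived and approximate (the published counts follow
    supplementary assumptions that are not in the main text).
    """
    c = carriers_total(params)
    n = params.population_size
    n_eligible, clin_detected, r_clin = _clinical_compartments(params)

    if not config.screening_active(1):
        if config.model_id != 1 and config.screening is None:
            raise ParameterError(
                f"model {config.model_id} requires screening performance"
            )
        return _result(1, c, eligible=n_eligible, screening=0.0,
                       clinical=clin_detected, cascade=0.0)

    perf = config.screening
    assert perf is not None
    sens, spec = perf.sensitivity, perf.specificity

    screening_route = c * sens
    if config.gen1_rule == "union":
        clinical_route = clin_detected * (1.0 - sens)
    else:  # additive
        clinical_route = clin_detected
    screen_pos = c * sens + (n - c) * (1.0 - spec)
    screen_neg_eligible = (
        (n_eligible - clin_detected) * spec + clin_detected * (1.0 - sens)
    )
    eligible = screen_pos + screen_neg_eligible
    return _result(1, c, eligible=eligible, screening=screening_route,
                   clinical=clinical_route, cascade=0.0)


def detect_cascade_generation(
    params: ScenarioParameters,
    config: ModelConfig,
    prev_awareness_fraction: float,
    generation_index: int = 2,
) -> DetectionResult:
    """Detection in a generation seeded by cascade testing.

    Carriers from aware families (``C x f``) are detected on family
    history alone. The residual ``R = C x (1 - f)`` is picked up by the
    active channels: with screening on, at rate ``min(1, sens + r_clin)``
    (additive residual rule); with screening withdrawn, not at all under
    the default ``cascade_only`` rule, or at ``r_clin`` under the
    ``clinical`` rule. Total detection is capped at ``C``.
    """
    if not 0.0 <= prev_awareness_fraction <= 1.0:
        raise ParameterError(
            f"prev_awareness_fraction must be in [0, 1], got {prev_awareness_fraction}"
        )
    if generation_index < 2:
        raise ParameterError("cascade generations start at index 2")

    c = carriers_total(params)
    n = params.population_size
    f = prev_awareness_fraction
    n_eligible, clin_detected, r_clin = _clinical_compartments(params)
    cascade_route = c * f
    residual = c * (1.0 - f)

    if config.screening_active(generation_index):
        perf = config.screening
        assert perf is not None
        sens, spec = perf.sensitivity, perf.specificity
        if config.residual_rule_active == "additive":
            p_resid = min(1.0, sens + r_clin)
        else:  # union of independent channels
            p_resid = sens + r_clin - sens * r_clin
        resid_detected = residual * p_resid
        # split the residual pickup for route bookkeeping
        if p_resid > 0:
            screening_route = resid_detected * min(sens, p_resid) / p_resid
            clinical_route = resid_detected - screening_route
        else:
            screening_route = clinical_route = 0.0
        eligible = (
            cascade_route
            + resid_detected
            + (n - c) * (1.0 - spec)
            + (n_eligible - clin_detected) * spec
        )
    else:
        if config.residual_rule_inactive == "clinical":
            clinical_route = residual * r_clin
        else:  # cascade_only
            clinical_route = 0.0
        screening_route = 0.0
        eligible = cascade_route + (n_eligible - clin_detected) * (1.0 - f)

    detected = cascade_route + screening_route + clinical_route
    if detected > c:  # cap after the additive rule
        scale = c / detected
        cascade_route *= scale
        screening_route *= scale
        clinical_route *= scale
    return _result(generation_index, c, eligible=eligible,
                   screening=screening_route, clinical=clinical_route,
                   cascade=cascade_route)


def awareness_end_of_cycle(
    detection: DetectionResult, cancers_unaware: float
) -> float:
    """Carriers aware of their status by cycle end.

    Undetected carriers learn their status at cancer diagnosis, so
    end-of-cycle awareness is detected + unaware-cancer cases.
    """
    if cancers_unaware < 0:
        raise ParameterError(f"cancers_unaware must be >= 0, got {cancers_unaware}")
    if cancers_unaware > detection.carriers_undetected + 1e-6:
        raise ParameterError(
            "cancers among unaware carriers exceed undetected carriers: "
            f"{cancers_unaware} > {detection.carriers_undetected}"
        )
    return detection.carriers_detected + cancers_unaware


def _result(
    generation_index: int,
    c: float,
    *,
    eligible: float,
    screening: float,
    clinical: float,
    cascade: float,
) -> DetectionResult:
    detected = screening + clinical + cascade
    return DetectionResult(
        generation_index=generation_index,
        carriers_total=c,
        eligible_for_testing=eligible,
        carriers_detected=detected,
        carriers_detected_by_screening=screening,
        carriers_detected_by_clinical=clinical,
        carriers_detected_by_cascade=cascade,
        carriers_undetected=c - detected,
    )
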