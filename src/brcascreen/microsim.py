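"""Individual-level Monte Carlo microsimulation.

This is the stochastic counterpart of the deterministic cohort engine:
each woman is a Bernoulli/multinomial draw through the same flow —
carrier status, clinical eligibility, screening result, detection,
surgery choice, cancer outcome — so that replicate means converge to the
cohort expectations. It doubles as the package's synthetic-data
generator (per-woman records) and as a validation harness: every cohort
compartment should lie within ~3 Monte Carlo standard errors of the
replicate mean.

Randomness policy: every entry point takes an explicit seed; replicate
seeds are spawned deterministically from the root seed with
``numpy.random.SeedSequence``.

Eligibility is sampled with carrier-dependent probabilities
reverse-engineered from the marginal rates so that expectations match
the cohort engine exactly: ``P(eligible | carrier) = r_clin`` and
``P(eligible | non-carrier) = (N e - r_clin C) / (N - C)``. In cascade
generations the cohort awareness fraction acts as a per-carrier
Bernoulli probability of having an aware first-degree relative (no
explicit pedigree); the residual pickup under active screening is one
Bernoulli draw at the cohort engine's additive rate ``min(1, sens +
r_clin)``, matching its expectation by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import clinical_detection_rate
from .generations import GenerationResult, run_model
from .outcomes import CANCER_TYPES
from .parameters import (
    ModelConfig,
    ParameterError,
    ScenarioParameters,
    SURGERY_STRATA,
    carriers_expected,
)

_CANCER_LEVELS = ("none",) + CANCER_TYPES
_STRATUM_LEVELS = SURGERY_STRATA + ("not_applicable",)


@dataclass
class CohortDraw:
    """Raw per-woman arrays for one simulated cohort (one generation)."""

    is_carrier: np.ndarray
    clinically_eligible: np.ndarray
    screen_result: np.ndarray  # -1 absent, 0 negative, 1 positive
    cascade_flagged: np.ndarray
    tested: np.ndarray
    detected_before_cancer: np.ndarray
    surgery_stratum: np.ndarray  # index into _STRATUM_LEVELS
    cancer_type: np.ndarray  # index into _CANCER_LEVELS
    aware_at_end: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        screen = pd.array(
            np.where(self.screen_result < 0, pd.NA, self.screen_result.astype(bool)),
            dtype="boolean",
        )
        return pd.DataFrame(
            {
                "id": np.arange(len(self.is_carrier)),
                "is_carrier": self.is_carrier,
                "clinically_eligible": self.clinically_eligible,
                "screen_result": screen,
                "tested": self.tested,
                "detected_before_cancer": self.detected_before_cancer,
                "surgery_stratum": pd.Categorical.from_codes(
                    self.surgery_stratum, categories=list(_STRATUM_LEVELS)
                ),
                "cancer_type": pd.Categorical.from_codes(
                    self.cancer_type, categories=list(_CANCER_LEVELS)
                ),
                "aware_at_end": self.aware_at_end,
            }
        )

    def counts(self) -> dict[str, float]:
        carrier = self.is_carrier
        detected = self.detected_before_cancer
        cancer = self.cancer_type > 0
        screen_route = carrier & (self.screen_result == 1) & ~self.cascade_flagged
        cascade_route = carrier & self.cascade_flagged
        clinical_route = detected & ~screen_route & ~cascade_route
        return {
            "carriers": int(carrier.sum()),
            "eligible_for_testing": int(self.tested.sum()),
            "carriers_detected": int(detected.sum()),
            "carriers_detected_by_screening": int(screen_route.sum()),
            "carriers_detected_by_clinical": int(clinical_route.sum()),
            "carriers_detected_by_cascade": int(cascade_route.sum()),
            "cancers_aware": int((cancer & detected).sum()),
            "cancers_unaware": int((cancer & carrier & ~detected).sum()),
            "cancers_total": int((cancer & carrier).sum()),
            "aware_at_end": int(self.aware_at_end.sum()),
        }


def _draw_cohort(
    params: ScenarioParameters,
    config: ModelConfig,
    rng: np.random.Generator,
    generation_index: int,
    prev_awareness_fraction: float,
) -> CohortDraw:
    n = int(params.population_size)
    c_exp = carriers_expected(params)
    r_clin = clinical_detection_rate(params) if c_exp > 0 else 0.0
    e_rate = params.clinical_eligibility_rate
    p_elig_noncarrier = (n * e_rate - r_clin * c_exp) / (n - c_exp)
    if not 0.0 <= p_elig_noncarrier <= 1.0:
        raise ParameterError(
            "implied non-carrier eligibility outside [0, 1]: "
            f"{p_elig_noncarrier}"
        )

    carrier = rng.random(n) < params.prevalence_carriers
    active = config.screening_active(generation_index)
    f = prev_awareness_fraction

    cascade_flagged = np.zeros(n, dtype=bool)
    screen = np.full(n, -1, dtype=np.int8)
    # model 1 without cascade memory re-runs the generation-1 flow each time
    cascading = generation_index > 1 and (
        config.model_id != 1 or config.model1_cascade
    )
    if not cascading:
        eligible = np.where(
            carrier,
            rng.random(n) < r_clin,
            rng.random(n) < p_elig_noncarrier,
        )
        if active:
            perf = config.screening
            assert perf is not None
            u = rng.random(n)
            screen = np.where(
                carrier, u < perf.sensitivity, u < (1.0 - perf.specificity)
            ).astype(np.int8)
        tested = eligible | (screen == 1)
        detected = carrier & tested
    else:
        cascade_flagged = carrier & (rng.random(n) < f)
        residual = carrier & ~cascade_flagged
        if active:
            perf = config.screening
            assert perf is not None
            if config.residual_rule_active == "additive":
                p_resid = min(1.0, perf.sensitivity + r_clin)
            else:
                p_resid = (
                    perf.sensitivity + r_clin - perf.sensitivity * r_clin
                )
            resid_detected = residual & (rng.random(n) < p_resid)
            # attribute the single residual draw to a route, screening first
            if p_resid > 0:
                screen_share = min(perf.sensitivity, p_resid) / p_resid
            else:
                screen_share = 0.0
            screen_hit = resid_detected & (rng.random(n) < screen_share)
            screen[screen_hit] = 1
            screen[residual & ~screen_hit] = 0
            fp = ~carrier & (rng.random(n) < (1.0 - perf.specificity))
            screen[fp] = 1
            eligible = (
                cascade_flagged
                | resid_detected
                | fp
                | (~carrier & (rng.random(n) < p_elig_noncarrier))
            )
            detected = cascade_flagged | resid_detected
        else:
            if config.residual_rule_inactive == "clinical":
                resid_detected = residual & (rng.random(n) < r_clin)
            else:
                resid_detected = np.zeros(n, dtype=bool)
            eligible = (
                cascade_flagged
                | resid_detected
                | (~carrier & (rng.random(n) < p_elig_noncarrier * (1.0 - f)))
            )
            detected = cascade_flagged | resid_detected
        tested = eligible

    # surgery choice for detected carriers; cancer per resulting stratum
    stratum = np.full(n, _STRATUM_LEVELS.index("not_applicable"), dtype=np.int8)
    mix = params.surgery_mix.as_dict()
    mix_p = np.array([mix[s] for s in SURGERY_STRATA])
    idx_detected = np.flatnonzero(detected)
    stratum[idx_detected] = rng.choice(
        len(SURGERY_STRATA), size=idx_detected.size, p=mix_p
    )

    cancer = np.zeros(n, dtype=np.int8)
    for s_idx, s_name in enumerate(SURGERY_STRATA):
        row = params.cancer_risks.stratum(s_name)
        probs = np.array(
            [row.p_no_cancer, row.p_breast_only, row.p_ovarian_only,
             row.p_both_cancers]
        )
        probs = probs / probs.sum()
        if s_name == "none":
            members = np.flatnonzero(carrier & (~detected | (stratum == s_idx)))
        else:
            members = np.flatnonzero(stratum == s_idx)
        cancer[members] = rng.choice(4, size=members.size, p=probs)

    aware = detected | (carrier & (cancer > 0))
    return CohortDraw(
        is_carrier=carrier,
        clinically_eligible=np.asarray(eligible) & ~cascade_flagged,
        screen_result=screen,
        cascade_flagged=cascade_flagged,
        tested=np.asarray(tested),
        detected_before_cancer=detected,
        surgery_stratum=stratum,
        cancer_type=cancer,
        aware_at_end=aware,
    )


def simulate_cohort(
    params: ScenarioParameters,
    config: ModelConfig,
    seed: int,
    generation_index: int = 1,
    prev_awareness_fraction: float = 0.0,
) -> pd.DataFrame:
    """Simulate one cohort and return per-woman records.

    A seed is mandatory: there is no implicit global randomness.
    """
    if seed is None:
        raise ParameterError("an explicit seed is required")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draw = _draw_cohort(
        params, config, rng, generation_index, prev_awareness_fraction
    )
    return draw.to_frame()


#: Compartments compared between microsim and the cohort engine.
_VALIDATED = (
    "carriers",
    "eligible_for_testing",
    "carriers_detected",
    "cancers_aware",
    "cancers_unaware",
    "cancers_total",
    "aware_at_end",
)


@dataclass
class MicrosimSummary:
    """Replicate-level counts with Monte Carlo means, standard errors and
    the cohort engine's closed-form expectations."""

    seed: int
    n_replicates: int
    replicates: pd.DataFrame  # index (replicate, generation), one col/compartment
    table: pd.DataFrame  # index (generation, compartment)
    replicate_seeds: list[int] = field(default_factory=list)

    @property
    def all_within_3se(self) -> bool:
        return bool(self.table["within_3se"].all())


def _cohort_expectations(results: list[GenerationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "generation": r.generation_index,
                "carriers": r.detection.carriers_total,
                "eligible_for_testing": r.detection.eligible_for_testing,
                "carriers_detected": r.detection.carriers_detected,
                "cancers_aware": r.outcome.cancers_aware,
                "cancers_unaware": r.outcome.cancers_unaware,
                "cancers_total": r.outcome.cancers_total,
                "aware_at_end": r.awareness_end,
            }
        )
    return pd.DataFrame(rows).set_index("generation")


def validate_against_cohort(
    params: ScenarioParameters,
    config: ModelConfig,
    n_replicates: int,
    seed: int,
) -> MicrosimSummary:
    """Run replicate microsimulations and compare compartment means with
    the cohort engine's expectations.

    Cascade generations reuse the cohort engine's awareness fractions as
    the per-carrier probability of an aware relative. A compartment is
    flagged when the cohort expectation falls outside the replicate mean
    +- 3 standard errors of the mean.
    """
    if n_replicates < 2:
        raise ParameterError("n_replicates must be >= 2")
    cohort = run_model(params, config)
    expected = _cohort_expectations(cohort)
    fractions = {1: 0.0}
    for r in cohort[:-1]:
        fractions[r.generation_index + 1] = r.awareness_fraction_end

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    rep_rows = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        for g in range(1, config.generations + 1):
            draw = _draw_cohort(params, config, rng, g, fractions[g])
            row = draw.counts()
            row["replicate"] = rep
            row["generation"] = g
            rep_rows.append(row)
    replicates = pd.DataFrame(rep_rows).set_index(["replicate", "generation"])

    records = []
    grouped = replicates.groupby(level="generation")
    means, sds = grouped.mean(), grouped.std(ddof=1)
    for g in range(1, config.generations + 1):
        for comp in _VALIDATED:
            mean = means.loc[g, comp]
            se = sds.loc[g, comp] / np.sqrt(n_replicates)
            exp = expected.loc[g, comp]
            within = bool(abs(exp - mean) <= 3.0 * se) if se > 0 else exp == mean
            records.append(
                {
                    "generation": g,
                    "compartment": comp,
                    "expected": exp,
                    "mean": mean,
                    "se": se,
                    "within_3se": within,
                }
            )
    table = pd.DataFrame(records).set_index(["generation", "compartment"])
    return MicrosimSummary(
        seed=seed,
        n_replicates=n_replicates,
        replicates=replicates,
        table=table,
        replicate_seeds=[int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children],
    )
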