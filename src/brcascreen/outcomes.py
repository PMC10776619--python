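"""Cancer outcomes and healthy-life-years lost.

Carriers detected before cancer onset choose a prophylactic-surgery
stratum (none / RRM only / RRSO only / both) and face that stratum's
lifetime cancer-risk row; undetected carriers face the no-surgery row.
Every cancer case costs the years from the scenario's average onset age
to the model exit age (80), with no disability weighting and no
discounting — the model tracks BRCA-cancer-free life years, not survival.
The output field is ``hly_lost`` (reported alongside the label "DALY"
used in the source tables).
"""

from __future__ import annotations

from dataclasses import dataclass

from .detection import DetectionResult
from .parameters import (
    CancerRiskTable,
    ParameterError,
    ScenarioParameters,
    SurgeryMix,
)

_TOL = 1e-9

CANCER_TYPES = ("breast_only", "ovarian_only", "both_cancers")


@dataclass(frozen=True)
class CancerOutcome:
    """Expected cancer counts by awareness and type, and life-years lost."""

    cancers_aware: float
    cancers_unaware: float
    cancers_total: float
    #: {"aware"|"unaware" -> {"breast_only"|"ovarian_only"|"both_cancers" -> count}}
    by_type: dict[str, dict[str, float]]
    hly_lost: float

    def __post_init__(self) -> None:
        if abs(self.cancers_aware + self.cancers_unaware - self.cancers_total) > 1e-6:
            raise ParameterError("cancers_total != aware + unaware")
        for group, expected in (
            ("aware", self.cancers_aware),
            ("unaware", self.cancers_unaware),
        ):
            total = sum(self.by_type[group].values())
            if abs(total - expected) > 1e-6:
                raise ParameterError(
                    f"by_type[{group}] sums to {total}, expected {expected}"
                )

    def _involved(self, cancer_type: str) -> float:
        return sum(
            self.by_type[group][cancer_type] + self.by_type[group]["both_cancers"]
            for group in ("aware", "unaware")
        )

    @property
    def breast_involved(self) -> float:
        """Cases with breast cancer (alone or with ovarian)."""
        return self._involved("breast_only")

    @property
    def ovarian_involved(self) -> float:
        """Cases with ovarian cancer (alone or with breast)."""
        return self._involved("ovarian_only")

    @property
    def both_cancers(self) -> float:
        return sum(self.by_type[g]["both_cancers"] for g in ("aware", "unaware"))


def cancer_prob_no_surgery(risks: CancerRiskTable) -> float:
    """Lifetime cancer probability without prophylactic surgery
    (central: 0.49 + 0.09 + 0.215 = 0.795)."""
    return risks.none.p_any_cancer


def cancer_prob_aware(mix: SurgeryMix, risks: CancerRiskTable) -> float:
    """Lifetime cancer probability of a carrier aware before onset:
    the surgery-mix-weighted stratum cancer probabilities
    (central: 0.37866)."""
    weights = {
        "none": mix.p_none,
        "rrm_only": mix.p_rrm_only,
        "rrso_only": mix.p_rrso_only,
        "both": mix.p_both,
    }
    return sum(w * risks.stratum(s).p_any_cancer for s, w in weights.items())


def expected_cancers(
    detection: DetectionResult, params: ScenarioParameters
) -> CancerOutcome:
    """Expected cancers and life-years lost for one detection result.

    Aware carriers are weighted over surgery strata; unaware carriers use
    the no-surgery row. Healthy life-years lost are
    ``cancers_total x (exit_age - onset_age)``.
    """
    mix, risks = params.surgery_mix, params.cancer_risks
    weights = {
        "none": mix.p_none,
        "rrm_only": mix.p_rrm_only,
        "rrso_only": mix.p_rrso_only,
        "both": mix.p_both,
    }
    aware_by_type = {t: 0.0 for t in CANCER_TYPES}
    for stratum, w in weights.items():
        row = risks.stratum(stratum)
        aware_by_type["breast_only"] += w * row.p_breast_only
        aware_by_type["ovarian_only"] += w * row.p_ovarian_only
        aware_by_type["both_cancers"] += w * row.p_both_cancers
    n_aware = detection.carriers_detected
    n_unaware = detection.carriers_undetected
    by_type = {
        "aware": {t: n_aware * p for t, p in aware_by_type.items()},
        "unaware": {
            "breast_only": n_unaware * risks.none.p_breast_only,
            "ovarian_only": n_unaware * risks.none.p_ovarian_only,
            "both_cancers": n_unaware * risks.none.p_both_cancers,
        },
    }
    cancers_aware = n_aware * cancer_prob_aware(mix, risks)
    cancers_unaware = n_unaware * cancer_prob_no_surgery(risks)
    total = cancers_aware + cancers_unaware
    hly_lost = total * params.timeline.fu_step2_years
    return CancerOutcome(
        cancers_aware=cancers_aware,
        cancers_unaware=cancers_unaware,
        cancers_total=total,
        by_type=by_type,
        hly_lost=hly_lost,
    )
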