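"""Incremental cost-effectiveness comparisons between models.

The ICER is the incremental total cost divided by the healthy life-years
gained (baseline life-years lost minus alternative life-years lost), per
generation, against model 1 of the same generation. A negative ICER with
positive health gain means the alternative is dominant (cost-saving).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .parameters import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .generations import GenerationResult


@dataclass(frozen=True)
class IcerResult:
    """One baseline-vs-alternative comparison."""

    baseline_model: int
    alternative_model: int
    generation_index: int
    scenario_label: str
    delta_cost_total: float
    delta_cost_per_year_per_person: float
    delta_hly: float
    icer: float | None
    icer_defined: bool


def compare(
    baseline: "GenerationResult", alternative: "GenerationResult"
) -> IcerResult:
    """ICER of ``alternative`` against ``baseline``.

    Both runs must share scenario, generation index and population.
    ``delta_hly`` is baseline-minus-alternative life-years LOST, so it is
    positive when the alternative prevents cancer-years. When
    ``delta_hly`` is zero the ICER is reported as undefined
    (``icer=None``, ``icer_defined=False``), never as infinity.
    """
    if baseline.scenario_label != alternative.scenario_label:
        raise ParameterError(
            "cannot compare runs from different scenarios: "
            f"{baseline.scenario_label} vs {alternative.scenario_label}"
        )
    if baseline.generation_index != alternative.generation_index:
        raise ParameterError(
            "cannot compare different generations: "
            f"{baseline.generation_index} vs {alternative.generation_index}"
        )
    if baseline.population_size != alternative.population_size:
        raise ParameterError("cannot compare runs with different populations")

    delta_cost = alternative.cost.total - baseline.cost.total
    delta_cost_pyp = (
        alternative.cost.per_year_per_person - baseline.cost.per_year_per_person
    )
    delta_hly = baseline.outcome.hly_lost - alternative.outcome.hly_lost
    if delta_hly == 0.0:
        icer, defined = None, False
    else:
        icer, defined = delta_cost / delta_hly, True
    return IcerResult(
        baseline_model=baseline.model_id,
        alternative_model=alternative.model_id,
        generation_index=baseline.generation_index,
        scenario_label=baseline.scenario_label,
        delta_cost_total=delta_cost,
        delta_cost_per_year_per_person=delta_cost_pyp,
        delta_hly=delta_hly,
        icer=icer,
        icer_defined=defined,
    )


def detection_gain_pp(
    baseline: "GenerationResult", alternative: "GenerationResult"
) -> float:
    """Detection-rate gain in percentage points of all carriers:
    ``100 x (alt detected - base detected) / C``
    (model 2 vs 1, generation 1, central: 41.8)."""
    base_det, alt_det = baseline.detection, alternative.detection
    if abs(base_det.carriers_total - alt_det.carriers_total) > 1e-6:
        raise ParameterError("runs have different carrier totals")
    return 100.0 * (
        (alt_det.carriers_detected - base_det.carriers_detected)
        / base_det.carriers_total
    )


def cancer_reduction_pct(
    baseline: "GenerationResult", alternative: "GenerationResult"
) -> float:
    """Relative reduction of expected cancers, in percent
    (model 2 vs 1, generation 1, central: 23.7)."""
    base_total = baseline.outcome.cancers_total
    if base_total <= 0:
        raise ParameterError("baseline has zero cancers; reduction undefined")
    return 100.0 * (base_total - alternative.outcome.cancers_total) / base_total
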