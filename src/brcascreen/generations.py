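"""Multi-generation orchestration: the engine behind the results tables.

Each generation is a fresh cohort of ``N`` eighteen-year-old women with
the same expected carrier count (steady-state population). The only
state carried between generations is the awareness fraction among
carriers: detected carriers plus carriers diagnosed at cancer onset,
divided by all carriers. Models 2/3 run the radiogenomic screen in
generations 1-2 and fall back to clinical criteria + cascade testing in
generation 3; model 1 runs identically every generation (no cascade
memory, matching its single published results column).

All arithmetic is carried at full precision; rounding (half away from
zero) happens only in the display tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from . import economics
from .costs import CostBreakdown, CostRules, total_cost
from .detection import (
    DetectionResult,
    awareness_end_of_cycle,
    detect_cascade_generation,
    detect_generation1,
)
from .outcomes import CancerOutcome, expected_cancers
from .parameters import (
    ModelConfig,
    ParameterError,
    ScenarioParameters,
    builtin_scenario,
    default_config,
)

logger = logging.getLogger("brcascreen")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention; 0.5 -> 1, -0.5 -> -1)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class GenerationResult:
    """All compartments for one model x generation x scenario."""

    model_id: int
    scenario_label: str
    generation_index: int
    population_size: float
    detection: DetectionResult
    outcome: CancerOutcome
    cost: CostBreakdown
    awareness_end: float
    awareness_fraction_end: float

    def __post_init__(self) -> None:
        expected = self.detection.carriers_detected + self.outcome.cancers_unaware
        if abs(self.awareness_end - expected) > 1e-6:
            raise ParameterError("awareness_end != detected + unaware cancers")
        if not 0.0 <= self.awareness_fraction_end <= 1.0 + 1e-9:
            raise ParameterError(
                f"awareness fraction outside [0, 1]: {self.awareness_fraction_end}"
            )


def run_model(
    params: ScenarioParameters,
    config: ModelConfig,
    cost_rules: CostRules | None = None,
) -> list[GenerationResult]:
    """Run one model for ``config.generations`` generations.

    Generation 1 uses the generation-1 detection engine; later
    generations cascade from the previous generation's awareness
    fraction. Model 1 re-runs generation-1 detection each time unless
    ``config.model1_cascade`` is set.
    """
    cost_rules = cost_rules or CostRules()
    results: list[GenerationResult] = []
    awareness_fraction = 0.0
    for g in range(1, config.generations + 1):
        cascading = g > 1 and (config.model_id != 1 or config.model1_cascade)
        if cascading:
            detection = detect_cascade_generation(
                params, config, awareness_fraction, generation_index=g
            )
        elif g == 1:
            detection = detect_generation1(params, config)
        else:  # model 1 without cascade memory: fresh generation-1 run
            det1 = detect_generation1(params, config)
            detection = DetectionResult(
                generation_index=g,
                carriers_total=det1.carriers_total,
                eligible_for_testing=det1.eligible_for_testing,
                carriers_detected=det1.carriers_detected,
                carriers_detected_by_screening=det1.carriers_detected_by_screening,
                carriers_detected_by_clinical=det1.carriers_detected_by_clinical,
                carriers_detected_by_cascade=det1.carriers_detected_by_cascade,
                carriers_undetected=det1.carriers_undetected,
            )
        outcome = expected_cancers(detection, params)
        cost = total_cost(
            detection, outcome, params, config.screening_active(g), cost_rules
        )
        aware_end = awareness_end_of_cycle(detection, outcome.cancers_unaware)
        awareness_fraction = (
            aware_end / detection.carriers_total
            if detection.carriers_total > 0
            else 0.0
        )
        results.append(
            GenerationResult(
                model_id=config.model_id,
                scenario_label=params.scenario_label,
                generation_index=g,
                population_size=params.population_size,
                detection=detection,
                outcome=outcome,
                cost=cost,
                awareness_end=aware_end,
                awareness_fraction_end=min(awareness_fraction, 1.0),
            )
        )
    return results


def run_scenario(
    params: ScenarioParameters,
    generations: int = 3,
    cost_rules: CostRules | None = None,
) -> dict[int, list[GenerationResult]]:
    """Run all three models on one scenario."""
    return {
        m: run_model(params, default_config(m, generations), cost_rules)
        for m in (1, 2, 3)
    }


def build_table2(
    results_by_model: dict[int, list[GenerationResult]],
    raw: bool = False,
) -> pd.DataFrame:
    """Assemble the main results table: one column per model x generation
    (model 1 collapsed to a single column when generation-invariant).

    Rows: eligible for testing, carriers detected, cancers among aware /
    unaware carriers, total cancers, healthy life-years lost (the source
    tables label this DALY), total direct cost (billions EUR) and cost
    per year per person. Display rounding is half away from zero; pass
    ``raw=True`` for unrounded values.
    """
    if not results_by_model or any(not v for v in results_by_model.values()):
        raise ParameterError("no generation results to tabulate")
    scenarios = {
        r.scenario_label for runs in results_by_model.values() for r in runs
    }
    if len(scenarios) > 1:
        raise ParameterError(f"mixed scenarios in one table: {sorted(scenarios)}")

    columns: dict[str, GenerationResult] = {}
    for model_id in sorted(results_by_model):
        runs = results_by_model[model_id]
        invariant = model_id == 1 and all(
            abs(r.outcome.cancers_total - runs[0].outcome.cancers_total) < 1e-6
            for r in runs
        )
        if invariant:
            columns[f"model{model_id}"] = runs[0]
        else:
            for r in runs:
                columns[f"model{model_id}_gen{r.generation_index}"] = r

    def row(extract, ndigits=0):
        return {
            name: round_half_away(extract(r), ndigits) if not raw else extract(r)
            for name, r in columns.items()
        }

    data = {
        "eligible_for_testing": row(lambda r: r.detection.eligible_for_testing),
        "carriers_detected": row(lambda r: r.detection.carriers_detected),
        "cancers_aware_carriers": row(lambda r: r.outcome.cancers_aware),
        "cancers_unaware_carriers": row(lambda r: r.outcome.cancers_unaware),
        "cancers_total": row(lambda r: r.outcome.cancers_total),
        "hly_lost (DALY)": row(lambda r: r.outcome.hly_lost),
        "total_cost_billion_eur": row(lambda r: r.cost.total / 1e9, 2),
        "cost_per_year_per_person_eur": row(
            lambda r: r.cost.per_year_per_person, 2
        ),
    }
    return pd.DataFrame(data).T[list(columns)]


def build_table3(
    scenarios: tuple[str, ...] = ("central", "best", "worst"),
    generations: int = 3,
    cost_rules: CostRules | None = None,
    raw: bool = False,
) -> pd.DataFrame:
    """ICER of models 2 and 3 vs model 1, per generation and scenario."""
    frames: dict[str, dict[str, float]] = {}
    for label in scenarios:
        params = builtin_scenario(label)
        runs = run_scenario(params, generations, cost_rules)
        col: dict[str, float] = {}
        for g in range(1, generations + 1):
            for alt in (2, 3):
                icer = economics.compare(runs[1][g - 1], runs[alt][g - 1])
                value = icer.icer if icer.icer_defined else float("nan")
                if not raw and value == value:
                    value = round_half_away(value)
                col[f"gen{g}_model{alt}_vs_1"] = value
        frames[label] = col
    return pd.DataFrame(frames)
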