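"""Parameter schema: built-in scenarios, validation, YAML round-trips."""

import dataclasses

import pytest
import yaml

from brcascreen import (
    ParameterError,
    SurgeryMix,
    builtin_scenario,
    default_config,
    load_parameters,
    save_parameters,
)
from brcascreen.parameters import SCENARIO_LABELS, packaged_scenario_path


@pytest.mark.parametrize("label", SCENARIO_LABELS)
def test_builtin_scenarios_validate_and_sum_to_one(label):
    params = builtin_scenario(label)
    assert params.scenario_label == label
    mix = params.surgery_mix
    assert mix.p_both + mix.p_rrso_only + mix.p_rrm_only + mix.p_none == pytest.approx(1, abs=1e-9)
    for _, row in params.cancer_risks.items():
        total = (
            row.p_breast_only + row.p_ovarian_only
            + row.p_both_cancers + row.p_no_cancer
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_builtin_scenario_is_pure():
    assert builtin_scenario("central") == builtin_scenario("central")
    assert builtin_scenario("best") != builtin_scenario("worst")


def test_central_values_match_input_table():
    p = builtin_scenario("central")
    assert p.prevalence_carriers == 0.0067
    assert p.clinical_eligibility_rate == 0.0098
    assert p.positivity_among_eligible == 0.10
    assert p.population_size == 274000
    assert p.surgery_mix.p_none == 0.2385
    assert p.cancer_risks.none.p_breast_only == 0.49
    assert p.cancer_risks.both.p_no_cancer == 0.9529
    assert p.costs.genetic_counselling_testing == 1099.48
    assert p.costs.parp_inhibitor == 82344.00
    assert p.timeline.fu_step1_years == 27
    assert p.timeline.fu_step2_years == 35
    assert p.timeline.cycle_years == 62


def test_scenario_columns_differ_where_the_table_does():
    best, worst = builtin_scenario("best"), builtin_scenario("worst")
    assert worst.prevalence_carriers == 0.0077
    assert worst.clinical_eligibility_rate == 0.0179
    assert best.timeline.cancer_onset_age == 60
    assert best.timeline.fu_step2_years == 20
    # costs are scenario-invariant (single tariff per row)
    assert best.costs == worst.costs == builtin_scenario("central").costs


def test_best_case_no_surgery_block_renormalized():
    # printed rows sum to 100.02 %; loaded values are renormalized to 1
    row = builtin_scenario("best").cancer_risks.none
    assert row.p_breast_only == pytest.approx(0.4820 / 1.0002)
    assert row.p_any_cancer + row.p_no_cancer == pytest.approx(1.0, abs=1e-12)


def test_unknown_scenario_label_names_valid_ones():
    with pytest.raises(ParameterError, match="central"):
        builtin_scenario("median")


@pytest.mark.parametrize("label", SCENARIO_LABELS)
def test_yaml_round_trip_identity(label, tmp_path):
    params = builtin_scenario(label)
    path = tmp_path / f"{label}.yaml"
    save_parameters(params, path)
    assert load_parameters(path) == params


@pytest.mark.parametrize("label", SCENARIO_LABELS)
def test_packaged_fixture_equals_builtin(label):
    assert load_parameters(packaged_scenario_path(label)) == builtin_scenario(label)


def _dump(data, tmp_path):
    path = tmp_path / "params.yaml"
    path.write_text(yaml.safe_dump(data))
    return path


def test_load_rejects_bad_surgery_mix_sum(central, tmp_path):
    data = central.to_dict()
    data["surgery_mix"]["none"] = 0.5
    with pytest.raises(ParameterError):
        load_parameters(_dump(data, tmp_path))


def test_load_rejects_bad_stratum_sum_naming_stratum(central, tmp_path):
    data = central.to_dict()
    data["cancer_risks"]["rrso_only"]["no_cancer"] = 0.9
    with pytest.raises(ParameterError, match="rrso_only"):
        load_parameters(_dump(data, tmp_path))


def test_load_missing_cost_names_field(central, tmp_path):
    data = central.to_dict()
    del data["costs"]["parp_inhibitor"]
    with pytest.raises(ParameterError, match="parp_inhibitor"):
        load_parameters(_dump(data, tmp_path))


def test_load_rejects_out_of_range_probability(central, tmp_path):
    data = central.to_dict()
    data["prevalence_carriers"] = 1.5
    with pytest.raises(ParameterError, match="prevalence_carriers"):
        load_parameters(_dump(data, tmp_path))


def test_surgery_mix_must_sum_to_one():
    with pytest.raises(ParameterError):
        SurgeryMix(p_both=0.5, p_rrso_only=0.5, p_rrm_only=0.5, p_none=0.5)


def test_timeline_consistency_enforced(central):
    bad = dataclasses.asdict(central.timeline)
    bad["fu_step1_years"] = 30
    from brcascreen import Timeline
    with pytest.raises(ParameterError, match="fu_step1_years"):
        Timeline(**bad)


def test_model_config_screening_presence():
    cfg2 = default_config(2)
    assert cfg2.screening.sensitivity == 0.49
    assert cfg2.screening.specificity == 0.87
    assert cfg2.screening_active_generations == frozenset({1, 2})
    cfg1 = default_config(1)
    assert cfg1.screening is None
    assert cfg1.screening_active_generations == frozenset()
    with pytest.raises(ParameterError):
        default_config(4)
    from brcascreen import ModelConfig, TestPerformance
    with pytest.raises(ParameterError):
        ModelConfig(model_id=2, screening=None)
    with pytest.raises(ParameterError):
        ModelConfig(model_id=1, screening=TestPerformance(0.5, 0.9))
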