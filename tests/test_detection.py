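"""Detection engine against closed-form arithmetic oracles.

Oracle values are computed here by direct arithmetic on the input-table
numbers (expected counts = population x rates), independent of the
engine's internals.
"""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from brcascreen import (
    ModelConfig,
    ParameterError,
    TestPerformance as ScreenPerformance,
    awareness_end_of_cycle,
    builtin_scenario,
    carriers_total,
    clinical_detection_rate,
    default_config,
    detect_cascade_generation,
    detect_generation1,
)

# direct-arithmetic oracles, central column
C = 274000 * 0.0067            # 1835.8 carriers
N_ELIG = 274000 * 0.0098       # 2685.2 clinically eligible women
CLIN = N_ELIG * 0.10           # 268.52 clinically detected carriers
R_CLIN = CLIN / C


def test_carriers_total_is_population_times_prevalence(central, best):
    assert carriers_total(central) == pytest.approx(1835.8)
    assert carriers_total(best) == pytest.approx(274000 * 0.0059)
    zero = dataclasses.replace(central, prevalence_carriers=0.0,
                               prevalence_in_not_eligible=0.0,
                               clinical_eligibility_rate=0.0)
    assert carriers_total(zero) == 0.0


def test_clinical_detection_rate(central):
    assert clinical_detection_rate(central) == pytest.approx(R_CLIN)
    assert clinical_detection_rate(central) == pytest.approx(0.1463, abs=5e-5)
    nopos = dataclasses.replace(central, positivity_among_eligible=0.0)
    assert clinical_detection_rate(nopos) * carriers_total(nopos) == 0.0


def test_clinical_rate_errors_on_zero_carriers(central):
    zero = dataclasses.replace(central, prevalence_carriers=0.0,
                               prevalence_in_not_eligible=0.0,
                               clinical_eligibility_rate=0.0)
    with pytest.raises(ParameterError):
        clinical_detection_rate(zero)


def test_model1_generation1(central, configs):
    det = detect_generation1(central, configs[1])
    assert det.eligible_for_testing == pytest.approx(N_ELIG)
    assert det.carriers_detected == pytest.approx(CLIN)
    assert det.carriers_detected_by_clinical == pytest.approx(CLIN)
    assert det.carriers_detected_by_screening == 0.0
    assert det.carriers_undetected == pytest.approx(C - CLIN)


def test_model2_generation1_union_decomposition(central, configs):
    det = detect_generation1(central, configs[2])
    assert det.carriers_detected_by_screening == pytest.approx(C * 0.49)
    assert det.carriers_detected_by_clinical == pytest.approx(CLIN * 0.51)
    assert det.carriers_detected == pytest.approx(C * 0.49 + CLIN * 0.51)
    assert round(det.carriers_detected_by_screening) == 900
    assert round(det.carriers_detected) == 1036


def test_model3_generation1(central, configs):
    det = detect_generation1(central, configs[3])
    assert det.carriers_detected == pytest.approx(C * 0.80 + CLIN * 0.20)
    assert round(det.carriers_detected) == 1522


def test_perfect_test_detects_all_carriers(central):
    cfg = ModelConfig(model_id=2, screening=ScreenPerformance(1.0, 1.0))
    det = detect_generation1(central, cfg)
    assert det.carriers_detected == pytest.approx(C)
    # with perfect specificity the only extra eligible women are the
    # clinically eligible non-carriers (screen-negative, still eligible)
    assert det.eligible_for_testing == pytest.approx(C + (N_ELIG - CLIN))


def test_cascade_generation2_additive_residual(central, configs):
    det1 = detect_generation1(central, configs[2])
    f1 = (det1.carriers_detected + (C - det1.carriers_detected) * 0.795) / C
    det2 = detect_cascade_generation(central, configs[2], f1, 2)
    expected = C * f1 + C * (1 - f1) * (0.49 + R_CLIN)
    assert det2.carriers_detected == pytest.approx(expected)
    assert round(det2.carriers_detected) == 1776
    assert det2.carriers_detected_by_cascade == pytest.approx(C * f1)


def test_cascade_screening_withdrawn_default_cascade_only(central, configs):
    det3 = detect_cascade_generation(central, configs[2], 0.9934, 3)
    assert det3.carriers_detected == pytest.approx(C * 0.9934)
    assert det3.carriers_detected_by_clinical == 0.0


def test_cascade_screening_withdrawn_clinical_rule(central):
    cfg = default_config(2, residual_rule_inactive="clinical")
    det3 = detect_cascade_generation(central, cfg, 0.9934, 3)
    assert det3.carriers_detected == pytest.approx(
        C * 0.9934 + C * (1 - 0.9934) * R_CLIN
    )


def test_full_awareness_saturates(central, configs):
    det = detect_cascade_generation(central, configs[2], 1.0, 2)
    assert det.carriers_detected == pytest.approx(C)
    assert det.carriers_undetected == pytest.approx(0.0, abs=1e-9)


def test_awareness_end_of_cycle(central, configs):
    det = detect_generation1(central, configs[2])
    unaware_cancers = (C - det.carriers_detected) * 0.795
    aware = awareness_end_of_cycle(det, unaware_cancers)
    assert round(aware) == 1672
    with pytest.raises(ParameterError):
        awareness_end_of_cycle(det, -1.0)
    with pytest.raises(ParameterError):
        awareness_end_of_cycle(det, det.carriers_undetected + 1.0)


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    sens_lo=st.floats(0.0, 1.0),
    sens_delta=st.floats(0.0, 1.0),
    spec=st.floats(0.0, 1.0),
)
def test_detection_monotone_in_sensitivity(sens_lo, sens_delta, spec):
    params = builtin_scenario("central")
    sens_hi = min(1.0, sens_lo + sens_delta)
    lo = detect_generation1(
        params, ModelConfig(2, ScreenPerformance(sens_lo, spec))
    )
    hi = detect_generation1(
        params, ModelConfig(2, ScreenPerformance(sens_hi, spec))
    )
    assert hi.carriers_detected >= lo.carriers_detected - 1e-9
    assert lo.carriers_detected <= lo.carriers_total + 1e-9


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    f_lo=st.floats(0.0, 1.0),
    f_delta=st.floats(0.0, 1.0),
    model=st.sampled_from([2, 3]),
)
def test_cascade_monotone_in_awareness_and_capped(f_lo, f_delta, model):
    params = builtin_scenario("central")
    cfg = default_config(model)
    f_hi = min(1.0, f_lo + f_delta)
    lo = detect_cascade_generation(params, cfg, f_lo, 2)
    hi = detect_cascade_generation(params, cfg, f_hi, 2)
    assert hi.carriers_detected >= lo.carriers_detected - 1e-9
    for det in (lo, hi):
        assert det.carriers_detected <= det.carriers_total + 1e-9
        routes = (
            det.carriers_detected_by_screening
            + det.carriers_detected_by_clinical
            + det.carriers_detected_by_cascade
        )
        assert routes == pytest.approx(det.carriers_detected)


def test_zero_sensitivity_screen_reduces_to_model1_detection(central, configs):
    cfg = ModelConfig(2, ScreenPerformance(0.0, 1.0))
    det = detect_generation1(central, cfg)
    det1 = detect_generation1(central, configs[1])
    assert det.carriers_detected == pytest.approx(det1.carriers_detected)
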