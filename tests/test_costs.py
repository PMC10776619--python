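"""Cost components against direct tariff arithmetic."""

import dataclasses

import pytest

from brcascreen import (
    CostRules,
    ParameterError,
    detect_generation1,
    expected_cancers,
    follow_up_cost,
    screening_visit_cost,
    surgery_cost,
    testing_cost as compute_testing_cost,
    total_cost,
    treatment_cost,
)

OVARIAN_BUNDLE = 6791.00 + 2226.00 + 82344.00      # 91,361.00
BREAST_BUNDLE = 3524.45 + 2226.00 + 6000.00        # 11,750.45
PER_CARRIER_SURGERY = (
    0.2585 * (1436.00 + 1960.00) + 0.2915 * 1436.00 + 0.2115 * 1960.00
)


def test_testing_cost(central):
    assert compute_testing_cost(2685.2, central.costs) == pytest.approx(2685.2 * 1099.48)
    assert compute_testing_cost(0.0, central.costs) == 0.0
    with pytest.raises(ParameterError):
        compute_testing_cost(-1.0, central.costs)


def test_surgery_cost_per_carrier_expectation(central):
    assert PER_CARRIER_SURGERY == pytest.approx(1711.00)
    assert surgery_cost(268.52, central.surgery_mix, central.costs) == (
        pytest.approx(268.52 * PER_CARRIER_SURGERY)
    )
    no_surgery = dataclasses.replace(
        central.surgery_mix, p_both=0.0, p_rrso_only=0.0, p_rrm_only=0.0,
        p_none=1.0,
    )
    assert surgery_cost(1000.0, no_surgery, central.costs) == 0.0


def test_treatment_bundles(central, configs):
    det = detect_generation1(central, configs[1])
    out = expected_cancers(det, central)
    expected = (
        out.ovarian_involved * OVARIAN_BUNDLE
        + out.breast_involved * BREAST_BUNDLE
    )
    assert treatment_cost(out, central.costs) == pytest.approx(expected)
    # restricting PARP reduces only the ovarian bundle
    half = treatment_cost(out, central.costs, CostRules(parp_fraction=0.5))
    assert half == pytest.approx(expected - out.ovarian_involved * 0.5 * 82344.00)


def test_follow_up_rates(central, configs):
    tl = central.timeline
    assert 69.60 * tl.cycle_years == pytest.approx(4315.20)
    assert 198.20 * tl.cycle_years == pytest.approx(12288.40)
    assert 69.60 * tl.fu_step1_years + 198.20 * tl.fu_step2_years == (
        pytest.approx(8816.20)
    )
    det = detect_generation1(central, configs[1])
    out = expected_cancers(det, central)
    expected = (
        det.carriers_detected * 12288.40
        + out.cancers_unaware * 8816.20
        + (274000 - det.carriers_detected - out.cancers_unaware) * 4315.20
    )
    assert follow_up_cost(det, out, central) == pytest.approx(expected)


def test_screening_visit_billed_only_when_active(central):
    active = screening_visit_cost(central, True)
    assert active == pytest.approx(274000 * (1 - 0.0098) * 51.65)
    assert screening_visit_cost(central, False) == 0.0
    assert screening_visit_cost(
        central, True, CostRules(bill_screening_visit=False)
    ) == 0.0


def test_total_cost_components_sum_and_per_person(central, configs):
    det = detect_generation1(central, configs[2])
    out = expected_cancers(det, central)
    cb = total_cost(det, out, central, screening_active=True)
    parts = (
        cb.testing + cb.screening + cb.prophylactic_surgery
        + cb.cancer_treatment + cb.follow_up
    )
    assert cb.total == pytest.approx(parts, abs=0.01)
    assert cb.per_year_per_person == pytest.approx(cb.total / (62 * 274000))


def test_model1_total_dominated_by_standard_follow_up(central, configs):
    det = detect_generation1(central, configs[1])
    out = expected_cancers(det, central)
    cb = total_cost(det, out, central, screening_active=False)
    assert cb.follow_up > 1.1e9  # ~272k women at 4315.20 EUR standard care
    assert cb.follow_up / cb.total > 0.9


def test_cost_ordering_generation1(central_runs):
    g1 = {m: central_runs[m][0].cost.total for m in (1, 2, 3)}
    assert g1[2] > g1[3] > g1[1]


def test_generation3_cheaper_than_model1(central_runs):
    m1 = central_runs[1][0].cost.total
    assert central_runs[2][2].cost.total < m1
    assert central_runs[3][2].cost.total < m1


def test_zero_sensitivity_screen_restores_model1_testing_cost(central, configs):
    from brcascreen import ModelConfig, TestPerformance
    cfg = ModelConfig(2, TestPerformance(0.0, 1.0))
    det = detect_generation1(central, cfg)
    det1 = detect_generation1(central, configs[1])
    assert compute_testing_cost(det.eligible_for_testing, central.costs) == (
        pytest.approx(compute_testing_cost(det1.eligible_for_testing, central.costs))
    )
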