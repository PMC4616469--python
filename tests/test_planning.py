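"""Activity planning: PM inversion, tolerance caps, BSA method, LSF reduction."""

import numpy as np
import pytest

import sirtdose as sd
from sirtdose.compartments import IN_TARGET, LUNG, OUT_TARGET, TUMOR
from sirtdose.errors import PatientExcludedError, PlanningError
from sirtdose.quantify import VOIMeasurement

from conftest import random_measurements


def test_required_activity_closed_form(fixed_measurements):
    """f_tm = 0.95*0.8 = 0.76, tumor mass 0.5 kg, 120 Gy -> 1.5894 GBq."""
    a = sd.activity_for_tumor_dose(fixed_measurements, 120.0)
    assert a == pytest.approx(120.0 * 0.5 / (49.67 * 0.76), rel=1e-12)
    assert a == pytest.approx(1.589438, rel=1e-6)


def test_required_activity_zero_target(fixed_measurements):
    assert sd.activity_for_tumor_dose(fixed_measurements, 0.0) == 0.0


def test_required_activity_round_trip(fixed_measurements):
    for target in (60.0, 120.0, 205.0):
        a = sd.activity_for_tumor_dose(fixed_measurements, target)
        assert sd.dose_report(a, fixed_measurements).absorbed_dose_gy[TUMOR] == pytest.approx(
            target, rel=1e-9
        )


def test_required_activity_no_tumor_counts_raises():
    m = sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(100.0, 0.0),
        in_target=VOIMeasurement.from_totals(500.0, 100.0),
        out_target=VOIMeasurement.from_totals(100.0, 10.0),
        lsf=0.05,
    )
    with pytest.raises(PlanningError):
        sd.activity_for_tumor_dose(m, 120.0)


def test_lung_tolerance_hand_value(fixed_measurements):
    """20 Gy x 0.99 kg / (49.67 x 0.05) = 7.9726 GBq."""
    a = sd.tolerance_activity(fixed_measurements, LUNG, 20.0)
    assert a == pytest.approx(7.972619287, rel=1e-9)


def test_out_target_tolerance_hand_value(fixed_measurements):
    """30 Gy x 0.3 kg / (49.67 x 0.0475) = 3.81465 GBq."""
    a = sd.tolerance_activity(fixed_measurements, OUT_TARGET, 30.0)
    assert a == pytest.approx(3.814650377, rel=1e-9)


def test_tolerance_unbounded_for_zero_fraction_compartment(fixed_measurements):
    m = sd.PartitionMeasurements(
        tumor=fixed_measurements.tumor,
        in_target=fixed_measurements.in_target,
        out_target=VOIMeasurement.from_totals(300.0, 0.0),
        lsf=0.05,
    )
    assert sd.tolerance_activity(m, OUT_TARGET, 30.0) == sd.UNBOUNDED


def test_tolerance_monotone_in_limit(fixed_measurements):
    lo = sd.tolerance_activity(fixed_measurements, LUNG, 10.0)
    hi = sd.tolerance_activity(fixed_measurements, LUNG, 20.0)
    assert hi > lo


def test_plan_feasible_when_tolerances_not_binding(fixed_measurements):
    plan = sd.plan_partition_model(fixed_measurements)
    assert plan.feasible
    assert plan.limiting_constraint is None
    assert plan.recommended_activity_gbq == pytest.approx(plan.required_activity_gbq)
    assert plan.reduction_fraction == 0.0
    # tumor dose at the recommendation meets the 120 Gy requirement exactly
    dose = sd.dose_report(plan.recommended_activity_gbq, fixed_measurements)
    assert dose.absorbed_dose_gy[TUMOR] == pytest.approx(120.0, rel=1e-9)


def test_plan_caps_at_binding_out_target_tolerance(fixed_measurements):
    """An out-target tolerance at 86% of the required activity caps the plan
    with a 14% reduction (the reduced-injection scenario)."""
    required = sd.activity_for_tumor_dose(fixed_measurements, 120.0)
    # choose the out-target limit so its tolerance activity is 0.86 x required
    per_gbq = 30.0 / sd.tolerance_activity(fixed_measurements, OUT_TARGET, 30.0)
    limit = 0.86 * required * per_gbq
    c = sd.PlanningConstraints(out_target_limit_gy=limit, use_out_target_limit=True)
    plan = sd.plan_partition_model(fixed_measurements, c)
    assert not plan.feasible
    assert plan.limiting_constraint == OUT_TARGET
    assert plan.reduction_fraction == pytest.approx(0.14, rel=1e-9)
    assert plan.recommended_activity_gbq == pytest.approx(0.86 * required, rel=1e-9)


def test_plan_excludes_high_lsf(fixed_measurements):
    m = sd.PartitionMeasurements(
        tumor=fixed_measurements.tumor,
        in_target=fixed_measurements.in_target,
        out_target=fixed_measurements.out_target,
        lsf=0.25,
    )
    with pytest.raises(PatientExcludedError):
        sd.plan_partition_model(m)


def test_plan_switches_to_out_target_for_small_in_target():
    m = sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(500.0, 800.0),
        in_target=VOIMeasurement.from_totals(40.0, 30.0),  # < 10% of liver
        out_target=VOIMeasurement.from_totals(600.0, 100.0),
        lsf=0.05,
    )
    plan = sd.plan_partition_model(m)
    assert plan.used_out_target_limit
    assert OUT_TARGET in plan.tolerance_activities_gbq
    assert IN_TARGET not in plan.tolerance_activities_gbq


def test_plan_invariant_to_count_scale(fixed_measurements):
    m = fixed_measurements
    scaled = sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(m.tumor.volume_ml, 11.0 * m.tumor.total_counts),
        in_target=VOIMeasurement.from_totals(m.in_target.volume_ml, 11.0 * m.in_target.total_counts),
        out_target=VOIMeasurement.from_totals(m.out_target.volume_ml, 11.0 * m.out_target.total_counts),
        lsf=m.lsf,
        lung_volume_ml=m.lung_volume_ml,
    )
    p1 = sd.plan_partition_model(m)
    p2 = sd.plan_partition_model(scaled)
    assert p2.required_activity_gbq == pytest.approx(p1.required_activity_gbq, rel=1e-12)
    assert p2.recommended_activity_gbq == pytest.approx(p1.recommended_activity_gbq, rel=1e-12)


def test_plan_respects_tolerances_over_random_cases():
    """Doses at the recommended activity never exceed the applied limits."""
    rng = np.random.default_rng(21)
    c = sd.PlanningConstraints()
    checked = 0
    while checked < 300:
        m = random_measurements(rng)
        try:
            plan = sd.plan_partition_model(m, c)
        except PatientExcludedError:
            continue
        rep = sd.dose_report(plan.recommended_activity_gbq, m)
        assert rep.absorbed_dose_gy[LUNG] <= c.lung_limit_gy * (1 + 1e-9)
        liver_limit = (
            (OUT_TARGET, c.out_target_limit_gy)
            if plan.used_out_target_limit
            else (IN_TARGET, c.in_target_limit_gy)
        )
        assert rep.absorbed_dose_gy[liver_limit[0]] <= liver_limit[1] * (1 + 1e-9)
        checked += 1


def test_bsa_hand_value():
    """DuBois 170 cm / 70 kg = 1.8097 m²; 10% involvement -> 1.7097 GBq."""
    assert sd.body_surface_area(170.0, 70.0) == pytest.approx(1.809708, rel=1e-6)
    assert sd.bsa_activity(170.0, 70.0, 100.0, 1000.0) == pytest.approx(1.709708, rel=1e-6)


def test_bsa_activity_monotone_in_involvement():
    a_low = sd.bsa_activity(170.0, 70.0, 50.0, 1000.0)
    a_high = sd.bsa_activity(170.0, 70.0, 500.0, 1000.0)
    assert a_high > a_low
    # involvement -> 0 limit approaches BSA - 0.2
    tiny = sd.bsa_activity(170.0, 70.0, 1e-9, 1000.0)
    assert tiny == pytest.approx(sd.body_surface_area(170.0, 70.0) - 0.2, abs=1e-9)


def test_bsa_validation():
    with pytest.raises(ValueError):
        sd.bsa_activity(170.0, 70.0, 1200.0, 1000.0)
    with pytest.raises(ValueError):
        sd.bsa_activity(0.0, 70.0, 100.0, 1000.0)


@pytest.mark.parametrize(
    "lsf,factor",
    [(0.0, 1.0), (0.05, 1.0), (0.099, 1.0), (0.10, 0.8), (0.149, 0.8), (0.15, 0.6), (0.18, 0.6), (0.199, 0.6)],
)
def test_lsf_reduction_bands(lsf, factor):
    assert sd.lsf_reduction(1.5, lsf) == pytest.approx(1.5 * factor)


def test_lsf_reduction_excludes_at_threshold():
    for lsf in (0.20, 0.22, 0.5):
        with pytest.raises(PatientExcludedError):
            sd.lsf_reduction(1.0, lsf)
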