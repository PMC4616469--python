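"""Partition-model dosimetry: masses, apportionment, absorbed dose."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sirtdose as sd
from sirtdose.compartments import COMPARTMENTS, LIVER_PARTITIONS, LUNG, TUMOR
from sirtdose.errors import ApportionmentError, UndefinedDoseError
from sirtdose.quantify import VOIMeasurement

from conftest import random_measurements


@pytest.mark.parametrize(
    "volume_ml,compartment,expected_kg",
    [
        (500.0, "tumor", 0.5),          # unit density soft tissue
        (3300.0, "lung", 0.99),         # 3.3 L lung at 0.3 kg/L
        (0.0, "in_target_liver", 0.0),
        (1234.0, "out_target_liver", 1.234),
    ],
)
def test_compartment_mass(volume_ml, compartment, expected_kg):
    assert sd.compartment_mass(volume_ml, compartment) == pytest.approx(expected_kg)


def test_compartment_mass_rejects_unknown_tag():
    with pytest.raises(ValueError):
        sd.compartment_mass(100.0, "spleen")


def test_apportionment_hand_example(fixed_measurements):
    """2 GBq at LSF 0.05 with liver counts 800/150/50 splits 0.10/1.52/0.285/0.095."""
    a0 = sd.apportion_activity(2.0, fixed_measurements)
    assert a0[LUNG] == pytest.approx(0.10, rel=1e-12)
    assert a0[TUMOR] == pytest.approx(1.52, rel=1e-12)
    assert a0["in_target_liver"] == pytest.approx(0.285, rel=1e-12)
    assert a0["out_target_liver"] == pytest.approx(0.095, rel=1e-12)


def test_apportionment_all_counts_in_tumor_zero_lsf():
    m = sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(400.0, 900.0),
        in_target=VOIMeasurement.from_totals(600.0, 0.0),
        out_target=VOIMeasurement.from_totals(200.0, 0.0),
        lsf=0.0,
    )
    a0 = sd.apportion_activity(1.7, m)
    assert a0[TUMOR] == pytest.approx(1.7)
    assert a0[LUNG] == 0.0


def test_apportionment_no_liver_counts_raises():
    m = sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(400.0, 0.0),
        in_target=VOIMeasurement.from_totals(600.0, 0.0),
        out_target=VOIMeasurement.from_totals(200.0, 0.0),
        lsf=0.1,
    )
    with pytest.raises(ApportionmentError):
        sd.apportion_activity(1.0, m)


def test_activity_conservation_is_exact_over_random_inputs():
    rng = np.random.default_rng(7)
    for _ in range(500):
        m = random_measurements(rng)
        injected = float(rng.uniform(0.1, 5.0))
        a0 = sd.apportion_activity(injected, m)
        assert sum(a0.values()) == pytest.approx(injected, rel=1e-12)


@given(
    injected=st.floats(0.0, 10.0),
    counts=st.tuples(*[st.floats(0.0, 5000.0)] * 3).filter(lambda c: sum(c) > 0),
    lsf=st.floats(0.0, 0.99),
)
@settings(max_examples=200, deadline=None)
def test_conservation_property(injected, counts, lsf):
    m = sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(100.0, counts[0]),
        in_target=VOIMeasurement.from_totals(100.0, counts[1]),
        out_target=VOIMeasurement.from_totals(100.0, counts[2]),
        lsf=lsf,
    )
    a0 = sd.apportion_activity(injected, m)
    assert sum(a0.values()) == pytest.approx(injected, rel=1e-9, abs=1e-12)


def test_absorbed_dose_reference_point():
    """1 GBq in 1 kg gives the integrated-dose constant, 49.67 Gy."""
    assert sd.absorbed_dose(1.0, 1.0) == pytest.approx(49.67)


def test_dose_constant_consistent_with_physical_decay_integral():
    """Integrating all decays of the 2.67-day, 0.927-MeV beta emitter gives
    an energy-per-mass within 1% of the pinned 49.67 Gy·kg/GBq constant."""
    mean_life_s = 2.67 * 86400.0 / math.log(2.0)
    j_per_decay = 0.927 * 1.602176634e-13
    gy_kg_per_gbq = 1e9 * mean_life_s * j_per_decay
    assert gy_kg_per_gbq == pytest.approx(sd.DOSE_CONSTANT_GY_KG_PER_GBQ, rel=0.01)


def test_absorbed_dose_linearity_and_zero():
    assert sd.absorbed_dose(0.0, 2.0) == 0.0
    assert sd.absorbed_dose(2.4, 0.8) == pytest.approx(2 * sd.absorbed_dose(1.2, 0.8))


def test_absorbed_dose_zero_mass_raises():
    with pytest.raises(UndefinedDoseError):
        sd.absorbed_dose(1.0, 0.0)


def test_dose_report_hand_example(fixed_measurements):
    """Tumor: 49.67 x 1.52 GBq / 0.5 kg = 150.9968 Gy at 2 GBq injected."""
    rep = sd.dose_report(2.0, fixed_measurements)
    assert rep.absorbed_dose_gy[TUMOR] == pytest.approx(150.9968, rel=1e-9)
    assert rep.absorbed_dose_gy[LUNG] == pytest.approx(49.67 * 0.10 / 0.99, rel=1e-9)


def test_dose_report_zero_injection_gives_zero_doses(fixed_measurements):
    rep = sd.dose_report(0.0, fixed_measurements)
    assert all(d == 0.0 for d in rep.absorbed_dose_gy.values())


def test_dose_homogeneity_in_injected_activity(fixed_measurements):
    r1 = sd.dose_report(1.3, fixed_measurements)
    r3 = sd.dose_report(3.9, fixed_measurements)
    for c in COMPARTMENTS:
        assert r3.absorbed_dose_gy[c] == pytest.approx(
            3.0 * r1.absorbed_dose_gy[c], rel=1e-12
        )


def test_doses_invariant_to_count_scale(fixed_measurements):
    """Counts are relative: rescaling every count leaves doses unchanged."""
    m = fixed_measurements
    scaled = sd.PartitionMeasurements(
        tumor=VOIMeasurement.from_totals(m.tumor.volume_ml, 37.0 * m.tumor.total_counts),
        in_target=VOIMeasurement.from_totals(
            m.in_target.volume_ml, 37.0 * m.in_target.total_counts
        ),
        out_target=VOIMeasurement.from_totals(
            m.out_target.volume_ml, 37.0 * m.out_target.total_counts
        ),
        lung_total_counts=37.0 * m.lung_total_counts,
        lsf=m.lsf,
        lung_volume_ml=m.lung_volume_ml,
    )
    r1 = sd.dose_report(2.0, m)
    r2 = sd.dose_report(2.0, scaled)
    for c in COMPARTMENTS:
        assert r2.absorbed_dose_gy[c] == pytest.approx(r1.absorbed_dose_gy[c], rel=1e-12)


def test_dose_report_matches_voxel_oracle_on_phantom(maa_truth):
    """Perfect VOI measurement on a noiseless phantom reproduces brute-force
    voxel-level dosimetry (same constant, label-wise masses) within 0.5%."""
    from sirtdose.compartments import DENSITY_KG_PER_L, LABEL_CODES

    injected = 2.1
    vois = {c: sd.measure_voi(maa_truth, c) for c in LIVER_PARTITIONS}
    lung_voi = sd.measure_voi(maa_truth, LUNG)
    m = sd.PartitionMeasurements(
        tumor=vois[TUMOR],
        in_target=vois["in_target_liver"],
        out_target=vois["out_target_liver"],
        lung_total_counts=lung_voi.total_counts,
        lsf=float(
            maa_truth.values[maa_truth.labels == LABEL_CODES[LUNG]].sum()
            / maa_truth.values.sum()
        ),
        lung_volume_ml=lung_voi.volume_ml,
    )
    rep = sd.dose_report(injected, m)
    total = maa_truth.values.sum()
    for comp, code in LABEL_CODES.items():
        mask = maa_truth.labels == code
        a0 = injected * float(maa_truth.values[mask].sum()) / total
        mass = mask.sum() * maa_truth.voxel_volume_ml / 1000.0 * DENSITY_KG_PER_L[comp]
        oracle = sd.DOSE_CONSTANT_GY_KG_PER_GBQ * a0 / mass
        assert rep.absorbed_dose_gy[comp] == pytest.approx(oracle, rel=0.005)
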