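"""Activity planning: partition-model inversion, BSA method, LSF reduction.

The partition-model (PM) plan inverts the dose calculator: the required
activity delivers the tumor dose requirement (120 Gy default), and each
organ-at-risk tolerance limit (lungs < 20 Gy; in-target normal liver
< 70 Gy, or out-target normal liver < 30 Gy when the in-target partition
is too small to be dose-limiting) caps the injectable activity. The
recommended activity is the required activity unless a tolerance binds,
in which case the plan is capped and reports the reduction fraction.
Patients with a lung shunt fraction above 0.2 are excluded from treatment.

The empirical body-surface-area (BSA) method prescribes

    A [GBq] = (BSA [m²] − 0.2) + V_tumor / V_liver,

with BSA from the DuBois–DuBois formula, then reduces the activity in
steps with increasing lung shunt (by 20% for LSF in [0.10, 0.15), by 40%
for LSF in [0.15, 0.20); LSF ≥ 0.20 excludes the patient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .compartments import IN_TARGET, LUNG, OUT_TARGET, TUMOR
from .dosimetry import (
    DOSE_CONSTANT_GY_KG_PER_GBQ,
    PartitionMeasurements,
    compartment_mass,
)
from .errors import PatientExcludedError, PlanningError

#: Sentinel for a tolerance that no finite activity can violate.
UNBOUNDED = math.inf


@dataclass(frozen=True)
class PlanningConstraints:
    """Dose requirement, tolerance limits and the exclusion threshold."""

    tumor_dose_requirement_gy: float = 120.0
    lung_limit_gy: float = 20.0
    in_target_limit_gy: float = 70.0
    out_target_limit_gy: float = 30.0
    lsf_exclusion: float = 0.2
    use_out_target_limit: bool = False
    #: When the in-target volume is below this fraction of the total liver
    #: volume, the out-target limit is applied instead (automatic analogue
    #: of the "considerably small in-target volume" switch).
    small_in_target_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "tumor_dose_requirement_gy",
            "lung_limit_gy",
            "in_target_limit_gy",
            "out_target_limit_gy",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.lsf_exclusion <= 1.0:
            raise ValueError("lsf_exclusion must be in (0, 1]")


@dataclass(frozen=True)
class ActivityPlan:
    """Outcome of partition-model planning for one case."""

    required_activity_gbq: float
    tolerance_activities_gbq: dict[str, float] = field(default_factory=dict)
    recommended_activity_gbq: float = 0.0
    limiting_constraint: str | None = None
    feasible: bool = True
    reduction_fraction: float = 0.0
    used_out_target_limit: bool = False


def _dose_per_gbq(
    m: PartitionMeasurements, compartment: str, dose_constant: float
) -> float:
    """Absorbed dose per unit injected activity (Gy/GBq) for a compartment."""
    fraction = m.activity_fraction(compartment)
    if compartment == LUNG:
        mass = compartment_mass(m.lung_volume_ml, LUNG)
    else:
        mass = compartment_mass(m.voi(compartment).volume_ml, compartment)
    if fraction == 0.0:
        return 0.0
    if mass <= 0:
        raise PlanningError(f"{compartment} has activity but zero mass")
    return dose_constant * fraction / mass


def activity_for_tumor_dose(
    m: PartitionMeasurements,
    target_dose_gy: float,
    dose_constant: float = DOSE_CONSTANT_GY_KG_PER_GBQ,
) -> float:
    """Injected activity (GBq) that delivers ``target_dose_gy`` to the tumor.

    Closed-form inversion: A = D_target · m_tumor / (k · f_tumor), with
    f_tumor the tumor's activity fraction.
    """
    if target_dose_gy < 0:
        raise ValueError("target dose must be >= 0")
    if target_dose_gy == 0:
        return 0.0
    if m.tumor.total_counts <= 0:
        raise PlanningError("no tumor uptake: required activity is undefined")
    if m.lsf >= 1.0:
        raise PlanningError("lsf = 1: no activity reaches the liver")
    per_gbq = _dose_per_gbq(m, TUMOR, dose_constant)
    return target_dose_gy / per_gbq


def tolerance_activity(
    m: PartitionMeasurements,
    compartment: str,
    limit_gy: float,
    dose_constant: float = DOSE_CONSTANT_GY_KG_PER_GBQ,
) -> float:
    """Largest injected activity keeping a compartment's dose at its limit.

    Returns the ``UNBOUNDED`` sentinel when the compartment traps no
    activity (its dose is zero at any injection).
    """
    if limit_gy < 0:
        raise ValueError("limit must be >= 0")
    per_gbq = _dose_per_gbq(m, compartment, dose_constant)
    if per_gbq == 0.0:
        return UNBOUNDED
    return limit_gy / per_gbq


def plan_partition_model(
    m: PartitionMeasurements,
    constraints: PlanningConstraints | None = None,
    dose_constant: float = DOSE_CONSTANT_GY_KG_PER_GBQ,
) -> ActivityPlan:
    """Partition-model activity recommendation under tolerance constraints."""
    c = constraints or PlanningConstraints()
    if m.lsf > c.lsf_exclusion:
        raise PatientExcludedError(
            f"lung shunt fraction {m.lsf:.3f} exceeds the exclusion "
            f"threshold {c.lsf_exclusion:.2f}"
        )
    required = activity_for_tumor_dose(m, c.tumor_dose_requirement_gy, dose_constant)

    liver_volume = (
        m.tumor.volume_ml + m.in_target.volume_ml + m.out_target.volume_ml
    )
    small_in_target = (
        liver_volume > 0
        and m.in_target.volume_ml < c.small_in_target_fraction * liver_volume
    )
    use_out = c.use_out_target_limit or small_in_target

    tolerances = {LUNG: tolerance_activity(m, LUNG, c.lung_limit_gy, dose_constant)}
    if use_out:
        tolerances[OUT_TARGET] = tolerance_activity(
            m, OUT_TARGET, c.out_target_limit_gy, dose_constant
        )
    else:
        tolerances[IN_TARGET] = tolerance_activity(
            m, IN_TARGET, c.in_target_limit_gy, dose_constant
        )

    binding = min(tolerances, key=tolerances.get)
    cap = tolerances[binding]
    feasible = required <= cap
    recommended = min(required, cap)
    reduction = 0.0 if feasible else 1.0 - recommended / required
    return ActivityPlan(
        required_activity_gbq=required,
        tolerance_activities_gbq=tolerances,
        recommended_activity_gbq=recommended,
        limiting_constraint=None if feasible else binding,
        feasible=feasible,
        reduction_fraction=reduction,
        used_out_target_limit=use_out,
    )


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """DuBois–DuBois body surface area (m²)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be > 0")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def bsa_activity(
    height_cm: float,
    weight_kg: float,
    tumor_volume_ml: float,
    total_liver_volume_ml: float,
) -> float:
    """Empirical BSA-method activity (GBq) for resin microspheres."""
    if tumor_volume_ml <= 0 or total_liver_volume_ml <= 0:
        raise ValueError("volumes must be > 0")
    if tumor_volume_ml > total_liver_volume_ml:
        raise ValueError("tumor volume cannot exceed total liver volume")
    bsa = body_surface_area(height_cm, weight_kg)
    return (bsa - 0.2) + tumor_volume_ml / total_liver_volume_ml


#: (lsf lower bound, factor) steps of the package-insert reduction rule.
LSF_REDUCTION_BANDS = ((0.15, 0.60), (0.10, 0.80), (0.0, 1.0))


def lsf_reduction(activity_gbq: float, lsf: float) -> float:
    """Reduce a BSA-planned activity according to the lung shunt fraction.

    No reduction below LSF 0.10; 20% for [0.10, 0.15); 40% for
    [0.15, 0.20); LSF >= 0.20 excludes the patient from treatment.
    """
    if activity_gbq < 0:
        raise ValueError("activity must be >= 0")
    if not 0.0 <= lsf <= 1.0:
        raise ValueError(f"lsf must be in [0, 1], got {lsf}")
    if lsf >= 0.20:
        raise PatientExcludedError(
            f"lung shunt fraction {lsf:.3f} >= 0.20: patient excluded"
        )
    for lo, factor in LSF_REDUCTION_BANDS:
        if lsf >= lo:
            return activity_gbq * factor
    return activity_gbq
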