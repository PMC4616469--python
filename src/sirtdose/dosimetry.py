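"""Four-compartment partition-model dosimetry for ⁹⁰Y microspheres.

⁹⁰Y-labelled microspheres are a permanent implant: once lodged, the entire
activity decays in place, so the absorbed dose to a compartment is
proportional to the initial activity it traps divided by its mass,

    D [Gy] = k · A₀ [GBq] / m [kg],

with k the integrated-dose constant (49.67 Gy·kg/GBq by default, the
canonical resin-microsphere value; numerical integration of the total
number of decays from the 2.67-day half-life and 0.927 MeV mean β energy
gives ≈49.4, consistent to within half a percent).

The injected activity is apportioned by relative imaging counts: the lungs
receive the lung-shunt fraction (LSF) of the injection, and the remainder
splits among tumor, in-target and out-target normal liver in proportion to
their total VOI counts C·V. Counts are relative quantities — only ratios
matter — so no camera calibration factor is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compartments import (
    COMPARTMENTS,
    DENSITY_KG_PER_L,
    IN_TARGET,
    LIVER_PARTITIONS,
    LUNG,
    OUT_TARGET,
    TUMOR,
)
from .errors import ApportionmentError, UndefinedDoseError
from .quantify import VOIMeasurement

#: Absorbed dose per unit initial activity per unit mass for a ⁹⁰Y
#: permanent implant, Gy·kg/GBq.
DOSE_CONSTANT_GY_KG_PER_GBQ = 49.67

#: Population-average CT-based lung volume, mL (3.3 L).
DEFAULT_LUNG_VOLUME_ML = 3300.0


@dataclass(frozen=True)
class PartitionMeasurements:
    """The per-case measurement set the partition model consumes.

    ``tumor``, ``in_target`` and ``out_target`` are VOI measurements
    (volume in mL, mean concentration in counts/mL, total counts);
    ``lung_total_counts`` is the total lung count estimate and ``lsf``
    the lung shunt fraction used for apportionment. ``lung_volume_ml``
    defaults to the 3.3 L population average.
    """

    tumor: VOIMeasurement
    in_target: VOIMeasurement
    out_target: VOIMeasurement
    lung_total_counts: float = 0.0
    lsf: float = 0.0
    lung_volume_ml: float = DEFAULT_LUNG_VOLUME_ML

    def __post_init__(self) -> None:
        if not 0.0 <= self.lsf <= 1.0:
            raise ValueError(f"lsf must be in [0, 1], got {self.lsf}")
        if self.lung_total_counts < 0:
            raise ValueError("lung_total_counts must be >= 0")
        if self.lung_volume_ml < 0:
            raise ValueError("lung_volume_ml must be >= 0")

    @property
    def liver_total_counts(self) -> float:
        return (
            self.tumor.total_counts
            + self.in_target.total_counts
            + self.out_target.total_counts
        )

    def voi(self, compartment: str) -> VOIMeasurement:
        try:
            return {
                TUMOR: self.tumor,
                IN_TARGET: self.in_target,
                OUT_TARGET: self.out_target,
            }[compartment]
        except KeyError:
            raise KeyError(f"unknown liver partition {compartment!r}") from None

    def activity_fraction(self, compartment: str) -> float:
        """Fraction of the injected activity trapped by a compartment."""
        if compartment == LUNG:
            return self.lsf
        total = self.liver_total_counts
        if total <= 0:
            if self.lsf < 1.0:
                raise ApportionmentError(
                    "no liver counts: cannot split the non-shunted activity"
                )
            return 0.0
        return (1.0 - self.lsf) * self.voi(compartment).total_counts / total


@dataclass(frozen=True)
class DoseReport:
    """Per-compartment apportioned activity, mass and absorbed dose."""

    injected_activity_gbq: float
    lsf: float
    apportioned_activity_gbq: dict[str, float] = field(default_factory=dict)
    mass_kg: dict[str, float] = field(default_factory=dict)
    absorbed_dose_gy: dict[str, float] = field(default_factory=dict)


def compartment_mass(volume_ml: float, compartment: str) -> float:
    """Mass (kg) of a compartment of given volume (mL).

    Density is 1.0 kg/L for tumor and liver partitions, 0.3 kg/L for lung.
    """
    if volume_ml < 0:
        raise ValueError(f"volume must be >= 0, got {volume_ml}")
    try:
        density = DENSITY_KG_PER_L[compartment]
    except KeyError:
        raise ValueError(f"unknown compartment {compartment!r}") from None
    return volume_ml / 1000.0 * density


def apportion_activity(
    injected_gbq: float, m: PartitionMeasurements
) -> dict[str, float]:
    """Split the injected activity among the four compartments.

    The lungs receive ``injected × lsf``; the remaining ``(1−lsf)`` splits
    among the liver partitions proportionally to their total counts C·V.
    The split conserves activity exactly.
    """
    if injected_gbq < 0:
        raise ValueError(f"injected activity must be >= 0, got {injected_gbq}")
    a0 = {LUNG: injected_gbq * m.lsf}
    remainder = injected_gbq - a0[LUNG]
    total = m.liver_total_counts
    if total <= 0:
        if m.lsf < 1.0 and injected_gbq > 0:
            raise ApportionmentError(
                "no liver counts: cannot split the non-shunted activity"
            )
        for c in LIVER_PARTITIONS:
            a0[c] = 0.0
        return a0
    shares = {c: m.voi(c).total_counts / total for c in LIVER_PARTITIONS}
    for c in LIVER_PARTITIONS:
        a0[c] = remainder * shares[c]
    # distribute any float residue onto the largest share to keep the sum exact
    residue = injected_gbq - sum(a0.values())
    if residue != 0.0:
        biggest = max(LIVER_PARTITIONS, key=lambda c: shares[c])
        a0[biggest] += residue
    return a0


def absorbed_dose(
    a0_gbq: float,
    mass_kg: float,
    dose_constant: float = DOSE_CONSTANT_GY_KG_PER_GBQ,
) -> float:
    """Absorbed dose (Gy) from initial activity (GBq) and mass (kg)."""
    if a0_gbq < 0:
        raise ValueError(f"activity must be >= 0, got {a0_gbq}")
    if mass_kg <= 0:
        raise UndefinedDoseError(f"mass must be > 0, got {mass_kg}")
    return dose_constant * a0_gbq / mass_kg


def dose_report(
    injected_gbq: float,
    m: PartitionMeasurements,
    dose_constant: float = DOSE_CONSTANT_GY_KG_PER_GBQ,
) -> DoseReport:
    """Full partition-model dose report for one injection.

    Lung mass is taken from ``m.lung_volume_ml`` (3.3 L default) at
    0.3 kg/L; liver partition masses come from their VOI volumes at
    unit density.
    """
    a0 = apportion_activity(injected_gbq, m)
    mass = {c: compartment_mass(m.voi(c).volume_ml, c) for c in LIVER_PARTITIONS}
    mass[LUNG] = compartment_mass(m.lung_volume_ml, LUNG)
    dose = {}
    for c in COMPARTMENTS:
        if a0[c] == 0.0 and mass[c] == 0.0:
            dose[c] = 0.0
        else:
            dose[c] = absorbed_dose(a0[c], mass[c], dose_constant)
    return DoseReport(
        injected_activity_gbq=injected_gbq,
        lsf=m.lsf,
        apportioned_activity_gbq=a0,
        mass_kg=mass,
        absorbed_dose_gy=dose,
    )
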