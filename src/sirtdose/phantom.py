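"""Digital emission phantoms and synthetic treatment cohorts.

Every downstream stage of the pipeline (quantification, dosimetry,
planning, outcome analysis) is exercised on seeded digital phantoms with
known ground truth, since no public imaging cohort exists for this
workflow. A phantom is four disjoint ellipsoidal compartments — tumor,
in-target normal liver, out-target normal liver, lungs — on a regular
grid, with per-compartment activity concentrations for each imaging
modality:

* ``"maa"`` — the ⁹⁹ᵐTc-MAA surrogate particles injected at planning
  angiography, imaged by planar scintigraphy and SPECT/CT;
* ``"microsphere"`` — the therapeutic ⁹⁰Y microspheres, imaged by
  post-treatment PET/CT.

The two particle types distribute differently in vivo (size, density,
number). That discrepancy has no accepted quantitative model, so it is
emulated phenomenologically: the MAA map scales the tumor concentration
down (MAA under-represents tumor trapping, hence over-represents normal
liver in relative terms) and carries a higher lung shunt fraction
(free/degraded MAA reaches the lungs). Acquisition is emulated as a
Gaussian point-spread blur, Poisson count noise and — for PET — a partial
axial field of view covering only the basal lungs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import dosimetry
from .compartments import (
    COMPARTMENTS,
    IN_TARGET,
    LABEL_CODES,
    LIVER_PARTITIONS,
    LUNG,
    OUT_TARGET,
    TUMOR,
)
from .errors import DegenerateInputError, GeometryError
from .quantify import measure_voi
from .survival import SurvivalRecord
from .volume import ActivityVolume

MAA = "maa"
MICROSPHERE = "microsphere"
MODALITIES = (MAA, MICROSPHERE)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class Ellipsoid:
    """One compartment: axis-aligned ellipsoid in physical (mm) coordinates."""

    label: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.label not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.label!r}")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")

    def volume_ml(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, uptake and acquisition parameters of one digital phantom.

    ``activity_concentration`` maps modality → {compartment: activity/mL}
    (arbitrary tracer units; only ratios matter downstream). The lung entry
    is a placeholder — the lung concentration is rescaled at build time so
    that the lung holds exactly ``lsf_true`` of the phantom's activity.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    compartments: tuple[Ellipsoid, ...] = ()
    activity_concentration: dict[str, dict[str, float]] = field(default_factory=dict)
    lsf_true: float = 0.06
    psf_fwhm_mm: dict[str, float] = field(
        default_factory=lambda: {MAA: 12.0, MICROSPHERE: 6.0}
    )
    noise_scale: float = 50.0
    pet_axial_coverage: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if not 0.0 <= self.lsf_true <= 0.3:
            raise ValueError(f"lsf_true must be in [0, 0.3], got {self.lsf_true}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not 0.0 < self.pet_axial_coverage <= 1.0:
            raise ValueError("pet_axial_coverage must be in (0, 1]")
        for conc in self.activity_concentration.values():
            if any(v < 0 for v in conc.values()):
                raise ValueError("activity concentrations must be >= 0")


def default_phantom_spec(
    tumor_to_normal_ratio: float = 4.0,
    maa_tumor_factor: float = 0.73,
    base_concentration: float = 10.0,
    lsf_true: float = 0.06,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size_mm: float | tuple[float, float, float] = 4.0,
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """Reference phantom: liver compartments caudally, lungs cranially.

    Geometry is fixed in millimetres (384 mm field of view), so changing
    the grid resolution resamples the same anatomy. ``maa_tumor_factor``
    scales the MAA tumor concentration relative to the microsphere map
    (< 1 reproduces the clinically observed MAA under-estimation of tumor
    uptake).
    """
    if isinstance(voxel_size_mm, (int, float)):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    c0 = base_concentration
    conc_ms = {TUMOR: tumor_to_normal_ratio * c0, IN_TARGET: c0, OUT_TARGET: 0.3 * c0, LUNG: 1.0}
    conc_maa = dict(conc_ms)
    conc_maa[TUMOR] = tumor_to_normal_ratio * maa_tumor_factor * c0
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        compartments=(
            Ellipsoid(TUMOR, (110.0, 190.0, 110.0), (48.0, 45.0, 45.0)),
            Ellipsoid(IN_TARGET, (230.0, 190.0, 110.0), (60.0, 55.0, 55.0)),
            Ellipsoid(OUT_TARGET, (324.0, 190.0, 110.0), (28.0, 40.0, 40.0)),
            Ellipsoid(LUNG, (190.0, 170.0, 270.0), (90.0, 60.0, 60.0)),
        ),
        activity_concentration={MAA: conc_maa, MICROSPHERE: conc_ms},
        lsf_true=lsf_true,
        seed=seed,
        **overrides,
    )


def _rasterize(spec: PhantomSpec) -> np.ndarray:
    """Label grid from the ellipsoid geometry; rejects overlaps voxel-wise."""
    shape = spec.grid_shape
    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(shape, spec.voxel_size_mm)
    ]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    labels = np.zeros(shape, dtype=np.int16)
    for ell in spec.compartments:
        cx, cy, cz = ell.center_mm
        ax, ay, az = ell.semi_axes_mm
        inside = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
        if np.any(labels[inside] != 0):
            raise GeometryError(
                f"compartment {ell.label!r} overlaps a previously placed compartment"
            )
        labels[inside] = LABEL_CODES[ell.label]
    return labels


def build_phantom(
    spec: PhantomSpec, modality: str, lsf_true: float | None = None
) -> ActivityVolume:
    """Ground-truth activity volume for one modality.

    Voxels inside each compartment carry concentration × voxel volume. The
    lung compartment is rescaled so its share of total phantom activity is
    exactly ``lsf_true`` (the PhantomSpec value unless overridden per call, as
    the cohort generator does to give the two modalities different shunts).
    """
    if modality not in spec.activity_concentration:
        raise ValueError(f"no concentration map for modality {modality!r}")
    lsf = spec.lsf_true if lsf_true is None else lsf_true
    if not 0.0 <= lsf < 1.0:
        raise ValueError(f"lsf_true must be in [0, 1), got {lsf}")
    labels = _rasterize(spec)
    conc = spec.activity_concentration[modality]
    voxel_volume = math.prod(spec.voxel_size_mm) / 1000.0
    values = np.zeros(spec.grid_shape, dtype=float)
    for comp, code in LABEL_CODES.items():
        values[labels == code] = conc.get(comp, 0.0) * voxel_volume

    lung_mask = labels == LABEL_CODES[LUNG]
    nonlung_total = float(values[~lung_mask].sum())
    if lsf > 0:
        if not lung_mask.any():
            raise GeometryError("lsf_true > 0 requires a lung compartment")
        if nonlung_total <= 0:
            raise DegenerateInputError("no liver activity to anchor the lung shunt")
        # lung/(lung + nonlung) = lsf  =>  lung_total = lsf/(1-lsf) * nonlung
        target = lsf / (1.0 - lsf) * nonlung_total
        values[lung_mask] = target / lung_mask.sum()
    else:
        values[lung_mask] = 0.0
    if values.sum() <= 0:
        raise DegenerateInputError("phantom holds no activity")
    return ActivityVolume(values, labels, spec.voxel_size_mm)


def simulate_emission_image(
    truth: ActivityVolume,
    psf_fwhm_mm: float,
    noise_scale: float,
    coverage: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> ActivityVolume:
    """Surrogate emission acquisition: Gaussian PSF, Poisson counts, partial FOV.

    ``noise_scale`` converts activity to expected counts per voxel; 0
    disables noise (the output stays in activity units). ``coverage`` is
    the fraction of the lungs' axial extent inside the field of view,
    counted from the caudal end so the liver and basal lungs are always
    retained; voxels beyond it are zeroed and ``fov_z`` records the cut.
    Labels pass through unchanged (they stand for the CT segmentation).
    """
    if psf_fwhm_mm < 0 or noise_scale < 0:
        raise ValueError("psf_fwhm_mm and noise_scale must be >= 0")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    values = truth.values
    if psf_fwhm_mm > 0:
        sigma_vox = [
            psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in truth.voxel_size_mm
        ]
        values = ndimage.gaussian_filter(values, sigma_vox, mode="constant")
        values = np.clip(values, 0.0, None)
    if noise_scale > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values = rng.poisson(values * noise_scale).astype(float)
    else:
        values = values.copy()

    fov_z = None
    if coverage < 1.0:
        lung_z = np.nonzero((truth.labels == LABEL_CODES[LUNG]).any(axis=(0, 1)))[0]
        if lung_z.size:
            z0, z1 = int(lung_z[0]), int(lung_z[-1]) + 1
            fov_z = z0 + max(1, math.ceil(coverage * (z1 - z0)))
        else:
            fov_z = truth.values.shape[2]
        values[:, :, fov_z:] = 0.0
    return ActivityVolume(values, truth.labels.copy(), truth.voxel_size_mm, fov_z)


def project_planar(
    truth: ActivityVolume, attenuation_mu: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate anterior/posterior planar projections along the y axis.

    Each view is a depth-weighted sum with attenuation factor
    exp(−μ·depth) from its own entrance face; μ = 0 gives plain axis sums.
    The posterior view is mirrored left–right to match display convention.
    """
    if attenuation_mu < 0:
        raise ValueError("attenuation_mu must be >= 0")
    ny = truth.values.shape[1]
    dy = truth.voxel_size_mm[1]
    depth = (np.arange(ny) + 0.5) * dy
    w_ant = np.exp(-attenuation_mu * depth)
    w_post = w_ant[::-1]
    anterior = np.tensordot(truth.values, w_ant, axes=([1], [0]))
    posterior = np.tensordot(truth.values, w_post, axes=([1], [0]))
    return anterior, np.flip(posterior, axis=0)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortParams:
    """Distributions defining a synthetic treatment cohort.

    Defaults emulate the study conditions of a resin-microsphere SIRT
    cohort: injected activities around 2.1 ± 0.9 GBq, microsphere (true)
    lung shunts around 0.018, an MAA shunt excess bringing the planning
    scan's LSF to ≈0.06 on average, MAA tumor uptake at ≈0.73 of the
    microsphere value, and progression-free survival that is exponential
    with mean 286 days above a 200 Gy true tumor dose and 92 days below,
    censored at 400 days.
    """

    tnr_mean: float = 4.0
    tnr_sd: float = 1.0
    lsf_mean: float = 0.018
    lsf_sd: float = 0.020
    maa_lsf_excess_mean: float = 0.042
    maa_lsf_excess_sd: float = 0.025
    maa_tumor_factor_mean: float = 0.73
    maa_tumor_factor_sd: float = 0.10
    injected_gbq_mean: float = 2.1
    injected_gbq_sd: float = 0.9
    dose_threshold_gy: float = 200.0
    pfs_mean_high_days: float = 286.0
    pfs_mean_low_days: float = 92.0
    censor_horizon_days: float = 400.0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 4.0
    psf_fwhm_spect_mm: float = 12.0
    psf_fwhm_pet_mm: float = 6.0
    noise_scale: float = 50.0
    pet_axial_coverage: float = 0.4


@dataclass(frozen=True)
class CaseTruth:
    """Ground truth for one synthetic case."""

    injected_gbq: float
    lsf_true: float
    lsf_true_maa: float
    tumor_to_normal_ratio: float
    maa_tumor_factor: float
    activities_gbq: dict[str, float]
    doses_gy: dict[str, float]
    volumes_ml: dict[str, float]


@dataclass
class SyntheticCase:
    """One simulated patient: images, ground truth and outcome."""

    case_id: int
    truth: CaseTruth
    pfs: SurvivalRecord
    maa_volume: ActivityVolume | None = None
    pet_volume: ActivityVolume | None = None
    planar_anterior: np.ndarray | None = None
    planar_posterior: np.ndarray | None = None


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def draw_pfs(
    true_tumor_dose_gy: float, params: CohortParams, rng: np.random.Generator
) -> SurvivalRecord:
    """Exponential PFS with a dose-threshold-switched mean, censored."""
    high = true_tumor_dose_gy > params.dose_threshold_gy
    mean = params.pfs_mean_high_days if high else params.pfs_mean_low_days
    t = rng.exponential(mean)
    t = max(t, 1e-6)
    event = t <= params.censor_horizon_days
    return SurvivalRecord(
        time_days=min(t, params.censor_horizon_days),
        event=bool(event),
        group="high" if high else "low",
    )


def _case_truth(
    ms_truth: ActivityVolume,
    injected: float,
    lsf_ms: float,
    lsf_maa: float,
    tnr: float,
    maa_factor: float,
) -> CaseTruth:
    """Ground-truth activities and doses from the microsphere distribution."""
    vois = {c: measure_voi(ms_truth, c) for c in LIVER_PARTITIONS}
    lung_voi = measure_voi(ms_truth, LUNG)
    m = dosimetry.PartitionMeasurements(
        tumor=vois[TUMOR],
        in_target=vois[IN_TARGET],
        out_target=vois[OUT_TARGET],
        lung_total_counts=lung_voi.total_counts,
        lsf=lsf_ms,
        lung_volume_ml=lung_voi.volume_ml,
    )
    report = dosimetry.dose_report(injected, m)
    volumes = {c: vois[c].volume_ml for c in LIVER_PARTITIONS}
    volumes[LUNG] = lung_voi.volume_ml
    return CaseTruth(
        injected_gbq=injected,
        lsf_true=lsf_ms,
        lsf_true_maa=lsf_maa,
        tumor_to_normal_ratio=tnr,
        maa_tumor_factor=maa_factor,
        activities_gbq=report.apportioned_activity_gbq,
        doses_gy=report.absorbed_dose_gy,
        volumes_ml=volumes,
    )


def make_case(
    case_id: int,
    params: CohortParams,
    rng: np.random.Generator,
    render: bool = True,
) -> SyntheticCase:
    """Draw one synthetic patient; ``render=False`` skips image synthesis."""
    tnr = _truncated_normal(rng, params.tnr_mean, params.tnr_sd, 1.5, 12.0)
    lsf_ms = _truncated_normal(rng, params.lsf_mean, params.lsf_sd, 0.001, 0.19)
    excess = _truncated_normal(
        rng, params.maa_lsf_excess_mean, params.maa_lsf_excess_sd, 0.0, 0.15
    )
    lsf_maa = min(lsf_ms + excess, 0.25)
    maa_factor = _truncated_normal(
        rng, params.maa_tumor_factor_mean, params.maa_tumor_factor_sd, 0.3, 1.1
    )
    injected = _truncated_normal(
        rng, params.injected_gbq_mean, params.injected_gbq_sd, 0.5, 4.0
    )
    spec = default_phantom_spec(
        tumor_to_normal_ratio=tnr,
        maa_tumor_factor=maa_factor,
        lsf_true=min(lsf_ms, 0.3),
        grid_shape=params.grid_shape,
        voxel_size_mm=params.voxel_size_mm,
        noise_scale=params.noise_scale,
        pet_axial_coverage=params.pet_axial_coverage,
        psf_fwhm_mm={MAA: params.psf_fwhm_spect_mm, MICROSPHERE: params.psf_fwhm_pet_mm},
        seed=case_id,
    )
    ms_truth = build_phantom(spec, MICROSPHERE, lsf_true=lsf_ms)
    truth = _case_truth(ms_truth, injected, lsf_ms, lsf_maa, tnr, maa_factor)
    pfs = draw_pfs(truth.doses_gy[TUMOR], params, rng)
    case = SyntheticCase(case_id=case_id, truth=truth, pfs=pfs)
    if render:
        maa_truth = build_phantom(spec, MAA, lsf_true=lsf_maa)
        case.maa_volume = simulate_emission_image(
            maa_truth, params.psf_fwhm_spect_mm, params.noise_scale, 1.0, rng
        )
        blurred = simulate_emission_image(maa_truth, params.psf_fwhm_spect_mm, 0.0, 1.0)
        ant, post = project_planar(blurred)
        if params.noise_scale > 0:
            ant = rng.poisson(ant * params.noise_scale).astype(float)
            post = rng.poisson(post * params.noise_scale).astype(float)
        case.planar_anterior, case.planar_posterior = ant, post
        case.pet_volume = simulate_emission_image(
            ms_truth,
            params.psf_fwhm_pet_mm,
            params.noise_scale,
            params.pet_axial_coverage,
            rng,
        )
    return case


def make_cohort(
    n: int,
    params: CohortParams | None = None,
    seed: int = 0,
    render: bool = True,
) -> list[SyntheticCase]:
    """Generate ``n`` synthetic patients, reproducibly from one seed.

    Each case derives its RNG from ``SeedSequence(seed).spawn``, so the
    cohort is a pure function of ``(n, params, seed)`` and cases are
    independent of cohort size ordering.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    params = params or CohortParams()
    children = np.random.SeedSequence(seed).spawn(n)
    return [
        make_case(i, params, np.random.default_rng(children[i]), render=render)
        for i in range(n)
    ]


def draw_survival_cohort(
    n_high: int,
    n_low: int,
    params: CohortParams | None = None,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """PFS records for fixed dose-group sizes (for power studies)."""
    params = params or CohortParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for group, n, mean in (
        ("high", n_high, params.pfs_mean_high_days),
        ("low", n_low, params.pfs_mean_low_days),
    ):
        for _ in range(n):
            t = max(rng.exponential(mean), 1e-6)
            records.append(
                SurvivalRecord(
                    time_days=min(t, params.censor_horizon_days),
                    event=bool(t <= params.censor_horizon_days),
                    group=group,
                )
            )
    return records
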