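"""VOI and planar-ROI quantification, lung shunt fraction, PET lung extrapolation.

The planning workflow measures the lung shunt fraction (LSF) on conjugate
anterior/posterior planar scintigrams: with ROIs over the lungs and the
liver, the conjugate (geometric-mean) counts TC satisfy

    LSF = TC_lung / (TC_lung + TC_liver).

On tomographic volumes, each compartment is measured as a VOI: its volume,
mean concentration (counts per mL) and total counts. A post-treatment PET
scan typically covers only one bed position, so only the basal lungs are in
the field of view; total lung counts are extrapolated as the basal mean
concentration times the lung volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .compartments import LABEL_CODES, LIVER_PARTITIONS, LUNG
from .errors import EmptyVOIError, UndefinedLSFError
from .volume import ActivityVolume

#: Population-average CT-based lung volume (mL) used when no per-case lung
#: volume is available.
DEFAULT_LUNG_VOLUME_ML = 3300.0


@dataclass(frozen=True)
class VOIMeasurement:
    """Volume (mL), mean concentration (counts/mL) and total counts of a VOI."""

    volume_ml: float
    mean_concentration: float
    total_counts: float

    def __post_init__(self) -> None:
        for name in ("volume_ml", "mean_concentration", "total_counts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_totals(cls, volume_ml: float, total_counts: float) -> "VOIMeasurement":
        conc = total_counts / volume_ml if volume_ml > 0 else 0.0
        return cls(volume_ml, conc, total_counts)


@dataclass(frozen=True)
class PlanarRoiCounts:
    """Counts in one ROI on the anterior and posterior planar images."""

    anterior_counts: float
    posterior_counts: float

    def __post_init__(self) -> None:
        if self.anterior_counts < 0 or self.posterior_counts < 0:
            raise ValueError("planar ROI counts must be >= 0")


def measure_voi(image: ActivityVolume, label: str) -> VOIMeasurement:
    """Measure one compartment VOI on a volume, using its label mask."""
    mask = image.labels == LABEL_CODES[label]
    n = int(mask.sum())
    if n == 0:
        raise EmptyVOIError(f"label {label!r} absent from the label grid")
    total = float(image.values[mask].sum())
    volume = n * image.voxel_volume_ml
    return VOIMeasurement(volume, total / volume, total)


def conjugate_counts(roi: PlanarRoiCounts) -> float:
    """Conjugate-view count estimate: geometric mean of anterior/posterior."""
    return math.sqrt(roi.anterior_counts * roi.posterior_counts)


def lung_shunt_fraction(lung: PlanarRoiCounts, liver: PlanarRoiCounts) -> float:
    """LSF from planar lung and liver ROI counts (conjugate-view estimate)."""
    tc_lung = conjugate_counts(lung)
    tc_liver = conjugate_counts(liver)
    if tc_lung + tc_liver == 0:
        raise UndefinedLSFError("no counts in lung or liver ROIs")
    return tc_lung / (tc_lung + tc_liver)


def extrapolate_lung_counts(
    basal_mean_concentration: float,
    lung_volume_ml: float = DEFAULT_LUNG_VOLUME_ML,
) -> float:
    """Total lung counts from the basal-lung mean concentration.

    Exact for uniform lung activity; on a nonuniform lung the bias equals
    the deviation of the basal mean from the whole-lung mean concentration.
    """
    if basal_mean_concentration < 0 or lung_volume_ml < 0:
        raise ValueError("inputs must be >= 0")
    return basal_mean_concentration * lung_volume_ml


def lsf_from_pet(lung_total_counts: float, partitions) -> float:
    """Post-treatment LSF analogue: lung counts over lung + liver counts.

    ``partitions`` is an iterable of the three liver VOIMeasurements.
    """
    liver_total = sum(p.total_counts for p in partitions)
    denom = lung_total_counts + liver_total
    if denom == 0:
        raise UndefinedLSFError("no counts in lungs or liver partitions")
    return lung_total_counts / denom


def basal_lung_concentration(image: ActivityVolume) -> float:
    """Mean lung concentration (counts/mL) over the acquired axial range."""
    mask = image.labels == LABEL_CODES[LUNG]
    if image.fov_z is not None:
        mask = mask.copy()
        mask[:, :, image.fov_z:] = False
    n = int(mask.sum())
    if n == 0:
        raise EmptyVOIError("no lung voxels inside the field of view")
    return float(image.values[mask].mean()) / image.voxel_volume_ml


def planar_roi_mask(
    labels: np.ndarray, label: str, margin_px: int = 3
) -> np.ndarray:
    """2D ROI mask for a planar image: label projected along y, dilated.

    The dilation margin emulates the generous hand-drawn ROIs that capture
    resolution spill-out around an organ boundary.
    """
    proj = (labels == LABEL_CODES[label]).any(axis=1)  # (x, z)
    if margin_px > 0:
        proj = ndimage.binary_dilation(proj, iterations=margin_px)
    return proj


def planar_liver_mask(labels: np.ndarray, margin_px: int = 3) -> np.ndarray:
    """Combined ROI over the three liver partitions."""
    mask = np.zeros(labels.shape[::2], dtype=bool)
    for part in LIVER_PARTITIONS:
        mask |= planar_roi_mask(labels, part, margin_px=0)
    if margin_px > 0:
        mask = ndimage.binary_dilation(mask, iterations=margin_px)
    return mask


def roi_counts(
    anterior: np.ndarray, posterior: np.ndarray, mask: np.ndarray
) -> PlanarRoiCounts:
    """Sum a planar ROI on the conjugate pair.

    The posterior image is stored left–right mirrored (display convention),
    so the mask is flipped along x before summing it.
    """
    ant = float(anterior[mask].sum())
    post = float(posterior[np.flip(mask, axis=0)].sum())
    return PlanarRoiCounts(ant, post)
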