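"""In-memory container for emission volumes with compartment labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compartments import CODE_LABELS


@dataclass
class ActivityVolume:
    """A 3D activity (or count) grid with a parallel compartment label grid.

    ``values`` holds per-voxel activity in arbitrary tracer units, or
    counts after simulated acquisition; ``labels`` holds compartment codes
    (0 background). ``voxel_size_mm`` is the per-axis spacing; axes follow
    (x: left→right, y: anterior→posterior, z: caudal→cranial).

    ``fov_z`` marks a partial axial field of view: only slices
    ``z < fov_z`` were acquired (``None`` means full coverage). Labels are
    always full-extent — they play the role of the CT segmentation, which
    is available even where the emission scan is not.
    """

    values: np.ndarray
    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    fov_z: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D grid")
        if self.values.shape != self.labels.shape:
            raise ValueError(
                f"values shape {self.values.shape} != labels shape {self.labels.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("voxel values must be >= 0")
        bad = set(np.unique(self.labels)) - {0} - set(CODE_LABELS)
        if bad:
            raise ValueError(f"unknown label codes {sorted(bad)}")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm³)."""
        sx, sy, sz = self.voxel_size_mm
        return sx * sy * sz / 1000.0

    def copy(self) -> "ActivityVolume":
        return ActivityVolume(
            self.values.copy(), self.labels.copy(), self.voxel_size_mm, self.fov_z
        )
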