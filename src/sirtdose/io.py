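"""Reading and writing volumes (NIfTI) and cohort tables (CSV)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import SyntheticCase
from .survival import SurvivalRecord
from .volume import ActivityVolume


def save_volume(vol: ActivityVolume, values_path, labels_path) -> None:
    """Write an activity volume and its label grid as a NIfTI pair."""
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(values_path))
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), affine), str(labels_path))


def load_volume(values_path, labels_path, fov_z: int | None = None) -> ActivityVolume:
    """Read a values/labels NIfTI pair back into an ActivityVolume."""
    img = nib.load(str(values_path))
    lab = nib.load(str(labels_path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ActivityVolume(
        np.asarray(img.dataobj, dtype=float),
        np.asarray(lab.dataobj, dtype=np.int16),
        voxel_size,
        fov_z,
    )


def cohort_truth_frame(cases: list[SyntheticCase]) -> pd.DataFrame:
    """Ground-truth block of a cohort as a tidy table."""
    rows = []
    for c in cases:
        row = {
            "case": c.case_id,
            "injected_gbq": c.truth.injected_gbq,
            "lsf_true": c.truth.lsf_true,
            "lsf_true_maa": c.truth.lsf_true_maa,
            "tumor_to_normal_ratio": c.truth.tumor_to_normal_ratio,
            "maa_tumor_factor": c.truth.maa_tumor_factor,
            "pfs_days": c.pfs.time_days,
            "pfs_event": int(c.pfs.event),
            "dose_group": c.pfs.group,
        }
        for comp, d in c.truth.doses_gy.items():
            row[f"dose_true_{comp}"] = d
        for comp, a in c.truth.activities_gbq.items():
            row[f"activity_true_{comp}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


def save_survival_csv(records: list[SurvivalRecord], path) -> None:
    pd.DataFrame(
        [
            {"time_days": r.time_days, "event": int(r.event), "group": r.group}
            for r in records
        ]
    ).to_csv(path, index=False)


def load_survival_csv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(Path(path))
    return [
        SurvivalRecord(
            time_days=float(r.time_days), event=bool(r.event), group=str(r.group)
        )
        for r in df.itertuples()
    ]
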