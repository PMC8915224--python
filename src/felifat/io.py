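"""Reading and writing CT volumes, masks, and cohort tables.

Volumes and label masks travel as NIfTI (via nibabel; spacing stored in
the header in mm, converted to cm in memory) or NRRD (via SimpleITK,
imported lazily).  Truth and necropsy tables are plain CSV.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ct import CTVolume, ExclusionMasks
from .phantom import PhantomTruth


def _is_nrrd(path: Path) -> bool:
    return path.suffix.lower() in (".nrrd", ".nhdr")


def read_volume(path, cat_id: str | None = None) -> CTVolume:
    path = Path(path)
    if _is_nrrd(path):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing_mm = img.GetSpacing()
    else:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing_mm = img.header.get_zooms()[:3]
    spacing_cm = tuple(float(s) / 10.0 for s in spacing_mm)
    return CTVolume(
        hu=np.asarray(data).astype(np.int32),
        spacing=spacing_cm,
        cat_id=cat_id if cat_id is not None else path.stem.split(".")[0],
    )


def write_volume(volume: CTVolume, path) -> None:
    path = Path(path)
    spacing_mm = tuple(10.0 * s for s in volume.spacing)
    if _is_nrrd(path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(volume.hu.transpose(2, 1, 0))
        img.SetSpacing(spacing_mm)
        sitk.WriteImage(img, str(path))
    else:
        import nibabel as nib

        affine = np.diag([*spacing_mm, 1.0])
        img = nib.Nifti1Image(volume.hu.astype(np.int32), affine)
        img.header.set_zooms(spacing_mm)
        nib.save(img, str(path))


def read_masks(path) -> ExclusionMasks:
    vol = read_volume(path)
    return ExclusionMasks(labels=vol.hu.astype(np.int16))


def write_masks(masks: ExclusionMasks, spacing_cm, path) -> None:
    write_volume(
        CTVolume(hu=masks.labels.astype(np.int32), spacing=tuple(spacing_cm)),
        path,
    )


def truths_to_frame(truths: list[PhantomTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        d = asdict(t)
        d.update(
            true_bfv=t.true_bfv,
            true_tbbv=t.true_tbbv,
            true_nbfv=t.true_nbfv,
        )
        rows.append(d)
    return pd.DataFrame(rows)
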