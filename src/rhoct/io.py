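"""Reading and writing the pipeline's table and volume formats.

Tables are UTF-8 comma-separated files with a header row and '.' decimals;
volumes are NIfTI with an affine built from the voxel spacing.  An optional
DICOM reader (requires pydicom) maps rescale slope/intercept to HU.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .calibration import SaitoParams
from .phantom import VmiPair

__all__ = [
    "read_roi_table",
    "write_table",
    "write_vmi_pair",
    "read_vmi_pair",
    "write_saito_params",
    "read_saito_params",
    "read_dicom_series",
]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_roi_table(path) -> pd.DataFrame:
    """Read an ROI table; requires hu_50kev/hu_200kev mean columns."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not {"hu_50kev_mean", "hu_200kev_mean"} <= cols and not {
        "hu_50kev",
        "hu_200kev",
    } <= cols:
        raise ValueError(
            f"{path}: expected hu_50kev[_mean] and hu_200kev[_mean] columns, "
            f"got {sorted(cols)}"
        )
    return df


def _affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def write_vmi_pair(pair: VmiPair, prefix) -> tuple[Path, Path]:
    """Write the two members as <prefix>_<energy>kev.nii.gz; returns paths."""
    prefix = Path(prefix)
    paths = []
    for img, e in zip((pair.hu_low, pair.hu_high), pair.energies):
        p = prefix.parent / f"{prefix.name}_{e:g}kev.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(img, dtype=np.float32), _affine(pair.spacing)), p)
        paths.append(p)
    return tuple(paths)


def read_vmi_pair(path_low, path_high, energies=(50.0, 200.0)) -> VmiPair:
    imgs = [nib.load(p) for p in (path_low, path_high)]
    spac = imgs[0].header.get_zooms()[:3]
    return VmiPair(
        hu_low=np.asarray(imgs[0].get_fdata()),
        hu_high=np.asarray(imgs[1].get_fdata()),
        energies=tuple(float(e) for e in energies),
        spacing=tuple(float(s) for s in spac),
    )


def write_saito_params(params, path, provenance: dict | None = None) -> None:
    doc = {
        "a": float(params["a"]),
        "b": float(params["b"]),
        "alpha": float(params["alpha"]),
    }
    if "sse" in params:
        doc["sse"] = float(params["sse"])
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_saito_params(path) -> SaitoParams:
    doc = yaml.safe_load(Path(path).read_text())
    missing = {"a", "b", "alpha"} - set(doc)
    if missing:
        raise ValueError(f"{path}: missing calibration keys {sorted(missing)}")
    return SaitoParams({k: doc[k] for k in doc if k != "provenance"})


def read_dicom_series(paths) -> np.ndarray:
    """Stack DICOM slices into an HU volume (rescale slope/intercept applied).

    Optional convenience for real scanner exports; needs pydicom.
    """
    import pydicom

    slices = sorted(
        (pydicom.dcmread(str(p)) for p in paths),
        key=lambda d: float(getattr(d, "SliceLocation", 0.0)),
    )
    vols = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        vols.append(arr * slope + intercept)
    return np.stack(vols, axis=-1)
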