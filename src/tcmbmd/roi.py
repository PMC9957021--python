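"""CT volume I/O and the vertebral ROI measurement protocol.

A vertebra is measured on the median axial cross-section of its body:
an elliptical ROI drawn in the central trabecular bone is averaged to
give CT_tra, which the two-compartment model converts to BVF and vBMD.
Manual ROI drawing is replaced by an explicit, reproducible annotation
file (JSON), one entry per vertebra (L1-L4): the axial index range of
the vertebral body and the ellipse parameters in voxel units.

Orientation convention: volumes are normalized at load so the third
array axis is the axial (superior-inferior) direction; NIfTI volumes
are reoriented to closest-canonical (RAS) order, DICOM series are
stacked slice-by-slice along the third axis.  Ellipses live in the
in-plane (first two) axes, 0-based voxel coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tcm import ReferenceCalibration, measure_vbmd

logger = logging.getLogger(__name__)

__all__ = [
    "CTVolume",
    "EllipseROI",
    "VertebraAnnotation",
    "load_ct_volume",
    "save_nifti",
    "load_annotations",
    "median_cross_section",
    "elliptical_roi_mean",
    "measure_vertebrae",
]

VERTEBRAE = ("L1", "L2", "L3", "L4")


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with voxel spacing in mm."""

    data: np.ndarray  # HU, shape (nx, ny, nz); axial = third axis
    spacing: tuple[float, float, float]  # mm
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("CT volume must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CT volume contains non-finite HU values")


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical ROI on one axial slice, voxel units, 0-based.

    A voxel belongs to the ROI when its center satisfies
    ((x-cx)/a)^2 + ((y-cy)/b)^2 <= 1.
    """

    slice_index: int
    cx: float
    cy: float
    a: float  # semi-axis along first in-plane axis, voxels
    b: float  # semi-axis along second in-plane axis, voxels

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class VertebraAnnotation:
    """One vertebra's body extent and trabecular ellipse."""

    vertebra: str  # L1..L4
    z_range: tuple[int, int]  # inclusive axial index range of the body
    cx: float
    cy: float
    a: float
    b: float

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if hi < lo:
            raise ValueError(f"empty axial range {self.z_range}")
        if self.vertebra not in VERTEBRAE:
            raise ValueError(f"unknown vertebra label {self.vertebra!r}")


def load_ct_volume(path: str | Path) -> CTVolume:
    """Load a NIfTI file or a DICOM series directory as HU.

    NIfTI voxel values are taken as already being in HU; DICOM stored
    values are converted with the mandatory RescaleSlope/Intercept tags
    (missing tags or a mixed series raise, never pass silently).
    """
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path)
    return _load_nifti(path)


def _load_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data=data, spacing=spacing, orientation="RAS")


def _load_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima", ""})
    datasets = [pydicom.dcmread(str(p)) for p in files if p.is_file()]
    if not datasets:
        raise ValueError(f"no DICOM files found in {path}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed DICOM series in {path}: {sorted(uids)}")

    def _z(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    datasets.sort(key=_z)
    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("DICOM slice missing RescaleSlope/RescaleIntercept")
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(hu.T)  # (row, col) -> (col, row) so in-plane axes come first
    data = np.stack(slices, axis=-1)
    ds0 = datasets[0]
    dy, dx = (float(v) for v in ds0.PixelSpacing)
    if len(datasets) > 1:
        dz = abs(_z(datasets[1]) - _z(datasets[0]))
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    return CTVolume(data=data, spacing=(dx, dy, dz), orientation="DICOM-stack")


def save_nifti(volume: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with its spacing in the affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def load_annotations(path: str | Path) -> dict[str, list[VertebraAnnotation]]:
    """Read an annotation JSON: list of per-vertebra entries per subject.

    Format: ``[{"subject": ..., "vertebra": "L1", "z_range": [lo, hi],
    "ellipse": {"cx":..., "cy":..., "a":..., "b":...}}, ...]``.
    """
    entries = json.loads(Path(path).read_text())
    out: dict[str, list[VertebraAnnotation]] = {}
    for e in entries:
        ann = VertebraAnnotation(
            vertebra=e["vertebra"],
            z_range=(int(e["z_range"][0]), int(e["z_range"][1])),
            cx=float(e["ellipse"]["cx"]),
            cy=float(e["ellipse"]["cy"]),
            a=float(e["ellipse"]["a"]),
            b=float(e["ellipse"]["b"]),
        )
        out.setdefault(str(e.get("subject", "subject")), []).append(ann)
    return out


def median_cross_section(annotation: VertebraAnnotation) -> int:
    """Middle axial index of the vertebral body range.

    Even-length ranges resolve to the lower of the two middle indices,
    so the result is always a valid slice inside the range.
    """
    lo, hi = annotation.z_range
    return lo + (hi - lo) // 2


def elliptical_roi_mean(volume: CTVolume, roi: EllipseROI) -> tuple[float, int]:
    """Mean HU and voxel count inside an elliptical ROI on one slice.

    Voxel-center inclusion rule (no partial-volume weighting); the count
    is returned so callers can propagate noise of the mean.
    """
    nz = volume.data.shape[2]
    if not 0 <= roi.slice_index < nz:
        raise ValueError(f"slice {roi.slice_index} outside volume (nz={nz})")
    plane = volume.data[:, :, roi.slice_index]
    nx, ny = plane.shape
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    mask = ((x - roi.cx) / roi.a) ** 2 + ((y - roi.cy) / roi.b) ** 2 <= 1.0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ellipse contains no voxel centers inside the volume")
    return float(plane[mask].mean()), n


def measure_vertebrae(
    volume: CTVolume,
    annotations: Sequence[VertebraAnnotation],
    calib: ReferenceCalibration,
    subject: str = "subject",
    clamp: bool = False,
) -> pd.DataFrame:
    """Measure vBMD of annotated lumbar vertebrae.

    Composes median-slice selection, elliptical ROI averaging and the
    two-compartment model.  A subset of L1-L4 is accepted with a
    warning; returns one row per annotated vertebra with columns
    subject, vertebra, slice, mean_hu, n_voxels, bvf, vbmd.
    """
    if not annotations:
        raise ValueError("no vertebra annotations supplied")
    present = {a.vertebra for a in annotations}
    missing = [v for v in VERTEBRAE if v not in present]
    if missing:
        msg = f"missing annotations for {', '.join(missing)}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    rows = []
    for ann in sorted(annotations, key=lambda a: a.vertebra):
        z = median_cross_section(ann)
        mean_hu, n = elliptical_roi_mean(
            volume, EllipseROI(slice_index=z, cx=ann.cx, cy=ann.cy, a=ann.a, b=ann.b)
        )
        res = measure_vbmd(mean_hu, calib, clamp=clamp)
        rows.append(
            {
                "subject": subject,
                "vertebra": ann.vertebra,
                "slice": z,
                "mean_hu": mean_hu,
                "n_voxels": n,
                "bvf": res.bvf,
                "vbmd": res.vbmd,
            }
        )
    return pd.DataFrame(rows)
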