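"""Readers and writers: DICOM CT series / RTDOSE / RTSTRUCT, landmark CSV,
and the package's own compressed-archive format for volumes, fields and masks.

The DICOM writers here produce minimal, synthetic-test-grade objects (enough
attributes for round-tripping through the readers); writing clinical-grade
RT objects is explicitly out of scope.

World-frame mapping: DICOM stores patient coordinates as (x, y, z) while this
package is (z, y, x); ImagePositionPatient / PixelSpacing are reordered on
read and write. Axial, axis-aligned acquisitions are assumed (direction
cosines (1,0,0)/(0,1,0)).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import (
    DeformationField,
    DoseGrid,
    FractionationScheme,
    Geometry,
    ImageVolume,
    LandmarkSet,
    StructureMask,
)

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

LANDMARK_COLUMNS = ["label", "ref_z", "ref_y", "ref_x", "flt_z", "flt_y", "flt_x"]


@dataclass
class CaseBundle:
    """One registration case: the exported DICOM triple of both treatment frames.

    The reference frame is the brachytherapy planning CT (applicator in situ);
    the floating frame is the external-beam planning CT. ``fractionation`` is
    the (EBRT, BRT) scheme pair.
    """

    reference_ct: ImageVolume
    floating_ct: ImageVolume
    reference_dose: DoseGrid | None = None
    floating_dose: DoseGrid | None = None
    masks: list[StructureMask] = dc_field(default_factory=list)
    landmarks: LandmarkSet | None = None
    fractionation: tuple[FractionationScheme, FractionationScheme] | None = None

    def get_mask(self, name: str) -> StructureMask:
        for m in self.masks:
            if m.name == name:
                return m
        raise KeyError(f"no mask named {name!r}; have {[m.name for m in self.masks]}")


# ---------------------------------------------------------------------------
# Internal compressed-archive format (.npz)
# ---------------------------------------------------------------------------
# Keys: kind ("image"|"dose"|"field"|"mask"), data/disp/mask, spacing, origin,
# and name for masks. One object per archive.


def save_volume(path, vol) -> None:
    if isinstance(vol, ImageVolume):
        kind = "image"
    elif isinstance(vol, DoseGrid):
        kind = "dose"
    else:
        raise TypeError(f"cannot serialize {type(vol).__name__} as a volume")
    np.savez_compressed(
        path, kind=kind, data=vol.data, spacing=vol.spacing, origin=vol.origin
    )


def save_field(path, f: DeformationField) -> None:
    np.savez_compressed(
        path, kind="field", disp=f.disp, spacing=f.spacing, origin=f.origin
    )


def save_mask(path, m: StructureMask) -> None:
    np.savez_compressed(
        path, kind="mask", name=m.name, mask=m.mask, spacing=m.spacing, origin=m.origin
    )


def load_archive(path):
    """Load any object saved by the ``save_*`` writers."""
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        spacing = tuple(z["spacing"])
        origin = tuple(z["origin"])
        if kind == "image":
            return ImageVolume(z["data"], spacing, origin)
        if kind == "dose":
            return DoseGrid(z["data"], spacing, origin)
        if kind == "field":
            return DeformationField(z["disp"], spacing, origin)
        if kind == "mask":
            return StructureMask(str(z["name"]), z["mask"], spacing, origin)
    raise ValueError(f"unknown archive kind {kind!r} in {path}")


# ---------------------------------------------------------------------------
# CT series
# ---------------------------------------------------------------------------


def read_ct_series(directory, spacing_tol: float = 1e-3) -> ImageVolume:
    """Read one DICOM CT series from a directory into an ImageVolume (HU).

    Slices are sorted by position along the slice axis regardless of file
    order; RescaleSlope/Intercept are applied. Mixed SeriesInstanceUIDs or
    non-uniform slice spacing raise.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in files]
    uids = {s.SeriesInstanceUID for s in slices}
    if len(uids) != 1:
        raise ValueError(f"directory {directory} holds {len(uids)} series, expected one")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    dz = np.diff(zs)
    if len(dz) == 0:
        raise ValueError("a CT series needs at least two slices")
    if np.ptp(dz) > spacing_tol:
        i = int(np.argmax(np.abs(dz - np.median(dz))))
        raise ValueError(
            f"non-uniform slice spacing: gap {dz[i]:.4f} mm between slices {i} and {i + 1} "
            f"(median {np.median(dz):.4f} mm)"
        )
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)  # row, column spacing
    data = np.stack(
        [
            s.pixel_array.astype(float) * float(getattr(s, "RescaleSlope", 1.0))
            + float(getattr(s, "RescaleIntercept", 0.0))
            for s in slices
        ]
    )
    origin = (
        zs[0],
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[0]),
    )
    return ImageVolume(data, (float(np.median(dz)), dy, dx), origin)


def write_ct_series(directory, vol: ImageVolume, series_uid: str | None = None) -> list[Path]:
    """Write an ImageVolume as a minimal synthetic CT series (one file/slice)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    intercept = -1024.0
    stored = np.rint(vol.data - intercept).astype(np.int16)
    paths = []
    for k in range(vol.shape[0]):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = CT_SOP_CLASS
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = CT_SOP_CLASS
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            vol.origin[2],
            vol.origin[1],
            vol.origin[0] + k * vol.spacing[0],
        ]
        ds.PixelSpacing = [vol.spacing[1], vol.spacing[2]]
        ds.SliceThickness = vol.spacing[0]
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[k].tobytes()
        p = directory / f"ct_{k:04d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# RTDOSE
# ---------------------------------------------------------------------------


def read_rtdose(path) -> DoseGrid:
    """Read an RTDOSE file; stored integers x DoseGridScaling give Gy."""
    ds = pydicom.dcmread(str(path))
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{path}: RTDOSE without DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    data = ds.pixel_array.astype(float) * scaling
    if data.ndim == 2:
        data = data[None]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(np.median(np.diff(offsets))) if len(offsets) > 1 else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    origin = (
        float(ds.ImagePositionPatient[2]) + offsets[0],
        float(ds.ImagePositionPatient[1]),
        float(ds.ImagePositionPatient[0]),
    )
    return DoseGrid(data, (dz, dy, dx), origin)


def write_rtdose(path, dose: DoseGrid, scaling: float | None = None) -> Path:
    """Write a DoseGrid as a minimal synthetic RTDOSE object."""
    if scaling is None:
        peak = float(dose.data.max())
        scaling = peak / (2**31 - 1) if peak > 0 else 1e-4
        scaling = max(scaling, 1e-7)
    stored = np.rint(dose.data / scaling).astype(np.uint32)
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = RTDOSE_SOP_CLASS
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [dose.origin[2], dose.origin[1], dose.origin[0]]
    ds.PixelSpacing = [dose.spacing[1], dose.spacing[2]]
    ds.GridFrameOffsetVector = [k * dose.spacing[0] for k in range(dose.shape[0])]
    ds.NumberOfFrames = dose.shape[0]
    ds.Rows, ds.Columns = dose.shape[1], dose.shape[2]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.tobytes()
    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# RTSTRUCT → masks
# ---------------------------------------------------------------------------


def _points_in_polygon(py: np.ndarray, px: np.ndarray, poly_y: np.ndarray, poly_x: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points."""
    inside = np.zeros(py.shape, dtype=bool)
    n = len(poly_y)
    j = n - 1
    for i in range(n):
        y1, x1 = poly_y[j], poly_x[j]
        y2, x2 = poly_y[i], poly_x[i]
        crosses = (y2 > py) != (y1 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (x1 - x2) * (py - y2) / (y1 - y2) + x2
        inside ^= crosses & (px < xint)
        j = i
    return inside


def rasterize_contour(poly_yx_mm: np.ndarray, geom: Geometry, shape_yx) -> np.ndarray:
    """Rasterize one planar polygon (world mm, (y, x) columns) onto a slice grid.

    A voxel counts as inside when its center is inside under the even-odd rule.
    """
    ny, nx = shape_yx
    ys = np.arange(ny) * geom.spacing[1] + geom.origin[1]
    xs = np.arange(nx) * geom.spacing[2] + geom.origin[2]
    py, px = np.meshgrid(ys, xs, indexing="ij")
    return _points_in_polygon(py, px, poly_yx_mm[:, 0], poly_yx_mm[:, 1])


def read_rtstruct_masks(path, geometry: Geometry, shape, warn=None) -> list[StructureMask]:
    """Rasterize RTSTRUCT planar contours to voxel masks on the given CT grid.

    Contours whose plane does not match a slice within half a slice spacing
    are assigned to the nearest slice after calling ``warn`` (if given) with a
    message. Multiple contours of one ROI on a slice are unioned. Empty
    structures produce empty (flagged) masks.
    """
    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    out = []
    for rc in ds.ROIContourSequence:
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"roi_{number}")
        mask = np.zeros(shape, dtype=bool)
        for contour in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            z_mm = float(np.mean(pts[:, 2]))
            k = (z_mm - geometry.origin[0]) / geometry.spacing[0]
            k_round = int(np.clip(np.rint(k), 0, shape[0] - 1))
            if abs(k - k_round) > 0.5 + 1e-9 and warn is not None:
                warn(
                    f"contour of {name!r} at z={z_mm:.2f} mm matches no slice; "
                    f"assigned to nearest slice {k_round}"
                )
            poly = pts[:, [1, 0]]  # (y, x) world mm
            mask[k_round] |= rasterize_contour(poly, geometry, shape[1:])
        out.append(StructureMask(name, mask, geometry.spacing, geometry.origin))
    return out


def write_rtstruct(path, contours: dict[str, list[np.ndarray]]) -> Path:
    """Write a minimal synthetic RTSTRUCT.

    ``contours`` maps ROI name → list of planar polygons, each an (n, 3) array
    of world-mm (z, y, x) points (constant z per polygon).
    """
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = RTSTRUCT_SOP_CLASS
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, (name, polys) in enumerate(contours.items(), start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi.ROIGenerationAlgorithm = "MANUAL"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = i
        rc.ContourSequence = []
        for poly in polys:
            poly = np.asarray(poly, dtype=float).reshape(-1, 3)
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = poly.shape[0]
            # DICOM order is x, y, z
            c.ContourData = [float(v) for p in poly for v in (p[2], p[1], p[0])]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    path = Path(path)
    ds.save_as(str(path), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# Landmark CSV
# ---------------------------------------------------------------------------


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV {path} missing column(s): {', '.join(missing)}")
    labels = df["label"].astype(str).tolist()
    if len(set(labels)) != len(labels):
        raise ValueError(f"landmark CSV {path} has duplicate labels")
    return LandmarkSet(
        labels,
        df[["ref_z", "ref_y", "ref_x"]].to_numpy(float),
        df[["flt_z", "flt_y", "flt_x"]].to_numpy(float),
    )


def write_landmarks(path, lm: LandmarkSet) -> Path:
    df = pd.DataFrame(
        {
            "label": lm.labels,
            "ref_z": lm.reference_mm[:, 0],
            "ref_y": lm.reference_mm[:, 1],
            "ref_x": lm.reference_mm[:, 2],
            "flt_z": lm.floating_mm[:, 0],
            "flt_y": lm.floating_mm[:, 1],
            "flt_x": lm.floating_mm[:, 2],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g")
    return path
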