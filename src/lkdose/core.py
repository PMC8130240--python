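"""Geometry-aware volume containers and the interpolation/warping primitives.

Everything downstream (registration, dose mapping, evaluation) speaks in terms
of the types defined here. Conventions, fixed once for the whole package:

* arrays are indexed ``(z, y, x)`` — slice axis first, matching how CT series
  stack axial slices;
* ``spacing`` and ``origin`` are in mm, world frame, same ``(z, y, x)`` order;
* displacement fields are stored in *voxel units* of the grid they live on
  (CT voxels are anisotropic — 2.5 mm slices vs ~1 mm in-plane — and the flow
  solver works in index space); convert to mm only for reporting;
* all interpolation is trilinear with edge-clamp (out-of-range coordinates
  read the nearest edge voxel), i.e. backward/pull warping with no holes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.ndimage import map_coordinates


class GeometryError(ValueError):
    """Raised when two grids that must share a geometry do not."""


def _triple(v, name: str) -> tuple[float, float, float]:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.size != 3 or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be 3 finite numbers, got {v!r}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class Geometry:
    """Grid placement in the world frame: mm/voxel spacing and mm origin (z,y,x)."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    def close_to(self, other: "Geometry", tol: float = 1e-6) -> bool:
        return (
            np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def world_to_voxel(geom: Geometry, p_mm) -> np.ndarray:
    """Continuous voxel coordinate of world point(s) ``p_mm`` (..., 3)."""
    p = np.asarray(p_mm, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("world coordinates must be finite")
    return (p - np.asarray(geom.origin)) / np.asarray(geom.spacing)


def voxel_to_world(geom: Geometry, p_voxel) -> np.ndarray:
    """World mm coordinate of continuous voxel point(s) ``p_voxel`` (..., 3)."""
    p = np.asarray(p_voxel, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("voxel coordinates must be finite")
    return p * np.asarray(geom.spacing) + np.asarray(geom.origin)


def _validate_grid(data: np.ndarray, name: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{name} must be a 3D array, got shape {data.shape}")
    if any(n < 2 for n in data.shape):
        raise ValueError(f"every {name} axis must have length >= 2, got {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{name} contains non-finite values")
    return data


@dataclass
class ImageVolume:
    """A 3D grid of Hounsfield units with its world-frame placement."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = _validate_grid(self.data, "image")
        g = Geometry(self.spacing, self.origin)
        self.spacing, self.origin = g.spacing, g.origin

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class DoseGrid:
    """A 3D grid of absorbed dose in Gy (non-negative) with its own geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = _validate_grid(self.data, "dose")
        if np.any(self.data < 0):
            raise ValueError("dose values must be >= 0")
        g = Geometry(self.spacing, self.origin)
        self.spacing, self.origin = g.spacing, g.origin

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class DeformationField:
    """Per-voxel displacement on a reference grid.

    ``disp`` has shape ``(nz, ny, nx, 3)`` with component order ``(dz, dy, dx)``
    in voxel units of the reference grid. Backward-warping semantics: the output
    voxel at index ``x`` reads the input at ``x + disp(x)``.
    """

    disp: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError(
                f"displacement must have shape (nz, ny, nx, 3), got {self.disp.shape}"
            )
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement contains non-finite values")
        g = Geometry(self.spacing, self.origin)
        self.spacing, self.origin = g.spacing, g.origin

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]

    @classmethod
    def zero(cls, shape, spacing, origin=(0.0, 0.0, 0.0)) -> "DeformationField":
        return cls(np.zeros((*shape, 3)), spacing, origin)

    def magnitude_voxels(self) -> np.ndarray:
        return np.linalg.norm(self.disp, axis=-1)

    def disp_mm(self) -> np.ndarray:
        """Displacements converted to mm (reporting only)."""
        return self.disp * np.asarray(self.spacing)


@dataclass
class StructureMask:
    """A named boolean mask on a grid (organ, body contour, applicator...)."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        g = Geometry(self.spacing, self.origin)
        self.spacing, self.origin = g.spacing, g.origin

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.spacing, self.origin)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class LandmarkSet:
    """Paired anatomical points, world mm, in the reference and floating frames."""

    labels: list[str]
    reference_mm: np.ndarray  # (n, 3)
    floating_mm: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.reference_mm = np.asarray(self.reference_mm, dtype=float).reshape(-1, 3)
        self.floating_mm = np.asarray(self.floating_mm, dtype=float).reshape(-1, 3)
        n = len(self.labels)
        if n < 1:
            raise ValueError("a landmark set needs at least one point")
        if len(set(self.labels)) != n:
            raise ValueError("landmark labels must be unique")
        if self.reference_mm.shape[0] != n or self.floating_mm.shape[0] != n:
            raise ValueError("labels and coordinate arrays disagree in length")
        if not (np.all(np.isfinite(self.reference_mm)) and np.all(np.isfinite(self.floating_mm))):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for i, lab in enumerate(self.labels):
            yield lab, self.reference_mm[i], self.floating_mm[i]


@dataclass(frozen=True)
class FractionationScheme:
    """Parameters of the linear-quadratic EQD2 conversion for one course.

    ``alpha_beta_gy`` is the tissue sensitivity ratio alpha/beta: 10 Gy is the
    customary value for tumor response, 3 Gy for late effects in organs at risk.
    """

    total_dose_gy: float | None
    n_fractions: int
    alpha_beta_gy: float

    def __post_init__(self):
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError("n_fractions must be a positive integer")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        if not (self.alpha_beta_gy > 0):
            raise ValueError("alpha/beta must be > 0 Gy")
        if self.total_dose_gy is not None and not (self.total_dose_gy >= 0):
            raise ValueError("total dose must be >= 0 Gy")


# ---------------------------------------------------------------------------
# Interpolation and warping
# ---------------------------------------------------------------------------


def trilinear_sample(vol, p_voxel) -> np.ndarray | float:
    """Trilinear interpolation of ``vol`` at continuous voxel coordinate(s).

    ``p_voxel`` is a single (z, y, x) triple or an (..., 3) array of them.
    Coordinates outside the grid are clamped to the edge. Returns a scalar for
    a single point, an array otherwise.
    """
    p = np.asarray(p_voxel, dtype=float)
    single = p.ndim == 1
    if p.shape[-1] != 3:
        raise ValueError(f"coordinates must end in a 3-axis, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("sample coordinates must be finite")
    data = vol.data if hasattr(vol, "data") else np.asarray(vol, dtype=float)
    pts = p.reshape(-1, 3).T  # (3, n)
    out = map_coordinates(data, pts, order=1, mode="nearest")
    if single:
        return float(out[0])
    return out.reshape(p.shape[:-1])


def _identity_coords(shape) -> np.ndarray:
    """Index grids stacked as (3, nz, ny, nx)."""
    return np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    )


def warp_volume(vol, fieldv: DeformationField):
    """Backward-warp a volume through a deformation field.

    Output voxel ``x`` is filled with a trilinear sample of the input at
    ``x + disp(x)``; the output carries the field's (reference) geometry.
    """
    if vol.data.shape != fieldv.shape:
        raise GeometryError(
            f"volume shape {vol.data.shape} does not match field shape {fieldv.shape}"
        )
    if not vol.geometry.close_to(fieldv.geometry):
        raise GeometryError(
            f"volume geometry {vol.geometry} does not match field geometry {fieldv.geometry}"
        )
    coords = _identity_coords(vol.data.shape) + np.moveaxis(fieldv.disp, -1, 0)
    out = map_coordinates(vol.data, coords, order=1, mode="nearest")
    if isinstance(vol, DoseGrid):
        out = np.maximum(out, 0.0)  # guard fp round-off below zero
        return DoseGrid(out, fieldv.spacing, fieldv.origin)
    return ImageVolume(out, fieldv.spacing, fieldv.origin)


def compose_update(base: DeformationField, update: DeformationField) -> DeformationField:
    """Compose an incremental field with an existing one.

    ``disp_out(x) = update(x) + disp_base(x + update(x))`` with the base field
    sampled trilinearly — true composition, not plain addition, so that the
    residual flow of one refinement step chains correctly onto the estimate it
    was computed against.
    """
    if base.shape != update.shape or not base.geometry.close_to(update.geometry):
        raise GeometryError("base and update fields must share shape and geometry")
    coords = _identity_coords(base.shape) + np.moveaxis(update.disp, -1, 0)
    out = np.empty_like(base.disp)
    for c in range(3):
        out[..., c] = update.disp[..., c] + map_coordinates(
            base.disp[..., c], coords, order=1, mode="nearest"
        )
    return DeformationField(out, base.spacing, base.origin)


def resample_volume(vol, geometry: Geometry, shape):
    """Trilinear resampling of a volume onto another grid (edge-clamped)."""
    idx = _identity_coords(shape)
    world = np.moveaxis(idx, 0, -1) * np.asarray(geometry.spacing) + np.asarray(
        geometry.origin
    )
    src = world_to_voxel(vol.geometry, world)
    out = map_coordinates(vol.data, np.moveaxis(src, -1, 0), order=1, mode="nearest")
    if isinstance(vol, DoseGrid):
        return DoseGrid(np.maximum(out, 0.0), geometry.spacing, geometry.origin)
    return ImageVolume(out, geometry.spacing, geometry.origin)
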