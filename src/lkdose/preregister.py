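"""Rigid and affine preregistration of the floating CT to the reference CT.

Deformable flow linearizes small motion, so gross misalignment (couch/position
differences between the EBRT and BRT planning scans) must be removed first:
a user-supplied rigid transform for bone matching, then an automatic affine
registration minimizing the masked mean-squared HU difference by
multi-resolution gradient descent (analytic gradients, backtracking step
halving).

Transform convention: :class:`AffineTransform` maps *floating-frame* world
points forward into the *reference frame*, ``p_ref = M p_flt + t`` (z, y, x
order). Resampling a floating volume onto the reference grid therefore pulls
intensities through the inverse map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    DeformationField,
    DoseGrid,
    Geometry,
    ImageVolume,
    LandmarkSet,
    StructureMask,
    _identity_coords,
    voxel_to_world,
    world_to_voxel,
)
from .lk import build_pyramid


@dataclass(frozen=True)
class AffineTransform:
    """World-frame affine map p_ref = matrix @ p_flt + translation (mm, z/y/x)."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(t))):
            raise ValueError("affine parameters must be finite")
        if abs(np.linalg.det(m)) <= 1e-8:
            raise ValueError("affine matrix is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply_points(self, p_mm) -> np.ndarray:
        p = np.asarray(p_mm, dtype=float)
        return p @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        minv = np.linalg.inv(self.matrix)
        return AffineTransform(minv, -minv @ self.translation)

    def compose(self, inner: "AffineTransform") -> "AffineTransform":
        """self ∘ inner (apply ``inner`` first)."""
        return AffineTransform(
            self.matrix @ inner.matrix, self.matrix @ inner.translation + self.translation
        )

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "convention": "p_ref = matrix @ p_flt + translation, mm, (z,y,x)",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"]), np.asarray(d["translation"]))


@dataclass(frozen=True)
class AffineRegParams:
    """Optimizer knobs for :func:`affine_register`."""

    levels: int = 3
    max_iters: int = 60
    step0: float = 1.0  # initial step in scaled parameter space
    tol: float = 1e-7  # relative MSE improvement below which a level stops
    sampling_fraction: float = 1.0  # <1 evaluates a deterministic strided subset
    matrix_scale: float = 0.01  # scaled-space unit for matrix entries
    translation_scale_mm: float = 1.0  # scaled-space unit for translations

    def __post_init__(self):
        if self.levels < 1 or self.max_iters < 1 or self.tol <= 0:
            raise ValueError("levels >= 1, max_iters >= 1 and tol > 0 required")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling_fraction must be in (0, 1]")


class RegistrationError(RuntimeError):
    pass


def _rotation_matrix(rz_deg: float, ry_deg: float, rx_deg: float) -> np.ndarray:
    """Rotation about the world z, then y, then x axes, in (z,y,x) coordinates."""
    rz, ry, rx = np.deg2rad([rz_deg, ry_deg, rx_deg])
    # rotation about z mixes (y, x); about y mixes (z, x); about x mixes (z, y)
    cz, sz = np.cos(rz), np.sin(rz)
    mz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    cy, sy = np.cos(ry), np.sin(ry)
    my = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    cx, sx = np.cos(rx), np.sin(rx)
    mx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return mx @ my @ mz


def _volume_center_mm(vol) -> np.ndarray:
    return voxel_to_world(vol.geometry, (np.asarray(vol.shape) - 1) / 2.0)


def rigid_transform(
    translation_mm: Sequence[float],
    rotation_deg_axes: Sequence[float] = (0.0, 0.0, 0.0),
    center_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> AffineTransform:
    """Rigid transform: rotate (deg, about z/y/x through ``center_mm``) then translate."""
    rot = _rotation_matrix(*rotation_deg_axes)
    c = np.asarray(center_mm, dtype=float)
    t = np.asarray(translation_mm, dtype=float) + c - rot @ c
    return AffineTransform(rot, t)


def apply_affine(obj, t: AffineTransform, geometry: Geometry | None = None, shape=None):
    """Apply an affine transform to a volume, dose grid, mask or landmark set.

    Volumes are resampled backward through ``t`` onto the output grid (the
    object's own grid unless ``geometry``/``shape`` are given). Landmark
    floating coordinates are mapped forward through ``t`` so they live in the
    affine-aligned frame; reference coordinates are untouched.
    """
    if isinstance(obj, LandmarkSet):
        return LandmarkSet(
            list(obj.labels), obj.reference_mm.copy(), t.apply_points(obj.floating_mm)
        )
    geometry = geometry or obj.geometry
    shape = shape if shape is not None else (
        obj.mask.shape if isinstance(obj, StructureMask) else obj.data.shape
    )
    tinv = t.inverse()
    idx = np.moveaxis(_identity_coords(shape), 0, -1)
    world = voxel_to_world(geometry, idx)
    src_world = tinv.apply_points(world)
    src_vox = world_to_voxel(obj.geometry, src_world)
    coords = np.moveaxis(src_vox, -1, 0)
    if isinstance(obj, StructureMask):
        vals = map_coordinates(
            obj.mask.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        return StructureMask(obj.name, vals >= 0.5, geometry.spacing, geometry.origin)
    vals = map_coordinates(obj.data, coords, order=1, mode="nearest")
    if isinstance(obj, DoseGrid):
        return DoseGrid(np.maximum(vals, 0.0), geometry.spacing, geometry.origin)
    return ImageVolume(vals, geometry.spacing, geometry.origin)


def apply_rigid(
    vol,
    translation_mm: Sequence[float],
    rotation_deg_axes: Sequence[float] = (0.0, 0.0, 0.0),
):
    """User-supplied rigid preregistration (bone matching is done by eye).

    Rotation is taken about the volume center. Resamples backward onto the
    volume's own grid.
    """
    t = rigid_transform(translation_mm, rotation_deg_axes, _volume_center_mm(vol))
    return apply_affine(vol, t)


def _params_to_transform(q: np.ndarray, p: AffineRegParams, center: np.ndarray) -> AffineTransform:
    m = np.eye(3) + (q[:9] * p.matrix_scale).reshape(3, 3)
    t = q[9:] * p.translation_scale_mm
    # parameterize about the volume center so matrix and translation decouple
    return AffineTransform(m, t + center - m @ center)


def affine_register(
    floating: ImageVolume,
    reference: ImageVolume,
    params: AffineRegParams = AffineRegParams(),
    body_mask: StructureMask | None = None,
) -> AffineTransform:
    """Automatic affine registration by masked-MSE gradient descent.

    Minimizes the mean squared HU difference between the reference and the
    affinely resampled floating image (within ``body_mask`` when given,
    mirroring the patient-only similarity evaluation), coarse to fine over a
    multi-resolution pyramid. Deterministic given its parameters. The final
    MSE never exceeds the initial one: only improving steps are accepted.
    """
    ref_pyr = build_pyramid(reference, params.levels)
    flt_pyr = build_pyramid(floating, params.levels)
    mask_pyr = None
    if body_mask is not None:
        mvol = ImageVolume(
            body_mask.mask.astype(float) + 0.0, body_mask.spacing, body_mask.origin
        )
        mask_pyr = [m.data >= 0.5 for m in build_pyramid(mvol, params.levels)]

    center = _volume_center_mm(reference)
    # optimize the pullback map s = t^{-1} (reference world -> floating world)
    # directly: the objective only touches t through it, and its gradient is
    # then a single chain rule instead of 24 extra resamples per iteration
    q = np.zeros(12)
    scale = np.concatenate(
        [np.full(9, params.matrix_scale), np.full(3, params.translation_scale_mm)]
    )

    def pullback(qv: np.ndarray) -> AffineTransform:
        m = np.eye(3) + (qv[:9] * params.matrix_scale).reshape(3, 3)
        u = qv[9:] * params.translation_scale_mm
        return AffineTransform(m, u + center - m @ center)

    def level_state(level: int, qv: np.ndarray):
        """Masked MSE and its gradient in scaled parameter space."""
        ref_l, flt_l = ref_pyr[level], flt_pyr[level]
        s = pullback(qv)
        idx = np.moveaxis(_identity_coords(ref_l.shape), 0, -1)
        world = voxel_to_world(ref_l.geometry, idx)
        src_world = s.apply_points(world)
        src_vox = world_to_voxel(flt_l.geometry, src_world)
        coords = np.moveaxis(src_vox, -1, 0)
        moved = map_coordinates(flt_l.data, coords, order=1, mode="nearest")
        sel = None
        if mask_pyr is not None and mask_pyr[level].any():
            sel = mask_pyr[level]
        r = moved - ref_l.data
        if sel is not None:
            r_sel = r[sel]
        else:
            r_sel = r.reshape(-1)
        mse = float(np.mean(r_sel**2))
        # HU gradient of the floating image at the sample points, per world mm
        g = np.stack(
            [
                map_coordinates(gc, coords, order=1, mode="nearest")
                for gc in np.gradient(flt_l.data, axis=(0, 1, 2))
            ],
            axis=-1,
        ) / np.asarray(flt_l.spacing)
        wc = world - center
        if sel is not None:
            g, wc = g[sel], wc[sel]
        else:
            g, wc = g.reshape(-1, 3), wc.reshape(-1, 3)
        n = r_sel.size
        grad_u = 2.0 / n * (r_sel[:, None] * g).sum(axis=0)  # d/du
        grad_m = 2.0 / n * np.einsum("n,ni,nj->ij", r_sel, g, wc)  # d/dQ
        grad = np.concatenate([grad_m.reshape(9), grad_u]) * scale
        return mse, grad

    from scipy.optimize import minimize

    for level in range(params.levels - 1, -1, -1):
        mse0, _ = level_state(level, q)
        if not np.isfinite(mse0):
            raise RegistrationError(f"non-finite MSE at level {level}")
        res = minimize(
            lambda qv: level_state(level, qv),
            q,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": params.max_iters, "ftol": params.tol},
        )
        # line-searched quasi-Newton steps only ever accept improvements, so
        # the per-level MSE trace is non-increasing; keep the guarantee explicit
        if np.isfinite(res.fun) and res.fun <= mse0:
            q = res.x
    return pullback(q).inverse()


def affine_to_field(
    t: AffineTransform, geometry: Geometry, shape
) -> DeformationField:
    """Displacement field (reference-grid voxel units) equivalent to an affine map.

    The field carries backward-warp semantics: voxel x of the reference grid
    reads the floating frame at ``x + disp(x)``, i.e. at ``t^{-1}(world(x))``.
    """
    tinv = t.inverse()
    idx = np.moveaxis(_identity_coords(shape), 0, -1)
    world = voxel_to_world(geometry, idx)
    src_vox = world_to_voxel(geometry, tinv.apply_points(world))
    return DeformationField(src_vox - idx, geometry.spacing, geometry.origin)


def compose_affine_field(
    t: AffineTransform, field: DeformationField
) -> DeformationField:
    """Total backward field of "affine resample then deformable field".

    The pipeline registers the affinely resampled floating image with the LK
    field u, so the composite mapping from a reference voxel x to the original
    floating frame is ``t^{-1}(world(x + u(x)))``. Returned in reference-grid
    voxel units with the usual backward semantics.
    """
    tinv = t.inverse()
    idx = np.moveaxis(_identity_coords(field.shape), 0, -1)
    world = voxel_to_world(field.geometry, idx + field.disp)
    src_vox = world_to_voxel(field.geometry, tinv.apply_points(world))
    return DeformationField(src_vox - idx, field.spacing, field.origin)
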