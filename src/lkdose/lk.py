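"""Weighted-window Lucas-Kanade optical flow in 3D with a coarse-to-fine
image pyramid — the deformable registration engine of this package.

The flow model assumes HU conservation and locally constant motion: within a
(2r+1)^3 window around each voxel, every neighbour contributes one linearized
brightness-constancy equation

    g(x') . v  =  -g_t(x'),

where g is the spatial HU gradient of the (current-estimate-warped) floating
image and g_t its difference to the reference. Neighbours are weighted by a
Gaussian of their distance, so each voxel solves the 3x3 weighted normal
system

    ( sum_w w g g^T ) v  =  - sum_w w g g_t .

Homogeneous tissue gives a (near-)singular system — the aperture problem —
handled by solving only in the eigensubspace of the normal matrix whose
eigenvalues clear a threshold (fully homogeneous windows update by zero,
edge-like structure by its observable normal-flow component) rather than by
regularizing; no post-optimization smoothing of the field is applied anywhere.

Large motions are handled by the pyramid: the flow is estimated at the
coarsest half-resolution-per-level image first, upsampled (displacements
scaled by the resolution ratio) as the initial estimate of the next finer
level, where only the residual flow is solved — so the small-motion
linearization stays valid even for deformations of many voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d, gaussian_filter

from .core import (
    DeformationField,
    GeometryError,
    ImageVolume,
    compose_update,
    trilinear_sample,
    warp_volume,
    _identity_coords,
)


@dataclass(frozen=True)
class LKParams:
    """Lucas-Kanade registration parameters.

    pyramid_levels: number of pyramid levels (1 = single resolution). Two
        levels with window radius 3 is the optimum found on clinical pelvic
        CTs and is the default.
    window_radius_voxels: neighborhood radius r; the window is (2r+1)^3.
    weight_sigma_voxels: Gaussian window-weight width; defaults to r/2.
    iters_per_level: warp/solve refinement iterations per pyramid level.
    min_eigen_threshold: eigenvalue cutoff on the (weight-normalized) normal
        matrix; eigendirections below it contribute no update (aperture
        problem handling).
    update_clip_voxels: per-iteration clamp on each displacement component.
    stop_mean_update_voxels: early stop when the mean update norm falls below.
    """

    pyramid_levels: int = 2
    window_radius_voxels: int = 3
    weight_sigma_voxels: float | None = None
    iters_per_level: int = 5
    min_eigen_threshold: float = 1e-4
    update_clip_voxels: float = 1.5
    stop_mean_update_voxels: float = 0.01

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.window_radius_voxels < 1:
            raise ValueError("window_radius_voxels must be >= 1")
        if self.weight_sigma_voxels is not None and self.weight_sigma_voxels <= 0:
            raise ValueError("weight_sigma_voxels must be > 0")
        if self.iters_per_level < 1:
            raise ValueError("iters_per_level must be >= 1")
        if self.min_eigen_threshold < 0:
            raise ValueError("min_eigen_threshold must be >= 0")

    @property
    def sigma(self) -> float:
        return (
            self.weight_sigma_voxels
            if self.weight_sigma_voxels is not None
            else self.window_radius_voxels / 2.0
        )


def spatial_gradients(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial HU derivatives (gz, gy, gx) in HU/voxel.

    Central differences on the interior, one-sided at borders (np.gradient
    semantics). Every axis must have length >= 2.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or any(n < 2 for n in data.shape):
        raise ValueError(f"need a 3D array with all axes >= 2, got shape {data.shape}")
    gz, gy, gx = np.gradient(data, axis=(0, 1, 2))
    return gz, gy, gx


def window_kernels(radius: int, sigma: float) -> list[np.ndarray]:
    """Separable 1D Gaussian window weights, jointly normalized to unit mass."""
    ax = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(ax**2) / (2.0 * sigma**2))
    total = k.sum() ** 3  # full 3D mass before normalization
    k_norm = k / np.cbrt(total)
    return [k_norm, k_norm, k_norm]


def _windowed_sum(arr: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    # zero padding: window truncated at the volume border
    out = arr
    for axis, k in enumerate(kernels):
        out = correlate1d(out, k, axis=axis, mode="constant", cval=0.0)
    return out


def smallest_eigenvalue_sym3(
    a00, a01, a02, a11, a12, a22
) -> np.ndarray:
    """Smallest eigenvalue of symmetric 3x3 matrices, vectorized (trig method)."""
    a00, a01, a02, a11, a12, a22 = (np.asarray(a) for a in (a00, a01, a02, a11, a12, a22))
    p1 = a01**2 + a02**2 + a12**2
    q = (a00 + a11 + a22) / 3.0
    p2 = (a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2, 0.0) / 6.0)
    safe_p = np.where(p > 0, p, 1.0)
    b00, b11, b22 = (a00 - q) / safe_p, (a11 - q) / safe_p, (a22 - q) / safe_p
    b01, b02, b12 = a01 / safe_p, a02 / safe_p, a12 / safe_p
    detb = (
        b00 * (b11 * b22 - b12 * b12)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    lam_min = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    return np.where(p > 0, lam_min, q)


def solve_gated_sym3(tensor_entries, rhs, eigen_threshold: float) -> np.ndarray:
    """Solve the per-voxel weighted normal systems in their well-conditioned
    eigensubspace.

    ``tensor_entries`` are the six unique entries (zz, zy, zx, yy, yx, xx) of
    the symmetric normal matrix per voxel, ``rhs`` the stacked (..., 3) right
    hand side. Eigendirections with eigenvalue below ``eigen_threshold`` are
    zeroed: a fully homogeneous window (all eigenvalues small — the aperture
    problem) yields no update, while 1D/2D intensity structure still yields
    its observable normal-flow component.
    """
    azz, azy, azx, ayy, ayx, axx = tensor_entries
    shape = azz.shape
    a = np.empty((*shape, 3, 3))
    a[..., 0, 0] = azz
    a[..., 0, 1] = a[..., 1, 0] = azy
    a[..., 0, 2] = a[..., 2, 0] = azx
    a[..., 1, 1] = ayy
    a[..., 1, 2] = a[..., 2, 1] = ayx
    a[..., 2, 2] = axx
    w, vecs = np.linalg.eigh(a.reshape(-1, 3, 3))
    winv = np.where(w >= eigen_threshold, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    proj = np.einsum("nij,nj->ni", vecs.transpose(0, 2, 1), rhs.reshape(-1, 3))
    sol = np.einsum("nij,nj->ni", vecs, winv * proj)
    return sol.reshape(*shape, 3)


def lk_normal_system(
    ref: np.ndarray, warped: np.ndarray, radius: int, sigma: float
):
    """Windowed normal-equation terms at every voxel.

    Returns the six unique entries of ``sum w g g^T`` (zz, zy, zx, yy, yx, xx)
    and the three of ``sum w g g_t`` (z, y, x), with the Gaussian window
    normalized to unit mass and truncated at the volume border.
    """
    gt = warped - ref
    gz, gy, gx = spatial_gradients(warped)
    kernels = window_kernels(radius, sigma)
    w = lambda a: _windowed_sum(a, kernels)
    return (
        (w(gz * gz), w(gz * gy), w(gz * gx), w(gy * gy), w(gy * gx), w(gx * gx)),
        (w(gz * gt), w(gy * gt), w(gx * gt)),
    )


def lk_flow_level(
    ref: ImageVolume,
    flt: ImageVolume,
    params: LKParams,
    init_field: DeformationField | None = None,
) -> DeformationField:
    """Iterative weighted-window LK flow at a single resolution.

    Each iteration warps the floating image through the current field, solves
    the per-voxel weighted 3x3 normal system for the residual flow (in the
    well-conditioned eigensubspace), clips the update, and composes it into
    the field. Deterministic.
    """
    if ref.shape != flt.shape:
        raise GeometryError(f"shape mismatch: ref {ref.shape} vs floating {flt.shape}")
    field = (
        init_field
        if init_field is not None
        else DeformationField.zero(ref.shape, ref.spacing, ref.origin)
    )
    if field.shape != ref.shape:
        raise GeometryError(f"init field shape {field.shape} != image shape {ref.shape}")
    for _ in range(params.iters_per_level):
        warped = warp_volume(flt, field)
        tensor, (bz, by, bx) = lk_normal_system(
            ref.data, warped.data, params.window_radius_voxels, params.sigma
        )
        rhs = -np.stack([bz, by, bx], axis=-1)
        upd = solve_gated_sym3(tensor, rhs, params.min_eigen_threshold)
        c = params.update_clip_voxels
        np.clip(upd, -c, c, out=upd)
        mean_update = float(np.linalg.norm(upd, axis=-1).mean())
        field = compose_update(field, DeformationField(upd, ref.spacing, ref.origin))
        if mean_update < params.stop_mean_update_voxels:
            break
    return field


def build_pyramid(vol: ImageVolume, levels: int) -> list[ImageVolume]:
    """Coarse-to-fine image pyramid; element 0 is the input resolution.

    Each next level is Gaussian-smoothed (sigma 1 voxel on downsampled axes)
    and decimated by 2 in-plane; the slice axis is decimated only while at
    least 8 slices remain (2.5 mm slices are already coarse). Spacing metadata
    doubles on decimated axes so world placement is preserved.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out = [vol]
    for _ in range(levels - 1):
        prev = out[-1]
        if prev.shape[1] // 2 < 4 or prev.shape[2] // 2 < 4:
            raise ValueError(
                f"cannot build {levels} pyramid levels: level {len(out)} would be "
                f"smaller than 4 voxels in-plane (have {prev.shape})"
            )
        down_z = prev.shape[0] >= 8
        sigma = (1.0 if down_z else 0.0, 1.0, 1.0)
        sm = gaussian_filter(prev.data, sigma=sigma)
        step_z = 2 if down_z else 1
        data = sm[::step_z, ::2, ::2]
        spacing = (
            prev.spacing[0] * step_z,
            prev.spacing[1] * 2.0,
            prev.spacing[2] * 2.0,
        )
        out.append(ImageVolume(data, spacing, prev.origin))
    return out


def upsample_field(field: DeformationField, fine: ImageVolume) -> DeformationField:
    """Interpolate a coarse-level field onto a finer level as an initial estimate.

    Displacement components are multiplied by the per-axis resolution ratio
    (coarse spacing / fine spacing), i.e. 2 on decimated axes.
    """
    ratio = np.asarray(field.spacing) / np.asarray(fine.spacing)
    idx = np.moveaxis(_identity_coords(fine.shape), 0, -1)  # (nz,ny,nx,3)
    coarse_coords = idx / ratio
    disp = np.empty((*fine.shape, 3))
    for c in range(3):
        disp[..., c] = trilinear_sample(field.disp[..., c], coarse_coords) * ratio[c]
    return DeformationField(disp, fine.spacing, fine.origin)


def pyramid_lk_register(
    ref: ImageVolume, flt: ImageVolume, params: LKParams = LKParams()
) -> DeformationField:
    """Coarse-to-fine LK registration of ``flt`` onto ``ref``.

    Runs the single-level solver at the coarsest pyramid level with a zero
    initial field, upsamples the result as the next level's initial estimate,
    and repeats down to full resolution. The returned field is unregularized;
    use :func:`negative_jacobian_count` to diagnose folding.
    """
    if ref.shape != flt.shape or not ref.geometry.close_to(flt.geometry):
        raise GeometryError("reference and floating volumes must share a geometry")
    refs = build_pyramid(ref, params.pyramid_levels)
    flts = build_pyramid(flt, params.pyramid_levels)
    field: DeformationField | None = None
    for level in range(params.pyramid_levels - 1, -1, -1):
        init = None if field is None else upsample_field(field, refs[level])
        field = lk_flow_level(refs[level], flts[level], params, init)
    return field


def negative_jacobian_count(field: DeformationField) -> int:
    """Number of voxels where the mapping x + disp(x) folds (Jacobian det <= 0).

    Diagnostic only — the solver applies no regularization, so a nonzero count
    flags locally non-diffeomorphic (visually unrealistic) deformations.
    """
    mapping = np.moveaxis(_identity_coords(field.shape), 0, -1) + field.disp
    jac = np.empty((*field.shape, 3, 3))
    for c in range(3):
        gz, gy, gx = np.gradient(mapping[..., c], axis=(0, 1, 2))
        jac[..., c, 0], jac[..., c, 1], jac[..., c, 2] = gz, gy, gx
    det = np.linalg.det(jac)
    return int((det <= 0).sum())
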