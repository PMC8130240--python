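"""Registration-accuracy metrics and DVH hot-spot analysis.

Three complementary similarity measures, because none is sufficient alone:
landmark distances probe true anatomical correspondence but only where points
were marked; HU RMSE covers every voxel but over-penalizes steep edges; 2D
gamma analysis combines a value criterion (%) with a distance-to-agreement
criterion (mm) per axial slice. Plus the GEC-ESTRO style hot-spot DVH
parameters D_0.1cm3 / D_2cm3 and the comparison of plain DVH-parameter
addition against deformation-based accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .core import (
    DeformationField,
    DoseGrid,
    GeometryError,
    ImageVolume,
    LandmarkSet,
    StructureMask,
    trilinear_sample,
    voxel_to_world,
    world_to_voxel,
)
from .dose import accumulate, map_dose


# ---------------------------------------------------------------------------
# Landmark distance
# ---------------------------------------------------------------------------


@dataclass
class LandmarkDistanceSummary:
    mean_mm: float
    min_mm: float
    max_mm: float
    per_point_mm: np.ndarray


def landmark_distance(
    landmarks: LandmarkSet, field: DeformationField | None = None
) -> LandmarkDistanceSummary:
    """3D world-mm distance between paired points, optionally through a field.

    Without a field: plain Euclidean distance between the reference and
    floating annotations. With a field: each reference point is mapped through
    the field (x + disp(x), trilinear, converted back to mm) to its predicted
    floating-frame location and the residual to the annotated floating point
    is reported — the target registration error of the field.
    """
    if len(landmarks) < 1:
        raise ValueError("empty landmark set")
    if field is None:
        d = np.linalg.norm(landmarks.reference_mm - landmarks.floating_mm, axis=1)
    else:
        geom = field.geometry
        p_vox = world_to_voxel(geom, landmarks.reference_mm)
        disp = np.stack(
            [trilinear_sample(field.disp[..., c], p_vox) for c in range(3)], axis=-1
        )
        predicted = voxel_to_world(geom, p_vox + disp)
        d = np.linalg.norm(predicted - landmarks.floating_mm, axis=1)
    return LandmarkDistanceSummary(float(d.mean()), float(d.min()), float(d.max()), d)


# ---------------------------------------------------------------------------
# RMSE
# ---------------------------------------------------------------------------


def rmse_within_mask(
    ref: ImageVolume, registered: ImageVolume, body_mask: StructureMask
) -> float:
    """Root mean squared HU difference over the body mask.

    Evaluated only within the patient: couch, positioning aids and air differ
    between the two acquisitions and would dominate an unmasked value.
    """
    if ref.shape != registered.shape or not ref.geometry.close_to(registered.geometry):
        raise GeometryError("reference and registered volumes must share a grid")
    if body_mask.mask.shape != ref.shape:
        raise GeometryError("body mask must live on the image grid")
    if body_mask.is_empty:
        raise ValueError("body mask is empty")
    diff = ref.data[body_mask.mask] - registered.data[body_mask.mask]
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# Gamma analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaParams:
    """2D gamma criteria and search discretization.

    Defaults are the 2%/2 mm local criteria. ``search_radius_mm`` /
    ``search_step_mm`` default to 3x and 1/10 of the distance criterion.
    ``local_floor`` (HU) bounds the local normalization away from zero.
    ``gamma_cap`` (optional) truncates gamma values above the cap and lets the
    distance-ordered search stop early; pass rates are exact for any cap >= 1.
    ``global_norm_value``: fixed normalization value for global mode; when
    None the reference slice's dynamic range (max - min over evaluated pixels)
    is used, which keeps the pass rate invariant under a common HU offset.
    """

    dose_crit_pct: float = 2.0
    dist_crit_mm: float = 2.0
    mode: str = "local"
    search_radius_mm: float | None = None
    search_step_mm: float | None = None
    low_cut: float | None = None
    local_floor: float = 1.0
    gamma_cap: float | None = None
    global_norm_value: float | None = None

    def __post_init__(self):
        if self.dose_crit_pct <= 0 or self.dist_crit_mm <= 0:
            raise ValueError("gamma criteria must be > 0")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")
        if self.radius < self.dist_crit_mm:
            raise ValueError("search radius must be >= the distance criterion")
        if self.step > self.dist_crit_mm / 4 + 1e-12:
            raise ValueError("search step must be <= dist_crit/4")

    @property
    def radius(self) -> float:
        return self.search_radius_mm if self.search_radius_mm is not None else 3.0 * self.dist_crit_mm

    @property
    def step(self) -> float:
        return self.search_step_mm if self.search_step_mm is not None else self.dist_crit_mm / 10.0


def _search_offsets(params: GammaParams) -> np.ndarray:
    """(n, 3) array of (dy_mm, dx_mm, dist_mm) offsets, sorted by distance."""
    nsteps = int(np.floor(params.radius / params.step + 1e-9))
    ax = np.arange(-nsteps, nsteps + 1) * params.step
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    dist = np.hypot(dy, dx)
    keep = dist <= params.radius + 1e-9
    out = np.stack([dy[keep], dx[keep], dist[keep]], axis=1)
    return out[np.argsort(out[:, 2], kind="stable")]


def gamma_slice(
    ref_slice: np.ndarray,
    eval_slice: np.ndarray,
    spacing_yx_mm,
    params: GammaParams = GammaParams(),
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Gamma map and pass rate (%) for one axial slice pair.

    For each evaluated reference pixel r the gamma index is the minimum over
    candidate positions e on a ``step``-spaced grid within ``radius`` of

        sqrt( (|e - r| / dist_crit)^2 + ((V_eval(e) - V_ref(r)) / dV(r))^2 ),

    with V_eval interpolated bilinearly and dV(r) the dose (value) criterion:
    ``pct% * |V_ref(r)|`` (floored) in local mode, ``pct% * norm`` in global
    mode. A pixel passes when gamma <= 1. Returns (map with NaN outside the
    evaluated region, pass rate in %); the pass rate is NaN when nothing is
    evaluated (degenerate mask), and callers should then exclude the slice.
    """
    ref_slice = np.asarray(ref_slice, dtype=float)
    eval_slice = np.asarray(eval_slice, dtype=float)
    if ref_slice.shape != eval_slice.shape or ref_slice.ndim != 2:
        raise ValueError("slices must be 2D and share a shape")
    sy, sx = float(spacing_yx_mm[0]), float(spacing_yx_mm[1])
    sel = np.ones(ref_slice.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if params.low_cut is not None:
        sel = sel & (np.abs(ref_slice) >= params.low_cut)
    gamma_map = np.full(ref_slice.shape, np.nan)
    n_eval = int(sel.sum())
    if n_eval == 0:
        return gamma_map, float("nan")

    iy, ix = np.nonzero(sel)
    refv = ref_slice[iy, ix]
    if params.mode == "local":
        denom = params.dose_crit_pct / 100.0 * np.maximum(np.abs(refv), params.local_floor)
    else:
        norm = (
            params.global_norm_value
            if params.global_norm_value is not None
            else float(refv.max() - refv.min())
        )
        denom = np.full(refv.shape, params.dose_crit_pct / 100.0 * max(norm, params.local_floor))

    best = np.full(refv.shape, np.inf)
    cap2 = params.gamma_cap**2 if params.gamma_cap is not None else np.inf
    for dy, dx, dist in _search_offsets(params):
        spatial2 = (dist / params.dist_crit_mm) ** 2
        # beyond this distance no unexplored position can beat the cap or any
        # pixel's current minimum (strict: the boundary itself may still tie)
        if spatial2 > min(cap2, best.max()):
            break
        vals = map_coordinates(
            eval_slice,
            np.stack([iy + dy / sy, ix + dx / sx]),
            order=1,
            mode="nearest",
        )
        g2 = spatial2 + ((vals - refv) / denom) ** 2
        np.minimum(best, g2, out=best)
    # pass/fail is decided on the un-truncated minima (exact for any cap >= 1)
    pass_rate = 100.0 * float((best <= 1.0 + 1e-12).sum()) / n_eval
    gamma = np.sqrt(best)
    if params.gamma_cap is not None:
        gamma = np.minimum(gamma, params.gamma_cap)
    gamma_map[iy, ix] = gamma
    return gamma_map, pass_rate


@dataclass
class GammaReport:
    study_score_pct: float
    per_slice_pct: pd.DataFrame  # columns: slice, pass_rate_pct, n_evaluated


def gamma_study(
    ref: ImageVolume,
    registered: ImageVolume,
    body_mask: StructureMask,
    params: GammaParams = GammaParams(),
) -> GammaReport:
    """Per-axial-slice 2D gamma pass rates and their study average.

    Slices with no evaluable pixel (empty mask) are excluded from the average;
    the per-slice table is retained because outer slices systematically score
    worse than the central region of interest.
    """
    if ref.shape != registered.shape or body_mask.mask.shape != ref.shape:
        raise GeometryError("volumes and body mask must share a grid")
    rows = []
    for k in range(ref.shape[0]):
        msk = body_mask.mask[k]
        if not msk.any():
            continue
        _, rate = gamma_slice(
            ref.data[k], registered.data[k], ref.spacing[1:], params, mask=msk
        )
        if np.isnan(rate):
            continue
        rows.append({"slice": k, "pass_rate_pct": rate, "n_evaluated": int(msk.sum())})
    if not rows:
        raise ValueError("no evaluable slice in the body mask")
    table = pd.DataFrame(rows)
    return GammaReport(float(table["pass_rate_pct"].mean()), table)


# ---------------------------------------------------------------------------
# DVH / hot-spot parameters
# ---------------------------------------------------------------------------


def dvh(dose: DoseGrid, mask: StructureMask, bin_gy: float = 0.01):
    """Cumulative DVH: (dose bins, fractional volume receiving >= bin)."""
    if mask.is_empty:
        raise ValueError("structure mask is empty")
    if mask.mask.shape != dose.shape:
        raise GeometryError("mask must live on the dose grid")
    doses = dose.data[mask.mask]
    top = float(doses.max())
    bins = np.arange(0.0, top + bin_gy, bin_gy)
    frac = np.searchsorted(np.sort(doses), bins, side="left")
    frac = 1.0 - frac / doses.size
    return bins, frac


def dose_at_volume(dose: DoseGrid, mask: StructureMask, v_cm3: float) -> float:
    """Minimum dose to the hottest ``v_cm3`` of the structure (exact estimator).

    Computed by sorting masked voxel doses in descending order and taking the
    k-th value with k = ceil(v / voxel_volume) — no DVH binning involved.
    """
    if mask.is_empty:
        raise ValueError("structure mask is empty")
    if mask.mask.shape != dose.shape:
        raise GeometryError("mask must live on the dose grid")
    if v_cm3 <= 0:
        raise ValueError("volume must be > 0 cm^3")
    voxel_cm3 = float(np.prod(dose.spacing)) / 1000.0
    n = mask.voxel_count()
    structure_cm3 = n * voxel_cm3
    if v_cm3 > structure_cm3 + 1e-12:
        raise ValueError(
            f"requested volume {v_cm3:g} cm^3 exceeds structure volume {structure_cm3:g} cm^3"
        )
    k = int(np.ceil(v_cm3 / voxel_cm3 - 1e-12))
    k = min(max(k, 1), n)
    doses = np.sort(dose.data[mask.mask])[::-1]
    return float(doses[k - 1])


def compare_accumulation(
    ebrt_eqd2: DoseGrid,
    brt_eqd2: DoseGrid,
    field: DeformationField,
    mask: StructureMask,
    v_list_cm3=(0.1, 2.0),
    mask_floating: StructureMask | None = None,
) -> pd.DataFrame:
    """DVH-parameter addition vs deformation-based accumulation, per volume.

    ``added`` is D_v(EBRT, its own frame's structure) + D_v(BRT, reference
    structure) — the plain addition that assumes both hot spots coincide in
    the same tissue. ``dir`` is D_v of the mapped-and-accumulated grid.
    Differences are reported in Gy and in % relative to the DIR value.
    ``mask_floating`` is the structure in the EBRT frame; defaults to ``mask``
    (valid when both frames share a grid and the structure barely moves).
    """
    acc = accumulate(map_dose(ebrt_eqd2, field), brt_eqd2)
    m_flt = mask_floating if mask_floating is not None else mask
    rows = []
    for v in v_list_cm3:
        added = dose_at_volume(ebrt_eqd2, m_flt, v) + dose_at_volume(brt_eqd2, mask, v)
        dir_v = dose_at_volume(acc, mask, v)
        rows.append(
            {
                "v_cm3": v,
                "added_gy": added,
                "dir_gy": dir_v,
                "diff_gy": added - dir_v,
                "diff_pct_of_dir": (added - dir_v) / dir_v * 100.0 if dir_v > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth field comparison (phantom studies)
# ---------------------------------------------------------------------------


def endpoint_error_voxels(
    estimated: DeformationField,
    truth: DeformationField,
    mask: StructureMask | None = None,
) -> float:
    """Mean endpoint error |u_est - u_true| in voxel units, optionally masked."""
    if estimated.shape != truth.shape:
        raise GeometryError("fields must share a grid")
    err = np.linalg.norm(estimated.disp - truth.disp, axis=-1)
    if mask is not None:
        err = err[mask.mask]
    return float(err.mean())
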