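"""End-to-end drivers: preprocess -> preregister -> LK -> evaluate/accumulate.

`run_study1` sweeps (pyramid levels x window radius) combinations over a set
of cases and reports the three similarity metrics per case and combined, with
the optimum selected on combined landmark distance (RMSE, then gamma, break
ties). `run_study2` runs the dose-accumulation assessment with fixed
registration parameters: EQD2 conversion, dose mapping, landmark dose
differences, and the DVH-addition vs DIR comparison for the hot-spot
parameters D_0.1cm3 and D_2cm3.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import DeformationField, ImageVolume, LandmarkSet
from .dose import dose_difference_report, eqd2
from .evaluation import (
    GammaParams,
    compare_accumulation,
    gamma_study,
    landmark_distance,
    rmse_within_mask,
)
from .io_dicom import CaseBundle
from .lk import LKParams, pyramid_lk_register
from .preprocess import InpaintParams, replace_applicator
from .preregister import (
    AffineRegParams,
    AffineTransform,
    affine_to_field,
    affine_register,
    apply_affine,
    compose_affine_field,
)

DEFAULT_SWEEP = ((2, 2), (2, 3), (2, 4), (3, 2), (3, 3))


@dataclass
class CaseRegistration:
    """Everything produced by registering one case."""

    reference: ImageVolume  # applicator-in-painted reference CT
    affine: AffineTransform
    floating_affine: ImageVolume
    field: DeformationField  # LK field, affine-aligned floating -> reference
    registered: ImageVolume  # floating after affine + LK warp
    landmarks_affine: LandmarkSet | None
    metrics: dict


def register_case(
    bundle: CaseBundle,
    lk_params: LKParams = LKParams(),
    inpaint: InpaintParams = InpaintParams(),
    affine_params: AffineRegParams = AffineRegParams(),
    gamma_params: GammaParams | None = None,
    body_mask_name: str = "body",
    applicator_mask_name: str = "applicator",
) -> CaseRegistration:
    """Run the full registration chain on one case and collect metrics.

    Gamma analysis is the costly step; pass ``gamma_params`` to enable it
    (a capped search keeps study-scale runs tractable without changing pass
    rates).
    """
    from .core import warp_volume

    body = bundle.get_mask(body_mask_name)
    try:
        applicator = bundle.get_mask(applicator_mask_name)
        ref = replace_applicator(bundle.reference_ct, applicator, inpaint)
    except KeyError:
        ref = bundle.reference_ct

    t = affine_register(bundle.floating_ct, ref, affine_params, body_mask=body)
    flt_affine = apply_affine(bundle.floating_ct, t, ref.geometry, ref.shape)
    field = pyramid_lk_register(ref, flt_affine, lk_params)
    registered = warp_volume(flt_affine, field)

    metrics: dict = {
        "rmse_pre_hu": rmse_within_mask(ref, bundle.floating_ct, body),
        "rmse_affine_hu": rmse_within_mask(ref, flt_affine, body),
        "rmse_lk_hu": rmse_within_mask(ref, registered, body),
    }
    lm_affine = None
    if bundle.landmarks is not None:
        lm = bundle.landmarks
        lm_affine = apply_affine(lm, t)
        metrics["landmark_pre_mm"] = landmark_distance(lm).mean_mm
        metrics["landmark_affine_mm"] = landmark_distance(lm_affine).mean_mm
        lk_sum = landmark_distance(lm_affine, field)
        metrics["landmark_lk_mm"] = lk_sum.mean_mm
        metrics["landmark_lk_range_mm"] = (lk_sum.min_mm, lk_sum.max_mm)
    if gamma_params is not None:
        metrics["gamma_affine_pct"] = gamma_study(ref, flt_affine, body, gamma_params).study_score_pct
        metrics["gamma_lk_pct"] = gamma_study(ref, registered, body, gamma_params).study_score_pct
    return CaseRegistration(ref, t, flt_affine, field, registered, lm_affine, metrics)


def run_study1(
    cases: list[CaseBundle],
    sweep=DEFAULT_SWEEP,
    base_lk: LKParams = LKParams(),
    inpaint: InpaintParams = InpaintParams(),
    affine_params: AffineRegParams = AffineRegParams(),
    gamma_params: GammaParams | None = GammaParams(gamma_cap=1.5),
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Parameter sweep over (pyramid_levels, window_radius) combinations.

    Returns the per-case x per-setting metric table (with an ``affine`` row
    per case as the baseline) and the selected optimum combination. Failures
    in one sweep cell are recorded and do not disturb other cells.
    """
    if not sweep:
        raise ValueError("sweep grid is empty")
    rows = []
    for ci, bundle in enumerate(cases):
        for levels, radius in sweep:
            lk = LKParams(
                pyramid_levels=levels,
                window_radius_voxels=radius,
                weight_sigma_voxels=base_lk.weight_sigma_voxels,
                iters_per_level=base_lk.iters_per_level,
                min_eigen_threshold=base_lk.min_eigen_threshold,
                update_clip_voxels=base_lk.update_clip_voxels,
                stop_mean_update_voxels=base_lk.stop_mean_update_voxels,
            )
            row = {"case": ci, "levels": levels, "radius": radius}
            try:
                res = register_case(bundle, lk, inpaint, affine_params, gamma_params)
                row.update(
                    landmark_mm=res.metrics.get("landmark_lk_mm"),
                    rmse_hu=res.metrics["rmse_lk_hu"],
                    gamma_pct=res.metrics.get("gamma_lk_pct"),
                    affine_landmark_mm=res.metrics.get("landmark_affine_mm"),
                    affine_rmse_hu=res.metrics["rmse_affine_hu"],
                    affine_gamma_pct=res.metrics.get("gamma_affine_pct"),
                )
            except Exception as exc:  # keep other cells independent
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table.get("error").isna()] if "error" in table else table
    combined = (
        ok.groupby(["levels", "radius"])
        .agg(landmark_mm=("landmark_mm", "mean"), rmse_hu=("rmse_hu", "mean"))
        .reset_index()
        .sort_values(["landmark_mm", "rmse_hu"], kind="stable")
    )
    best = combined.iloc[0]
    return table, (int(best["levels"]), int(best["radius"]))


def run_study2(
    cases: list[CaseBundle],
    lk_params: LKParams = LKParams(pyramid_levels=2, window_radius_voxels=3),
    inpaint: InpaintParams = InpaintParams(),
    affine_params: AffineRegParams = AffineRegParams(),
    oar_mask_name: str = "bladder",
    v_list_cm3=(0.1, 2.0),
) -> pd.DataFrame:
    """Dose-accumulation assessment with fixed (optimized) LK parameters.

    Per case: register, convert both courses to EQD2 (each with its own
    fractionation), map the EBRT dose through the total (affine + LK) field,
    report landmark dose differences for the LK field and the affine-only
    baseline, and compare DVH-parameter addition against DIR accumulation for
    the OAR hot-spot volumes.
    """
    rows = []
    for ci, bundle in enumerate(cases):
        if bundle.floating_dose is None or bundle.reference_dose is None or bundle.landmarks is None:
            raise ValueError(f"case {ci} lacks doses or landmarks")
        ebrt_scheme, brt_scheme = bundle.fractionation
        res = register_case(bundle, lk_params, inpaint, affine_params, gamma_params=None)
        ebrt = eqd2(bundle.floating_dose, ebrt_scheme)
        brt = eqd2(bundle.reference_dose, brt_scheme)
        total = compose_affine_field(res.affine, res.field)
        affine_only = affine_to_field(res.affine, res.reference.geometry, res.reference.shape)
        rep_lk = dose_difference_report(bundle.landmarks, ebrt, brt, total)
        rep_affine = dose_difference_report(bundle.landmarks, ebrt, brt, affine_only)
        row = {
            "case": ci,
            "abs_diff_lk_gy": rep_lk.mean_abs_diff_gy,
            "rel_diff_lk_pct": rep_lk.mean_rel_diff_pct,
            "abs_diff_affine_gy": rep_affine.mean_abs_diff_gy,
            "rel_diff_affine_pct": rep_affine.mean_rel_diff_pct,
        }
        try:
            mask = bundle.get_mask(oar_mask_name)
            try:
                mask_flt = bundle.get_mask(oar_mask_name + "_floating")
            except KeyError:
                mask_flt = None
            cmp_tab = compare_accumulation(ebrt, brt, total, mask, v_list_cm3, mask_flt)
            for _, r in cmp_tab.iterrows():
                row[f"d{r.v_cm3:g}cm3_added_gy"] = r.added_gy
                row[f"d{r.v_cm3:g}cm3_dir_gy"] = r.dir_gy
                row[f"d{r.v_cm3:g}cm3_diff_gy"] = r.diff_gy
        except KeyError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(path, config: dict, seed: int | None = None) -> Path:
    """Record enough provenance to reproduce a run byte-identically."""
    manifest = {
        "lkdose_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
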