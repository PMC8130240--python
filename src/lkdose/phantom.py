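"""Deterministic synthetic pelvic cases with known ground-truth deformation.

No clinical CT pairs are distributed with this package, so its test bed is a
generator of CT-like volume pairs related by a known smooth deformation:

* the *floating* volume plays the external-beam planning CT — an elliptical
  body of soft tissue carrying smooth random HU texture, a bony shell, a
  bladder and a rectum;
* the *reference* volume plays the brachytherapy planning CT — the floating
  volume warped through a sum-of-Gaussian-bumps displacement field, with
  high-HU applicator rods stamped in;
* independent Gaussian HU noise is added to each frame;
* organ masks are generated analytically in both frames consistently with the
  field, landmark pairs are sampled at high-gradient voxels and paired exactly
  through the field, and EBRT-like (smooth plateau) and BRT-like (capped
  inverse-square around the applicator) dose grids are attached.

Interior texture matters: optical flow is observable only where intensity
varies, so a texture-free phantom would make motion in homogeneous tissue
unrecoverable for any intensity-based method. Clinical soft tissue is not
texture-free; the default texture amplitude (40 HU smoothed over a few
voxels) is a deliberately modest stand-in.

Everything is a pure function of the spec (including its seed): the same spec
yields byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    DeformationField,
    DoseGrid,
    FractionationScheme,
    Geometry,
    ImageVolume,
    LandmarkSet,
    StructureMask,
    _identity_coords,
    voxel_to_world,
    warp_volume,
)
from .io_dicom import CaseBundle
from .lk import spatial_gradients


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center as a fraction of the volume extent,
    semi-axes in mm (z, y, x)."""

    center_frac: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]


@dataclass(frozen=True)
class Bump:
    """One Gaussian displacement bump: amplitude vector (voxels, z/y/x),
    center as a fraction of the volume extent, width in voxels."""

    center_frac: tuple[float, float, float]
    amplitude_voxels: tuple[float, float, float]
    width_voxels: float


# Four Gaussian bumps with opposing slice-axis (SI) displacements in the four
# in-plane quadrants, plus small in-plane components. Inter-fraction pelvic
# deformation is dominated by superior-inferior organ motion (bladder filling,
# rectal gas) that differs between neighbouring structures; the alternating
# pattern is deliberately far from any affine map, so it is what deformable —
# not affine — registration must recover. Max displacement ~3.1 voxels.
DEFAULT_BUMPS = (
    Bump((0.45, 0.35, 0.32), (2.8, 1.5, 1.3), 15.0),
    Bump((0.55, 0.35, 0.68), (-2.7, -1.3, 1.5), 15.0),
    Bump((0.45, 0.65, 0.32), (-2.6, 1.4, -1.4), 15.0),
    Bump((0.55, 0.65, 0.68), (2.7, -1.5, -1.3), 15.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case; the seed fixes every draw."""

    shape: tuple[int, int, int] = (64, 128, 128)
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # anatomy
    body: Ellipsoid = Ellipsoid((0.5, 0.5, 0.5), (85.0, 55.0, 58.0))
    bone_outer: Ellipsoid = Ellipsoid((0.5, 0.52, 0.5), (60.0, 44.0, 48.0))
    bone_inner: Ellipsoid = Ellipsoid((0.5, 0.52, 0.5), (52.0, 36.0, 40.0))
    bladder: Ellipsoid = Ellipsoid((0.48, 0.42, 0.5), (22.0, 16.0, 18.0))
    rectum: Ellipsoid = Ellipsoid((0.5, 0.68, 0.5), (30.0, 9.0, 9.0))
    hu_air: float = -1000.0
    hu_body: float = 35.0
    hu_bone: float = 700.0
    hu_bladder: float = 5.0
    hu_rectum: float = -70.0
    texture_sigma_hu: float = 40.0
    texture_smooth_voxels: tuple[float, float, float] = (1.5, 3.0, 3.0)
    noise_sigma_hu: float = 10.0
    # applicator (reference frame only)
    n_rods: int = 3
    rod_radius_mm: float = 3.0
    rod_hu: float = 3000.0
    rod_center_frac: tuple[float, float] = (0.52, 0.5)  # (y, x)
    rod_spacing_mm: float = 12.0
    rod_z_extent_frac: tuple[float, float] = (0.35, 0.75)
    # deformation
    bumps: tuple[Bump, ...] = DEFAULT_BUMPS
    uniform_shift_voxels: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # doses
    ebrt_total_gy: float = 45.0
    ebrt_fractions: int = 25
    ebrt_field_scale: float = 1.3  # plateau half-extent / body semiaxes
    ebrt_hotspot_frac: tuple[float, float, float] | None = None
    ebrt_hotspot_gain: float = 0.15
    ebrt_hotspot_width_mm: float = 20.0
    brt_total_gy: float = 28.0
    brt_fractions: int = 4
    brt_ref_distance_mm: float = 10.0  # distance at which a rod gives brt_total
    brt_cap_gy: float = 80.0
    alpha_beta_gy: float = 3.0
    # landmarks
    n_landmarks: int = 120
    landmark_min_separation_voxels: int = 3
    landmark_gradient_percentile: float = 75.0
    seed: int = 0

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.spacing, self.origin)


def _world_grid(spec: PhantomSpec) -> np.ndarray:
    idx = np.moveaxis(_identity_coords(spec.shape), 0, -1)
    return voxel_to_world(spec.geometry, idx)


def _extent_mm(spec: PhantomSpec) -> np.ndarray:
    return (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)


def _ellipsoid_inside(spec: PhantomSpec, e: Ellipsoid, world: np.ndarray) -> np.ndarray:
    center = np.asarray(spec.origin) + np.asarray(e.center_frac) * _extent_mm(spec)
    r = (world - center) / np.asarray(e.semiaxes_mm)
    return np.sum(r * r, axis=-1) <= 1.0


def make_field(spec: PhantomSpec) -> DeformationField:
    """Sum-of-Gaussian-bumps displacement field on the reference grid.

    disp(x) = sum_k a_k exp(-|x - c_k|^2 / (2 w_k^2)) in voxel units. Bump
    amplitudes must stay below half the bump width (smoothness guard) and the
    finite-difference Jacobian determinant of x + disp(x) must be positive
    everywhere; violations raise with advice to shrink the amplitude.
    """
    for b in spec.bumps:
        if np.linalg.norm(b.amplitude_voxels) >= b.width_voxels / 2.0:
            raise ValueError(
                f"bump amplitude {b.amplitude_voxels} too large for width {b.width_voxels}; "
                "keep |a| < width/2"
            )
    idx = np.moveaxis(_identity_coords(spec.shape), 0, -1)
    disp = np.zeros((*spec.shape, 3))
    disp += np.asarray(spec.uniform_shift_voxels, dtype=float)
    for b in spec.bumps:
        center = np.asarray(b.center_frac) * (np.asarray(spec.shape) - 1)
        d2 = np.sum((idx - center) ** 2, axis=-1)
        g = np.exp(-d2 / (2.0 * b.width_voxels**2))
        disp += g[..., None] * np.asarray(b.amplitude_voxels)
    f = DeformationField(disp, spec.spacing, spec.origin)
    if spec.bumps:
        from .lk import negative_jacobian_count

        if negative_jacobian_count(f) > 0:
            raise ValueError(
                "ground-truth field folds (negative Jacobian); reduce bump amplitudes"
            )
    return f


def _clean_floating(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Analytic EBRT-frame phantom: tissue levels plus smooth HU texture.

    The texture covers every tissue inside the body, organs included — optical
    flow is observable only where intensity varies, and real tissue is nowhere
    perfectly homogeneous at CT noise scales. (Truly constant regions, where
    any intensity-based method is blind, are exercised separately in tests.)
    """
    world = _world_grid(spec)
    data = np.full(spec.shape, spec.hu_air)
    body = _ellipsoid_inside(spec, spec.body, world)
    data[body] = spec.hu_body
    bone = _ellipsoid_inside(spec, spec.bone_outer, world) & ~_ellipsoid_inside(
        spec, spec.bone_inner, world
    )
    data[bone] = spec.hu_bone
    data[_ellipsoid_inside(spec, spec.bladder, world)] = spec.hu_bladder
    data[_ellipsoid_inside(spec, spec.rectum, world)] = spec.hu_rectum
    if spec.texture_sigma_hu > 0:
        tex = rng.standard_normal(spec.shape)
        tex = gaussian_filter(tex, sigma=spec.texture_smooth_voxels)
        std = tex.std()
        if std > 0:
            tex = tex / std * spec.texture_sigma_hu
        data[body] += tex[body]
    return data


def _rod_centers_mm(spec: PhantomSpec) -> np.ndarray:
    ext = _extent_mm(spec)
    cy = spec.origin[1] + spec.rod_center_frac[0] * ext[1]
    cx = spec.origin[2] + spec.rod_center_frac[1] * ext[2]
    offsets = (np.arange(spec.n_rods) - (spec.n_rods - 1) / 2.0) * spec.rod_spacing_mm
    return np.stack([np.full(spec.n_rods, cy), cx + offsets], axis=1)  # (n, [y, x])


def _applicator_mask(spec: PhantomSpec) -> np.ndarray:
    world = _world_grid(spec)
    ext = _extent_mm(spec)
    z0 = spec.origin[0] + spec.rod_z_extent_frac[0] * ext[0]
    z1 = spec.origin[0] + spec.rod_z_extent_frac[1] * ext[0]
    in_z = (world[..., 0] >= z0) & (world[..., 0] <= z1)
    mask = np.zeros(spec.shape, dtype=bool)
    for cy, cx in _rod_centers_mm(spec):
        r2 = (world[..., 1] - cy) ** 2 + (world[..., 2] - cx) ** 2
        mask |= in_z & (r2 <= spec.rod_radius_mm**2)
    return mask


def _ebrt_dose(spec: PhantomSpec) -> np.ndarray:
    """Smooth super-Gaussian plateau over the pelvis, floating frame.

    The plateau half-extent defaults to 1.3x the body semiaxes so the dose
    inside the body stays near the prescription with only gentle gradients —
    an external-beam course covers its planning volume nearly uniformly, and
    the steep fall-off belongs outside the patient.
    """
    world = _world_grid(spec)
    center = np.asarray(spec.origin) + np.asarray(spec.body.center_frac) * _extent_mm(spec)
    radii = spec.ebrt_field_scale * np.asarray(spec.body.semiaxes_mm)
    r = (world - center) / radii
    dose = spec.ebrt_total_gy * np.exp(-np.sum(r * r, axis=-1) ** 3)
    if spec.ebrt_hotspot_frac is not None:
        hc = np.asarray(spec.origin) + np.asarray(spec.ebrt_hotspot_frac) * _extent_mm(spec)
        d2 = np.sum((world - hc) ** 2, axis=-1)
        dose += (
            spec.ebrt_hotspot_gain
            * spec.ebrt_total_gy
            * np.exp(-d2 / (2.0 * spec.ebrt_hotspot_width_mm**2))
        )
    return dose


def _brt_dose(spec: PhantomSpec) -> np.ndarray:
    """Capped inverse-square fall-off around the applicator rods, reference frame.

    Emulates the steep brachytherapy gradient; deliberately not a TG-43 model.
    """
    world = _world_grid(spec)
    ext = _extent_mm(spec)
    zc = spec.origin[0] + 0.5 * (spec.rod_z_extent_frac[0] + spec.rod_z_extent_frac[1]) * ext[0]
    strength = spec.brt_total_gy * spec.brt_ref_distance_mm**2
    dose = np.zeros(spec.shape)
    for cy, cx in _rod_centers_mm(spec):
        d2 = (
            (world[..., 0] - zc) ** 2
            + (world[..., 1] - cy) ** 2
            + (world[..., 2] - cx) ** 2
        )
        dose += strength / np.maximum(d2, 1.0)
    return np.minimum(dose, spec.brt_cap_gy)


def _sample_landmarks(
    spec: PhantomSpec,
    ref_clean: np.ndarray,
    body_ref: np.ndarray,
    applicator: np.ndarray,
    field: DeformationField,
    rng: np.random.Generator,
) -> LandmarkSet:
    gz, gy, gx = spatial_gradients(ref_clean)
    gmag = np.sqrt(gz**2 + gy**2 + gx**2)
    # keep clear of the rods (features absent in the floating frame) and the border
    from scipy.ndimage import binary_dilation

    excl = binary_dilation(applicator, iterations=4)
    candidate = body_ref & ~excl
    candidate[[0, -1], :, :] = False
    candidate[:, [0, -1], :] = False
    candidate[:, :, [0, -1]] = False
    if not candidate.any():
        raise ValueError("no candidate landmark voxels in the body")
    thresh = np.percentile(gmag[candidate], spec.landmark_gradient_percentile)
    candidate &= gmag >= thresh
    coords = np.argwhere(candidate)
    order = rng.permutation(len(coords))
    sep = max(1, int(spec.landmark_min_separation_voxels))
    taken: set[tuple[int, int, int]] = set()
    chosen = []
    for i in order:
        c = coords[i]
        key = tuple((c // sep).tolist())
        if key in taken:
            continue
        taken.add(key)
        chosen.append(c)
        if len(chosen) == spec.n_landmarks:
            break
    if len(chosen) < spec.n_landmarks:
        raise ValueError(
            f"only {len(chosen)} high-gradient voxels available for "
            f"{spec.n_landmarks} requested landmarks"
        )
    chosen = np.asarray(chosen, dtype=float)
    disp = field.disp[tuple(chosen.astype(int).T)]
    ref_mm = voxel_to_world(spec.geometry, chosen)
    flt_mm = voxel_to_world(spec.geometry, chosen + disp)
    labels = [f"lm{i:03d}" for i in range(len(chosen))]
    return LandmarkSet(labels, ref_mm, flt_mm)


def make_case(spec: PhantomSpec = PhantomSpec()) -> tuple[CaseBundle, DeformationField]:
    """Generate one synthetic case and its ground-truth deformation field.

    Returns a :class:`CaseBundle` whose masks are named ``body``, ``bone``,
    ``bladder``, ``rectum`` (reference frame), the same with a ``_floating``
    suffix (floating frame), and ``applicator`` (reference frame), plus the
    exact field relating the frames (backward semantics: the clean reference
    equals the clean floating warped through the field).
    """
    rng = np.random.default_rng(spec.seed)
    field = make_field(spec)
    flt_clean = _clean_floating(spec, rng)
    geom = spec.geometry
    ref_clean = warp_volume(ImageVolume(flt_clean, spec.spacing, spec.origin), field).data

    world = _world_grid(spec)
    mapped_world = voxel_to_world(
        geom, np.moveaxis(_identity_coords(spec.shape), 0, -1) + field.disp
    )

    def masks_for(frame_world, suffix=""):
        out = []
        for name, e in (
            ("body", spec.body),
            ("bone", None),
            ("bladder", spec.bladder),
            ("rectum", spec.rectum),
        ):
            if name == "bone":
                m = _ellipsoid_inside(spec, spec.bone_outer, frame_world) & ~_ellipsoid_inside(
                    spec, spec.bone_inner, frame_world
                )
            else:
                m = _ellipsoid_inside(spec, e, frame_world)
            out.append(StructureMask(name + suffix, m, spec.spacing, spec.origin))
        return out

    masks = masks_for(mapped_world) + masks_for(world, "_floating")
    applicator = _applicator_mask(spec)
    masks.append(StructureMask("applicator", applicator, spec.spacing, spec.origin))

    body_ref = masks[0].mask
    landmarks = _sample_landmarks(spec, ref_clean, body_ref, applicator, field, rng)

    ref_data = ref_clean.copy()
    ref_data[applicator] = spec.rod_hu
    if spec.noise_sigma_hu > 0:
        ref_data = ref_data + rng.normal(0.0, spec.noise_sigma_hu, spec.shape)
        flt_data = flt_clean + rng.normal(0.0, spec.noise_sigma_hu, spec.shape)
    else:
        flt_data = flt_clean.copy()

    bundle = CaseBundle(
        reference_ct=ImageVolume(ref_data, spec.spacing, spec.origin),
        floating_ct=ImageVolume(flt_data, spec.spacing, spec.origin),
        reference_dose=DoseGrid(_brt_dose(spec), spec.spacing, spec.origin),
        floating_dose=DoseGrid(_ebrt_dose(spec), spec.spacing, spec.origin),
        masks=masks,
        landmarks=landmarks,
        fractionation=(
            FractionationScheme(spec.ebrt_total_gy, spec.ebrt_fractions, spec.alpha_beta_gy),
            FractionationScheme(spec.brt_total_gy, spec.brt_fractions, spec.alpha_beta_gy),
        ),
    )
    return bundle, field


def smooth_spec(
    shift_voxels: tuple[float, float, float] = (0.0, 0.0, 6.0),
    shape: tuple[int, int, int] = (32, 96, 96),
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """The "smooth" phantom: a textured soft-tissue body, nothing else.

    High-contrast structures (bone, organ boundaries, applicator rods) and
    acquisition noise are disabled, and the texture is fine-grained
    ((1, 2, 2)-voxel correlation). This isolates what a translation-recovery
    oracle is meant to probe — the pyramid's large-motion benefit: fine
    texture de-correlates at offsets beyond its correlation length, so a
    single-level solver demonstrably fails on a large shift while the
    coarse-to-fine scheme recovers it; edges and noise robustness are
    exercised by the default phantom instead.
    """
    defaults = dict(
        noise_sigma_hu=0.0,
        texture_smooth_voxels=(1.0, 2.0, 2.0),
        hu_bone=35.0,
        hu_bladder=35.0,
        hu_rectum=35.0,
        rod_hu=35.0,
    )
    defaults.update(overrides)
    return translation_spec(shift_voxels, shape=shape, seed=seed, **defaults)


def interior_body_mask(
    bundle: CaseBundle, margin_voxels: tuple[int, int, int] = (3, 7, 7)
) -> StructureMask:
    """Body interior for field-recovery evaluation.

    Erodes the reference-frame body mask by one window diameter (in-plane)
    and removes a dilation of the applicator region: within the boundary
    annulus the flow window straddles the body/air edge and measures the
    aperture problem rather than registration, and the in-painted applicator
    has no counterpart in the floating frame (mirrors evaluating similarity
    only within the patient).
    """
    from scipy.ndimage import binary_dilation, binary_erosion

    body = bundle.get_mask("body")
    m = binary_erosion(body.mask, np.ones(margin_voxels))
    try:
        app = bundle.get_mask("applicator")
        if not app.is_empty:
            m &= ~binary_dilation(app.mask, np.ones(margin_voxels))
    except KeyError:
        pass
    return StructureMask("body_interior", m, body.spacing, body.origin)


def translation_spec(
    shift_voxels: tuple[float, float, float],
    shape: tuple[int, int, int] = (32, 96, 96),
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """Spec whose deformation is an exact uniform translation (voxel units),
    used for large-shift recovery studies where the ground truth is a shift."""
    return PhantomSpec(
        shape=shape,
        seed=seed,
        bumps=(),
        uniform_shift_voxels=tuple(float(s) for s in shift_voxels),
        **overrides,
    )
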