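# Methods

`lkdose` estimates the deformation between the planning CTs of the two parts
of combined cervical-cancer radiotherapy — the external-beam (EBRT) course and
the intracavitary brachytherapy (BRT) boost — and uses it to accumulate the
two dose distributions in the same anatomy rather than the same coordinates.
This note records the models, the numerical choices, what the synthetic test
bed does and does not represent, and the known limitations.

## Registration model

**Weighted-window Lucas-Kanade flow.** HU conservation with locally constant
motion: within a `(2r+1)^3` window around each voxel, every neighbour `x'`
contributes one linearized equation `g(x')·v = −g_t(x')`, where `g` is the
spatial HU gradient of the current-estimate-warped floating image and `g_t`
its difference to the reference. Neighbours are weighted with a Gaussian of
distance (width `σ_w`, default `r/2`, normalized to unit mass), giving the
3×3 normal system `(Σ w g gᵀ) v = −Σ w g g_t` per voxel. Gradients are
central differences (one-sided at borders); windowed sums are separable
correlations, zero-padded at the volume border.

**Degenerate windows.** The normal matrix is solved in its well-conditioned
eigensubspace: eigendirections with eigenvalue below `min_eigen_threshold`
(default `1e-4` on the unit-mass-normalized tensor) contribute no update. A
fully homogeneous window therefore updates by exactly zero (the aperture
problem), while edge-like structure still yields its observable normal-flow
component — which is what makes the solver exact on affine intensity
profiles such as linear ramps. A hard all-or-nothing gate on the smallest
eigenvalue was considered and rejected: it would zero the recoverable
component of any rank-deficient but informative window.

**Iteration.** Per level: warp the floating image through the current field
(trilinear, edge-clamped), solve, clip each update component to
±`update_clip_voxels` (1.5), compose the update into the field by true
composition `u'(x) = v(x) + u(x + v(x))`, and stop after `iters_per_level`
(5) iterations or when the mean update norm falls below 0.01 voxel.

**Pyramid.** Each level above full resolution is Gaussian-smoothed (σ = 1
voxel on decimated axes) and decimated by 2 in-plane; the slice axis is
decimated only while at least 8 slices remain, because 2.5 mm slices are
already coarse. The coarse-level field is upsampled trilinearly with
displacement components multiplied by the per-axis resolution ratio and used
as the next level's initial estimate, so each level solves only residual
flow and the small-motion linearization stays valid for large deformations.
Two levels with window radius 3 is the default — the optimum found on
clinical pelvic CT pairs.

**No regularization.** The field is never smoothed after solving; the window
is the only spatial coupling. A diagnostic (`negative_jacobian_count`)
reports folding voxels instead of repairing them. This is a faithful design
choice, and its cost is visible in the phantom studies: flow noise in
low-texture tissue of roughly 0.5–1 voxel, and unreliable estimates
wherever a high-contrast edge dominates the window and the motion component
along the edge tangent is unobservable.

## Preprocessing and preregistration

**Applicator in-painting.** The applicator exists only in the BRT frame, so
its voxels are replaced before registration: the mean HU `m` of a
surrounding-tissue ring (mask dilation of width 2 voxels, minus the mask) is
computed, each applicator voxel is drawn independently and uniformly from
`m ± 200` HU (seeded), and a Gaussian blur (σ = 1.5 mm) is written back
inside a one-voxel dilation of the mask only. Everything outside that
region is bit-identical to the input. Ring width and blur width are
conventions of this package; the ±200 HU band and the blur itself follow
standard practice for applicator removal.

**Affine preregistration.** A user-supplied rigid transform (bone matching
is a manual step) may precede an automatic affine registration that
minimizes the mean squared HU difference within the body mask, coarse to
fine over a 3-level pyramid. The 12 parameters of the pullback map are
optimized by quasi-Newton descent (L-BFGS-B) with analytic gradients via the
chain rule through the resampling; only improving steps are accepted, so the
per-level MSE trace is non-increasing. Parameter-recovery accuracy on
smooth analytic images: translations to ≲0.1 mm, scale factors to <0.01.
Recovery tests must construct the floating image analytically — resampling
narrowband texture shifts the MSE optimum measurably away from the
generating transform, a property of the fixture, not of the optimizer.

## Dose model

**EQD2.** The two courses have very different fraction sizes, so physical
dose is converted to the equieffective dose in 2 Gy fractions under the
linear-quadratic model, `EQD2 = D·(α/β + d)/(α/β + 2)`, with the dose per
fraction computed per voxel as `d(x) = D(x)/n`. α/β defaults: 10 Gy for
tumor response, 3 Gy for late effects in organs at risk; both are plain
parameters. Conversion happens *before* warping: EQD2 is nonlinear in `D`,
so conversion and trilinear interpolation do not commute, and converting
first applies the radiobiological model to the planned distribution.

**Mapping and accumulation.** The EBRT dose is warped through the total
(affine ∘ deformable) field with the same backward semantics as image
warping — so the mapped dose is spatially congruent with the registered
image — and summed voxelwise with the BRT dose on the reference grid.

**Landmark doses.** BRT distributions have steep gradients, so the dose
"at" a point is the mean over the six face-adjacent neighbours of its
nearest voxel (the enclosing voxel itself excluded; out-of-grid neighbours
edge-clamped). Agreement is summarized per landmark as |after − before|
with *before* = EBRT dose at the floating-frame point + BRT dose at the
reference point (native frames, no registration) and *after* = the
accumulated grid at the reference point; relative differences are
normalized to the single global maximum of the accumulated grid, so small
absolute differences in low-dose regions do not masquerade as large
relative ones.

## Evaluation suite

* **Landmark distance** — Euclidean world-mm distance of paired points;
  with a field, the reference point is mapped through it and the residual
  to the annotated floating point is the target registration error. (Which
  frame's points to map is a convention; this package maps reference
  points, the other direction is obtained by swapping the frames.)
* **RMSE of HU** inside the body mask only (couch and positioning aids
  differ between the scans).
* **2D gamma analysis** per axial slice, criteria 2%/2 mm with local
  normalization by default, treating HU as the "dose". The search scans a
  distance-sorted grid (radius 3× and step 1/10 of the distance criterion)
  with bilinear interpolation of the evaluated slice. Local normalization
  is floored at 1 HU to avoid division by zero near water density. Global
  mode normalizes to the reference slice's dynamic range (max − min over
  evaluated pixels) rather than the maximum, so the pass rate is invariant
  under a common HU offset — HU, unlike dose, has an arbitrary zero; a
  fixed normalization value can be supplied instead. An optional cap
  truncates gamma values above `gamma_cap` and lets the search stop early;
  pass rates are exact for any cap ≥ 1 (pass/fail is decided on the
  un-truncated minima), and the toy-slice oracle tests run uncapped.
  Slices with no evaluable pixel are excluded from the study average;
  per-slice rates are retained because outer slices score systematically
  worse.
* **DVH hot spots** — `D_v` is computed exactly by sorting masked voxel
  doses and taking the k-th largest with `k = ceil(v / voxel volume)`; no
  binning. The cumulative DVH uses 0.01 Gy bins for display only.
* **Accumulation-standard comparison** — `D_v(EBRT) + D_v(BRT)` (the
  plain addition that assumes coincident hot spots) against `D_v` of the
  mapped-and-accumulated grid, absolute and relative to the DIR value.

## Synthetic test bed

No clinical CT pairs ship with this package; `lkdose.phantom` generates the
study conditions. The default case (64×128×128 voxels at 2.5×1×1 mm — sized
so the full register-and-evaluate cycle runs in minutes on one CPU) is an
elliptical soft-tissue body with a bony shell, bladder and rectum, plus:

* **Texture everywhere inside the body** (σ = 40 HU, correlation ≈
  (1.5, 3, 3) voxels), organs included. Optical flow is observable only
  where intensity varies; real tissue is nowhere perfectly homogeneous at
  CT noise scales, and a texture-free organ interior would make motion
  there unrecoverable for *any* intensity-based method. Truly constant
  regions are exercised separately in unit tests.
* **Ground-truth deformation**: four Gaussian bumps (width 15 voxels) with
  opposing slice-axis displacements in the four in-plane quadrants plus
  smaller in-plane components (max ≈ 3.3 voxels, mean landmark displacement
  ≈ 2 mm). Inter-fraction pelvic deformation is dominated by
  superior-inferior organ motion that differs between neighbouring
  structures; the alternating pattern is far from any affine map, so it
  probes specifically what deformable registration must add over the affine
  step. Positivity of the Jacobian is verified at construction.
* **Applicator rods** (three 3 mm-radius cylinders at 3000 HU) stamped only
  into the reference frame; independent Gaussian HU noise (σ = 10) added to
  each frame.
* **Landmarks** sampled at high-gradient voxels (75th percentile of the
  clean reference gradient) inside the body, away from the rods and the
  volume border, and paired *exactly* through the ground-truth field. The
  saliency threshold deliberately stays moderate: restricting to the very
  strongest edges concentrates points where the aperture problem governs,
  which measures the method's known failure mode rather than its accuracy.
* **Doses**: the EBRT course is a smooth super-Gaussian plateau with
  half-extent 1.3× the body semiaxes, keeping in-body dose at 79–100% of
  the 45 Gy prescription — an external-beam plan covers its target nearly
  uniformly, and the steep fall-off belongs outside the patient. The BRT
  course is a capped inverse-square fall-off around the rods (cap 80 Gy),
  emulating the brachytherapy gradient without any TG-43 formalism.
  Fractionation defaults: 45 Gy/25 fx (EBRT) and 28 Gy/4 fx (BRT).

Two purpose-built variants: `smooth_spec()` disables the high-contrast
structures, the rods and the noise and uses finer texture — the fixture for
translation-recovery oracles, where a single pyramid level must demonstrably
fail on a 6-voxel shift while two levels recover it (with the full-structure
phantom that contrast is confounded by edge-induced aperture noise, which is
level-independent); translation-recovery endpoint errors are evaluated on
the eroded body interior (`interior_body_mask`), mirroring the
within-the-patient evaluation policy. A misaligned-hot-spot variant (EBRT
hot spot placed anterior in the bladder, away from the rods) reproduces the
regime where plain DVH-parameter addition overestimates the accumulated
hot-spot dose.

Everything is a pure function of the spec including its seed; identical
specs give byte-identical cases.

**What passing these tests does not show.** The phantom has axis-aligned
analytic anatomy, stationary Gaussian texture and noise, a known smooth
invertible deformation, and perfectly consistent landmark pairs. Real CT
pairs add couch and FOV differences, non-smooth sliding motion, organ
filling changes that create and destroy intensity (bladder, rectal gas),
annotation error in landmarks, and deformations that can defeat an
unregularized method entirely — the failure case reported clinically for
one patient in ten. Phantom metrics therefore validate the implementation
and the direction of effects, not clinical accuracy.

## Problem sizes and runtimes

Chosen as the package's own defaults: default phantom 64×128×128 (full
chain with capped gamma ≈ 2–3 min on one CPU), pyramid-benefit study at
32×96×96 (≈ 1 min), oracle tests at 9³–16² (seconds). The acceptance script
runs all of them from scratch in roughly ten minutes.

## Known limitations

* Axial, axis-aligned geometry only; no oblique direction cosines, no 4D.
* No field regularization: folding is reported, not repaired.
* Gamma is 2D per axial slice (matching the evaluation protocol it
  implements); no 3D gamma.
* The affine optimizer assumes enough overlap after the rigid step; it has
  no automatic initialization.
* DICOM writers are minimal, synthetic-test-grade objects, not clinical
  exports.
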