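# lkdose

Deformable dose accumulation for combined external-beam (EBRT) +
brachytherapy (BRT) treatment of cervical cancer: pyramidal, weighted-window
Lucas-Kanade registration of the two planning CTs, EQD2 conversion, dose
mapping, and the evaluation suite that goes with it.

## The problem

The accumulation standard for combined radiotherapy adds per-course DVH
parameters, which silently assumes each course's hot spot lands in the same
tissue. Between the EBRT planning CT and the BRT planning CT (applicator in
situ) the pelvic anatomy deforms by centimetres, so the assumption fails and
organ-at-risk hot-spot doses are systematically misreported. Summing doses
*in the same tissue* requires the deformation field between the scans.

`lkdose` estimates that field with Lucas-Kanade optical flow: within a
`(2r+1)³` window around every voxel the motion `v` is assumed constant, each
neighbour contributes a linearized HU-conservation equation, and the
Gaussian-weighted least-squares normal system

&nbsp;&nbsp;&nbsp;&nbsp;`(Σ w g gᵀ) v = − Σ w g g_t`

is solved per voxel (`g` spatial HU gradient, `g_t` temporal difference,
solved in the well-conditioned eigensubspace). A coarse-to-fine image
pyramid (half resolution per level) handles large motions by solving only
residual flow at each finer level; the defaults — two pyramid levels,
window radius 3 — are the optimum found on clinical pelvic CT pairs. Around
the flow solver sit applicator in-painting (mean of surrounding tissue ±200
HU, then Gaussian blur), automatic affine preregistration (masked-MSE
descent), per-voxel EQD2 conversion `EQD2 = D(α/β + d)/(α/β + 2)`, backward
dose mapping, and the three accuracy metrics used to validate it: landmark
distance, in-body HU RMSE, and 2%/2 mm local-normalization 2D gamma
analysis, plus sorted-voxel D_0.1cm³/D_2cm³ DVH parameters.

No clinical data ships with the package; `lkdose.phantom` generates
CT-like pelvic cases with known ground-truth deformations, doses, masks and
landmark pairs (see `docs/methods.md` for what that test bed does and does
not represent).

## Worked example

```sh
python examples/01_registration.py
```

```
Landmark distance (mm): before 1.68 -> affine 1.62 -> Lucas-Kanade 0.59
RMSE of HU in body:     before 114.9 -> affine 93.3 -> Lucas-Kanade 23.9
Gamma 2%/2mm score (%): affine 75.2 -> Lucas-Kanade 85.1
Mean endpoint error vs ground truth: 0.58 voxels
```

The affine step removes the gross misalignment (RMSE 115 → 93) but cannot
touch the non-affine organ motion (landmarks stay at 1.6 mm); the pyramidal
LK flow recovers it (0.59 mm, endpoint error 0.58 voxels against the field
the phantom was built with). `examples/02_dose_accumulation.py` then
converts both courses to EQD2 (45 Gy/25 fx at α/β = 10 → 44.25 Gy;
28 Gy/4 fx at α/β = 3 → 56.00 Gy), maps and accumulates, and shows the
landmark-level agreement; `examples/03_dvh_comparison.py` reproduces the
direction of the accumulation-standard bias (plain DVH addition
overestimates bladder D_0.1cm³/D_2cm³ when the hot spots are misaligned);
`examples/04_dicom_roundtrip.py` exercises the DICOM CT/RTDOSE/RTSTRUCT and
landmark-CSV I/O.

The same steps are available as a thin CLI (`lkdose phantom`, `preprocess`,
`preregister`, `register`, `accumulate`, `evaluate`, `study1`, `study2`);
volumes and fields travel between subcommands as `.npz` archives.

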