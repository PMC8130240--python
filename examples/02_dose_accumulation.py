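"""EQD2 conversion, dose mapping and landmark-level accumulation accuracy.

Converts the two courses of a synthetic case to the equieffective dose in
2 Gy fractions, maps the external-beam dose through the ground-truth
deformation into the brachytherapy frame, accumulates, and compares the
accumulated dose at each landmark with the sum of the doses sampled
directly in the two native frames.
"""

from lkdose import FractionationScheme
from lkdose.dose import dose_difference_report, eqd2
from lkdose.phantom import PhantomSpec, make_case

bundle, truth = make_case(PhantomSpec(shape=(32, 96, 96), seed=1))
ebrt_scheme, brt_scheme = bundle.fractionation

print(f"EQD2(45 Gy / 25 fx, a/b = 10 Gy) = {eqd2(45.0, FractionationScheme(45, 25, 10.0)):.2f} Gy")
print(f"EQD2(28 Gy /  4 fx, a/b =  3 Gy) = {eqd2(28.0, FractionationScheme(28, 4, 3.0)):.2f} Gy")

ebrt = eqd2(bundle.floating_dose, ebrt_scheme)
brt = eqd2(bundle.reference_dose, brt_scheme)
rep = dose_difference_report(bundle.landmarks, ebrt, brt, truth)
print(f"\nLandmarks: {len(bundle.landmarks)}")
print(f"Mean |difference|: {rep.mean_abs_diff_gy:.3f} Gy "
      f"({rep.mean_rel_diff_pct:.3f}% of the {rep.global_max_gy:.0f} Gy global maximum)")
print(f"Range: {rep.abs_diff_range_gy[0]:.3f} - {rep.abs_diff_range_gy[1]:.3f} Gy")
print("\nWith the exact deformation the accumulated dose at each landmark "
      "should match direct sampling up to interpolation - the mean difference "
      "above is that numerical floor. Registration error adds on top of it.")
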