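"""Hot-spot DVH parameters: plain addition vs deformation-based accumulation.

Builds a phantom whose external-beam hot spot is deliberately misaligned
with the brachytherapy hot spot inside the bladder, then compares bladder
D_0.1cm3 and D_2cm3 from (a) adding the per-course DVH parameters — the
accumulation standard, which assumes both hot spots land in the same
tissue — and (b) accumulating the doses through the deformation field.
"""

from lkdose.dose import eqd2
from lkdose.evaluation import compare_accumulation
from lkdose.phantom import PhantomSpec, make_case

spec = PhantomSpec(
    shape=(32, 96, 96),
    seed=1,
    n_landmarks=40,
    ebrt_hotspot_frac=(0.48, 0.30, 0.42),  # anterior bladder, away from the rods
    ebrt_hotspot_gain=0.35,
)
bundle, truth = make_case(spec)
ebrt = eqd2(bundle.floating_dose, bundle.fractionation[0])
brt = eqd2(bundle.reference_dose, bundle.fractionation[1])

table = compare_accumulation(
    ebrt, brt, truth,
    bundle.get_mask("bladder"), (0.1, 2.0),
    mask_floating=bundle.get_mask("bladder_floating"),
)
for _, row in table.iterrows():
    print(f"D_{row.v_cm3:g}cm3: addition {row.added_gy:.1f} Gy, "
          f"DIR {row.dir_gy:.1f} Gy, difference {row.diff_gy:+.1f} Gy "
          f"({row.diff_pct_of_dir:+.1f}% of DIR)")
print("\nPositive differences mean plain DVH-parameter addition overestimates "
      "the accumulated bladder hot-spot dose: the two courses' maxima do not "
      "coincide in the same tissue, and only the deformation-based sum sees that.")
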