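"""Contour agreement and DVH metrics on an analytic sphere phantom.

Two equal spheres displaced by 8 mm stand in for a ground-truth and an
alternative organ contour; a linear dose gradient plays the dose grid.
"""

import ntcpsim as ns

mask_gt, mask_alt, dose = ns.generate_phantom_pair(
    shape=(64, 64, 64),
    spacing=(0.75, 0.75, 0.75),
    radius_mm=15.0,
    offset_mm=(8.0, 0.0, 0.0),
    dose_field="linear",
    dose_params={"slope": 1.2, "offset": 2.0},
)

print(f"Dice:                {ns.dice(mask_gt, mask_alt):.3f}")
print(f"surface Dice @ 3 mm: {ns.surface_dice(mask_gt, mask_alt, 3.0):.3f}")
for label, mask in (("ground truth", mask_gt), ("alternative", mask_alt)):
    mhd = ns.mean_dose(dose, mask)
    v30 = ns.vxgy(dose, mask, 30.0)
    print(f"{label:13s}: mean dose {mhd:5.2f} Gy, V30Gy {v30:5.1f} %")

# The 8 mm displacement along the dose gradient shifts the alternative
# contour's mean dose and V30Gy — exactly the kind of dosimetric-parameter
# difference the Monte Carlo framework turns into a model-performance
# difference.
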