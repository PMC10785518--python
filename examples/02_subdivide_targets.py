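"""Subdivide the nodal CTV of a phantom into its 11 evaluation subregions.

The nodal chain is cut by three axial landmark planes (femoral head,
piriformis, iliac bifurcation) and the body midline; the middle two bands
are further quartered. Region-wise evaluation localizes where automatic
contours need editing.
"""
from adaptrt.subdivision import split_ctvn, split_longitudinal
from adaptrt.synthetic import PhantomConfig, make_phantom

structures, landmarks = make_phantom(PhantomConfig(cohort="uterine"))
parts = split_ctvn(structures["CTV-N"], landmarks)

print(f"CTV-N volume: {structures['CTV-N'].volume_cm3:.1f} cm^3, "
      f"{len(parts.labels)} subregions:")
for name, mask in sorted(parts.labels.items()):
    print(f"  {name:22s} {mask.volume_cm3:6.1f} cm^3")

halves = split_longitudinal(structures["CTV-C"])
print("\nCervical target halved along its length:")
for name, mask in sorted(halves.labels.items()):
    print(f"  {name:22s} {mask.volume_cm3:6.1f} cm^3")
print("(subregion volumes sum exactly to the parent structure)")
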