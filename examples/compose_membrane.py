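"""Build an asymmetric two-leaflet membrane spec from a lipid composition.

Whole-membrane species fractions are split between cytoplasmic and
intermembrane-space leaflets by headgroup asymmetry, rounded to integer
counts (minimum 5 per retained species), and area-matched so the
juxtaposed leaflets carry no tension.
"""

from lipopore.membrane import compose_membrane

species_fractions = {
    "PC 34:1": 0.25, "PC 36:2": 0.18, "PE 34:1": 0.20, "PE 38:4": 0.12,
    "PI 38:4": 0.10, "PS 36:1": 0.10, "PG 34:1": 0.05,
}

spec = compose_membrane(
    species_fractions,
    box_x=20.0, box_y=20.0,          # nm
    apl_cyto=0.708, apl_ims=0.708,   # nm^2 per lipid, from symmetric runs
)

print(f"Total lipids: {spec.n_lipids} "
      f"(cyto {sum(spec.counts_cyto.values())}, "
      f"ims {sum(spec.counts_ims.values())})")
print(f"Hydration: {spec.n_water} water beads (25 per lipid)")
print(f"Ions for 0.15 M + neutrality: {spec.n_cation} cations, "
      f"{spec.n_anion} anions")
print("\nCytoplasmic leaflet counts (note PE enriched at 77/23):")
for s, n in sorted(spec.counts_cyto.items()):
    print(f"  {s}: {n}")
print("\nIMS leaflet counts (PS/PI enriched at 70/30):")
for s, n in sorted(spec.counts_ims.items()):
    print(f"  {s}: {n}")
print("\nBilayer-builder composition string:")
print(" ", spec.insane_string())
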