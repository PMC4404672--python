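"""Seed-color phenotyping: mean RGB per genotype, converted to CIE-L*a*b*.

Five seeds are imaged per genotype; channel averages are taken in RGB and
the mean color is converted to the perceptually even L*a*b* space, where
L* separates light from dark seed coats and a*/b* carry the hue.
"""

import sweepkit as sk

palette = [(150, 40, 27),     # red-brown seed coat
           (222, 184, 135),   # tan
           (255, 255, 240)]   # ivory
seed_df, assignment = sk.simulate_seed_colors(
    n_genotypes=6, palette_spec=palette, noise_sd=5.0, seed=6)
print(f"{len(seed_df)} seed measurements "
      f"({len(seed_df) // 5} genotypes x 5 seeds)\n")

pheno = sk.phenotype_table(seed_df)
print(pheno.round(2).to_string(index=False))

print("\nsingle-color checks:")
for rgb in [(255, 255, 255), (255, 0, 0)]:
    lab = sk.rgb_to_lab(sk.RGBColor(*rgb))
    print(f"  RGB {rgb} -> L*a*b* "
          f"({lab.L:.2f}, {lab.a:.2f}, {lab.b:.2f})")
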