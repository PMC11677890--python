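"""Compare petal and corolla traits between the two synthetic species.

Tukey's HSD at alpha = 0.05 on the standard trait set; species sharing a
letter do not differ significantly in that trait.
"""

from corolla import compare_species_traits, default_config, generate_dataset

ds = generate_dataset(default_config(seed=42))
results = compare_species_traits(ds.petals, ds.flowers)

for r in results:
    cells = "   ".join(f"{g}: {r.means[g]:.3f} ({r.letters[g]})"
                       for g in sorted(r.means))
    p = min(pc.p_value for pc in r.pairwise)
    print(f"{r.trait:>10}   {cells}   p = {p:.2e}")

# A and L are petal area (cm^2) and length (cm); W/L is the petal shape
# ratio; A_T is the whole-corolla area; W_KS/L_KS is the corolla-level
# shape ratio (max petal length over summed petal widths).
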