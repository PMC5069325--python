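"""De novo key tags, Dice distances, PCoA and UPGMA.

The catalogue-free comparison selects 'key tags' seen 20-50 times in each
normalized species table (a depth/repeat filter), truncates every species
to an equal contribution, and ordinates species on the resulting binary
presence matrix.
"""

from gbspaint import (
    AncestralModel,
    SpeciesSpec,
    dice_matrix,
    pcoa,
    presence_matrix,
    select_key_tags,
    simulate_reference_model,
    simulate_species_tagcounts,
    upgma,
    normalize_by_ploidy,
)

ref = simulate_reference_model(AncestralModel(n_loci=420), seed=3)
specs = [
    SpeciesSpec("A_dip", ("A",), depth=30.0),
    SpeciesSpec("C_dip", ("C",), depth=30.0),
    SpeciesSpec("DC_tet", ("D", "C"), depth=30.0),
    SpeciesSpec("ACD_hex", ("A", "C", "D"), depth=30.0,
                divergence_scale=0.0, locus_dropout=0.0),
]
tables = [simulate_species_tagcounts(ref, s, seed=2) for s in specs]
normalized, _ = normalize_by_ploidy(tables, seed=2)

keyset = select_key_tags(normalized, lo=20, hi=50, seed=2)
print(f"key tags: {len(keyset.union)} in the union, "
      f"{keyset.truncation_size} contributed per species")

pm = presence_matrix(keyset, normalized)
dist = dice_matrix(pm)
print("\nDice dissimilarity:")
print(dist.to_frame().round(3))

ordn = pcoa(dist, k=2)
print("\nPCoA coordinates (first two axes):")
print(ordn.to_frame().round(3))

print("\nUPGMA tree:", upgma(dist).newick())
# The DC tetraploid sits closest to the hexaploid (it shares two of its
# three subgenomes); the two diploids are the outgroups on axis 1.
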