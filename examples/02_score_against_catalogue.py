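"""Score species against the hexaploid locus catalogue.

Each catalogued locus owns lettered tag-level haplotypes (one 64 bp tag per
letter).  Scoring is exact-match lookup; the share of catalogue loci with
at least one matching haplotype is the similarity statistic reported per
species, and in the idealized case it equals (shared subgenomes)/3.
"""

from gbspaint import (
    AncestralModel,
    SpeciesSpec,
    score_sample,
    shared_stats,
    simulate_reference_model,
    simulate_species_tagcounts,
)

# a small balanced reference: 210 loci over 21 chromosomes, 70 per subgenome
ref = simulate_reference_model(AncestralModel(n_loci=210), seed=7)
print(f"catalogue: {ref.catalog.n_loci} loci, {ref.catalog.n_tags} haplotype tags")

ideal = dict(depth=30.0, dropout=0.0, divergence_scale=0.0, locus_dropout=0.0)
for name, genomes in [("A_diploid", ("A",)),
                      ("DC_tetraploid", ("D", "C")),
                      ("ACD_hexaploid", ("A", "C", "D"))]:
    spec = SpeciesSpec(name, genomes, **ideal)
    table = simulate_species_tagcounts(ref, spec, seed=1)
    row = score_sample(ref.catalog, table)
    st = shared_stats(row, ref.catalog)
    print(f"{name:15s} shares {st.pct_loci_present:6.2f} % of loci, "
          f"{st.haplotypes_per_shared_locus:.2f} haplotypes per shared locus")
# A one-subgenome diploid shares exactly 1/3 of loci, a DC tetraploid 2/3,
# and the hexaploid all of them - the ploidy logic behind the thresholds
# used later in chromosome E-painting.
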