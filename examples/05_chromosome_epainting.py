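"""Full pipeline run with chromosome E-painting on a synthetic study.

Simulates a multi-species panel (A and C diploids, DC tetraploids, an AB
tetraploid and an ACD hexaploid plus one deliberately mislabelled sample),
then runs validation, normalization, scoring, de novo and in silico
analyses, and finally paints the 21 consensus-map chromosomes by ancestral
genome, exposing the planted C-origin translocation.
"""

from pathlib import Path

from gbspaint import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=11,
    output_dir=Path("scratch/example_run"),
    simulate={
        "n_loci": 2100,
        "samples_per_species": 3,
        "misclassified": [{"cohort": "A_dip_1", "wrong": "C_dip_1"}],
    },
)
summary = run_pipeline(cfg)

print("flagged as misclassified:", summary["stages"]["validation"]["flagged"])
print("1x normalization unit:", summary["stages"]["normalize"]["unit"], "tags")
print("\nshared-locus percentages (Table-1-style):")
for sp, rec in summary["stages"]["scoring"].items():
    print(f"  {sp:10s} {rec['pct']:6.2f} %")

print("\nchromosome genome assignments:")
primary = summary["stages"]["epaint"]["primary"]
for chrom in sorted(primary):
    print(f"  {chrom}: {primary[chrom]}")
print("\nfull segments with the planted translocation on Mrg03:")
for line in (cfg.output_dir / "segments.tsv").read_text().splitlines():
    if line.startswith("Mrg03"):
        print(" ", line)
# Mrg03 is a D chromosome whose terminal 30 % was planted from the C
# genome: the painted C segment boundary falls within half a window
# (15 cM) of the true 70 cM breakpoint.
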