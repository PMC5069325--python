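# Methods

This note documents the statistical model and procedures implemented in
`gbspaint`, the assumptions behind them, the synthetic-data generator used
to validate them, and the numerical conventions and known limitations a
user should be aware of.

## The analysis model

The unit datum is a GBS *tag*: a fixed-length (64 bp, uppercase ACGT)
sequence representative with an integer observation count per sample. A
*locus catalogue* assigns lettered *tag-level haplotypes* (one tag per
letter, letters `a`–`z` unique within a locus, tags unique across the
catalogue) to loci discovered in the hexaploid. Because haplotypes may
differ by several internal SNPs, exact-match tag lookup is more sensitive
to ancestry than single-SNP genotyping; it is also the reason no alignment
step exists anywhere in the pipeline — everything is exact string match.

### Normalization

Species tables are union-sum merges of their validated samples. Because a
tetraploid yields roughly twice and a hexaploid three times the tags of a
diploid at equal sequencing effort per genome copy, totals are rescaled so
that every species holds (ploidy/2) × U tags, where the unit
U = min over species of total/(ploidy/2), floored to an integer. Taking
the minimum means the default operation is down-sampling only; a species
flagged for up-sampling (e.g. a single-accession species with the lowest
coverage) is excluded from the minimum and scaled up by the same rule.
Scaling is per-tag stochastic rounding: with ratio r, a count c becomes
⌊cr⌋ + Bernoulli(cr − ⌊cr⌋). This is unbiased, produces whole numbers,
never invents tags, and is deterministic whenever cr is integral (a tag
counted 600 times at ratio 2/3 is always exactly 400; a singleton at the
same ratio survives with probability 2/3). Zero counts are dropped
throughout: presence means "observed at least once".

### Scoring and summary statistics

Production-mode scoring restricts enumeration to previously discovered
haplotypes: letter *h* is called at a locus for a sample iff the
catalogue tag of (locus, h) has count ≥ `min_count` in that sample's
table. The default `min_count` is 1, consistent with counting any
observed tag as present; it is exposed as a parameter because deeper
per-sample thresholds are sometimes wanted for noisy libraries. Scoring
is monotone in the input table and the binary (plus–minus) matrix is a
pure function of the text matrix. Per species we report the percent of
catalogue loci present and the mean number of haplotype letters per
present locus (the haplotype-diversity index; undefined, reported as
missing, when nothing is present).

### Dice / PCoA / UPGMA / outlier screen

Dissimilarity between presence vectors is Dice, d = 1 − 2a/(2a+b+c);
a pair with no presences at all is defined to have d = 0 (such pairs only
arise in degenerate fixtures). Ordination is classical scaling (PCoA):
eigendecomposition of the doubly centred −d²/2 matrix, coordinates =
eigenvectors × √eigenvalue. Negative eigenvalues (Dice matrices are not
generally Euclidean) are reported but their axes are dropped; no
Lingoes/Cailliez correction is applied since only the leading axes are
interpreted. Axis signs are fixed by making the first nonzero loading
positive so plots are reproducible. Clustering is UPGMA (size-weighted
average linkage, via `scipy.cluster.hierarchy.linkage`), serialized as
Newick with leaf-to-root height equal to half the final merge distance;
trees are ultrametric by construction.

The misclassification screen is deliberately simple and configurable: in
each species cohort of ≥ 3 samples, a sample's statistic is its median
Dice distance to the other members; it is flagged when the statistic
exceeds the cohort median of the statistic + k×MAD with k = 3. The MAD is
floored at 0.02 Dice units: in very tight cohorts the raw MAD collapses
toward zero and would flag ordinary sampling noise, while genuine
misclassifications (a different genome composition) sit near d ≈ 1.
Cohorts of one or two samples are never flagged. This rule automates only
the clustering-based part of accession validation; in practice flow
cytometry and phenotype would corroborate it.

### Key tags and in silico polyploids

The catalogue-free branch avoids hexaploid ascertainment bias. From each
*normalized* species table, tags with counts in the inclusive window
[20, 50] are key tags — the lower bound favours efficiently sampled tags,
the upper bound avoids repetitive elements. Selection operates after
normalization so the window means the same thing for every species. Each
species' candidate set is truncated by seeded uniform subsampling without
replacement to the smallest set size, sets are unioned, and species are
scored present (count > 0) per key tag.

In silico polyploids are union-sum merges of normalized tables: 1× + 2×
gives a 3× theoretical hexaploid directly comparable to extant hexaploids
with no further normalization (a warning is raised if input totals are
inconsistent with their ploidy multipliers). Combination enumeration is a
configurable cross-product over species groups with self-pairs and
unordered duplicates removed. Key-tag ascertainment always uses extant
species only, so derived species cannot feed back into the marker set.
The package ranks reconstructions by distance; it does not attempt to
optimize an ancestral composition.

### Chromosome E-painting

For a reference group's call row on the mapped catalogue subset, the
window profile at each 1 cM grid point p of a chromosome summarizes the
loci in [p − W/2, p + W/2] (W = 30 cM, truncated at chromosome ends — no
padding or reflection, which affects less than W/2 at each end):
f = present loci / loci in window, and v = total haplotype letters /
present loci (missing where the window is empty or nothing is present).

Painting is *relative*: the threshold is a percentile of the metric
pooled over all of the group's chromosomes, so it differentiates
chromosomes within a group regardless of the group's absolute similarity.
Because an idealized one-subgenome diploid carries 1/3 of hexaploid
haplotypes and a two-subgenome (DC) tetraploid 2/3, diploid reference
groups use the 66.7th percentile (their top third of windows) and
tetraploid groups the 33.3rd (their top two thirds). Percentiles use the
linear-interpolation definition and painting is strictly above threshold,
so a constant profile paints nothing. Diversity tracks default to the
same percentiles; any finer adjustment is deliberately manual
configuration, as no principled automatic rule exists.

Genome assignment intersects three painted presence tracks per grid
point: DC ∧ C ∧ ¬A → C; DC ∧ ¬C ∧ ¬A → D; A ∧ ¬DC → A; anything else is
ambiguous and filled from the nearest labelled grid point on the same
chromosome (ties to the left). Coordinates are 0-based half-open cM
intervals everywhere; the Circos export is the only place integers
appear (units of 0.01 cM). Contiguous runs shorter than 15 % of their
chromosome are absorbed into the flanking label for the summary report —
mirroring the convention of not reporting putative translocations below
that size — but the full segmentation is always written separately. The
primary genome of a chromosome is the label with the largest aggregate
length. Segment boundaries inherit the smoothing resolution: they can be
off by up to W/2 = 15 cM, which is the accuracy bound used in the
recovery tests.

## The synthetic-data generator

`gbspaint.simulate` generates studies with the structure the analysis
assumes, plus ground-truth tables that the analysis modules never read.

**Reference model.** 21 chromosomes of 100 cM whose genomes of origin
interleave A, C, D (so equal locus splits are equal per subgenome); 2100
loci by default, dealt round-robin across chromosomes and placed at
uniform-random cM positions (real linkage maps are irregular, and the
irregularity keeps window statistics from collapsing onto a few tied
values). Haplotypes per locus follow a configurable distribution (default
60 % / 30 % / 10 % for 1/2/3, mean 1.5); tags are unique random 64-mers.
A locus inside a configured translocation interval takes the donor
genome as its truth label; the default model plants one C-origin
translocation covering the terminal 30 % of a D chromosome, comfortably
above the 15 % reporting threshold.

**Species.** A species is a multiset of genome labels (one per genome
copy; ploidy = 2 × copies) from {A, B, C, D}, where B is a diverged
variant of A. Each genome copy emits, per haplotype of its home
subgenome's loci, Poisson(depth) observations (default depth 12 per
sample), zeroed with per-sample probability `dropout` (default 0.1,
allele dropout). Expected totals are therefore proportional to ploidy/2
at fixed depth. Two lineage-level mechanisms are realized once per
(species, genome) from the reference seed and shared by all of the
species' samples: *divergence* (default 0.05 within the A/C/D lineages,
0.8 for B vs A) substitutes a private tag for the hexaploid tag, since
under exact-match scoring any mutation is equivalent to a private tag;
and *locus dropout* (default 0.05) removes the haplotype entirely,
emulating restriction-site loss and null alleles. The hexaploid panel
species uses scale 0 for both — the catalogue is by definition discovered
from it. The three hexaploid subgenomes occupy disjoint locus sets with
globally unique tags, so A, C and D are fully diverged from one another
by construction; in particular the D genome, carried only by the DC
tetraploids and the hexaploid, is structurally distinct from A.

The default panel is two A diploids, two C diploids, two DC tetraploids,
one AB tetraploid and one ACD hexaploid, three samples each. A
misclassified sample is a table drawn from one species but labelled as
another, with the swap recorded in a truth flag.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: read-level errors below the tag level,
barcode/adapter artefacts, within-species allelic segregation and
heterozygosity, uneven library depth between samples, paralogous tag
collisions, and continuous gradients of divergence along chromosomes.
Real GBS studies also validate ploidy by flow cytometry, which has no
synthetic counterpart here.

## Numerical choices and determinism

* One master seed per run; every stochastic step draws a named substream
  (CRC32 of stage and label into a `SeedSequence`), so adding or removing
  a species never perturbs another's draws, and identical seeds give
  byte-identical outputs.
* Stochastic rounding is per-tag and independent; integral expectations
  are deterministic.
* Problem sizes in the test and acceptance suites: 2100 loci for
  end-to-end recovery (≈ 100 loci per chromosome, ≈ 30 per window), 210
  loci for exact idealized-fraction checks, 150 000 draws for the
  singleton down-sampling frequency. These sizes give the recovery
  experiments comfortable statistical margins while keeping a full run in
  seconds.
* Degenerate inputs: empty tables normalize to empty; all-zero presence
  pairs get Dice 0; all-missing profiles paint nothing; cohorts under
  three samples are never flagged; percentile thresholds require q
  strictly inside (0, 100).

## Known limitations

* The percentile thresholds assume each reference group's own-subgenome
  windows are its top fraction; groups whose coverage deviates far from
  the 1/3 / 2/3 logic (e.g. highly introgressed material) would need the
  configurable percentiles adjusted.
* Boundary placement of translocation segments is limited by the 30 cM
  window (±15 cM) and further by map resolution.
* The outlier screen is a heuristic for cohort coherence, not a
  classifier; heterogeneous accessions can evade it or be over-flagged at
  aggressive k.
* Haplotype discovery (building new catalogues) and SNP calling within
  tags are out of scope; the catalogue is always an input or simulated.
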