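"""Synthetic multi-species GBS study generator.

Emulates the statistical structure the analysis assumes for a hexaploid
species complex with three ancestral subgenomes (A, C, D) spread over 21
linkage-map chromosomes:

* a hexaploid locus catalogue with lettered tag-level haplotypes and a
  consensus map with genome-of-origin ground truth (optionally carrying
  inter-genome translocations);
* extant species of ploidy 2/4/6 composed of subgenome subsets (A or C
  diploids, DC or AB tetraploids, ACD hexaploids), whose per-sample
  tag-count tables have ploidy-proportional totals, Poisson sequencing
  depth and allele dropout;
* diverged genome variants: the three hexaploid subgenomes occupy disjoint
  locus sets with globally unique tags (fully diverged from each other by
  construction), while the dials in ``AncestralModel.divergence`` set how
  often an *extant* genome carries a private tag instead of the hexaploid
  tag — (B, A) models the diverged B variant of the A genome;
* optional misclassified samples for validating the outlier screen.

Ground-truth tables are written alongside fixtures for parameter-recovery
tests and are never read by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .epaint import ConsensusMap, write_map
from .scoring import LocusCatalog, write_catalog
from .tagcounts import TagCountTable, write_tagcounts

__all__ = [
    "Chromosome",
    "Translocation",
    "AncestralModel",
    "SpeciesSpec",
    "SimulatedReference",
    "default_model",
    "study_species",
    "simulate_reference_model",
    "simulate_species_tagcounts",
    "simulate_cohort",
    "inject_misclassified_sample",
    "write_reference",
]

#: species genome label -> the hexaploid subgenome whose loci it carries
BASE_GENOME = {"A": "A", "B": "A", "C": "C", "D": "D"}
_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cm: float
    genome: str  # hexaploid genome of origin: A, C or D


@dataclass(frozen=True)
class Translocation:
    chromosome: str
    start_cm: float
    end_cm: float
    donor: str  # genome contributing the interval's loci


@dataclass
class AncestralModel:
    """Configuration of the ancestral-genome model behind a synthetic study."""

    n_loci: int = 2100
    tag_length: int = 64
    chromosomes: list[Chromosome] = field(default_factory=lambda: [
        # genomes interleave A, C, D so even locus splits are even per genome
        Chromosome(f"Mrg{i + 1:02d}", 100.0, "ACD"[i % 3]) for i in range(21)
    ])
    translocations: list[Translocation] = field(default_factory=list)
    divergence: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("A", "A"): 0.05,
        ("C", "C"): 0.05,
        ("D", "D"): 0.05,
        ("B", "A"): 0.8,
    })
    haplotypes_per_locus: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})

    def __post_init__(self) -> None:
        if self.n_loci < len(self.chromosomes):
            raise ValueError("need at least one locus per chromosome")
        if self.tag_length < 1:
            raise ValueError("tag_length must be positive")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for c in self.chromosomes:
            if c.genome not in ("A", "C", "D"):
                raise ValueError(f"chromosome genome must be A/C/D, got {c.genome!r}")
        by_name = {c.name: c for c in self.chromosomes}
        seen: dict[str, list[tuple[float, float]]] = {}
        for t in self.translocations:
            if t.chromosome not in by_name:
                raise ValueError(f"translocation on unknown chromosome {t.chromosome!r}")
            if t.donor not in ("A", "C", "D"):
                raise ValueError(f"translocation donor must be A/C/D, got {t.donor!r}")
            length = by_name[t.chromosome].length_cm
            if not (0.0 <= t.start_cm < t.end_cm <= length):
                raise ValueError(f"translocation interval outside {t.chromosome}")
            for s, e in seen.setdefault(t.chromosome, []):
                if t.start_cm < e and s < t.end_cm:
                    raise ValueError(f"overlapping translocations on {t.chromosome}")
            seen[t.chromosome].append((t.start_cm, t.end_cm))
        for pair, p in self.divergence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"divergence{pair} = {p} outside [0, 1]")
            if pair[1] != BASE_GENOME.get(pair[0]):
                raise ValueError(f"divergence pair {pair} does not match a genome lineage")
        total = sum(self.haplotypes_per_locus.values())
        if not np.isclose(total, 1.0):
            raise ValueError("haplotypes_per_locus probabilities must sum to 1")
        for k in self.haplotypes_per_locus:
            if not 1 <= k <= 26:
                raise ValueError("haplotypes per locus must be in 1..26")


@dataclass(frozen=True)
class SpeciesSpec:
    """An extant species: its genome composition, ploidy and sequencing regime.

    ``divergence_scale`` multiplies the model's per-lineage divergence
    probabilities for this species; 0 marks the species whose accessions the
    catalogue was discovered in (it matches the catalogue exactly).
    ``locus_dropout`` is lineage-level locus loss (restriction-site mutation
    or null allele): the affected haplotype is absent from *every* sample of
    the species, unlike ``dropout`` which is per-sample sequencing dropout.
    """

    name: str
    genomes: tuple[str, ...]  # one label per genome copy, e.g. ("D", "C")
    depth: float = 12.0  # mean tag observations per haplotype per sample
    dropout: float = 0.1  # probability a truly present haplotype yields zero tags in a sample
    divergence_scale: float = 1.0
    locus_dropout: float = 0.05

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValueError("species needs at least one genome copy")
        for g in self.genomes:
            if g not in BASE_GENOME:
                raise ValueError(f"unknown genome label {g!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.divergence_scale < 0:
            raise ValueError("divergence_scale must be >= 0")
        if not 0.0 <= self.locus_dropout < 1.0:
            raise ValueError("locus_dropout must be in [0, 1)")

    @property
    def ploidy(self) -> int:
        return 2 * len(self.genomes)


def default_model(**overrides) -> AncestralModel:
    """The study-condition model: 21 chromosomes x 100 cM, 2100 loci,
    one C-origin terminal translocation covering 30 % of one D chromosome."""
    params = dict(
        translocations=[Translocation("Mrg03", 70.0, 100.0, "C")],
    )
    params.update(overrides)
    return AncestralModel(**params)


def study_species() -> list[SpeciesSpec]:
    """Default extant species panel: two A and two C diploids, two DC
    tetraploids, one AB tetraploid and one ACD hexaploid."""
    return [
        SpeciesSpec("A_dip_1", ("A",)),
        SpeciesSpec("A_dip_2", ("A",)),
        SpeciesSpec("C_dip_1", ("C",)),
        SpeciesSpec("C_dip_2", ("C",)),
        SpeciesSpec("DC_tet_1", ("D", "C")),
        SpeciesSpec("DC_tet_2", ("D", "C")),
        SpeciesSpec("AB_tet_1", ("A", "B")),
        SpeciesSpec("ACD_hex", ("A", "C", "D"), divergence_scale=0.0, locus_dropout=0.0),
    ]


@dataclass
class SimulatedReference:
    """Realized reference model: catalogue, map, ground truth and the
    per-subgenome haplotype tag sets species simulation draws from.

    ``base_tags[g]`` maps (locus, letter) -> catalogue tag over the home loci
    of genome label ``g``'s base subgenome.  Divergence is realized lazily
    per (species, genome copy) — each extant lineage substitutes its own
    private tags with probability divergence x the species' scale — and is
    deterministic in the reference seed, so every sample of a species sees
    the same realization.
    """

    model: AncestralModel
    seed: int
    catalog: LocusCatalog
    cmap: ConsensusMap
    truth: pd.DataFrame  # locus, chromosome, position, genome
    base_tags: dict[str, dict[tuple[str, str], str]]

    def truth_genome(self, locus: str) -> str:
        return self._truth_map[locus]

    def __post_init__(self) -> None:
        self._truth_map = dict(zip(self.truth["locus"], self.truth["genome"]))
        self._species_tags: dict[tuple[str, str, float], dict] = {}

    def species_genome_tags(
        self, spec: SpeciesSpec, genome: str
    ) -> dict[tuple[str, str], str]:
        """Realized (locus, letter) -> tag mapping for one genome copy of a species."""
        if genome not in self.base_tags:
            raise ValueError(f"genome label {genome!r} absent from the reference model")
        d = self.model.divergence.get((genome, BASE_GENOME[genome]), 0.0)
        d = min(d * spec.divergence_scale, 1.0)
        lost = spec.locus_dropout
        if d == 0.0 and lost == 0.0:
            return self.base_tags[genome]
        key = (spec.name, genome, d, lost)
        if key not in self._species_tags:
            rng = substream(self.seed, "divergence", spec.name, genome)
            base = self.base_tags[genome]
            n = len(base)
            diverged = rng.random(n) < d
            dropped = rng.random(n) < lost
            out: dict[tuple[str, str], str] = {}
            for (lk, tag), hit, gone in zip(base.items(), diverged, dropped):
                if gone:
                    continue
                if hit:
                    tag = "".join(_ALPHABET[rng.integers(0, 4, size=self.model.tag_length)])
                out[lk] = tag
            self._species_tags[key] = out
        return self._species_tags[key]


def _random_tags(rng: np.random.Generator, n: int, length: int,
                 taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        block = _ALPHABET[rng.integers(0, 4, size=((n - len(out)), length))]
        for row in block:
            tag = "".join(row)
            if tag not in taken:
                taken.add(tag)
                out.append(tag)
    return out


def simulate_reference_model(model: AncestralModel, seed: int) -> SimulatedReference:
    """Realize a catalogue, consensus map, ground truth and genome tag sets.

    Loci are dealt round-robin across chromosomes (so equal splits are equal
    per genome given the interleaved default chromosome order) and placed at
    uniform-random cM positions along each chromosome.  A locus inside a translocation interval
    takes the donor's genome as its truth label.  Haplotype letters run
    consecutively from 'a'; all tags are unique across the catalogue and
    across every diverged-genome private tag.
    """
    rng = substream(seed, "reference")
    chroms = model.chromosomes
    per_chrom: dict[str, list[str]] = {c.name: [] for c in chroms}
    width = len(str(model.n_loci))
    locus_ids = [f"L{i + 1:0{width}d}" for i in range(model.n_loci)]
    for i, lid in enumerate(locus_ids):
        per_chrom[chroms[i % len(chroms)].name].append(lid)

    trans_by_chrom: dict[str, list[Translocation]] = {}
    for t in model.translocations:
        trans_by_chrom.setdefault(t.chromosome, []).append(t)

    ks, probs = zip(*sorted(model.haplotypes_per_locus.items()))
    n_haps = rng.choice(ks, size=model.n_loci, p=np.asarray(probs) / sum(probs))
    hap_of = dict(zip(locus_ids, (int(k) for k in n_haps)))

    taken: set[str] = set()
    loci: dict[str, dict[str, str]] = {}
    rows = []
    for chrom in chroms:
        lids = per_chrom[chrom.name]
        m = len(lids)
        positions = np.sort(rng.uniform(0.0, chrom.length_cm, size=m))
        for lid, pos in zip(lids, positions):
            genome = chrom.genome
            for t in trans_by_chrom.get(chrom.name, []):
                if t.start_cm <= pos < t.end_cm:
                    genome = t.donor
            k = hap_of[lid]
            tags = _random_tags(rng, k, model.tag_length, taken)
            loci[lid] = {chr(ord("a") + j): tags[j] for j in range(k)}
            rows.append((lid, chrom.name, float(pos), genome))
    truth = pd.DataFrame(rows, columns=["locus", "chromosome", "position", "genome"])
    truth = truth.sort_values("locus", ignore_index=True)
    catalog = LocusCatalog(loci, map_subset=set(locus_ids))
    cmap = ConsensusMap({c.name: c.length_cm for c in chroms},
                        {r.locus: (r.chromosome, r.position) for r in truth.itertuples()})

    truth_genome = dict(zip(truth["locus"], truth["genome"]))
    base_tags: dict[str, dict[tuple[str, str], str]] = {}
    present = {c.genome for c in chroms}
    for g, base in BASE_GENOME.items():
        if base not in present:
            continue
        assigned: dict[tuple[str, str], str] = {}
        for lid in locus_ids:
            if truth_genome[lid] != base:
                continue
            for letter, tag in sorted(catalog.loci[lid].items()):
                assigned[(lid, letter)] = tag
        base_tags[g] = assigned
    return SimulatedReference(model=model, seed=seed, catalog=catalog,
                              cmap=cmap, truth=truth, base_tags=base_tags)


def simulate_species_tagcounts(
    ref: SimulatedReference,
    spec: SpeciesSpec,
    seed: int,
    sample: str | None = None,
) -> TagCountTable:
    """Draw one sample's tag-count table for a species.

    Each genome copy emits, for every haplotype of every locus of its home
    subgenome, Poisson(depth) observations of that genome's realized tag,
    zeroed with probability ``dropout`` (allele dropout).  Expected totals
    therefore scale with ploidy/2 at fixed depth.
    """
    missing = [g for g in spec.genomes if g not in ref.base_tags]
    if missing:
        raise ValueError(f"genome labels {missing} absent from the reference model")
    label = sample or spec.name
    rng = substream(seed, "sample", spec.name, label)
    counts: dict[str, int] = {}
    for g in spec.genomes:
        tags = ref.species_genome_tags(spec, g)
        n = len(tags)
        draws = rng.poisson(spec.depth, size=n)
        if spec.dropout > 0:
            draws = np.where(rng.random(n) < spec.dropout, 0, draws)
        for (key, tag), c in zip(tags.items(), draws):
            if c > 0:
                counts[tag] = counts.get(tag, 0) + int(c)
    return TagCountTable(counts, label=label, ploidy=spec.ploidy)


def simulate_cohort(
    ref: SimulatedReference,
    spec: SpeciesSpec,
    n_samples: int,
    seed: int,
) -> list[TagCountTable]:
    """Independent per-sample tables for one species."""
    return [
        simulate_species_tagcounts(ref, spec, seed, sample=f"{spec.name}_s{i + 1}")
        for i in range(n_samples)
    ]


def inject_misclassified_sample(
    ref: SimulatedReference,
    cohort_spec: SpeciesSpec,
    wrong_spec: SpeciesSpec,
    seed: int,
    sample: str | None = None,
) -> tuple[TagCountTable, dict[str, str]]:
    """A sample drawn from ``wrong_spec`` but labelled as ``cohort_spec``.

    Returns the mislabelled table and a truth flag recording the swap (for
    recovery tests of the downstream outlier screen).
    """
    label = sample or f"{cohort_spec.name}_mis"
    table = simulate_species_tagcounts(ref, wrong_spec, seed, sample=label)
    table = table.relabel(label, ploidy=cohort_spec.ploidy)
    flag = {
        "sample": label,
        "labelled_as": cohort_spec.name,
        "drawn_from": wrong_spec.name,
        "misclassified": str(cohort_spec.name != wrong_spec.name),
    }
    return table, flag


def write_reference(ref: SimulatedReference, outdir: str | Path) -> dict[str, Path]:
    """Write catalogue, map, truth table and a YAML parameter sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": outdir / "catalog.tsv",
        "map": outdir / "consensus_map.tsv",
        "truth": outdir / "truth.tsv",
        "params": outdir / "params.yaml",
    }
    write_catalog(ref.catalog, paths["catalog"])
    write_map(ref.cmap, paths["map"])
    ref.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    params = {
        "seed": ref.seed,
        "n_loci": ref.model.n_loci,
        "tag_length": ref.model.tag_length,
        "chromosomes": [
            {"name": c.name, "length_cm": c.length_cm, "genome": c.genome}
            for c in ref.model.chromosomes
        ],
        "translocations": [
            {"chromosome": t.chromosome, "start_cm": t.start_cm,
             "end_cm": t.end_cm, "donor": t.donor}
            for t in ref.model.translocations
        ],
        "divergence": {f"{a}-{b}": p for (a, b), p in ref.model.divergence.items()},
        "haplotypes_per_locus": dict(ref.model.haplotypes_per_locus),
    }
    with paths["params"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)
    return paths
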