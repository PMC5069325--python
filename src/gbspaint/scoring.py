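"""Scoring samples against a fixed hexaploid locus catalogue.

The catalogue assigns lettered tag-level haplotypes (one 64 bp tag per letter)
to loci discovered in the hexaploid.  Scoring a tag-count table against it is
a pure exact-match lookup: letter *h* is called at a locus when the catalogue
tag for (locus, h) was observed at least ``min_count`` times.  The result is a
samples x loci matrix of sorted letter strings (the "text" matrix) and its
derived presence/absence ("plus-minus") form.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "LocusCatalog",
    "CallMatrix",
    "SharedStats",
    "CatalogFormatError",
    "read_catalog",
    "write_catalog",
    "score_sample",
    "score_tables",
    "shared_stats",
]

_LETTER_RE = re.compile(r"^[a-z]$")
_TAG_RE = re.compile(r"^[ACGT]+$")


class CatalogFormatError(ValueError):
    """Raised when a catalogue file violates its TSV dialect or invariants."""


@dataclass
class LocusCatalog:
    """Loci, each owning lettered tag-level haplotypes.

    ``loci`` maps locus id -> {letter -> tag}.  A tag belongs to at most one
    (locus, letter) pair across the whole catalogue.  ``map_subset`` flags the
    loci placed on the consensus linkage map.
    """

    loci: dict[str, dict[str, str]] = field(default_factory=dict)
    map_subset: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: dict[str, tuple[str, str]] = {}
        for locus, haps in self.loci.items():
            for letter, tag in haps.items():
                if not _LETTER_RE.match(letter):
                    raise CatalogFormatError(
                        f"locus {locus!r}: haplotype letter {letter!r} not in a-z")
                if tag in seen:
                    raise CatalogFormatError(
                        f"tag {tag!r} assigned to both {seen[tag]} and {(locus, letter)}")
                seen[tag] = (locus, letter)
        self._tag_index = seen

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_tags(self) -> int:
        return sum(len(h) for h in self.loci.values())

    def tag_lookup(self) -> Mapping[str, tuple[str, str]]:
        """tag -> (locus, letter) for every catalogued haplotype."""
        return self._tag_index

    def subset(self, loci: Sequence[str]) -> "LocusCatalog":
        keep = set(loci)
        return LocusCatalog(
            {l: dict(h) for l, h in self.loci.items() if l in keep},
            map_subset=self.map_subset & keep,
        )

    def mapped(self) -> "LocusCatalog":
        """The catalogue restricted to loci on the consensus map."""
        return self.subset(sorted(self.map_subset))


def read_catalog(path: str | Path) -> LocusCatalog:
    """Read `locus<TAB>letter<TAB>tag[<TAB>map_flag]` rows into a catalogue."""
    path = Path(path)
    loci: dict[str, dict[str, str]] = {}
    map_subset: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise CatalogFormatError(f"{path}:{lineno}: expected 3 or 4 columns")
            locus, letter, tag = parts[:3]
            if not _TAG_RE.match(tag):
                raise CatalogFormatError(f"{path}:{lineno}: non-ACGT tag")
            haps = loci.setdefault(locus, {})
            if letter in haps:
                raise CatalogFormatError(
                    f"{path}:{lineno}: duplicate letter {letter!r} in locus {locus!r}")
            haps[letter] = tag
            if len(parts) == 4 and parts[3] not in ("", "0"):
                map_subset.add(locus)
    return LocusCatalog(loci, map_subset=map_subset)


def write_catalog(catalog: LocusCatalog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for locus in sorted(catalog.loci):
            for letter in sorted(catalog.loci[locus]):
                flag = "1" if locus in catalog.map_subset else "0"
                fh.write(f"{locus}\t{letter}\t{catalog.loci[locus][letter]}\t{flag}\n")


@dataclass
class CallMatrix:
    """Samples x loci haplotype-string matrix with a derived binary form.

    ``text.loc[s, l]`` is the sorted string of haplotype letters called for
    sample ``s`` at locus ``l`` ("" when none).  ``binary`` is 1 wherever the
    string is non-empty.
    """

    text: pd.DataFrame

    @property
    def binary(self) -> pd.DataFrame:
        return (self.text.map(len) > 0).astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.text.index)

    @property
    def loci(self) -> list[str]:
        return list(self.text.columns)

    def row(self, sample: str) -> pd.Series:
        return self.text.loc[sample]


def score_sample(
    catalog: LocusCatalog,
    table,
    min_count: int = 1,
) -> pd.Series:
    """Score one tag-count table against the catalogue.

    Returns a Series indexed by locus id whose values are sorted letter
    strings.  Tags absent from the catalogue are ignored by design (the
    analysis is restricted to previously discovered haplotypes).
    """
    calls = {}
    counts = table.counts if hasattr(table, "counts") else dict(table)
    for locus in sorted(catalog.loci):
        letters = [
            letter
            for letter, tag in catalog.loci[locus].items()
            if counts.get(tag, 0) >= min_count
        ]
        calls[locus] = "".join(sorted(letters))
    return pd.Series(calls, name=getattr(table, "label", None), dtype=object)


def score_tables(catalog: LocusCatalog, tables: Sequence, min_count: int = 1) -> CallMatrix:
    """Score several tables (samples or species) into one CallMatrix."""
    rows = [score_sample(catalog, t, min_count=min_count) for t in tables]
    text = pd.DataFrame(rows)
    text.index = [t.label for t in tables]
    return CallMatrix(text)


@dataclass
class SharedStats:
    """Catalogue-sharing summary for one sample or species.

    ``pct_loci_present``: percent of catalogue loci with at least one called
    haplotype.  ``haplotypes_per_shared_locus``: mean number of letters over
    loci with at least one (NaN when nothing is present).
    """

    pct_loci_present: float
    haplotypes_per_shared_locus: float


def shared_stats(row: pd.Series, catalog: LocusCatalog) -> SharedStats:
    n_loci = catalog.n_loci
    present = int((row.map(len) > 0).sum())
    letters = int(row.map(len).sum())
    pct = 100.0 * present / n_loci if n_loci else math.nan
    ratio = letters / present if present else math.nan
    return SharedStats(pct_loci_present=pct, haplotypes_per_shared_locus=ratio)
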