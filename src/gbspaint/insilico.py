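"""In silico polyploid construction and placement.

Theoretical polyploids are built by union-sum merging the *normalized* tag
counts of extant species: a 1x diploid plus a 2x tetraploid yields a 3x
in silico hexaploid directly comparable to extant hexaploids, and two
diploids yield a 2x in silico tetraploid.  The derived species are scored
against the de novo key-tag set ascertained from extant species only (no
ascertainment feedback), then placed in the Dice/PCoA/UPGMA ordination
alongside the extant species.  If an extant tetraploid really carries the
D genome, diploid+DC combinations should land much closer to extant
hexaploids than any combination of three diploid-derived genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

from .keytags import KeyTagSet, presence_matrix
from .ordination import DistanceMatrix, Ordination, TreeNode, dice_matrix, pcoa, upgma
from .tagcounts import TagCountTable, merge_tagcounts

__all__ = [
    "ComboSpec",
    "combine_species",
    "enumerate_combos",
    "insilico_analysis",
    "write_combo_manifest",
]

_SCHEMES = {
    "hexaploid": (2, 4),  # diploid + tetraploid -> in silico hexaploid
    "tetraploid": (2, 2),  # diploid + diploid -> in silico tetraploid
}


@dataclass(frozen=True)
class ComboSpec:
    """One theoretical polyploid: two component species and the merge scheme."""

    components: tuple[str, str]
    scheme: str  # 'hexaploid' (2n + 4n) or 'tetraploid' (2n + 2n)

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.components[0] == self.components[1]:
            raise ValueError("a species cannot be combined with itself")

    @property
    def label(self) -> str:
        return f"is[{self.components[0]}+{self.components[1]}]"


def combine_species(
    x: TagCountTable,
    y: TagCountTable,
    label: str | None = None,
) -> TagCountTable:
    """Union-sum merge of two normalized species tables.

    The output total is the sum of the inputs, so normalized 1x + 2x inputs
    give a 3x product needing no further normalization.  A warning is issued
    when the inputs' totals are inconsistent with their ploidy multipliers
    (evidence they were not normalized together).
    """
    if x.ploidy and y.ploidy:
        mx, my = x.ploidy // 2, y.ploidy // 2
        if x.total and y.total:
            ratio = (x.total / mx) / (y.total / my)
            if not 0.95 < ratio < 1.05:
                warnings.warn(
                    f"totals of {x.label!r} and {y.label!r} are inconsistent with "
                    f"ploidy multipliers (unit ratio {ratio:.3f}); inputs may not "
                    "be normalized", stacklevel=2)
    merged = merge_tagcounts([x, y])
    merged.label = label or f"is[{x.label}+{y.label}]"
    if x.ploidy and y.ploidy:
        merged.ploidy = x.ploidy + y.ploidy if x.ploidy + y.ploidy in (2, 4, 6) else None
    return merged


def enumerate_combos(
    groups: Mapping[str, Sequence[str]],
    pairing: Sequence[tuple[str, str]],
    scheme: str = "hexaploid",
) -> list[ComboSpec]:
    """Full cross-product of species for each (group1, group2) pairing rule.

    ``groups`` maps a group name (e.g. "A_diploid", "DC_tetraploid") to its
    species labels; ``pairing`` lists which group pairs to cross.  Self-pairs
    and duplicate unordered pairs are excluded; no duplicate combos are
    returned.
    """
    combos: list[ComboSpec] = []
    seen: set[frozenset[str]] = set()
    for g1, g2 in pairing:
        for name in (g1, g2):
            if name not in groups or not groups[name]:
                raise ValueError(f"empty or unknown species group {name!r}")
        for a, b in product(groups[g1], groups[g2]):
            if a == b:
                continue
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            combos.append(ComboSpec((a, b), scheme))
    return combos


def insilico_analysis(
    combos: Sequence[ComboSpec],
    tables: Mapping[str, TagCountTable],
    keyset: KeyTagSet,
    axes: int = 2,
) -> tuple["pd.DataFrame", DistanceMatrix, Ordination, TreeNode]:
    """Score extant plus derived species on the key-tag set and ordinate.

    ``tables`` maps extant species label -> its normalized table; the keyset
    must have been ascertained from extant species only.  Returns the
    combined presence matrix, Dice distances, PCoA and UPGMA tree.
    """
    derived = []
    for combo in combos:
        a, b = combo.components
        for lbl in (a, b):
            if lbl not in tables:
                raise KeyError(f"combo component {lbl!r} has no table")
        derived.append(combine_species(tables[a], tables[b], label=combo.label))
    all_tables = list(tables.values()) + derived
    pm = presence_matrix(keyset, all_tables)
    dist = dice_matrix(pm)
    return pm, dist, pcoa(dist, k=axes), upgma(dist)


def write_combo_manifest(combos: Sequence[ComboSpec], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("label\tcomponent_1\tcomponent_2\tscheme\n")
        for c in combos:
            fh.write(f"{c.label}\t{c.components[0]}\t{c.components[1]}\t{c.scheme}\n")
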