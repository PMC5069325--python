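"""De novo key-tag selection and species presence matrix.

The catalogue-free ("de novo") comparison avoids hexaploid ascertainment bias:
from each ploidy-normalized species table, tags observed between ``lo`` and
``hi`` times (inclusive; the window filters out poorly sampled tags below and
repetitive-element tags above) are "key tags".  Each species' candidate set is
randomly truncated to the size of the smallest set so every species
contributes equally, the truncated sets are unioned, and species are scored
present/absent (count > 0) on the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ._rng import substream
from .tagcounts import TagCountTable

__all__ = ["KeyTagSet", "select_key_tags", "presence_matrix"]


@dataclass
class KeyTagSet:
    """Per-species selected key tags plus their deduplicated union."""

    lo: int
    hi: int
    truncation_size: int
    per_species: dict[str, list[str]] = field(default_factory=dict)
    union: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return list(self.per_species)


def select_key_tags(
    tables: Sequence[TagCountTable],
    lo: int = 20,
    hi: int = 50,
    seed: int = 0,
) -> KeyTagSet:
    """Pick each species' key tags in the [lo, hi] count window and union them.

    Truncation is a seeded uniform subsample without replacement down to the
    smallest species' candidate count, applied before the union.
    """
    if not tables:
        raise ValueError("no species tables")
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid count window [{lo}, {hi}]")
    candidates: dict[str, list[str]] = {}
    for t in tables:
        sel = sorted(tag for tag, c in t.counts.items() if lo <= c <= hi)
        if not sel:
            raise ValueError(
                f"species {t.label!r} has no tags with counts in [{lo}, {hi}]")
        candidates[t.label] = sel
    k = min(len(v) for v in candidates.values())
    per_species: dict[str, list[str]] = {}
    union: list[str] = []
    seen: set[str] = set()
    for label, sel in candidates.items():
        if len(sel) > k:
            rng = substream(seed, "keytags", label)
            idx = rng.choice(len(sel), size=k, replace=False)
            sel = [sel[i] for i in sorted(idx)]
        per_species[label] = sel
        for tag in sel:
            if tag not in seen:
                seen.add(tag)
                union.append(tag)
    return KeyTagSet(lo=lo, hi=hi, truncation_size=k,
                     per_species=per_species, union=union)


def presence_matrix(keyset: KeyTagSet, tables: Sequence[TagCountTable]) -> pd.DataFrame:
    """Binary species x key-tag matrix: 1 where the species observed the tag at all."""
    data = {
        t.label: [1 if t.counts.get(tag, 0) > 0 else 0 for tag in keyset.union]
        for t in tables
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=keyset.union)
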