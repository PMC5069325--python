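"""Tag-count tables: data model, TSV I/O, merging and ploidy normalization.

A *tag* is a fixed-length uppercase DNA sequence (the GBS read representative);
the datum is how many times each tag was observed in a sample or species.
Species tables are built by union-sum merging of their samples, then scaled so
a diploid species totals 1 unit, a tetraploid 2 and a hexaploid 3 — the
"ploidy-proportional" normalization that makes presence/absence comparisons
across ploidy levels meaningful.  Scaling uses stochastic rounding on each
tag's scaled expectation, which is unbiased and preserves whole-number counts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._rng import substream

__all__ = [
    "TagCountTable",
    "NormalizationPlan",
    "TagCountFormatError",
    "read_tagcounts",
    "write_tagcounts",
    "merge_tagcounts",
    "downsample_counts",
    "normalize_by_ploidy",
]

_TAG_RE = re.compile(r"^[ACGT]+$")


class TagCountFormatError(ValueError):
    """Raised when a tag-count file violates the TSV dialect."""


@dataclass
class TagCountTable:
    """Map from tag sequence to a non-negative observation count.

    Zero-count entries are dropped (presence means "observed > 0 times").
    ``ploidy`` is carried when known (2, 4 or 6) so normalization can infer
    the multiplier ploidy/2.
    """

    counts: dict[str, int] = field(default_factory=dict)
    label: str = ""
    ploidy: int | None = None

    def __post_init__(self) -> None:
        self.counts = {t: int(c) for t, c in self.counts.items() if int(c) != 0}
        for tag, c in self.counts.items():
            if c < 0:
                raise TagCountFormatError(f"negative count for tag {tag!r}")
        lengths = {len(t) for t in self.counts}
        if len(lengths) > 1:
            raise TagCountFormatError(f"ragged tag lengths {sorted(lengths)}")
        if self.ploidy is not None and self.ploidy not in (2, 4, 6):
            raise ValueError(f"ploidy must be 2, 4 or 6, got {self.ploidy}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def tag_length(self) -> int | None:
        return len(next(iter(self.counts))) if self.counts else None

    def get(self, tag: str) -> int:
        return self.counts.get(tag, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagCountTable):
            return NotImplemented
        return (
            self.counts == other.counts
            and self.label == other.label
            and self.ploidy == other.ploidy
        )

    def relabel(self, label: str, ploidy: int | None = None) -> "TagCountTable":
        return TagCountTable(dict(self.counts), label=label,
                             ploidy=self.ploidy if ploidy is None else ploidy)


def read_tagcounts(path: str | Path) -> TagCountTable:
    """Read a tag-count TSV: '#' comment lines, then ``tag<TAB>count`` rows.

    ``# label=...`` and ``# ploidy=...`` comments written by
    :func:`write_tagcounts` are recognised and restored.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    label = path.stem
    ploidy: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(label|ploidy)=(.*)$", line)
                if m:
                    if m.group(1) == "label":
                        label = m.group(2).strip()
                    else:
                        ploidy = int(m.group(2))
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TagCountFormatError(f"{path}:{lineno}: expected 2 columns")
            tag, raw = parts
            if not _TAG_RE.match(tag):
                raise TagCountFormatError(f"{path}:{lineno}: non-ACGT tag {tag!r}")
            try:
                c = int(raw)
            except ValueError as exc:
                raise TagCountFormatError(f"{path}:{lineno}: bad count {raw!r}") from exc
            if c < 0:
                raise TagCountFormatError(f"{path}:{lineno}: negative count")
            if tag in counts:
                raise TagCountFormatError(f"{path}:{lineno}: duplicate tag {tag!r}")
            counts[tag] = c
    return TagCountTable(counts, label=label, ploidy=ploidy)


def write_tagcounts(table: TagCountTable, path: str | Path) -> None:
    """Write the canonical TSV: metadata comments then tags in lexicographic order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if table.label:
            fh.write(f"# label={table.label}\n")
        if table.ploidy is not None:
            fh.write(f"# ploidy={table.ploidy}\n")
        for tag in sorted(table.counts):
            fh.write(f"{tag}\t{table.counts[tag]}\n")


def merge_tagcounts(tables: Sequence[TagCountTable], label: str = "") -> TagCountTable:
    """Union-sum merge: each output count is the sum of input counts for that tag."""
    if not tables:
        raise ValueError("merge_tagcounts requires at least one table")
    lengths = {t.tag_length for t in tables if t.tag_length is not None}
    if len(lengths) > 1:
        raise TagCountFormatError(f"tables mix tag lengths {sorted(lengths)}")
    merged: dict[str, int] = {}
    for t in tables:
        for tag, c in t.counts.items():
            merged[tag] = merged.get(tag, 0) + c
    if not label:
        label = "+".join(t.label for t in tables if t.label)
    return TagCountTable(merged, label=label)


def downsample_counts(
    table: TagCountTable,
    target_total: int,
    seed: int | np.random.Generator = 0,
    allow_upsample: bool = False,
) -> TagCountTable:
    """Rescale a table to ``target_total`` by per-tag stochastic rounding.

    Each count c has expectation e = c * target_total/total under the new
    depth; the new count is floor(e) plus a Bernoulli draw on the fractional
    part, so it is always floor(e) or ceil(e) and unbiased: a tag seen 600
    times at ratio 2/3 becomes exactly 400, while a singleton at the same
    ratio drops to 0 with probability 1/3 and stays 1 with probability 2/3.
    """
    if target_total < 0:
        raise ValueError("target_total must be non-negative")
    total = table.total
    if total == 0:
        if target_total > 0:
            raise ValueError("cannot scale an empty table to a positive total")
        return TagCountTable({}, label=table.label, ploidy=table.ploidy)
    if target_total > total and not allow_upsample:
        raise ValueError(
            f"target {target_total} exceeds total {total}; pass allow_upsample=True to up-sample"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = target_total / total
    tags = sorted(table.counts)  # fixed order => reproducible draws
    expect = np.array([table.counts[t] for t in tags], dtype=float) * r
    floors = np.floor(expect)
    frac = expect - floors
    new = floors + (rng.random(len(tags)) < frac)
    counts = {t: int(c) for t, c in zip(tags, new) if c > 0}
    return TagCountTable(counts, label=table.label, ploidy=table.ploidy)


@dataclass
class NormalizationPlan:
    """Record of a ploidy normalization: the 1x unit and per-table targets."""

    unit: int
    multipliers: dict[str, int]
    targets: dict[str, int]
    ratios: dict[str, float]
    upsampled: set[str] = field(default_factory=set)


def normalize_by_ploidy(
    tables: Sequence[TagCountTable],
    seed: int = 0,
    upsample_labels: Iterable[str] = (),
    ploidy_map: Mapping[str, int] | None = None,
) -> tuple[list[TagCountTable], NormalizationPlan]:
    """Scale species tables so totals are proportional to ploidy/2.

    The 1x unit U is the minimum of total/(ploidy/2) over species *not*
    flagged for up-sampling, so the default operation is down-sampling only;
    a species whose target then exceeds its own total (e.g. a lone
    low-coverage tetraploid flagged via ``upsample_labels``) is up-sampled
    with the same stochastic-rounding rule.
    """
    if not tables:
        raise ValueError("no tables to normalize")
    upsample = set(upsample_labels)
    mult: dict[str, int] = {}
    for t in tables:
        ploidy = t.ploidy if t.ploidy is not None else (ploidy_map or {}).get(t.label)
        if ploidy not in (2, 4, 6):
            raise ValueError(f"table {t.label!r}: ploidy must be 2, 4 or 6, got {ploidy}")
        mult[t.label] = ploidy // 2
    anchors = [t for t in tables if t.label not in upsample]
    if not anchors:
        raise ValueError("every species is flagged for up-sampling; the 1x unit is undefined")
    unit = min(t.total // mult[t.label] for t in anchors)
    targets = {t.label: mult[t.label] * unit for t in tables}
    ratios = {t.label: targets[t.label] / t.total if t.total else math.inf for t in tables}
    out: list[TagCountTable] = []
    upsampled: set[str] = set()
    for t in tables:
        target = targets[t.label]
        up = target > t.total
        if up and t.label not in upsample:
            raise ValueError(
                f"table {t.label!r} would need up-sampling but is not flagged for it"
            )
        if up:
            upsampled.add(t.label)
        rng = substream(seed, "normalize", t.label)
        out.append(downsample_counts(t, target, seed=rng, allow_upsample=up))
    plan = NormalizationPlan(unit=unit, multipliers=mult, targets=targets,
                             ratios=ratios, upsampled=upsampled)
    return out, plan
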