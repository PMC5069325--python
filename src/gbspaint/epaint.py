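"""Map-based chromosome E-painting.

"Electronic painting" marks the regions of a hexaploid consensus linkage map
where an ancestral group's marker similarity is relatively high, by analogy
with cytogenetic chromosome painting.  Per group, the locus presence calls on
the mapped catalogue subset are smoothed with a sliding 30 cM window at every
1 cM increment into a locus-presence frequency f and a haplotype-diversity
index v (letters per present locus).  A group's windows are painted where the
metric exceeds a percentile threshold pooled over all of its chromosomes:
an idealized one-subgenome diploid carries ~1/3 of hexaploid haplotypes, so
diploid reference groups use the 66.7th percentile (their top third of
windows) and two-subgenome tetraploid groups the 33.3rd (their top two
thirds).  Intersecting the painted tracks of the A-diploid, C-diploid and
DC-tetraploid groups assigns each chromosome segment to the A, C or D
ancestral genome and exposes inter-genome translocations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusMap",
    "WindowProfile",
    "PaintTrack",
    "GenomeAssignment",
    "read_map",
    "write_map",
    "window_profiles",
    "percentile_paint",
    "assign_genomes",
    "export_circos",
    "read_circos_highlights",
    "write_segments",
    "write_assignment_summary",
]

DIPLOID_PCT = 66.7
TETRAPLOID_PCT = 33.3


@dataclass
class ConsensusMap:
    """Consensus linkage map: ordered chromosomes and locus cM positions.

    ``chromosomes`` maps label -> length in cM; ``loci`` maps locus id ->
    (chromosome, position).  Positions are 0-based cM, intervals downstream
    are half-open [start, end).
    """

    chromosomes: dict[str, float]
    loci: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for locus, (chrom, pos) in self.loci.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"locus {locus!r} on unknown chromosome {chrom!r}")
            if not 0.0 <= pos <= self.chromosomes[chrom]:
                raise ValueError(
                    f"locus {locus!r} at {pos} cM outside [0, {self.chromosomes[chrom]}]")

    def loci_on(self, chrom: str) -> tuple[list[str], np.ndarray]:
        """Locus ids and positions on ``chrom``, sorted by position."""
        pairs = sorted(
            ((pos, lid) for lid, (c, pos) in self.loci.items() if c == chrom))
        return [lid for _, lid in pairs], np.array([p for p, _ in pairs])


def read_map(path: str | Path) -> ConsensusMap:
    """Read `locus<TAB>chromosome<TAB>cM`; `# chrom=NAME:LENGTH` comments set lengths."""
    path = Path(path)
    chroms: dict[str, float] = {}
    loci: dict[str, tuple[str, float]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# chrom="):
                    name, length = line[len("# chrom="):].split(":")
                    chroms[name] = float(length)
                continue
            locus, chrom, cm = line.split("\t")
            loci[locus] = (chrom, float(cm))
    if not chroms:  # fall back to observed extents
        for chrom, pos in loci.values():
            chroms[chrom] = max(chroms.get(chrom, 0.0), pos)
    return ConsensusMap(chroms, loci)


def write_map(cmap: ConsensusMap, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for chrom in cmap.chromosomes:
            fh.write(f"# chrom={chrom}:{cmap.chromosomes[chrom]:.6g}\n")
        for locus in sorted(cmap.loci):
            chrom, pos = cmap.loci[locus]
            fh.write(f"{locus}\t{chrom}\t{pos:.6g}\n")


@dataclass
class WindowProfile:
    """Sliding-window summary on the 1 cM grid of every chromosome.

    ``table`` has columns chromosome, position, n (loci in window), f
    (presence frequency) and v (haplotype diversity; NaN where no locus in
    the window is present).  Grid points whose window holds no mapped locus
    carry NaN for both metrics.
    """

    group: str
    window: float
    step: float
    table: pd.DataFrame

    def metric(self, name: str) -> pd.Series:
        if name not in ("f", "v"):
            raise ValueError("metric must be 'f' (presence) or 'v' (diversity)")
        return self.table[name]


def window_profiles(
    calls: pd.Series,
    cmap: ConsensusMap,
    window: float = 30.0,
    step: float = 1.0,
    group: str | None = None,
) -> WindowProfile:
    """Smooth one row of locus calls along the map.

    ``calls`` maps locus id -> sorted haplotype-letter string ("" = absent);
    every mapped locus must be scored.  At each grid point p the window is
    [p - W/2, p + W/2] clipped to the chromosome; f = present loci / loci in
    window, v = total letters / present loci.  Windows are truncated at
    chromosome ends (no padding).
    """
    rows = []
    half = window / 2.0
    for chrom, length in cmap.chromosomes.items():
        lids, pos = cmap.loci_on(chrom)
        missing = [l for l in lids if l not in calls.index]
        if missing:
            raise ValueError(f"unscored mapped loci on {chrom}: {missing[:3]}...")
        present = np.array([1 if calls[l] else 0 for l in lids])
        letters = np.array([len(calls[l]) for l in lids])
        cum_n = np.concatenate([[0], np.cumsum(np.ones_like(present))])
        cum_p = np.concatenate([[0], np.cumsum(present)])
        cum_l = np.concatenate([[0], np.cumsum(letters)])
        grid = np.arange(0.0, length + step / 2.0, step)
        lo = np.searchsorted(pos, grid - half, side="left")
        hi = np.searchsorted(pos, grid + half, side="right")
        for p, i, j in zip(grid, lo, hi):
            n = int(cum_n[j] - cum_n[i])
            np_ = int(cum_p[j] - cum_p[i])
            nl = int(cum_l[j] - cum_l[i])
            f = np_ / n if n else math.nan
            v = nl / np_ if np_ else math.nan
            rows.append((chrom, float(p), n, f, v))
    table = pd.DataFrame(rows, columns=["chromosome", "position", "n", "f", "v"])
    return WindowProfile(group=group or (calls.name or ""), window=window,
                         step=step, table=table)


@dataclass
class PaintTrack:
    """Painted intervals (half-open cM) where a group's metric exceeds its threshold."""

    group: str
    metric: str
    percentile: float
    threshold: float
    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def painted_mask(self, profile: WindowProfile) -> np.ndarray:
        """Boolean mask over ``profile.table`` rows covered by the intervals."""
        tab = profile.table
        mask = np.zeros(len(tab), dtype=bool)
        for chrom, start, end in self.intervals:
            mask |= (
                (tab["chromosome"] == chrom).to_numpy()
                & (tab["position"].to_numpy() >= start)
                & (tab["position"].to_numpy() < end)
            )
        return mask


def percentile_paint(
    profile: WindowProfile,
    q: float,
    metric: str = "f",
) -> PaintTrack:
    """Paint grid points where the metric strictly exceeds its q-th percentile.

    The percentile (linear-interpolation definition) is pooled over all
    non-missing grid points of the group's chromosomes, so painting reflects
    *relative* similarity within the group.  Adjacent painted grid points are
    merged into maximal half-open intervals [first, last + step).
    """
    if not 0.0 < q < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    values = profile.metric(metric).to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    track = PaintTrack(group=profile.group, metric=metric, percentile=q,
                       threshold=math.nan)
    if finite.size == 0:
        return track
    threshold = float(np.percentile(finite, q))
    track.threshold = threshold
    tab = profile.table
    painted = np.isfinite(values) & (values > threshold)
    for chrom in dict.fromkeys(tab["chromosome"]):
        sel = (tab["chromosome"] == chrom).to_numpy()
        pos = tab.loc[sel, "position"].to_numpy()
        hit = painted[sel]
        start = None
        prev = None
        for p, h in zip(pos, hit):
            if h and start is None:
                start = p
            elif not h and start is not None:
                track.intervals.append((chrom, float(start), float(prev + profile.step)))
                start = None
            prev = p
        if start is not None:
            track.intervals.append((chrom, float(start), float(prev + profile.step)))
    return track


@dataclass
class GenomeAssignment:
    """Per-chromosome ancestral-genome calls.

    ``segments`` partition each chromosome into half-open (start, end, genome)
    runs; ``primary`` is the genome with the largest aggregate length;
    ``report_segments`` drops runs shorter than ``min_frac`` of the
    chromosome (absorbed into their flank) for the summary-table view.
    """

    primary: dict[str, str]
    segments: dict[str, list[tuple[float, float, str]]]
    report_segments: dict[str, list[tuple[float, float, str]]]
    min_frac: float


def _merge_runs(runs: list[tuple[float, float, str]]) -> list[tuple[float, float, str]]:
    merged: list[tuple[float, float, str]] = []
    for start, end, g in runs:
        if merged and merged[-1][2] == g and math.isclose(merged[-1][1], start):
            merged[-1] = (merged[-1][0], end, g)
        else:
            merged.append((start, end, g))
    return merged


def assign_genomes(
    track_a: PaintTrack,
    track_c: PaintTrack,
    track_dc: PaintTrack,
    profiles: Mapping[str, WindowProfile],
    cmap: ConsensusMap,
    min_frac: float = 0.15,
) -> GenomeAssignment:
    """Intersect the three reference tracks into per-chromosome genome calls.

    Rule table per grid point: DC and C painted without A -> C; DC alone -> D;
    A painted without DC -> A; anything else is ambiguous and is filled from
    the nearest non-ambiguous grid point on the same chromosome (ties to the
    left).  For the summary report, contiguous runs shorter than
    ``min_frac`` x chromosome length are absorbed into the flanking label
    (left flank preferred); the full segmentation is retained separately.
    """
    ref = profiles.get(track_a.group) or next(iter(profiles.values()))
    masks = {
        "A": track_a.painted_mask(ref),
        "C": track_c.painted_mask(ref),
        "DC": track_dc.painted_mask(ref),
    }
    tab = ref.table
    primary: dict[str, str] = {}
    segments: dict[str, list[tuple[float, float, str]]] = {}
    report: dict[str, list[tuple[float, float, str]]] = {}
    for chrom, length in cmap.chromosomes.items():
        sel = (tab["chromosome"] == chrom).to_numpy()
        pos = tab.loc[sel, "position"].to_numpy()
        pa, pc, pdc = masks["A"][sel], masks["C"][sel], masks["DC"][sel]
        labels = np.full(pos.shape, "", dtype=object)
        labels[pdc & pc & ~pa] = "C"
        labels[pdc & ~pc & ~pa] = "D"
        labels[pa & ~pdc] = "A"
        known = np.flatnonzero(labels != "")
        if known.size == 0:
            labels[:] = "ambiguous"
        else:
            for i in np.flatnonzero(labels == ""):
                j = known[np.argmin(np.abs(known - i))]  # argmin ties -> left
                labels[i] = labels[j]
        runs: list[tuple[float, float, str]] = []
        start = 0.0
        for idx in range(len(pos)):
            last = idx == len(pos) - 1
            if last or labels[idx + 1] != labels[idx]:
                end = length if last else (pos[idx] + pos[idx + 1]) / 2.0
                runs.append((start, float(end), str(labels[idx])))
                start = float(end)
        segments[chrom] = _merge_runs(runs)
        # absorb short runs into the flanking label for the report view
        rep = list(segments[chrom])
        changed = True
        while changed and len(rep) > 1:
            changed = False
            for i, (s, e, g) in enumerate(rep):
                if e - s < min_frac * length:
                    if i > 0:
                        rep[i] = (s, e, rep[i - 1][2])
                    else:
                        rep[i] = (s, e, rep[i + 1][2])
                    rep = _merge_runs(rep)
                    changed = True
                    break
        report[chrom] = rep
        shares: dict[str, float] = {}
        for s, e, g in segments[chrom]:
            shares[g] = shares.get(g, 0.0) + (e - s)
        primary[chrom] = max(shares, key=lambda g: shares[g])
    return GenomeAssignment(primary=primary, segments=segments,
                            report_segments=report, min_frac=min_frac)


# ---------------------------------------------------------------------------
# Exports


def export_circos(
    cmap: ConsensusMap,
    tracks: Sequence[PaintTrack],
    outdir: str | Path,
    assignment: GenomeAssignment | None = None,
) -> dict[str, Path]:
    """Write Circos-compatible karyotype and per-track highlight files.

    Coordinates are integer units of 0.01 cM (round(cM * 100)).  Returns the
    mapping from logical name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    karyo = outdir / "karyotype.txt"
    colors = {"A": "blue", "C": "orange", "D": "green"}
    with karyo.open("w", encoding="utf-8", newline="\n") as fh:
        for chrom, length in cmap.chromosomes.items():
            color = colors.get((assignment.primary.get(chrom) if assignment else None),
                               "grey")
            fh.write(f"chr - {chrom} {chrom} 0 {round(length * 100)} {color}\n")
    written["karyotype"] = karyo
    for track in tracks:
        path = outdir / f"highlight_{track.group}_{track.metric}.txt"
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for chrom, start, end in track.intervals:
                fh.write(f"{chrom} {round(start * 100)} {round(end * 100)}\n")
        written[f"highlight:{track.group}:{track.metric}"] = path
    return written


def read_circos_highlights(path: str | Path) -> list[tuple[str, float, float]]:
    """Re-import a highlight file back into cM intervals (0.01 cM resolution)."""
    out: list[tuple[str, float, float]] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        chrom, start, end = line.split()
        out.append((chrom, int(start) / 100.0, int(end) / 100.0))
    return out


def write_segments(assignment: GenomeAssignment, path: str | Path) -> None:
    """Full segmentation as BED-like TSV (0-based, half-open cM)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for chrom, runs in assignment.segments.items():
            for start, end, g in runs:
                fh.write(f"{chrom}\t{start:.6g}\t{end:.6g}\t{g}\n")


def write_assignment_summary(assignment: GenomeAssignment, path: str | Path) -> None:
    """Per-chromosome summary: primary genome and reportable segment labels."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("chromosome\tprimary_genome\tassignment\n")
        for chrom, runs in assignment.report_segments.items():
            parts = [g for _, _, g in runs]
            fh.write(f"{chrom}\t{assignment.primary[chrom]}\t{'/'.join(parts)}\n")
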