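"""Dice dissimilarity, principal coordinates, UPGMA and cohort outliers.

These are the comparative statistics of the pipeline: presence/absence
matrices are turned into Dice dissimilarities d = 1 - 2a/(2a+b+c), ordinated
by classical scaling (PCoA) for the figures, clustered by UPGMA for the
trees, and used to flag samples that sit far from the rest of their labelled
species cohort (candidate misclassifications).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "dice_matrix",
    "pcoa",
    "upgma",
    "flag_outliers",
    "write_distance",
    "read_distance",
    "write_ordination",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with row labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


def dice_matrix(binary: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Dice dissimilarity between the 0/1 rows of ``binary``.

    d(x, y) = 1 - 2a / (2a + b + c) with a shared presences, b and c the
    one-sided presences.  A pair with no presences at all (a+b+c = 0) is
    defined to have distance 0.
    """
    x = binary.to_numpy()
    if not np.isin(x, (0, 1)).all():
        raise ValueError("presence matrix must contain only 0 and 1")
    x = x.astype(float)
    a = x @ x.T
    row = x.sum(axis=1)
    denom = row[:, None] + row[None, :]  # 2a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.divide(2.0 * a, denom, out=np.ones_like(a), where=denom > 0)
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(binary.index), d)


@dataclass
class Ordination:
    """Classical-scaling result: sample coordinates on positive-eigenvalue axes."""

    labels: list[str]
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(dist: DistanceMatrix, k: int = 2) -> Ordination:
    """Principal coordinates analysis (Gower's classical scaling).

    The doubly centred matrix -d^2/2 is eigendecomposed; coordinates are
    eigenvectors scaled by sqrt(eigenvalue), restricted to positive
    eigenvalues (no Lingoes/Cailliez correction — negative eigenvalues are
    reported but their axes dropped).  Axis signs are fixed by making the
    first nonzero loading of each axis positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dist.values
    n = d.shape[0]
    b = -0.5 * d**2
    centre = np.eye(n) - np.ones((n, n)) / n
    b = centre @ b @ centre
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    n_pos = int((eigval > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = max(n_pos, 0)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    pos = eigval[eigval > tol]
    prop = pos / pos.sum() if pos.size else np.array([])
    return Ordination(list(dist.labels), coords, eigval, prop)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    """Binary ultrametric tree node; ``height`` is half the merge distance."""

    name: str | None = None
    height: float = 0.0
    children: tuple["TreeNode", "TreeNode"] | None = None

    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name or ""]
        return [n for c in self.children for n in c.leaves()]

    def newick(self) -> str:
        return self._newick_rec() + ";"

    def _newick_rec(self) -> str:
        if self.is_leaf():
            return self.name or ""
        parts = []
        for child in self.children:
            bl = self.height - child.height
            parts.append(f"{child._newick_rec()}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering into an ultrametric tree.

    Merge heights are half the average inter-cluster distance (so
    leaf-to-root path length equals half the final merge distance), matching
    the classic phenogram convention.
    """
    if len(dist.labels) < 2:
        raise ValueError("UPGMA needs at least two taxa")
    z = linkage(dist.condensed(), method="average")
    root, nodes = to_tree(z, rd=True)

    def convert(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(name=dist.labels[node.id], height=0.0)
        left = convert(node.get_left())
        right = convert(node.get_right())
        return TreeNode(height=node.dist / 2.0, children=(left, right))

    return convert(root)


def flag_outliers(
    dist: DistanceMatrix,
    cohorts: dict[str, str] | pd.Series,
    k_mad: float = 3.0,
    mad_floor: float = 0.02,
) -> list[str]:
    """Flag samples far from their own species cohort.

    For each cohort of >= 3 samples, a sample's statistic is its median
    distance to the other cohort members; samples whose statistic exceeds the
    cohort median of that statistic plus ``k_mad`` x MAD are flagged.
    Cohorts of one or two samples are never flagged.  The MAD is floored at
    ``mad_floor`` (Dice units) so that very tight cohorts, where the MAD
    collapses toward zero, do not flag ordinary sampling noise.
    """
    cohorts = dict(cohorts.items() if isinstance(cohorts, pd.Series) else cohorts.items())
    flagged: list[str] = []
    by_cohort: dict[str, list[str]] = {}
    for sample, cohort in cohorts.items():
        by_cohort.setdefault(cohort, []).append(sample)
    for members in by_cohort.values():
        if len(members) < 3:
            continue
        idx = [dist.labels.index(m) for m in members]
        sub = dist.values[np.ix_(idx, idx)]
        stats = np.array([
            np.median(np.delete(sub[i], i)) for i in range(len(members))
        ])
        med = np.median(stats)
        mad = max(np.median(np.abs(stats - med)), mad_floor)
        cut = med + k_mad * mad
        for m, s in zip(members, stats):
            if s > cut:
                flagged.append(m)
    return sorted(flagged)


# ---------------------------------------------------------------------------
# I/O


def write_distance(dist: DistanceMatrix, path: str | Path) -> None:
    dist.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_distance(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix([str(l) for l in df.index], df.to_numpy(dtype=float))


def write_ordination(ord_: Ordination, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in ord_.eigenvalues) + "\n")
        fh.write("# proportion_explained\t"
                 + "\t".join(f"{v:.10g}" for v in ord_.proportion_explained) + "\n")
        ord_.to_frame().to_csv(fh, sep="\t", float_format="%.10g")
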