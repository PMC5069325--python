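"""Dice, PCoA, UPGMA and cohort-outlier flagging."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from gbspaint.ordination import (
    DistanceMatrix,
    dice_matrix,
    flag_outliers,
    pcoa,
    read_distance,
    upgma,
    write_distance,
)


def _binary(rows, labels=None):
    labels = labels or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame([list(map(int, r)) for r in rows], index=labels)


class TestDice:
    def test_identical_vectors(self):
        d = dice_matrix(_binary(["1100", "1100"]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_support(self):
        d = dice_matrix(_binary(["1100", "0011"]))
        assert d.values[0, 1] == 1.0

    def test_hand_enumeration(self):
        d = dice_matrix(_binary(["110", "101"]))
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_empty_pair_defined_zero(self):
        d = dice_matrix(_binary(["000", "000"]))
        assert d.values[0, 1] == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            dice_matrix(pd.DataFrame([[0, 2], [1, 0]]))

    def test_matches_scipy_pairwise(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            x = rng.integers(0, 2, size=(6, 40))
            if not x.any(axis=1).all():
                continue
            mine = dice_matrix(pd.DataFrame(x)).values
            ref = squareform(pdist(x, metric="dice"))
            assert np.allclose(mine, ref, atol=1e-12)

    def test_row_permutation_exchangeable(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.integers(0, 2, size=(7, 25)),
                         index=[f"s{i}" for i in range(7)])
        perm = list(rng.permutation(x.index))
        d1 = dice_matrix(x).to_frame().loc[perm, perm]
        d2 = dice_matrix(x.loc[perm]).to_frame()
        assert np.allclose(d1.values, d2.values)


class TestPCoA:
    def test_two_points(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 0.8], [0.8, 0]]))
        ord_ = pcoa(d, k=1)
        assert np.allclose(np.abs(ord_.coordinates[:, 0]), 0.4)

    def test_three_equidistant_points(self):
        d = DistanceMatrix(list("abc"), 1.0 - np.eye(3))
        ord_ = pcoa(d, k=2)
        for i, j in itertools.combinations(range(3), 2):
            dist = np.linalg.norm(ord_.coordinates[i] - ord_.coordinates[j])
            assert dist == pytest.approx(1.0, abs=1e-9)

    def test_planar_round_trip(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(9, 2))
        d = squareform(pdist(pts))
        ord_ = pcoa(DistanceMatrix([f"p{i}" for i in range(9)], d), k=2)
        rec = squareform(pdist(ord_.coordinates))
        assert np.allclose(rec, d, atol=1e-9)

    def test_matches_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        mine = pcoa(DistanceMatrix([f"p{i}" for i in range(8)], d), k=3)
        ref = skbio_ord.pcoa(SkDM(d), method="eigh")
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1][:3]
        assert np.allclose(np.sort(mine.eigenvalues)[::-1][:3], ref_eig, atol=1e-8)
        ref_coords = ref.samples.to_numpy()[:, :3]
        assert np.allclose(np.abs(mine.coordinates), np.abs(ref_coords), atol=1e-6)

    def test_truncation_warns_when_k_exceeds_rank(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.warns(UserWarning):
            ord_ = pcoa(d, k=5)
        assert ord_.coordinates.shape[1] == 1

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 4))
        d = squareform(pdist(pts))
        ord_ = pcoa(DistanceMatrix([f"p{i}" for i in range(6)], d), k=2)
        assert (np.diff(ord_.eigenvalues) <= 1e-9).all()


def brute_force_upgma(labels, d):
    """Naive UPGMA: explicit cluster-pair averaging, for cross-checking."""
    clusters = {i: [i] for i in range(len(labels))}
    heights = {i: 0.0 for i in range(len(labels))}
    trees = {i: labels[i] for i in range(len(labels))}
    dist = {frozenset((i, j)): d[i, j]
            for i, j in itertools.combinations(range(len(labels)), 2)}
    merges = []
    nxt = len(labels)
    while len(clusters) > 1:
        (i, j), dij = min(
            ((tuple(sorted(k)), v) for k, v in dist.items()
             if all(x in clusters for x in k)),
            key=lambda kv: (kv[1], kv[0]))
        new = nxt
        nxt += 1
        clusters[new] = clusters[i] + clusters[j]
        heights[new] = dij / 2.0
        trees[new] = f"{trees[i]}|{trees[j]}"
        for k in list(clusters):
            if k in (i, j, new):
                continue
            ni, nj = len(clusters[i]), len(clusters[j])
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            dist[frozenset((new, k))] = (ni * dik + nj * djk) / (ni + nj)
        del clusters[i], clusters[j]
        merges.append((frozenset(trees[new].split("|")), heights[new]))
    return merges


def tree_clades(node):
    """(leafset, height) for every internal node."""
    out = []
    if not node.is_leaf():
        out.append((frozenset(node.leaves()), node.height))
        for c in node.children:
            out.extend(tree_clades(c))
    return out


class TestUPGMA:
    def test_two_taxa(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(d)
        assert tree.height == pytest.approx(0.2)
        assert tree.newick() in ("(A:0.2,B:0.2);", "(B:0.2,A:0.2);")

    def test_hand_computed_three_taxa(self):
        d = DistanceMatrix(list("ABC"), np.array([
            [0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float))
        tree = upgma(d)
        clades = dict(tree_clades(tree))
        assert clades[frozenset("AB")] == pytest.approx(1.0)
        assert clades[frozenset("ABC")] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        labels = list("abcde")
        for _ in range(40):
            pts = rng.normal(size=(5, 3))
            d = squareform(pdist(pts))
            tree = upgma(DistanceMatrix(labels, d))
            mine = {cl: h for cl, h in tree_clades(tree)}
            oracle = dict(brute_force_upgma(labels, d))
            assert set(mine) == set(oracle)
            for cl in mine:
                assert mine[cl] == pytest.approx(oracle[cl], abs=1e-10)

    def test_ultrametric(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            d = squareform(pdist(rng.normal(size=(n, 3))))
            tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))

            def depths(node, acc=0.0):
                if node.is_leaf():
                    return [acc]
                out = []
                for c in node.children:
                    assert c.height <= node.height + 1e-12
                    out.extend(depths(c, acc + node.height - c.height))
                return out

            leaf_depths = depths(tree)
            assert max(leaf_depths) - min(leaf_depths) < 1e-9


class TestOutliers:
    def _dist(self, values, labels):
        return DistanceMatrix(labels, np.array(values, dtype=float))

    def test_identical_sample_not_flagged(self):
        labels = ["a1", "a2", "a3"]
        d = self._dist([[0, .05, .06], [.05, 0, .055], [.06, .055, 0]], labels)
        assert flag_outliers(d, {l: "A" for l in labels}) == []

    def test_misclassified_sample_flagged(self):
        labels = ["a1", "a2", "a3", "bad"]
        v = np.full((4, 4), 0.06)
        np.fill_diagonal(v, 0)
        v[3, :3] = v[:3, 3] = 0.95
        d = self._dist(v, labels)
        assert flag_outliers(d, {l: "A" for l in labels}) == ["bad"]

    def test_cohort_of_two_never_flagged(self):
        labels = ["a1", "a2"]
        d = self._dist([[0, 0.99], [0.99, 0]], labels)
        assert flag_outliers(d, {l: "A" for l in labels}) == []


class TestIO:
    def test_distance_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        d = squareform(pdist(rng.normal(size=(5, 2))))
        dm = DistanceMatrix([f"s{i}" for i in range(5)], d)
        write_distance(dm, tmp_path / "d.tsv")
        back = read_distance(tmp_path / "d.tsv")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-9)
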