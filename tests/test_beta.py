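"""GUniFrac, PERMANOVA and PCoA with hand-worked and library oracles."""

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform

from ncmkit import OtuTable, gunifrac, pcoa, permanova, simulate_tree
from ncmkit.core_io import DistanceMatrix

from conftest import tree_from_string


def hand_gunifrac_3tip(alpha):
    """Branch-by-branch oracle on ((A:1,B:1):0.5,C:1.5) for the two samples
    (0.5 A, 0.5 B) and (0.25 A, 0.75 C)."""
    # (length, pA, pB) for branches A, B, AB-internal, C
    branches = [(1.0, 0.5, 0.25), (1.0, 0.5, 0.0),
                (0.5, 1.0, 0.25), (1.5, 0.0, 0.75)]
    num = den = 0.0
    for L, pa, pb in branches:
        s = pa + pb
        if s == 0:
            continue
        w = L * s ** alpha
        num += w * abs(pa - pb) / s
        den += w
    return num / den


class TestGUniFrac:
    def test_identical_samples_zero(self, three_tip_tree):
        tbl = OtuTable(("A", "B", "C"), ("s1", "s2"),
                       np.array([[3, 3], [5, 5], [2, 2]]))
        d = gunifrac(tbl, three_tip_tree, alpha=0.5)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_two_tips_is_one(self):
        tree = tree_from_string("(A:1,B:1);")
        tbl = OtuTable(("A", "B"), ("s1", "s2"), np.array([[10, 0], [0, 10]]))
        d = gunifrac(tbl, tree, alpha=0.5)
        assert d.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_three_tip_hand_oracle(self, three_tip_tree, alpha):
        tbl = OtuTable(("A", "B", "C"), ("s1", "s2"),
                       np.array([[2, 1], [2, 0], [0, 3]]))
        d = gunifrac(tbl, three_tip_tree, alpha=alpha)
        assert d.values[0, 1] == pytest.approx(hand_gunifrac_3tip(alpha),
                                               abs=1e-12)

    def test_branch_length_scale_invariance(self):
        ids = [f"t{i}" for i in range(12)]
        tree = simulate_tree(ids, seed=0)
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(12, 5))
        counts[0] += 1
        tbl = OtuTable(tuple(ids), tuple(f"s{j}" for j in range(5)), counts)
        d1 = gunifrac(tbl, tree, alpha=0.5)
        for node in tree.traverse(include_self=False):
            node.length *= 7.3
        d2 = gunifrac(tbl, tree, alpha=0.5)
        assert np.allclose(d1.values, d2.values, atol=1e-12)

    def test_alpha_one_matches_skbio_weighted_normalized(self):
        ids = [f"t{i}" for i in range(15)]
        tree = simulate_tree(ids, seed=5)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 40, size=(15, 4))
        counts[0] += 1
        tbl = OtuTable(tuple(ids), tuple(f"s{j}" for j in range(4)), counts)
        mine = gunifrac(tbl, tree, alpha=1.0)
        ref = skbio.diversity.beta_diversity(
            "weighted_unifrac", counts.T.copy(), ids=list(tbl.sample_ids),
            taxa=ids, tree=tree, normalized=True)
        assert np.allclose(mine.values, ref.data, atol=1e-12)

    def test_row_order_invariance(self, three_tip_tree):
        a = OtuTable(("A", "B", "C"), ("s1", "s2"),
                     np.array([[2, 1], [2, 0], [0, 3]]))
        b = OtuTable(("C", "A", "B"), ("s1", "s2"),
                     np.array([[0, 3], [2, 1], [2, 0]]))
        assert np.allclose(gunifrac(a, three_tip_tree).values,
                           gunifrac(b, three_tip_tree).values)

    def test_missing_taxon_named(self):
        tree = tree_from_string("(A:1,B:1);")
        tbl = OtuTable(("A", "B", "Z"), ("s1", "s2"),
                       np.array([[1, 1], [1, 1], [1, 1]]))
        with pytest.raises(ValueError, match="Z"):
            gunifrac(tbl, tree)


class TestPermanova:
    def test_perfect_separation_exact_p(self):
        d = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [1, 1, 0, 0], [1, 1, 0, 0]], float)
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_perm="exact")
        assert res.p == pytest.approx(1 / 3)
        assert res.R2 == pytest.approx(1.0)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3))
        pts[6:] += 1.0
        D = squareform(pdist(pts))
        ids = tuple(f"s{i}" for i in range(12))
        grp = ["a"] * 6 + ["b"] * 6
        mine = permanova(DistanceMatrix(ids, D), grp, n_perm=49, seed=1)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.copy(), ids), grouping=grp, permutations=49)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_p_floor_and_reproducibility(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        pts[5:] += 5.0
        D = squareform(pdist(pts))
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(10)), D)
        grp = ["a"] * 5 + ["b"] * 5
        r1 = permanova(dm, grp, n_perm=99, seed=7)
        r2 = permanova(dm, grp, n_perm=99, seed=7)
        assert r1.p == r2.p
        assert r1.p >= 1 / 100

    def test_all_equal_distances_not_significant(self):
        n = 8
        D = np.ones((n, n)) - np.eye(n)
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(n)), D)
        res = permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert np.isfinite(res.pseudo_F)
        assert res.p > 0.5

    def test_empty_group_rejected(self):
        D = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(tuple("abcd"), D)
        with pytest.raises(ValueError):
            permanova(dm, ["a"] * 4, n_perm=9)


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(("x", "y", "z"), d), k=2)
        assert np.allclose(res.proportion_explained, [0.5, 0.5])
        c = res.coordinates.to_numpy()
        dists = [np.linalg.norm(c[i] - c[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(dists, 1.0)

    def test_line_recovered_on_first_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(tuple("abcd"), D), k=2)
        axis1 = res.coordinates["PC1"].to_numpy()
        assert (np.all(np.diff(axis1) > 0) or np.all(np.diff(axis1) < 0))

    def test_two_samples_single_axis(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        res = pcoa(DistanceMatrix(("a", "b"), D), k=2)
        assert res.coordinates.shape[1] == 1
        sep = abs(res.coordinates.iloc[0, 0] - res.coordinates.iloc[1, 0])
        assert sep == pytest.approx(0.7)

    def test_matches_skbio_up_to_sign(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 4))
        D = squareform(pdist(pts))
        ids = tuple(f"s{i}" for i in range(9))
        mine = pcoa(DistanceMatrix(ids, D), k=3).coordinates.to_numpy()
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.copy(), ids),
            number_of_dimensions=3).samples.to_numpy()
        for ax in range(3):
            diff = min(np.abs(mine[:, ax] - ref[:, ax]).max(),
                       np.abs(mine[:, ax] + ref[:, ax]).max())
            assert diff < 1e-10
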