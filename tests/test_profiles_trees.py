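"""Profile distances, UPGMA and RF tests with manual/enumeration oracles."""

import itertools

import numpy as np
import pytest

from phagekit.profiles_trees import (
    DistanceMatrix,
    ProfileTable,
    TreeError,
    TreeNode,
    bipartitions,
    parse_newick,
    profile_distance,
    rf_distance,
    upgma,
)


def table(rows, cols, values):
    return ProfileTable(row_ids=rows, column_ids=cols, values=np.array(values))


class TestProfileDistance:
    def test_identical_rows_zero(self):
        t = table(["a", "b"], list("xyz"), [[1, 2, 0], [1, 2, 0]])
        for metric in ("jaccard", "braycurtis"):
            dm = profile_distance(t, metric=metric, binarize=metric == "jaccard")
            assert dm.d[0, 1] == 0.0

    def test_jaccard_hand_example(self):
        t = table(["a", "b"], list("xyz"), [[1, 1, 0], [1, 0, 1]])
        dm = profile_distance(t, metric="jaccard")
        assert dm.d[0, 1] == pytest.approx(2 / 3)

    def test_braycurtis_brute_force(self, rng):
        vals = rng.integers(0, 9, size=(10, 30))
        vals[:, 0] += 1  # avoid all-zero rows
        t = table([f"r{i}" for i in range(10)], [f"c{j}" for j in range(30)], vals)
        dm = profile_distance(t, metric="braycurtis", binarize=False)
        for i in range(10):
            for j in range(10):
                expect = np.abs(vals[i] - vals[j]).sum() / (vals[i] + vals[j]).sum()
                assert dm.d[i, j] == pytest.approx(expect)

    def test_all_zero_row_braycurtis_errors(self):
        t = table(["a", "zed"], list("xy"), [[1, 2], [0, 0]])
        with pytest.raises(TreeError, match="zed"):
            profile_distance(t, metric="braycurtis", binarize=False)

    def test_outputs_in_unit_interval(self, rng):
        vals = rng.integers(0, 5, size=(6, 12))
        vals[:, 0] += 1
        t = table([f"r{i}" for i in range(6)], [f"c{j}" for j in range(12)], vals)
        for metric in ("jaccard", "braycurtis"):
            dm = profile_distance(t, metric=metric, binarize=metric == "jaccard")
            assert ((dm.d >= 0) & (dm.d <= 1)).all()

    def test_binarize_then_jaccard_equals_support_jaccard(self, rng):
        vals = rng.integers(0, 4, size=(5, 20))
        t = table([f"r{i}" for i in range(5)], [f"c{j}" for j in range(20)], vals)
        d1 = profile_distance(t, metric="jaccard", binarize=True)
        support = (vals > 0).astype(int)
        t2 = table(t.row_ids, t.column_ids, support)
        d2 = profile_distance(t2, metric="jaccard", binarize=False)
        assert np.allclose(d1.d, d2.d)


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(ids=["a", "b"], d=np.array([[0, 0.4], [0.4, 0]]))
        t = upgma(dm)
        assert sorted(t.leaves()) == ["a", "b"]
        assert t.height == pytest.approx(0.2)

    def test_hand_built_ultrametric_4x4(self):
        # (a,b) at 0.2, (c,d) at 0.2, the two pairs at 0.6
        ids = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.2],
                [0.6, 0.6, 0.2, 0.0],
            ]
        )
        t = upgma(DistanceMatrix(ids=ids, d=d))
        assert t.height == pytest.approx(0.3)
        kids = sorted(sorted(c.leaves()) for c in t.children)
        assert kids == [["a", "b"], ["c", "d"]]
        for c in t.children:
            assert c.height == pytest.approx(0.1)

    def test_manual_agglomeration_oracle_5_leaves(self):
        # ultrametric heights: ((a,b):0.1, c):0.25, (d,e):0.15, root 0.4
        ids = ["a", "b", "c", "d", "e"]
        h = {
            ("a", "b"): 0.2,
            ("a", "c"): 0.5,
            ("b", "c"): 0.5,
            ("d", "e"): 0.3,
        }
        d = np.zeros((5, 5))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i == j:
                    continue
                pair = tuple(sorted((x, y)))
                d[i, j] = h.get(pair, 0.8 if {x, y} & {"d", "e"} and {x, y} & {"a", "b", "c"} else 0.8)
        t = upgma(DistanceMatrix(ids=ids, d=d))
        # expected topology: ((a,b),c) vs (d,e)
        sides = {frozenset(c.leaves()) for c in t.children}
        assert sides == {frozenset("abc"), frozenset("de")}
        assert t.height == pytest.approx(0.4)

    def test_leaf_set_preserved(self, rng):
        n = 7
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        t = upgma(DistanceMatrix(ids=ids, d=d))
        assert sorted(t.leaves()) == ids

    def test_heights_nondecreasing_rootward(self, rng):
        n = 8
        m = rng.random((n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        t = upgma(DistanceMatrix(ids=[f"t{i}" for i in range(n)], d=d))

        def check(node):
            for c in node.children:
                assert node.height >= c.height - 1e-12
                check(c)

        check(t)

    def test_ultrametric_exact_recovery(self, rng):
        # build a random ultrametric tree, read off its distances, re-infer
        from phagekit.synthetic_data import random_ultrametric_tree

        labels = [f"x{i}" for i in range(6)]
        truth = random_ultrametric_tree(labels, 1.0, rng)

        # pairwise ultrametric distance = 2 * height of the MRCA
        def mrca_height(t, a, b):
            for c in t.children:
                lv = set(c.leaves())
                if a in lv and b in lv:
                    return mrca_height(c, a, b)
            return t.height

        n = len(labels)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = 2 * mrca_height(truth, labels[i], labels[j])
        inferred = upgma(DistanceMatrix(ids=labels, d=d))
        assert rf_distance(truth, inferred) == 0

        from phagekit.profiles_trees import _walk

        def heights(t):
            return sorted(n.height for n in _walk(t) if not n.is_leaf)

        assert heights(inferred) == pytest.approx(heights(truth), abs=1e-9)

    def test_rejects_tiny(self):
        with pytest.raises(TreeError):
            upgma(DistanceMatrix(ids=["a"], d=np.zeros((1, 1))))


class TestNewick:
    def test_roundtrip(self, rng):
        from phagekit.synthetic_data import random_ultrametric_tree

        t = random_ultrametric_tree([f"l{i}" for i in range(8)], 2.0, rng)
        back = parse_newick(t.newick())
        assert sorted(back.leaves()) == sorted(t.leaves())
        assert rf_distance(t, back) == 0
        assert back.height == pytest.approx(t.height, abs=1e-9)

    def test_parse_simple(self):
        t = parse_newick("((a:1,b:1):1,c:2);")
        assert sorted(t.leaves()) == ["a", "b", "c"]
        assert t.height == pytest.approx(2.0)


class TestRfDistance:
    def test_self_zero(self, rng):
        from phagekit.synthetic_data import random_ultrametric_tree

        t = random_ultrametric_tree(list("abcdef"), 1.0, rng)
        assert rf_distance(t, t) == 0

    def test_two_resolved_quartets(self):
        t1 = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_mismatched_leaves_error(self):
        t1 = parse_newick("((a:1,b:1):1,c:2);")
        t2 = parse_newick("((a:1,b:1):1,d:2);")
        with pytest.raises(TreeError):
            rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(5))
    def test_bipartition_enumeration_oracle_8_leaves(self, seed):
        rng = np.random.default_rng(seed)
        from phagekit.synthetic_data import random_ultrametric_tree

        labels = list("abcdefgh")
        t1 = random_ultrametric_tree(labels, 1.0, rng)
        t2 = random_ultrametric_tree(labels, 1.0, rng)

        def oracle_bipartitions(tree):
            """Enumerate all splits by checking every subset against the tree's
            clusters (independent of the bipartitions() helper)."""
            leafset = frozenset(labels)
            clusters = set()

            def collect(node):
                if not node.is_leaf:
                    clusters.add(frozenset(node.leaves()))
                    for c in node.children:
                        collect(c)

            collect(tree)
            clusters.discard(leafset)
            out = set()
            for c in clusters:
                comp = leafset - c
                if len(c) >= 2 and len(comp) >= 2:
                    out.add(min(c, comp, key=lambda x: (len(x), sorted(x))))
            return out

        o1, o2 = oracle_bipartitions(t1), oracle_bipartitions(t2)
        assert rf_distance(t1, t2) == len(o1 ^ o2)

    def test_dendropy_cross_check(self, rng):
        import dendropy

        from phagekit.synthetic_data import random_ultrametric_tree

        labels = [f"l{i}" for i in range(8)]
        t1 = random_ultrametric_tree(labels, 1.0, rng)
        t2 = random_ultrametric_tree(labels, 1.0, rng)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.newick(), schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.newick(), schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf_distance(t1, t2) == expected
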