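import math

import numpy as np
import pandas as pd
import pytest

from mgecompare.homology import GeneFamily
from mgecompare.pangenome import (ConservationClass, classify_conservation,
                                  delineate_subfamilies, gene_content_distance,
                                  nj_tree, presence_matrix, root_with_outgroup,
                                  to_phylip)


def _fam(fid, members):
    members = frozenset(members)
    rep = max((pid for _, pid in members))
    return GeneFamily(fid, members, rep)


def _matrix(rows: dict[str, str]) -> pd.DataFrame:
    """rows: replicon -> string of 0/1 per family column."""
    reps = list(rows)
    ncol = len(next(iter(rows.values())))
    return pd.DataFrame(
        [[int(c) for c in rows[r]] for r in reps],
        index=reps, columns=[f"f{i}" for i in range(ncol)])


class TestPresenceMatrix:
    def test_shared_and_private_families(self):
        fams = [_fam("shared", {("A", "a1"), ("B", "b1")}),
                _fam("onlyA", {("A", "a2")}),
                _fam("onlyB", {("B", "b2")})]
        m = presence_matrix(fams, ["A", "B"])
        assert m.shape == (2, 3)
        assert list(m.sum(axis=1)) == [2, 2]

    def test_paralogs_collapse_to_one(self):
        fams = [_fam("f", {("A", "a1"), ("A", "a2"), ("B", "b1")})]
        m = presence_matrix(fams, ["A", "B"])
        assert m.loc["A"].max() == 1

    def test_empty_families_error(self):
        with pytest.raises(ValueError):
            presence_matrix([], ["A"])

    def test_unknown_replicon_error(self):
        with pytest.raises(ValueError):
            presence_matrix([_fam("f", {("Z", "z1")})], ["A"])


class TestGeneContentDistance:
    def test_closed_form_values(self):
        # A = {f0..f3}, B = {f0, f1, f4}
        m = _matrix({"A": "11110", "B": "11001"})
        d = gene_content_distance(m, "jaccard")
        assert d.loc["A", "B"] == pytest.approx(1 - 2 / 5)
        d2 = gene_content_distance(m, "shared_min")
        assert d2.loc["A", "B"] == pytest.approx(-math.log(2 / 3))

    def test_identical_and_disjoint(self):
        m = _matrix({"A": "110", "B": "110"})
        assert gene_content_distance(m).loc["A", "B"] == 0
        m = _matrix({"A": "10", "B": "01"})
        assert gene_content_distance(m).loc["A", "B"] == 1.0

    def test_zero_overlap_ceiling(self):
        m = _matrix({"A": "10", "B": "01"})
        d = gene_content_distance(m, "shared_min", zero_overlap_ceiling=7.5)
        assert d.loc["A", "B"] == 7.5

    def test_empty_replicon_is_error(self):
        m = _matrix({"A": "11", "B": "00"})
        with pytest.raises(ValueError):
            gene_content_distance(m)

    @pytest.mark.parametrize("method", ["jaccard", "shared_min"])
    def test_distance_axioms_on_random_matrices(self, method):
        rng = np.random.default_rng(8)
        for _ in range(10):
            X = rng.integers(0, 2, size=(5, 12))
            X[:, 0] = 1  # no empty replicon
            m = pd.DataFrame(X, index=[f"r{i}" for i in range(5)],
                             columns=[f"f{j}" for j in range(12)])
            d = gene_content_distance(m, method).to_numpy()
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= 0).all() and np.isfinite(d).all()


class TestNjTree:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame([[0, 5, 9], [5, 0, 8], [9, 8, 0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = nj_tree(d)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["A"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["B"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 8 - 5) / 2)

    def test_four_taxon_additive_recovery(self):
        # hand-built tree: ((A:2,B:3):1,C:4,D:5) with internal edge 1
        d = pd.DataFrame(0.0, index=list("ABCD"), columns=list("ABCD"))
        paths = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
                 ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        for (x, y), v in paths.items():
            d.loc[x, y] = d.loc[y, x] = v
        tree = nj_tree(d)
        assert tree.splits() == {frozenset({"A", "B"})}
        # total tree length = sum of the 5 branch lengths
        total = 0.0
        stack = [tree.root]
        while stack:
            n = stack.pop()
            total += n.length
            stack.extend(n.children)
        assert total == pytest.approx(2 + 3 + 1 + 4 + 5)

    def test_additive_and_least_squares_oracles(self):
        from mgecompare.evaluation import (nj_additive_check,
                                           nj_least_squares_check)
        a4 = nj_additive_check(n_trees=10, n_taxa=4, seed=1)
        assert a4[0] == a4[1]
        a5 = nj_least_squares_check(n_trees=10, seed=2)
        assert a5[0] == a5[1]

    def test_agrees_with_skbio_on_random_matrices(self):
        import io
        from skbio import DistanceMatrix, TreeNode as SkTreeNode
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(13)
        ids = [f"t{i}" for i in range(6)]
        for _ in range(5):
            a = rng.uniform(0.5, 3.0, size=(6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            d = pd.DataFrame(a, index=ids, columns=ids)
            mine = nj_tree(d).splits()
            sk_tree = sk_nj(DistanceMatrix(a, ids))
            theirs = set()
            for node in sk_tree.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 1 < len(below) < len(ids) - 1:
                    other = frozenset(ids) - below
                    theirs.add(min(below, other,
                                   key=lambda s: (len(s), sorted(s))))
            assert mine == theirs

    def test_non_finite_matrix_rejected(self):
        d = pd.DataFrame([[0, np.inf], [np.inf, 0]], index=list("AB"),
                         columns=list("AB"))
        with pytest.raises(ValueError):
            nj_tree(d)

    def test_newick_and_outgroup_rooting(self):
        d = pd.DataFrame(0.0, index=list("ABCD"), columns=list("ABCD"))
        for (x, y), v in {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
                          ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}.items():
            d.loc[x, y] = d.loc[y, x] = v
        tree = nj_tree(d)
        assert tree.newick.endswith(";")
        rooted = root_with_outgroup(tree, "D")
        assert len(rooted.children) == 2
        assert sorted(rooted.leaves()) == list("ABCD")
        sides = [frozenset(c.leaves()) for c in rooted.children]
        assert frozenset({"D"}) in sides

    def test_phylip_output_shape(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["aa", "bb"],
                         columns=["aa", "bb"])
        text = to_phylip(d)
        assert text.splitlines()[0].strip() == "2"
        assert len(text.splitlines()) == 3


class TestSubfamilies:
    def test_two_planted_blocks(self):
        m = _matrix({
            "A1": "1111000", "A2": "1110100", "A3": "1111000",
            "B1": "1000111", "B2": "1001011", "B3": "1000111"})
        d = gene_content_distance(m)
        labels = delineate_subfamilies(d, k=2)
        assert labels["A1"] == labels["A2"] == labels["A3"]
        assert labels["B1"] == labels["B2"] == labels["B3"]
        assert labels["A1"] != labels["B1"]

    def test_k_equals_n(self):
        m = _matrix({"A": "110", "B": "101", "C": "011"})
        d = gene_content_distance(m)
        labels = delineate_subfamilies(d, k=3)
        assert len(set(labels.values())) == 3

    def test_all_equal_distances_split_deterministically(self):
        ids = list("ABCD")
        a = np.ones((4, 4)) - np.eye(4)
        d = pd.DataFrame(a, index=ids, columns=ids)
        l1 = delineate_subfamilies(d, k=2)
        l2 = delineate_subfamilies(d, k=2)
        assert l1 == l2 and len(set(l1.values())) == 2

    def test_k_too_large_is_error(self):
        m = _matrix({"A": "11", "B": "10"})
        d = gene_content_distance(m)
        with pytest.raises(ValueError):
            delineate_subfamilies(d, k=3)


class TestConservationClasses:
    def test_definitions(self):
        m = _matrix({
            "A1": "110110", "A2": "110100", "B1": "101011", "B2": "100011"})
        labels = {"A1": 0, "A2": 0, "B1": 1, "B2": 1}
        classes = classify_conservation(m, labels)
        assert classes["f0"] == ConservationClass.CORE
        assert classes["f1"] == ConservationClass.GROUP_SPECIFIC  # both A
        assert classes["f2"] == ConservationClass.SINGLETON       # B1 only
        assert classes["f3"] == ConservationClass.GROUP_SPECIFIC  # both A
        assert classes["f4"] == ConservationClass.SEMI_CONSERVED  # A1+B1+B2
        assert classes["f5"] == ConservationClass.GROUP_SPECIFIC  # both B

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(6, 15))
        X[:, 0] = 1
        m = pd.DataFrame(X, index=[f"r{i}" for i in range(6)],
                         columns=[f"f{j}" for j in range(15)])
        m = m.loc[:, m.sum(axis=0) > 0]
        labels = {f"r{i}": i % 2 for i in range(6)}
        classes = classify_conservation(m, labels)
        assert set(classes) == set(m.columns)  # every family classified once

    def test_requires_two_subfamilies(self):
        m = _matrix({"A": "11", "B": "10"})
        with pytest.raises(ValueError):
            classify_conservation(m, {"A": 0, "B": 0})


class TestEndToEndRecovery:
    def test_synthetic_set_recovery(self):
        from mgecompare.evaluation import pangenome_recovery_once
        out = pangenome_recovery_once(31415)
        assert out.ari == 1.0 and out.split_ok and out.classes_ok
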