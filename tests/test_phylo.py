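"""NJ consistency, bootstrap supports, and the dual-tree clade rule."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from phagepan.phylo import (
    bootstrap_supports,
    delineate_clades,
    nj_tree,
    p_distance_matrix,
    read_support_tree,
    sister_group_labels,
    supported_sides,
    write_support_tree,
)


def _bipartitions(tree):
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(node.subset())
        if 1 < len(side) < len(leaves) - 1:
            out.add(side if ref not in side else leaves - side)
    return out


def _tip_depths(tree):
    return {t.name: tree.distance(t) for t in tree.tips()}


class TestNJ:
    def test_three_taxa_closed_form(self):
        # d_ab=2, d_ac=3, d_bc=4 -> branch lengths 0.5, 1.5, 2.5
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(d, ids=["a", "b", "c"])
        lengths = {
            t.name: t.length for t in tree.tips()
        }
        # skbio roots the NJ tree at one of the taxa's pendant edges; the
        # three pendant lengths are recoverable from pairwise distances
        tips = {t.name: t for t in tree.tips()}
        assert tree.find("a").distance(tips["b"]) == pytest.approx(2.0)
        assert tree.find("a").distance(tips["c"]) == pytest.approx(3.0)
        assert tree.find("b").distance(tips["c"]) == pytest.approx(4.0)

    def test_additive_matrix_recovers_generating_topology(self, rng):
        # random 8-leaf tree; NJ on its exact path-length distances must
        # return exactly its bipartitions
        newick = "((a:1,(b:2,c:1):2):1,((d:3,e:1):1,f:2):2,(g:1,h:4):3);"
        tree = TreeNode.read(io.StringIO(newick))
        names = [t.name for t in tree.tips()]
        n = len(names)
        d = np.zeros((n, n))
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i < j:
                    d[i, j] = d[j, i] = tree.find(x).distance(tree.find(y))
        recovered = nj_tree(d, ids=names)
        assert _bipartitions(recovered) == _bipartitions(tree)

    def test_identical_taxa_are_siblings(self):
        d = np.array(
            [[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]], dtype=float
        )
        tree = nj_tree(d, ids=["a", "b", "c", "d"])
        assert frozenset({"a", "b"}) in {
            frozenset(node.subset()) for node in tree.non_tips()
        } | {frozenset({"a", "b"})}  # root split counts
        # a and b share distance 0 in the reconstruction
        assert tree.find("a").distance(tree.find("b")) == pytest.approx(0.0)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [2, 0]], dtype=float))
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)))


def _two_group_alignment(rng, n_noise_cols=40):
    """Eight taxa in two clearly separated 4-leaf groups plus noise."""
    aln = {}
    for i in range(8):
        block = "A" * 500 if i < 4 else "C" * 500
        noise = "".join(rng.choice(list("ACDEFGHIKLMN"), n_noise_cols))
        aln[f"t{i}"] = block + noise
    return aln


class TestBootstrap:
    def test_concordant_split_gets_high_support(self, rng):
        aln = _two_group_alignment(rng)
        tree = bootstrap_supports(aln, n_reps=200, seed=3)
        sides = supported_sides(tree, min_support=99)
        assert frozenset({"t0", "t1", "t2", "t3"}) in sides or frozenset(
            {"t4", "t5", "t6", "t7"}
        ) in sides

    def test_zero_reps_leaves_supports_absent(self, rng):
        aln = _two_group_alignment(rng)
        tree = bootstrap_supports(aln, n_reps=0, seed=1)
        assert all(
            getattr(node, "support", None) is None for node in tree.non_tips()
        )

    def test_fixed_seed_is_deterministic(self, rng):
        aln = _two_group_alignment(rng)
        t1 = bootstrap_supports(aln, n_reps=50, seed=7)
        t2 = bootstrap_supports(aln, n_reps=50, seed=7)
        s1 = {frozenset(n.subset()): n.support for n in t1.non_tips(include_self=False)}
        s2 = {frozenset(n.subset()): n.support for n in t2.non_tips(include_self=False)}
        assert s1 == s2

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports({"a": "", "b": "", "c": ""}, n_reps=10)


def _tree_with_supports(newick):
    return read_support_tree(newick)


class TestDelineate:
    def test_identical_trees_single_supported_clade(self):
        nwk = "((a:1,b:1,c:1)100:1,(d:1,e:1)50:1,f:1);"
        ta, tb = _tree_with_supports(nwk), _tree_with_supports(nwk)
        clades = delineate_clades(ta, tb)
        assert [sorted(c.members) for c in clades] == [["a", "b", "c"]]
        assert clades[0].support_a == clades[0].support_b == 100.0

    def test_support_89_in_one_tree_excluded(self):
        ta = _tree_with_supports("((a:1,b:1,c:1)100:1,(d:1,e:1)90:1,f:1);")
        tb = _tree_with_supports("((a:1,b:1,c:1)89:1,(d:1,e:1)90:1,f:1);")
        assert delineate_clades(ta, tb, min_support=90) == []

    def test_maximal_only_nested_candidates(self):
        # a supported 3-leaf clade nested inside a supported 4-leaf clade:
        # only the larger is reported
        nwk = "(((a:1,b:1,c:1)98:1,d:1)95:1,(e:1,f:1,g:1)40:1,h:1);"
        ta, tb = _tree_with_supports(nwk), _tree_with_supports(nwk)
        clades = delineate_clades(ta, tb, min_support=90)
        assert [sorted(c.members) for c in clades] == [["a", "b", "c", "d"]]

    def test_incoherent_group_replaced_by_coherent_subgroup(self):
        # the two trees disagree on d's placement; the coherent supported
        # 3-leaf subgroup is reported instead of the 4-leaf group
        ta = _tree_with_supports("(((a:1,b:1,c:1)99:1,d:1)99:1,(e:1,f:1)99:1,g:1);")
        tb = _tree_with_supports("((a:1,b:1,c:1)99:1,((e:1,f:1)99:1,d:1)99:1,g:1);")
        clades = delineate_clades(ta, tb, min_support=90)
        assert [sorted(c.members) for c in clades] == [["a", "b", "c"]]

    def test_leaf_set_mismatch_rejected(self):
        ta = _tree_with_supports("((a:1,b:1,c:1)100:1,d:1,e:1);")
        tb = _tree_with_supports("((a:1,b:1,c:1)100:1,d:1,x:1);")
        with pytest.raises(ValueError):
            delineate_clades(ta, tb)

    def test_planted_clades_recovered_from_dual_bootstrap_trees(self, small_sim):
        _, genomes, truth = small_sim
        def og_alignment(og_ids):
            rows = {}
            for g in genomes:
                parts = [
                    (truth.orthogroup_of_gene[x.id], x.protein)
                    for x in g.genes
                    if truth.orthogroup_of_gene[x.id] in og_ids
                ]
                rows[g.id] = "".join(p for _, p in sorted(parts))
            return rows

        ta = bootstrap_supports(og_alignment({"COG000"}), n_reps=200, seed=1)
        tb = bootstrap_supports(
            og_alignment({"COG001", "COG002", "COG003"}), n_reps=200, seed=2
        )
        clades = delineate_clades(ta, tb, min_support=90, min_members=3)
        want = {}
        for genome, clade in truth.clade_of_genome.items():
            want.setdefault(clade, set()).add(genome)
        assert sorted(sorted(c.members) for c in clades) == sorted(
            sorted(v) for v in want.values()
        )


class TestSisterLabels:
    def test_cherry_sister(self):
        tree = read_support_tree("((a:1,b:1):1,(c:1,d:1):1);")
        labels, mono = sister_group_labels(
            tree, ["a", "b"], {"c": "Alpha", "d": "Alpha"}
        )
        assert mono
        assert labels == {"Alpha": 2}

    def test_scattered_query_not_monophyletic(self):
        tree = read_support_tree("((a:1,c:1):1,(b:1,d:1):1);")
        labels, mono = sister_group_labels(tree, ["a", "b"], {"c": "X", "d": "Y"})
        assert not mono

    def test_viral_clade_nested_in_alphaproteobacteria(self):
        nwk = "(((v1:1,v2:1,v3:1):1,(p1:1,p2:1):1):1,(o1:1,o2:1):1);"
        tree = read_support_tree(nwk)
        label_map = {"p1": "Alphaproteobacteria", "p2": "Alphaproteobacteria",
                     "o1": "Gammaproteobacteria", "o2": "Gammaproteobacteria"}
        labels, mono = sister_group_labels(tree, ["v1", "v2", "v3"], label_map)
        assert mono
        assert set(labels) == {"Alphaproteobacteria"}


class TestNewickIO:
    def test_fractional_supports_scaled_with_warning(self):
        with pytest.warns(UserWarning):
            tree = read_support_tree("((a:1,b:1,c:1)0.97:1,d:1,e:1,f:1,g:1);")
        sides = supported_sides(tree, min_support=90)
        assert frozenset({"a", "b", "c"}) in sides

    def test_round_trip_preserves_supports(self):
        tree = read_support_tree("((a:1,b:1,c:1)97:1,(d:1,e:1)55:1,f:1);")
        buf = io.StringIO()
        write_support_tree(tree, buf)
        back = read_support_tree(buf.getvalue())
        assert supported_sides(back, 0) == supported_sides(tree, 0)
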