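import itertools

import dendropy
import numpy as np
import pytest

from gbdphylo import formats, phylo, synthetic
from gbdphylo.errors import UsageError
from gbdphylo.gbdp import DistanceMatrix
from gbdphylo.phylo import (
    MONOPHYLETIC,
    PARAPHYLETIC,
    POLYPHYLETIC,
    TRIVIAL,
    branch_support,
    classify_taxon,
    midpoint_root,
    nj_tree,
    taxon_support,
    tree_bipartitions,
)

from conftest import tree_path_matrix

import pandas as pd


def dm(labels, rows):
    return DistanceMatrix(list(labels), np.array(rows, dtype=float))


def leaf_depths(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        m = dm("ABC", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = nj_tree(m)
        lengths = {
            nd.taxon.label: nd.edge.length for nd in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_additive_quartet_split_and_internal_branch(self):
        # leaves at 0.1 from their cherry nodes, internal edge 0.2:
        # dAB=dCD=0.2, cross=0.1+0.2+0.1=0.4 -> split AB|CD
        m = dm(
            "ABCD",
            [
                [0, 0.2, 0.4, 0.4],
                [0.2, 0, 0.4, 0.4],
                [0.4, 0.4, 0, 0.2],
                [0.4, 0.4, 0.2, 0],
            ],
        )
        tree = nj_tree(m)
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        internal = [
            nd.edge.length
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd is not tree.seed_node
        ]
        assert internal == [pytest.approx(0.2)]

    def test_all_zero_matrix_gives_star(self):
        m = dm("ABCD", np.zeros((4, 4)))
        tree = nj_tree(m)
        assert tree_bipartitions(tree) == set()
        assert all((nd.edge.length or 0) == 0 for nd in tree if nd is not tree.seed_node)

    def test_two_taxa_split_evenly(self):
        m = dm("AB", [[0, 0.3], [0.3, 0]])
        tree = nj_tree(m)
        assert {nd.edge.length for nd in tree.leaf_node_iter()} == {0.15}

    def test_single_taxon_rejected(self):
        with pytest.raises(UsageError):
            nj_tree(DistanceMatrix(["A"], np.zeros((1, 1))))

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_trees_exactly(self, seed):
        spec = synthetic.SimulationSpec(
            n_taxa=int(np.random.default_rng(seed).integers(4, 9)),
            tree_shape="random", branch_length_mean=0.04, seed=seed,
        )
        true = synthetic.simulate_tree(spec)
        labels, m = tree_path_matrix(true)
        assert m.max() < 1.0
        est = nj_tree(DistanceMatrix(labels, m))
        assert tree_bipartitions(est) == tree_bipartitions(true)
        est_labels, est_m = tree_path_matrix(est)
        assert est_labels == labels
        np.testing.assert_allclose(est_m, m, atol=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        spec = synthetic.SimulationSpec(n_taxa=7, tree_shape="random", seed=33)
        true = synthetic.simulate_tree(spec)
        labels, m = tree_path_matrix(true)
        ours = nj_tree(DistanceMatrix(labels, m))
        theirs_nwk = skbio_nj(SkbioDM(m, ids=labels)).__str__()
        theirs = formats.read_newick(theirs_nwk)
        assert tree_bipartitions(ours) == tree_bipartitions(theirs)


class TestMidpointRoot:
    def test_two_leaf_edge_split(self):
        tree = formats.read_newick("(A:1.0,B:3.0);")
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_long_leaf_branch_attracts_root(self):
        tree = formats.read_newick("((A:10,B:1):1,(C:1,D:1):1);")
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        # most distant pair is (A, C) or (A, D) at distance 13 -> root 6.5 out
        assert depths["A"] == pytest.approx(6.5)
        assert max(depths["C"], depths["D"]) == pytest.approx(6.5)
        # root must sit on A's terminal branch: A's path has no internal node
        a = [nd for nd in rooted.leaf_node_iter() if nd.taxon.label == "A"][0]
        assert a.parent_node is rooted.seed_node

    def test_symmetric_quartet_roots_on_internal_edge(self):
        tree = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = midpoint_root(tree)
        depths = leaf_depths(rooted)
        assert all(v == pytest.approx(2.0) for v in depths.values())

    def test_most_distant_leaves_equidistant_property(self):
        for seed in range(5):
            spec = synthetic.SimulationSpec(
                n_taxa=8, tree_shape="random", seed=40 + seed
            )
            tree = synthetic.simulate_tree(spec)
            labels, m = tree_path_matrix(tree)
            rooted = midpoint_root(tree)
            depths = leaf_depths(rooted)
            dmax = m.max()
            assert max(depths.values()) == pytest.approx(dmax / 2, abs=1e-9)

    def test_all_zero_lengths_roots_at_smallest_leaf(self):
        tree = formats.read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        rooted = midpoint_root(tree)
        assert rooted.is_rooted
        a = [nd for nd in rooted.leaf_node_iter() if nd.taxon.label == "A"][0]
        assert a.parent_node is rooted.seed_node


class TestBranchSupport:
    def test_all_replicates_identical_gives_100(self):
        ref = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
        reps = [formats.read_newick("((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);")
                for _ in range(10)]
        branch_support(ref, reps)
        sup = [nd.support for nd in ref.preorder_node_iter()
               if not nd.is_leaf() and nd is not ref.seed_node]
        assert sup == [100, 100, 100]

    def test_fractional_count(self):
        ref = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        yes = "((A:1,B:1):1,(C:1,D:1):1);"
        no = "((A:1,C:1):1,(B:1,D:1):1);"
        reps = [formats.read_newick(yes) for _ in range(50)]
        reps += [formats.read_newick(no) for _ in range(50)]
        branch_support(ref, reps)
        sups = {nd.support for nd in ref.preorder_node_iter()
                if not nd.is_leaf() and nd is not ref.seed_node}
        assert sups == {50}

    def test_star_replicates_zero_support(self):
        ref = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        reps = [formats.read_newick("(A:1,B:1,C:1,D:1);") for _ in range(5)]
        branch_support(ref, reps)
        sups = [nd.support for nd in ref.preorder_node_iter()
                if not nd.is_leaf() and nd is not ref.seed_node]
        assert sups == [0, 0]

    def test_leafset_mismatch_lists_difference(self):
        ref = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rep = formats.read_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(UsageError, match="D.*E|E.*D"):
            branch_support(ref, [rep])

    def test_support_invariant_under_leaf_order_permutation(self):
        ref = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ref2 = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        reps1 = [formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")]
        reps2 = [formats.read_newick("((D:1,C:1):1,(B:1,A:1):1);")]
        branch_support(ref, reps1)
        branch_support(ref2, reps2)
        s1 = sorted(nd.support for nd in ref.preorder_node_iter()
                    if not nd.is_leaf() and nd is not ref.seed_node)
        s2 = sorted(nd.support for nd in ref2.preorder_node_iter()
                    if not nd.is_leaf() and nd is not ref2.seed_node)
        assert s1 == s2 == [100, 100]


def brute_force_min_changes(tree, members, fix_mrca_state=None):
    """Exhaustive minimum-change count for the binary membership character."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    clades = phylo._clade_sets(tree)
    mrca = None
    for nd in tree.postorder_node_iter():
        if frozenset(members) <= clades[id(nd)]:
            mrca = nd
            break
    best = np.inf
    for states in itertools.product((0, 1), repeat=len(internals)):
        assign = {id(nd): s for nd, s in zip(internals, states)}
        if fix_mrca_state is not None and assign[id(mrca)] != fix_mrca_state:
            continue
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = 1 if leaf.taxon.label in members else 0
        changes = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                changes += assign[id(nd)] != assign[id(nd.parent_node)]
        best = min(best, changes)
    return best


class TestClassifyTaxon:
    def test_clade_is_monophyletic(self):
        tree = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert classify_taxon(tree, {"A", "B"}) == MONOPHYLETIC

    def test_single_leaf_trivial(self):
        tree = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert classify_taxon(tree, {"A"}) == TRIVIAL

    def test_split_pair_is_paraphyletic(self):
        tree = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert classify_taxon(tree, {"A", "C"}) == PARAPHYLETIC

    def test_unknown_leaf_rejected(self):
        tree = formats.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(UsageError):
            classify_taxon(tree, {"A", "Z"})

    def test_scattered_members_polyphyletic(self):
        # members scattered among large non-member clades: every
        # most-parsimonious reconstruction needs >= 2 independent gains
        nwk = (
            "(((A:1,(a1:1,(a2:1,a3:1):1):1):1,(B:1,(b1:1,(b2:1,b3:1):1):1):1):1,"
            "((C:1,(c1:1,(c2:1,c3:1):1):1):1,(D:1,(d1:1,(d2:1,d3:1):1):1):1):1);"
        )
        tree = formats.read_newick(nwk)
        members = {"A", "B", "C"}
        assert classify_taxon(tree, members) == POLYPHYLETIC
        # cross-check with the exhaustive oracle
        total = brute_force_min_changes(tree, members)
        with_member_mrca = brute_force_min_changes(tree, members, fix_mrca_state=1)
        assert with_member_mrca > total

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_exhaustive_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        spec = synthetic.SimulationSpec(n_taxa=7, tree_shape="random", seed=seed)
        tree = synthetic.simulate_tree(spec)
        leaves = sorted(nd.taxon.label for nd in tree.leaf_node_iter())
        members = set(rng.choice(leaves, size=3, replace=False))
        got = classify_taxon(tree, members)
        clades = phylo._clade_sets(tree)
        if any(clades[id(nd)] == frozenset(members)
               for nd in tree.preorder_node_iter()):
            assert got == MONOPHYLETIC
        else:
            total = brute_force_min_changes(tree, members)
            fixed = brute_force_min_changes(tree, members, fix_mrca_state=1)
            assert got == (PARAPHYLETIC if fixed == total else POLYPHYLETIC)


def taxonomy_frame(mapping, rank="genus"):
    rows = []
    for gid, value in mapping.items():
        row = dict(genome_id=gid, species="", genus="", subfamily="", family="")
        row[rank] = value
        rows.append(row)
    return pd.DataFrame(rows)


class TestTaxonSupport:
    def support_tree(self, nwk):
        return formats.read_newick(nwk)

    def test_all_monophyletic_overall_one(self):
        tree = self.support_tree("((A:1,B:1)100:1,(C:1,D:1)80:1);")
        tax = taxonomy_frame({"A": "t1", "B": "t1", "C": "t2", "D": "t2"})
        rep = taxon_support(tree, tax, "genus")
        signed = {r["taxon"]: r["signed_support"] for r in rep.rows}
        assert signed == {"t1": 100, "t2": 80}
        assert rep.overall == 1.0

    def test_crossed_taxa_overall_minus_one(self):
        tree = self.support_tree("((A:1,B:1)100:1,(C:1,D:1)100:1);")
        tax = taxonomy_frame({"A": "t1", "C": "t1", "B": "t2", "D": "t2"})
        rep = taxon_support(tree, tax, "genus")
        signed = {r["taxon"]: r["signed_support"] for r in rep.rows}
        assert signed == {"t1": -100, "t2": -100}
        assert rep.overall == -1.0

    def test_mixed_signed_sum(self):
        tree = self.support_tree(
            "(((A:1,B:1)100:1,(C:1,D:1)100:1)100:1,((E:1,G:1)100:1,(F:1,H:1)100:1)100:1);"
        )
        tax = taxonomy_frame(
            {"A": "t1", "B": "t1", "C": "t2", "D": "t2",
             "E": "t3", "F": "t3", "G": "t4", "H": "t4"}
        )
        rep = taxon_support(tree, tax, "genus")
        signed = {r["taxon"]: r["signed_support"] for r in rep.rows}
        assert signed["t1"] == 100 and signed["t2"] == 100
        assert signed["t3"] == -100 and signed["t4"] == -100
        assert rep.overall == 0.0

    def test_trivial_taxa_excluded_from_sums(self):
        tree = self.support_tree("((A:1,B:1)100:1,(C:1,D:1)100:1);")
        tax = taxonomy_frame({"A": "t1", "B": "t1", "C": "t2", "D": "t3"})
        rep = taxon_support(tree, tax, "genus")
        by_taxon = {r["taxon"]: r for r in rep.rows}
        assert by_taxon["t2"]["status"] == TRIVIAL
        assert rep.overall == 1.0

    def test_unassigned_leaves_excluded(self):
        tree = self.support_tree("((A:1,B:1)100:1,(C:1,D:1)100:1);")
        tax = taxonomy_frame({"A": "t1", "B": "t1", "C": "", "D": ""})
        rep = taxon_support(tree, tax, "genus")
        assert [r["taxon"] for r in rep.rows] == ["t1"]

    def test_root_spanning_taxon_scores_100(self):
        tree = self.support_tree("((A:1,B:1)70:1,(C:1,D:1)70:1);")
        tax = taxonomy_frame({x: "all" for x in "ABCD"})
        rep = taxon_support(tree, tax, "genus")
        assert rep.rows[0]["signed_support"] == 100

    def test_missing_rank_column_rejected(self):
        tree = self.support_tree("((A:1,B:1)70:1,(C:1,D:1)70:1);")
        tax = taxonomy_frame({x: "t" for x in "ABCD"})
        with pytest.raises(UsageError):
            taxon_support(tree, tax, "order")

    def test_overall_bounded(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            spec = synthetic.SimulationSpec(n_taxa=8, tree_shape="random", seed=seed)
            tree = synthetic.simulate_tree(spec)
            for nd in tree.preorder_node_iter():
                if not nd.is_leaf() and nd is not tree.seed_node:
                    nd.support = int(rng.integers(0, 101))
            leaves = sorted(nd.taxon.label for nd in tree.leaf_node_iter())
            tax = taxonomy_frame(
                {lab: f"g{rng.integers(0, 3)}" for lab in leaves}
            )
            rep = taxon_support(tree, tax, "genus")
            assert -1.0 <= rep.overall <= 1.0
            for r in rep.rows:
                assert -100 <= r["signed_support"] <= 100
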