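import itertools
import math

import dendropy
import numpy as np
import pytest

from gcpsr.phylo import (
    BootstrapConfig,
    DistanceMatrix,
    bootstrap_support,
    fitch_score,
    leaf_labels,
    nj_tree,
    nontrivial_splits,
    p_distance,
    root_tree,
    supports_by_split,
)
from gcpsr.seqio import LocusAlignment, read_newick


def aln_from(rows, name="loc"):
    return LocusAlignment.from_dict(name, rows)


def random_tree_with_lengths(n, seed, min_len=0.05, max_len=1.0):
    """Random binary unrooted tree topology with positive branch lengths."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for t in taxa:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(t)
        nodes.append(nd)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = rng.uniform(min_len, max_len)
        b.edge.length = rng.uniform(min_len, max_len)
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
        nd.edge.length = rng.uniform(min_len, max_len)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def additive_distances(tree):
    """Path-length distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                m[i, j] = m[j, i] = pdm.distance(taxa[a], taxa[b])
    return DistanceMatrix(labels, m)


class TestPDistance:
    def test_identical_pair_zero_both_corrections(self):
        aln = aln_from({"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGTAT"})
        for corr in ("raw", "JC69"):
            assert p_distance(aln, corr).value("a", "b") == 0.0

    def test_three_in_ten_mismatches(self):
        aln = aln_from({"a": "AAAAAAAAAA", "b": "TTTAAAAAAA", "c": "AAAAAAAAAA"})
        assert p_distance(aln).value("a", "b") == pytest.approx(0.3)
        jc = p_distance(aln, "JC69").value("a", "b")
        assert jc == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
        assert jc == pytest.approx(0.3831, abs=1e-4)

    def test_saturated_pair_named(self):
        aln = aln_from({"a": "AAAA", "b": "TTTT", "c": "AAAA"})
        with pytest.raises(ValueError, match="a vs b"):
            p_distance(aln, "JC69")

    def test_symmetry_and_zero_diagonal(self, random_alignment):
        aln = random_alignment(6, 60, 3)
        d = p_distance(aln)  # validated in DistanceMatrix.__post_init__
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0.0)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # ((a,b),(c,d)): d(a,b)=2, d(c,d)=2, cross distances 6
        ids = ["a", "b", "c", "d"]
        m = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(ids, m))
        splits = set(nontrivial_splits(tree))
        assert splits == {frozenset({"c", "d"})}  # canonical side omits "a"
        # additive: leaf edges 1, internal edge 4
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert all(v == pytest.approx(1.0) for v in lengths.values())
        internal = [
            nd.edge.length
            for nd in tree.preorder_internal_node_iter()
            if nd is not tree.seed_node
        ]
        assert internal == [pytest.approx(4.0)]

    def test_three_taxon_closed_form(self):
        ids = ["a", "b", "c"]
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, m))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]])))

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (8, 2), (10, 3), (12, 4)])
    def test_consistent_on_additive_matrices(self, n, seed):
        true_tree = random_tree_with_lengths(n, seed)
        est = nj_tree(additive_distances(true_tree))
        assert set(nontrivial_splits(est)) == set(nontrivial_splits(true_tree))

    def test_matches_dendropy_nj_topology(self, random_alignment):
        # independent NJ implementation as cross-check on real distances
        aln = random_alignment(7, 200, 9, gap_frac=0.0)
        ours = nj_tree(p_distance(aln))
        csv_rows = ["," + ",".join(aln.ids)]
        d = p_distance(aln)
        for i, a in enumerate(aln.ids):
            csv_rows.append(a + "," + ",".join(str(x) for x in d.matrix[i]))
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO("\n".join(csv_rows)), delimiter=","
        )
        theirs = pdm.nj_tree()
        their_splits = set()
        labels = leaf_labels(ours)
        for nd in theirs.preorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if 2 <= len(clade) <= len(labels) - 2:
                ref = min(labels)
                their_splits.add(
                    frozenset(labels - clade) if ref in clade else clade
                )
        assert set(nontrivial_splits(ours)) == their_splits


class TestBootstrap:
    @pytest.fixture
    def two_cluster_alignment(self):
        rng = np.random.default_rng(42)
        base = rng.choice(list("ACGT"), size=200)
        other = base.copy()
        flip = rng.choice(200, size=60, replace=False)
        subst = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i in flip:
            other[i] = subst[str(other[i])]

        def noisy(seq):
            s = seq.copy()
            idx = rng.choice(200, size=3, replace=False)
            for i in idx:
                s[i] = subst[str(s[i])]
            return "".join(s)

        return aln_from(
            {"a1": noisy(base), "a2": noisy(base),
             "b1": noisy(other), "b2": noisy(other)}
        )

    def test_focal_split_strongly_supported(self, two_cluster_alignment):
        tree = bootstrap_support(
            two_cluster_alignment, BootstrapConfig(seed=1, n_replicates=100)
        )
        sups = supports_by_split(tree)
        focal = frozenset({"b1", "b2"})
        assert focal in sups and sups[focal] >= 95

    def test_supports_in_range_and_deterministic(self, two_cluster_alignment):
        cfg = BootstrapConfig(seed=7, n_replicates=50)
        t1 = bootstrap_support(two_cluster_alignment, cfg)
        t2 = bootstrap_support(two_cluster_alignment, cfg)
        s1, s2 = supports_by_split(t1), supports_by_split(t2)
        assert s1 == s2
        assert all(0 <= v <= 100 for v in s1.values())

    def test_too_few_sequences_rejected(self):
        aln = aln_from({"a": "ACGT", "b": "ACGA", "c": "ACTT"})
        with pytest.raises(ValueError):
            bootstrap_support(aln, BootstrapConfig(seed=0, n_replicates=10))


def fitch_oracle(tree, aln):
    """Exhaustive minimization over internal-node state assignments.

    States {A,C,G,T,-}; a leaf with N may take any state at no cost.
    """
    states = "ACGT-"
    leaf_sets = {}
    for lf in tree.leaf_node_iter():
        c_row = aln.sequence(lf.taxon.label)
        leaf_sets[lf.taxon.label] = [
            states if c == "N" else c for c in c_row
        ]
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    total = 0
    for site in range(aln.length):
        best = math.inf
        for assign in itertools.product(states, repeat=len(internals)):
            lookup = {id(nd): s for nd, s in zip(internals, assign)}
            cost = 0
            for nd in tree.preorder_node_iter():
                if nd.parent_node is None:
                    continue
                ps = lookup[id(nd.parent_node)]
                if nd.is_leaf():
                    cost += ps not in leaf_sets[nd.taxon.label][site]
                else:
                    cost += ps != lookup[id(nd)]
            best = min(best, cost)
        total += best
    return total


class TestFitch:
    def test_invariant_alignment_zero_steps(self):
        tree = read_newick("((a,b),(c,d));")
        aln = aln_from({s: "AAAA" for s in "abcd"})
        assert fitch_score(tree, aln) == 0

    def test_single_site_split_congruence(self):
        aln = aln_from({"a": "A", "b": "A", "c": "T", "d": "T"})
        assert fitch_score(read_newick("((a,b),(c,d));"), aln) == 1
        assert fitch_score(read_newick("((a,c),(b,d));"), aln) == 2

    def test_gap_is_a_fifth_state(self):
        aln = aln_from({"a": "-", "b": "-", "c": "A", "d": "A"})
        assert fitch_score(read_newick("((a,b),(c,d));"), aln) == 1
        # N is missing data, not a state: no step needed
        aln2 = aln_from({"a": "N", "b": "A", "c": "A", "d": "A"})
        assert fitch_score(read_newick("((a,b),(c,d));"), aln2) == 0

    def test_missing_leaf_sequence_rejected(self):
        tree = read_newick("((a,b),(c,d));")
        aln = aln_from({"a": "A", "b": "A", "c": "A"})
        with pytest.raises(ValueError, match="d"):
            fitch_score(tree, aln)

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (5, 2), (6, 3)])
    def test_matches_exhaustive_minimization(
        self, random_alignment, n, seed
    ):
        tree = random_tree_with_lengths(n, seed)
        aln = random_alignment(n, 12, seed + 100, gap_frac=0.15)
        aln = LocusAlignment("loc", [f"t{i}" for i in range(n)], aln.matrix)
        assert fitch_score(tree, aln) == fitch_oracle(tree, aln)


class TestRooting:
    def test_outgroup_rooting(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        rooted = root_tree(tree, "outgroup", {"d"})
        kids = [
            frozenset(lf.taxon.label for lf in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()
        ]
        assert frozenset({"d"}) in kids
        assert frozenset({"a", "b", "c"}) in kids

    def test_midpoint_on_chain(self):
        # path a-b is 5, b-c is 1: longest path a..c = 6, midpoint 3 from a
        tree = read_newick("(a:5,b:0.0,c:1);")
        rooted = root_tree(tree, "midpoint")
        def depth(leaf):
            total, nd = 0.0, leaf
            while nd.parent_node is not None:
                total += nd.edge.length or 0.0
                nd = nd.parent_node
            return total

        depths = {lf.taxon.label: depth(lf) for lf in rooted.leaf_node_iter()}
        assert depths["a"] == pytest.approx(3.0)
        assert depths["c"] == pytest.approx(3.0)

    def test_rooting_preserves_bipartitions_and_supports(self):
        tree = read_newick("((a:1,b:1)80:1,(c:1,d:1)90:1,e:2);")
        before = set(nontrivial_splits(tree))
        sup_before = supports_by_split(tree)
        rooted = root_tree(tree, "outgroup", {"e"})
        assert set(nontrivial_splits(rooted)) >= before
        sup_after = supports_by_split(rooted)
        for split, sup in sup_before.items():
            assert sup_after.get(split) == sup

    def test_missing_outgroup_rejected(self):
        tree = read_newick("((a,b),(c,d),e);")
        with pytest.raises(ValueError, match="absent"):
            root_tree(tree, "outgroup", {"zz"})
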