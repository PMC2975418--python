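"""Tree structure, Newick I/O, enumeration, comparison, pruning."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

import longbranch as lb
from longbranch.trees import TaxonSet, TreeError, n_unrooted_topologies


def dendropy_rf(nwk_a: str, nwk_b: str) -> int:
    """Independent unrooted RF distance via dendropy."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=nwk_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=nwk_b, schema="newick", taxon_namespace=tns)
    for t in (ta, tb):
        t.is_rooted = False
        t.update_bipartitions()
    return treecompare.symmetric_difference(ta, tb)


class TestParseNewick:
    def test_quartet_structure(self):
        t = lb.parse_newick("(A:0.1,B:0.1,(C:0.1,D:0.1):0.1);")
        assert t.n_leaves == 4
        assert len(t.edges()) == 5
        assert t.has_branch_lengths
        assert t.tree_length() == pytest.approx(0.5)

    def test_two_leaf_tree_lengths_absent(self):
        t = lb.parse_newick("(A,B);")
        assert t.n_leaves == 2
        assert not t.has_branch_lengths

    def test_three_cherry_tree(self):
        t = lb.parse_newick("((A,B),(C,D),(E,F));")
        assert t.n_leaves == 6
        # three cherries = three splits of size 2
        assert sum(1 for s in t.bipartitions() if len(s) in (2, 4)) == 3

    def test_rooted_input_collapsed_to_unrooted(self):
        rooted = lb.parse_newick("((A:0.1,B:0.2):0.05,(C:0.1,D:0.1):0.05);")
        unrooted = lb.parse_newick("(A:0.1,B:0.2,(C:0.1,D:0.1):0.1);")
        assert rooted.topologies_equal(unrooted)
        assert rooted.tree_length() == pytest.approx(unrooted.tree_length())

    @pytest.mark.parametrize(
        "bad",
        ["(A,B", "(A,B));", "(A,(B,C),D,E);", "((A,B),(A,C),(D,E));"],
        ids=["unbalanced", "trailing", "polytomy", "duplicate-leaf"],
    )
    def test_rejects_malformed_input(self, bad):
        with pytest.raises(TreeError):
            lb.parse_newick(bad)

    def test_roundtrip_topology_and_lengths(self, six_taxa):
        rng = np.random.default_rng(0)
        for tree in lb.enumerate_unrooted_topologies(six_taxa[:5]):
            for (u, v) in tree.edges():
                tree.set_edge_length(u, v, float(rng.uniform(0.01, 2.0)))
            back = lb.parse_newick(tree.newick())
            assert back.topologies_equal(tree)
            assert sorted(back.branch_lengths()) == pytest.approx(
                sorted(tree.branch_lengths()), abs=1e-9
            )


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105), (7, 945)])
    def test_counts_match_double_factorial(self, n, count):
        taxa = [f"T{i}" for i in range(n)]
        assert n_unrooted_topologies(n) == count
        assert sum(1 for _ in lb.enumerate_unrooted_topologies(taxa)) == count

    def test_refuses_out_of_bounds(self):
        with pytest.raises(TreeError):
            list(lb.enumerate_unrooted_topologies(["A", "B"]))
        with pytest.raises(TreeError, match="2027025"):
            list(lb.enumerate_unrooted_topologies([f"T{i}" for i in range(10)]))

    def test_all_105_pairwise_distinct(self, six_taxa):
        keys = {t.topology_key() for t in lb.enumerate_unrooted_topologies(six_taxa)}
        assert len(keys) == 105

    def test_deterministic_order(self, six_taxa):
        first = [t.newick() for t in lb.enumerate_unrooted_topologies(six_taxa)]
        second = [t.newick() for t in lb.enumerate_unrooted_topologies(six_taxa)]
        assert first == second


class TestComparison:
    def test_rerooting_is_identity(self):
        t = lb.parse_newick("((A,B),(C,D),(E,F));")
        for name in t.taxa:
            assert lb.topologies_equal(t, t.rerooted_near(name))

    def test_known_unequal_pair(self):
        a = lb.parse_newick("((A,B),(C,D),(E,F));")
        b = lb.parse_newick("((A,C),(B,D),(E,F));")
        assert not lb.topologies_equal(a, b)
        assert lb.rf_distance(a, b) > 0

    def test_symmetry_and_max(self, six_taxa):
        topos = list(lb.enumerate_unrooted_topologies(six_taxa))
        rng = np.random.default_rng(1)
        pairs = rng.integers(0, len(topos), size=(30, 2))
        for i, j in pairs:
            d = lb.rf_distance(topos[i], topos[j])
            assert d == lb.rf_distance(topos[j], topos[i])
            assert 0 <= d <= 2 * (6 - 3)
            assert (d == 0) == (i == j) or topos[i].topology_key() == topos[j].topology_key()

    def test_agrees_with_dendropy(self, six_taxa):
        topos = list(lb.enumerate_unrooted_topologies(six_taxa))
        rng = np.random.default_rng(2)
        for i, j in rng.integers(0, len(topos), size=(25, 2)):
            mine = lb.rf_distance(topos[i], topos[j])
            theirs = dendropy_rf(topos[i].newick(), topos[j].newick())
            assert mine == theirs

    def test_differing_leaf_sets_error(self):
        a = lb.parse_newick("((A,B),(C,D),(E,F));")
        b = lb.parse_newick("((A,B),(C,D),(E,G));")
        with pytest.raises(TreeError, match="G"):
            lb.rf_distance(a, b)


class TestPrune:
    def test_prune_shape(self):
        t = lb.parse_newick("((A,B),(C,D),(E,F));")
        p = t.prune_taxon("E")
        assert p.n_leaves == 5
        assert "E" not in p.taxa
        assert p.topologies_equal(lb.parse_newick("((A,B),(C,D),F);"))

    def test_length_additivity(self):
        t = lb.parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,(E:0.3,F:0.2):0.1);")
        p = t.prune_taxon("E")
        # F's 0.2 pendant merges with the cherry's 0.1 stem
        assert p.pendant_length("F") == pytest.approx(0.3)
        assert p.tree_length() == pytest.approx(t.tree_length() - 0.3 - 0.1 + 0.3 - 0.2)

    def test_commutes_with_rerooting(self, six_taxa):
        for tree in lb.enumerate_unrooted_topologies(six_taxa):
            for name in six_taxa:
                a = tree.prune_taxon(name)
                b = tree.rerooted_near(name if name != "T1" else "T2").prune_taxon(name)
                assert a.topologies_equal(b)

    def test_errors(self):
        t = lb.parse_newick("((A,B),(C,D),(E,F));")
        with pytest.raises(TreeError):
            t.prune_taxon("Z")
        small = lb.parse_newick("(A,B,(C,D));")
        with pytest.raises(TreeError):
            small.prune_taxon("A").prune_taxon("B")


class TestTaxonSet:
    def test_rejects_duplicates_and_empty(self):
        with pytest.raises(TreeError):
            TaxonSet(["A", "A"])
        with pytest.raises(TreeError):
            TaxonSet(["A", ""])

    def test_preserves_order(self):
        ts = TaxonSet(["Z", "A", "M"])
        assert list(ts) == ["Z", "A", "M"]
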