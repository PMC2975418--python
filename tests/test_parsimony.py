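"""Fitch scoring and the exhaustive / TBR parsimony searches."""

import numpy as np
import pytest

import longbranch as lb
from longbranch.parsimony import tbr_neighbors
from oracles import sankoff_score


def column_alignment(assignments: dict[str, str]) -> lb.Alignment:
    return lb.Alignment(assignments)


def random_alignment(taxa, n_cols, seed, gap_rate=0.05):
    rng = np.random.default_rng(seed)
    chars = np.array(list("ACGT-"))
    probs = [(1 - gap_rate) / 4] * 4 + [gap_rate]
    return lb.Alignment(
        {name: "".join(rng.choice(chars, size=n_cols, p=probs)) for name in taxa}
    )


class TestFitchScore:
    def test_constant_column_is_free(self):
        aln = column_alignment({"A": "G", "B": "G", "C": "G", "D": "G"})
        tree = lb.parse_newick("((A,B),(C,D));")
        assert lb.fitch_score(tree, aln) == 0

    @pytest.mark.parametrize(
        "newick,expected",
        [("((A,B),(C,D));", 1), ("((A,C),(B,D));", 2)],
        ids=["matching-split", "conflicting-split"],
    )
    def test_aacc_column(self, newick, expected):
        aln = column_alignment({"A": "A", "B": "A", "C": "C", "D": "C"})
        tree = lb.parse_newick(newick)
        assert lb.fitch_score(tree, aln) == expected
        assert sankoff_score(tree, aln) == expected

    def test_all_different_column_needs_three_steps(self):
        aln = column_alignment({"A": "A", "B": "C", "C": "G", "D": "T"})
        for tree in lb.enumerate_unrooted_topologies(["A", "B", "C", "D"]):
            assert lb.fitch_score(tree, aln) == 3

    def test_gap_is_missing_data(self):
        aln = column_alignment({"A": "A", "B": "-", "C": "C", "D": "C"})
        tree = lb.parse_newick("((A,B),(C,D));")
        assert lb.fitch_score(tree, aln) == 1  # gap never adds steps

    def test_invariant_under_rerooting(self, six_taxa):
        aln = random_alignment(six_taxa, 60, seed=0)
        for tree in list(lb.enumerate_unrooted_topologies(six_taxa))[:10]:
            base = lb.fitch_score(tree, aln)
            for name in six_taxa:
                assert lb.fitch_score(tree.rerooted_near(name), aln) == base

    def test_additive_over_duplicated_columns(self, six_taxa):
        aln = random_alignment(six_taxa, 40, seed=1)
        doubled = lb.Alignment({n: s + s for n, s in aln.items()})
        tree = next(lb.enumerate_unrooted_topologies(six_taxa))
        assert lb.fitch_score(tree, doubled) == 2 * lb.fitch_score(tree, aln)

    def test_matches_sankoff_on_random_trees(self):
        rng = np.random.default_rng(7)
        for rep in range(4):
            n = int(rng.integers(5, 9))
            taxa = [f"T{i}" for i in range(n)]
            topos = list(lb.enumerate_unrooted_topologies(taxa[:6] if n > 6 else taxa))
            tree = topos[int(rng.integers(len(topos)))]
            aln = random_alignment(tree.taxa, 50, seed=100 + rep)
            assert lb.fitch_score(tree, aln) == sankoff_score(tree, aln)

    def test_missing_sequence_errors(self):
        aln = column_alignment({"A": "A", "B": "C", "C": "G"})
        tree = lb.parse_newick("((A,B),(C,D));")
        with pytest.raises(lb.TreeError):
            lb.fitch_score(tree, aln)


class TestExhaustiveSearch:
    def test_evaluates_all_105(self, six_taxa, zone_model):
        tree = lb.make_zone_tree(lb.ZoneSpec("farris_like", 0.5, 0.5))
        aln = lb.simulate_alignment(tree, zone_model, 300, seed=2)
        res = lb.exhaustive_mp_search(aln)
        assert res.n_evaluated == 105

    def test_no_signal_ties_everything(self, six_taxa):
        aln = lb.Alignment({name: "ACGTAC" for name in six_taxa})
        res = lb.exhaustive_mp_search(aln)
        assert res.best_score == 0
        assert len(res.best_trees) == 105

    def test_recovers_generating_topology(self, zone_model):
        truth = lb.make_zone_tree(lb.ZoneSpec("farris_like", 0.5, 0.5))
        aln = lb.simulate_alignment(truth, zone_model, 2000, seed=3)
        res = lb.exhaustive_mp_search(aln)
        assert any(t.topologies_equal(truth) for t in res.best_trees)

    def test_taxon_bounds(self):
        aln = column_alignment({"A": "A", "B": "C", "C": "G"})
        with pytest.raises(lb.TreeError):
            lb.exhaustive_mp_search(aln)


class TestTBRSearch:
    def test_neighbors_are_valid_and_distinct(self, six_taxa):
        tree = next(lb.enumerate_unrooted_topologies(six_taxa))
        neighbors = tbr_neighbors(tree)
        keys = {t.topology_key() for t in neighbors}
        assert len(keys) == len(neighbors)
        assert tree.topology_key() not in keys
        for t in neighbors:
            assert t.taxa == tree.taxa
            assert all(t.degree(v) == 3 for v in t._adj if not t.is_leaf(v))

    def test_deterministic_given_seed(self, zone_model):
        truth = lb.make_zone_tree(lb.ZoneSpec("felsenstein_like", 0.4, 1.2))
        aln = lb.simulate_alignment(truth, zone_model, 500, seed=4)
        a = lb.tbr_search(aln, n_starts=3, seed=5)
        b = lb.tbr_search(aln, n_starts=3, seed=5)
        assert a.best_score == b.best_score
        assert [t.newick() for t in a.best_trees] == [t.newick() for t in b.best_trees]

    def test_matches_exhaustive_on_replicates(self, zone_model):
        """Heuristic finds the global optimum in >= 95% of 100 replicates
        (and never beats it)."""
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(100):
            alpha, beta = rng.uniform(0.2, 1.8, size=2)
            kind = "felsenstein_like" if rep % 2 else "farris_like"
            truth = lb.make_zone_tree(lb.ZoneSpec(kind, alpha, beta))
            aln = lb.simulate_alignment(truth, zone_model, 500, seed=1000 + rep)
            exact = lb.exhaustive_mp_search(aln)
            heur = lb.tbr_search(aln, n_starts=5, seed=rep)
            assert heur.best_score >= exact.best_score
            hits += heur.best_score == exact.best_score
        assert hits >= 95

    def test_local_optimum_stays_put_with_strong_signal(self, zone_model):
        truth = lb.make_zone_tree(lb.ZoneSpec("farris_like", 0.1, 0.1))
        aln = lb.simulate_alignment(truth, zone_model, 2000, seed=8)
        res = lb.tbr_search(aln, n_starts=1, seed=8)
        exact = lb.exhaustive_mp_search(aln)
        assert res.best_score == exact.best_score
        assert res.best_trees[0].topologies_equal(truth)
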