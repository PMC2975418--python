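"""Long Branch Shortening: ancestor construction, hybridization, p-scan."""

import math

import numpy as np
import pytest
from scipy import stats

import longbranch as lb
from longbranch.lbs import _attachment_signature, _clades_with


@pytest.fixture(scope="module")
def study_model():
    return lb.GTRModel.zone_study()


class TestCladeAncestor:
    def tree(self):
        return lb.parse_newick("((T1,T2),(T3,T4),(T5,T6));")

    def test_identical_clade_gives_that_sequence(self):
        aln = lb.Alignment(
            {"T1": "AAAA", "T2": "CCCC", "T3": "ACGT", "T4": "ACGT",
             "T5": "ACGT", "T6": "ACGT"}
        )
        anc = lb.construct_clade_ancestor(aln, self.tree(), "T1", "T2")
        assert anc == "ACGT"

    def test_fitch_tie_breaks_by_frequency_then_order(self):
        # clade states {A,A,C,C}: root set {A,C}, frequencies tied -> 'A'
        aln = lb.Alignment(
            {"T1": "G", "T2": "G", "T3": "A", "T4": "A", "T5": "C", "T6": "C"}
        )
        anc = lb.construct_clade_ancestor(aln, self.tree(), "T1", "T2")
        assert anc == "A"
        # frequency beats the fixed order when counts differ
        aln2 = lb.Alignment(
            {"T1": "G", "T2": "G", "T3": "C", "T4": "C", "T5": "C", "T6": "A"}
        )
        anc2 = lb.construct_clade_ancestor(aln2, self.tree(), "T1", "T2")
        assert anc2 == "C"

    def test_excluded_taxa_never_leak(self):
        aln = lb.Alignment(
            {"T1": "T", "T2": "T", "T3": "G", "T4": "G", "T5": "G", "T6": "G"}
        )
        for method in ("fitch", "consensus"):
            anc = lb.construct_clade_ancestor(aln, self.tree(), "T1", "T2", method)
            assert anc == "G"

    def test_all_gap_column_stays_gap(self):
        aln = lb.Alignment(
            {"T1": "A", "T2": "A", "T3": "-", "T4": "-", "T5": "-", "T6": "-"}
        )
        anc = lb.construct_clade_ancestor(aln, self.tree(), "T1", "T2")
        assert anc == "-"

    def test_too_few_clade_members(self):
        aln = lb.Alignment({"T1": "A", "T2": "C", "T3": "G"})
        tree = lb.parse_newick("(T1,T2,T3);")
        with pytest.raises(lb.TreeError):
            lb.construct_clade_ancestor(aln, tree, "T1", "T2")


class TestHybridize:
    def test_limits_are_exact(self):
        target, ancestor = "ACGTACGT", "TGCATGCA"
        assert lb.hybridize(target, ancestor, 0.0, seed=1) == target
        assert lb.hybridize(target, ancestor, 1.0, seed=1) == ancestor

    def test_replacement_count_is_binomial(self):
        rng_seed = 42
        n, p = 2000, 0.3
        target = "A" * n
        ancestor = "C" * n
        out = lb.hybridize(target, ancestor, p, seed=rng_seed)
        k = out.count("C")
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, p)
        assert lo <= k <= hi
        assert lb.hybridize(target, ancestor, p, seed=rng_seed) == out

    def test_distance_to_ancestor_shrinks_with_p(self):
        rng = np.random.default_rng(0)
        target = "".join(rng.choice(list("ACGT"), size=1000))
        ancestor = "".join(rng.choice(list("ACGT"), size=1000))
        dist = [
            sum(a != b for a, b in zip(lb.hybridize(target, ancestor, p, seed=7), ancestor))
            for p in (0.0, 0.3, 0.6, 0.9, 1.0)
        ]
        assert dist == sorted(dist, reverse=True)
        assert dist[-1] == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lb.hybridize("ACGT", "ACG", 0.5, seed=0)


class TestRunLBS:
    def test_p_zero_never_moves(self, study_model):
        truth = lb.make_zone_tree(lb.ZoneSpec("felsenstein_like", 0.1, 1.8))
        aln = lb.simulate_alignment(truth, study_model, 600, seed=1)
        cfg = lb.LBSConfig(outgroup="T1", qtaxa="T2", sampling_frequencies=(0.0,))
        res = lb.run_lbs(aln, cfg, seed=1)
        assert res.per_p_move_rates == {0.0: 0.0}
        assert math.isinf(res.p_star)
        assert res.verdict == "NOT_LBA"

    def test_p_one_always_moves(self, study_model):
        """At p=1 the hybridized taxon IS the clade ancestor, so whenever
        the baseline tree shows the attraction artifact (qtaxa grouped
        with the outgroup), every run relocates it into the clade."""
        truth = lb.make_zone_tree(lb.ZoneSpec("felsenstein_like", 0.3, 1.5))
        artifacts = 0
        for seed in range(10):
            aln = lb.simulate_alignment(truth, study_model, 600, seed=100 + seed)
            baseline = lb.tbr_search(aln, n_starts=5, seed=seed * 104729).best_trees[0]
            if _clades_with(baseline, "T2", "T1"):
                continue  # premise violated: qtaxa not stuck to the outgroup
            artifacts += 1
            cfg = lb.LBSConfig(outgroup="T1", qtaxa="T2", sampling_frequencies=(1.0,))
            res = lb.run_lbs(aln, cfg, seed=seed)
            assert res.per_p_move_rates[1.0] == 1.0
        assert artifacts >= 5  # the zone produces plenty of artifact baselines

    def test_deep_zone_detected_at_high_sampling_frequency(self, study_model):
        """In the deep LBA zone the attracted branch stays put without
        hybridization but relocates into the clade once a large fraction
        of its characters are resampled from the clade ancestor."""
        moved_high = 0
        for seed in range(10):
            truth = lb.make_zone_tree(lb.ZoneSpec("felsenstein_like", 0.1, 1.8))
            aln = lb.simulate_alignment(truth, study_model, 600, seed=200 + seed)
            cfg = lb.LBSConfig(outgroup="T1", qtaxa="T2")
            res = lb.run_lbs(aln, cfg, seed=seed)
            assert res.per_p_move_rates[0.0] == 0.0
            assert res.p_star <= 0.9  # a scan always ends in detection here
            moved_high += res.p_star <= 0.8
        assert moved_high >= 8

    def test_move_rate_roughly_monotone_in_p(self, study_model):
        """Mean move rate is non-decreasing in p up to sampling noise
        (at most one inversion, bounded by 3 binomial SEs)."""
        truth = lb.make_zone_tree(lb.ZoneSpec("felsenstein_like", 0.1, 1.4))
        aln = lb.simulate_alignment(truth, study_model, 600, seed=9)
        baseline = lb.tbr_search(aln, seed=0).best_trees[0]
        anc = lb.construct_clade_ancestor(aln, baseline, "T1", "T2")
        sig0 = _attachment_signature(baseline, "T2")
        runs = 20
        rates = []
        for ip, p in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            moves = 0
            for r in range(runs):
                hyb = lb.hybridize(aln["T2"], anc, p, seed=ip * 1000 + r)
                if hyb == aln["T2"]:
                    continue
                t = lb.tbr_search(aln.replace("T2", hyb), seed=r).best_trees[0]
                moves += (
                    _attachment_signature(t, "T2") != sig0
                    and _clades_with(t, "T2", "T1")
                )
            rates.append(moves / runs)
        se = 3 * math.sqrt(0.25 / runs)
        inversions = sum(
            1 for a, b in zip(rates, rates[1:]) if b < a - 1e-12
        )
        assert inversions <= 1
        for a, b in zip(rates, rates[1:]):
            assert b >= a - se

    def test_scan_stops_early_at_majority(self, study_model):
        truth = lb.make_zone_tree(lb.ZoneSpec("felsenstein_like", 0.1, 1.8))
        aln = lb.simulate_alignment(truth, study_model, 600, seed=3)
        cfg = lb.LBSConfig(outgroup="T1", qtaxa="T2")
        res = lb.run_lbs(aln, cfg, seed=3)
        if not math.isinf(res.p_star):
            assert max(res.per_p_move_rates) == res.p_star
            assert res.per_p_move_rates[res.p_star] >= 0.5

    def test_config_validation(self):
        with pytest.raises(ValueError):
            lb.LBSConfig(outgroup="T1", qtaxa="T2", sampling_frequencies=(0.5, 0.1))
        with pytest.raises(ValueError):
            lb.LBSConfig(outgroup="T1", qtaxa="T2", sampling_frequencies=(1.5,))
        with pytest.raises(ValueError):
            lb.LBSConfig(outgroup="T1", qtaxa="T1")
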