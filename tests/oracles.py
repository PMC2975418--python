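"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: parsimony
is re-scored by a per-column unit-cost Sankoff dynamic program, and
likelihood by explicit enumeration of all internal-state assignments.
Both are slow and only used at tiny scale.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from longbranch.gtr import transition_matrix

_INF = 10**6
_IDX = {c: i for i, c in enumerate("ACGT")}


def sankoff_score(tree, aln) -> int:
    """Unit-cost Sankoff DP summed over all columns (gap = missing)."""
    order, children, parent = tree.rooted_structure()
    total = 0
    for col in range(aln.length):
        cost: dict[int, list[int]] = {}
        for v in order:
            if not children[v]:
                ch = aln[tree.leaf_name(v)][col]
                if ch == "-":
                    cost[v] = [0, 0, 0, 0]
                else:
                    cost[v] = [0 if s == _IDX[ch] else _INF for s in range(4)]
            else:
                acc = [0, 0, 0, 0]
                for k in children[v]:
                    acc = [
                        acc[s] + min(cost[k][t] + (s != t) for t in range(4))
                        for s in range(4)
                    ]
                if tree.is_leaf(v):  # rooted at a leaf: its state constrains
                    ch = aln[tree.leaf_name(v)][col]
                    if ch != "-":
                        acc = [
                            acc[s] if s == _IDX[ch] else _INF for s in range(4)
                        ]
                cost[v] = acc
        total += min(cost[order[-1]])
    return total


def brute_force_loglik(tree, model, aln) -> float:
    """Likelihood by summing over every internal-state assignment."""
    root = tree._root
    order, children, parent = tree.rooted_structure(root)
    internal = [v for v in order if children[v]]
    pmats = {
        v: transition_matrix(model, tree.edge_length(parent[v], v))
        for v in order
        if parent[v] is not None
    }
    pi = np.asarray(model.pi)
    total = 0.0
    for col in range(aln.length):
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            amap = dict(zip(internal, assign))
            prob = pi[amap[root]]
            for v in order:
                p = parent[v]
                if p is None:
                    continue
                pm = pmats[v]
                if tree.is_leaf(v):
                    ch = aln[tree.leaf_name(v)][col]
                    if ch == "-":
                        prob *= pm[amap[p]].sum()
                    else:
                        prob *= pm[amap[p], _IDX[ch]]
                else:
                    prob *= pm[amap[p], amap[v]]
            site += prob
        total += math.log(site)
    return total


def jc_transition_prob_same(t: float) -> float:
    """Jukes-Cantor P(no net change) = 1/4 + 3/4 exp(-4t/3)."""
    return 0.25 + 0.75 * math.exp(-4.0 * t / 3.0)


def jc_expected_p_distance(d: float) -> float:
    """Expected proportion of differing sites at JC distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_mle_distance(p_hat: float) -> float:
    """Closed-form JC distance estimate from an observed p-distance."""
    return -0.75 * math.log(1.0 - 4.0 * p_hat / 3.0)
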