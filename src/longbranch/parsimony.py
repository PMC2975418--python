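"""Maximum parsimony: Fitch scoring, exhaustive search, TBR heuristic.

Scoring uses the Fitch set algorithm on bitmask-encoded states (A=1,
C=2, G=4, T=8); gaps are missing data, i.e. the full set 15, never a
fifth state.  Identical alignment columns are collapsed to weighted
patterns before scoring, which is provably score-neutral and makes the
exhaustive 105-topology sweep cheap.  Scoring roots the tree at an
arbitrary leaf, which leaves the parsimony score unchanged.

The heuristic search follows the usual recipe: random-order stepwise
addition, then hill climbing over full tree-bisection-reconnection
(TBR) neighborhoods, accepting strict improvements until a local
optimum; multiple starts with a seeded RNG keep results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .trees import TaxonSet, Tree, TreeError, enumerate_unrooted_topologies

# bitmask per code 0..4 (A,C,G,T,-); gap = all four states
_BITS = np.array([1, 2, 4, 8, 15], dtype=np.uint8)

__all__ = ["SearchResult", "fitch_score", "exhaustive_mp_search", "tbr_search", "tbr_neighbors"]


@dataclass(frozen=True)
class SearchResult:
    """Outcome of a parsimony search: score, all co-optimal trees found,
    and how many topologies were evaluated."""

    best_score: int
    best_trees: tuple[Tree, ...]
    n_evaluated: int

    def __post_init__(self):
        if not self.best_trees:
            raise ValueError("best_trees must be non-empty")


def _pattern_data(aln: Alignment, taxa) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Compress columns to unique weighted patterns of Fitch bitmasks."""
    codes = aln.codes(taxa)
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    masks = _BITS[patterns]
    return {name: masks[i] for i, name in enumerate(taxa)}, weights.astype(np.int64)


def _score_tree(tree: Tree, masks: dict[str, np.ndarray], weights: np.ndarray) -> int:
    root_leaf = tree.leaf_node(min(tree._name_to_leaf))
    order, children, _ = tree.rooted_structure(root_leaf)
    sets: dict[int, np.ndarray] = {}
    changes = np.zeros(len(weights), dtype=np.int64)
    for v in order:
        kids = children[v]
        if not kids:
            sets[v] = masks[tree.leaf_name(v)]
        elif v == root_leaf:
            inter = sets[kids[0]] & masks[tree.leaf_name(v)]
            changes += inter == 0
        else:
            a, b = sets[kids[0]], sets[kids[1]]
            inter = a & b
            changes += inter == 0
            sets[v] = np.where(inter != 0, inter, a | b)
    return int(np.dot(changes, weights))


def fitch_score(tree: Tree, aln: Alignment) -> int:
    """Minimum number of unordered state changes over all columns."""
    missing = [n for n in tree.taxa if n not in aln]
    if missing:
        raise TreeError(f"tree leaves without sequences: {missing}")
    masks, weights = _pattern_data(aln, tree.taxa)
    return _score_tree(tree, masks, weights)


def exhaustive_mp_search(aln: Alignment, taxa=None) -> SearchResult:
    """Score every unrooted binary topology; return all co-optimal trees."""
    ts = TaxonSet(taxa if taxa is not None else aln.taxa)
    if not 4 <= len(ts) <= 9:
        raise TreeError(f"exhaustive search supports 4..9 taxa, got {len(ts)}")
    masks, weights = _pattern_data(aln, tuple(ts))
    best_score = None
    best: list[Tree] = []
    n_eval = 0
    for tree in enumerate_unrooted_topologies(ts):
        n_eval += 1
        score = _score_tree(tree, masks, weights)
        if best_score is None or score < best_score:
            best_score = score
            best = [tree]
        elif score == best_score:
            best.append(tree)
    return SearchResult(best_score, tuple(best), n_eval)


# -- TBR -----------------------------------------------------------------------


def _attachment_options(tree: Tree, nodes: set[int]):
    if len(nodes) == 1:
        return [("node", next(iter(nodes)))]
    opts = []
    for v in sorted(nodes):
        for w in tree.neighbors(v):
            if w > v:
                opts.append(("edge", (v, w)))
    return opts


def tbr_neighbors(tree: Tree) -> list[Tree]:
    """All distinct topologies one TBR move away (the original excluded).

    Each edge is bisected; the dangling degree-2 endpoints are
    suppressed and the two fragments reconnected across every pair of
    attachment points.
    """
    seen = {tree.topology_key()}
    out: list[Tree] = []
    for (u, v) in tree.edges():
        base = tree.copy(strip_lengths=True)
        base._remove_edge(u, v)
        reps = []
        for x in (u, v):
            if not base.is_leaf(x) and base.degree(x) == 2:
                a, _ = base._suppress_degree2(x)
                reps.append(a)
            else:
                reps.append(x)
        comp_a = base._component(reps[0])
        comp_b = base._component(reps[1])
        for opt_a in _attachment_options(base, comp_a):
            for opt_b in _attachment_options(base, comp_b):
                t2 = base.copy()
                ends = []
                for kind, val in (opt_a, opt_b):
                    ends.append(val if kind == "node" else t2._subdivide(*val))
                t2._add_edge(ends[0], ends[1])
                t2._fix_root()
                key = t2.topology_key()
                if key not in seen:
                    seen.add(key)
                    out.append(t2)
    return out


def _stepwise_addition(names: list[str], masks, weights) -> Tree:
    tree = Tree()
    center = tree._new_node()
    for name in names[:3]:
        tree._add_edge(center, tree._new_node(name))
    tree._root = center
    for name in names[3:]:
        best = None
        best_score = None
        for (u, v) in tree.edges():
            t2 = tree.copy()
            w = t2._subdivide(u, v)
            t2._add_edge(w, t2._new_node(name))
            s = _score_tree(t2, masks, weights)
            if best_score is None or s < best_score:
                best_score, best = s, t2
        tree = best
    return tree


def tbr_search(aln: Alignment, n_starts: int = 5, seed: int = 0) -> SearchResult:
    """Heuristic parsimony search; deterministic for a given seed.

    Each start builds a stepwise-addition tree from a random taxon
    order, then repeatedly moves to the best strictly-improving TBR
    neighbor.  Returns the co-optimal trees found across all starts.
    """
    taxa = aln.taxa
    if len(taxa) < 4:
        raise TreeError(f"search requires at least 4 taxa, got {len(taxa)}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    masks, weights = _pattern_data(aln, taxa)
    rng = np.random.default_rng(seed)

    best_score = None
    best: list[Tree] = []
    best_keys: set = set()
    n_eval = 0
    for _ in range(n_starts):
        perm = rng.permutation(len(taxa))
        names = [taxa[i] for i in perm]
        tree = _stepwise_addition(names, masks, weights)
        score = _score_tree(tree, masks, weights)
        n_eval += 1
        local = [tree]
        while True:
            neighbors = tbr_neighbors(tree)
            scored = [(_score_tree(t, masks, weights), t) for t in neighbors]
            n_eval += len(scored)
            improving = [(s, t) for s, t in scored if s < score]
            if improving:
                score, tree = min(improving, key=lambda st: st[0])
                local = [tree]
            else:
                local = [tree] + [t for s, t in scored if s == score]
                break
        if best_score is None or score < best_score:
            best_score = score
            best, best_keys = [], set()
        if score == best_score:
            for t in local:
                key = t.topology_key()
                if key not in best_keys:
                    best_keys.add(key)
                    best.append(t)
    return SearchResult(best_score, tuple(best), n_eval)
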