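"""Sequence simulation on Felsenstein-like and Farris-like zone trees.

The six-taxon zone tree is the symmetric "star shape": three cherries
joined to a central node by internal edges of length alpha; all pendant
edges have length alpha except two beta leaves, which sit in different
cherries (Felsenstein-like, long branches are non-sisters) or in the
same cherry (Farris-like, long branches are sisters).  The four-taxon
variant is the classic quartet.  A 6-leaf zone tree therefore has
exactly 7 alpha edges (4 pendant + 3 internal) and 2 beta edges.

Simulation draws the root sequence from the stationary distribution,
evolves each edge site-by-site under P(t) = exp(Qt), and optionally
applies an indel process: Poisson(lambda * t * L) events per edge at
rate lambda relative to the substitution rate, split evenly between
insertions and deletions, with geometric lengths.  Inserted characters
are drawn from the stationary distribution (the correct marginal for a
reversible process).  Gaps appear as '-' columns in the output
alignment; columns deleted in every surviving lineage are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .gtr import GTRModel, transition_matrix
from .trees import Tree, TreeError

FELSENSTEIN = "felsenstein_like"
FARRIS = "farris_like"

__all__ = ["ZoneSpec", "make_zone_tree", "simulate_alignment", "FELSENSTEIN", "FARRIS"]


@dataclass(frozen=True)
class ZoneSpec:
    """Parameters of a zone topology: kind, branch lengths, taxon count."""

    kind: str
    alpha: float
    beta: float
    n_taxa: int = 6

    def __post_init__(self):
        if self.kind not in (FELSENSTEIN, FARRIS):
            raise ValueError(f"kind must be {FELSENSTEIN!r} or {FARRIS!r}, got {self.kind!r}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.n_taxa not in (4, 6):
            raise ValueError(f"n_taxa must be 4 or 6, got {self.n_taxa}")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(f"T{i + 1}" for i in range(self.n_taxa))

    @property
    def beta_taxa(self) -> tuple[str, str]:
        """The two long-branch leaves; sisters only in the Farris-like tree."""
        return ("T1", "T2")


def make_zone_tree(spec: ZoneSpec) -> Tree:
    """Build the zone tree for the spec, rooted at the central node.

    The long leaves are always T1 and T2; the two kinds differ in
    topology (same branch-length multiset): Farris-like puts them in
    one cherry, Felsenstein-like in different cherries.
    """
    a, b = spec.alpha, spec.beta
    long_leaves = set(spec.beta_taxa)

    def pendant(name):
        return b if name in long_leaves else a

    if spec.n_taxa == 6:
        if spec.kind == FARRIS:
            cherries = (("T1", "T2"), ("T3", "T4"), ("T5", "T6"))
        else:
            cherries = (("T1", "T3"), ("T2", "T4"), ("T5", "T6"))
    else:
        if spec.kind == FARRIS:
            cherries = (("T1", "T2"), ("T3", "T4"))
        else:
            cherries = (("T1", "T3"), ("T2", "T4"))

    t = Tree()
    if spec.n_taxa == 6:
        center = t._new_node()
        for pair in cherries:
            cherry = t._new_node()
            t._add_edge(center, cherry, a)
            for name in pair:
                t._add_edge(cherry, t._new_node(name), pendant(name))
        t._root = center
    else:
        left = t._new_node()
        right = t._new_node()
        t._add_edge(left, right, a)
        for node, pair in zip((left, right), cherries):
            for name in pair:
                t._add_edge(node, t._new_node(name), pendant(name))
        t._root = left
    return t


def _evolve_states(states: np.ndarray, p: np.ndarray, rng) -> np.ndarray:
    """Sample child states from transition matrix rows, vectorized."""
    cum = np.cumsum(p, axis=1)
    u = rng.random(states.shape[0])
    child = (u[:, None] > cum[states]).sum(axis=1)
    return np.minimum(child, 3).astype(np.int64)


def simulate_alignment(tree: Tree, model: GTRModel, length: int, seed: int) -> Alignment:
    """Simulate an alignment of ``length`` root sites along ``tree``.

    Identical (tree, model, length, seed) inputs give byte-identical
    output.  With ``model.indel_rate == 0`` the alignment has no gaps
    and exactly ``length`` columns.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not tree.has_branch_lengths:
        raise TreeError("simulation requires branch lengths on every edge")
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.pi)
    root = tree._root
    if tree.is_leaf(root) and tree.n_leaves > 1:
        (root,) = tree.neighbors(root)
    order, children, parent = tree.rooted_structure(root)
    preorder = list(reversed(order))

    root_states = rng.choice(4, size=length, p=pi)

    if model.indel_rate == 0:
        states = {root: root_states}
        for v in preorder:
            for c in children[v]:
                p = transition_matrix(model, tree.edge_length(v, c))
                states[c] = _evolve_states(states[v], p, rng)
        seqs = {
            tree.leaf_name(v): "".join("ACGT"[s] for s in states[v])
            for v in states
            if tree.is_leaf(v)
        }
        return Alignment(seqs)

    return _simulate_with_indels(
        tree, model, rng, root, preorder, children, root_states
    )


def _simulate_with_indels(tree, model, rng, root, preorder, children, root_states):
    # Global column order is a doubly linked list over site tokens; each
    # lineage carries the subset of tokens it still possesses.  -1 is a
    # head sentinel, None terminates the list.
    nxt: dict = {-1: 0 if len(root_states) else None}
    prv: dict = {}
    n0 = len(root_states)
    for i in range(n0):
        nxt[i] = i + 1 if i + 1 < n0 else None
        prv[i] = i - 1
    if n0:
        prv[0] = -1
    counter = n0
    geo_p = 1.0 / model.indel_length_mean

    def link_after(anchor: int, new_ids: np.ndarray) -> None:
        tail = nxt[anchor]
        cur = anchor
        for nid in new_ids:
            nxt[cur] = int(nid)
            prv[int(nid)] = cur
            cur = int(nid)
        nxt[cur] = tail
        if tail is not None:
            prv[tail] = cur

    tokens = {root: (np.arange(n0, dtype=np.int64), root_states.copy())}
    pi = np.asarray(model.pi)
    for v in preorder:
        for c in children[v]:
            t_edge = tree.edge_length(v, c)
            ids, chars = tokens[v]
            ids = ids.copy()
            p = transition_matrix(model, t_edge)
            chars = _evolve_states(chars, p, rng)
            n_events = rng.poisson(model.indel_rate * t_edge * len(ids))
            for _ in range(n_events):
                if rng.random() < 0.5 and len(ids) > 0:  # deletion
                    start = int(rng.integers(len(ids)))
                    run = int(rng.geometric(geo_p))
                    ids = np.delete(ids, slice(start, start + run))
                    chars = np.delete(chars, slice(start, start + run))
                else:  # insertion
                    pos = int(rng.integers(len(ids) + 1))
                    run = int(rng.geometric(geo_p))
                    new_ids = np.arange(counter, counter + run, dtype=np.int64)
                    counter += run
                    new_chars = rng.choice(4, size=run, p=pi)
                    anchor = int(ids[pos - 1]) if pos > 0 else (prv[int(ids[0])] if len(ids) else -1)
                    link_after(anchor, new_ids)
                    ids = np.insert(ids, pos, new_ids)
                    chars = np.insert(chars, pos, new_chars)
            tokens[c] = (ids, chars)

    leaf_maps = {}
    present: set[int] = set()
    for v, (ids, chars) in tokens.items():
        if tree.is_leaf(v):
            leaf_maps[tree.leaf_name(v)] = dict(zip(ids.tolist(), chars.tolist()))
            present.update(ids.tolist())

    columns = []
    cur = nxt[-1]
    while cur is not None:
        if cur in present:
            columns.append(cur)
        cur = nxt.get(cur)

    seqs = {
        name: "".join("ACGT"[m[c]] if c in m else "-" for c in columns)
        for name, m in leaf_maps.items()
    }
    return Alignment(seqs)
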