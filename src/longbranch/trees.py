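"""Unrooted binary phylogenetic trees.

This module is the substrate for everything else in the toolkit: a small
leaf-labelled tree structure with non-negative branch lengths
(substitutions/site), Newick I/O, exhaustive enumeration of unrooted
binary topologies, Robinson-Foulds comparison and taxon pruning.

Trees carry an explicit root node purely for traversal and Newick
output; every comparison operates on the unrooted view, where internal
nodes have degree 3.  Polytomies are rejected at parse time because all
searches in this package are over binary topologies.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Tree",
    "TaxonSet",
    "TreeError",
    "NewickError",
    "parse_newick",
    "write_newick",
    "enumerate_unrooted_topologies",
    "n_unrooted_topologies",
    "rf_distance",
    "topologies_equal",
    "prune_taxon",
]


class TreeError(ValueError):
    """Structural problem with a tree or an operation on it."""


class NewickError(TreeError):
    """Malformed Newick input."""


class TaxonSet(Sequence):
    """Ordered collection of unique, non-empty taxon names.

    The order is canonical: topology enumeration inserts taxa in this
    order, which fixes tie-breaking everywhere downstream.
    """

    def __init__(self, names: Iterable[str]):
        names = tuple(str(n) for n in names)
        if any(not n for n in names):
            raise TreeError("taxon names must be non-empty strings")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate taxon names: {dupes}")
        self._names = names

    def __getitem__(self, i):
        return self._names[i]

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name) -> bool:
        return name in self._names

    def __iter__(self):
        return iter(self._names)

    def __eq__(self, other):
        return isinstance(other, TaxonSet) and self._names == other._names

    def __hash__(self):
        return hash(self._names)

    def __repr__(self):
        return f"TaxonSet({list(self._names)!r})"


def n_unrooted_topologies(n: int) -> int:
    """Number of unrooted binary leaf-labelled topologies, (2n-5)!!."""
    if n < 3:
        raise TreeError("need at least 3 taxa")
    count = 1
    for k in range(3, 2 * n - 4, 2):
        count *= k
    return count


class Tree:
    """Leaf-labelled tree with optional branch lengths.

    Nodes are integer ids; leaves carry taxon names.  The adjacency
    structure is undirected; ``_root`` only anchors traversals and
    Newick output.
    """

    __slots__ = ("_adj", "_lengths", "_leaf_names", "_name_to_leaf", "_root", "_next_id")

    def __init__(self):
        self._adj: dict[int, list[int]] = {}
        self._lengths: dict[tuple[int, int], float | None] = {}
        self._leaf_names: dict[int, str] = {}
        self._name_to_leaf: dict[str, int] = {}
        self._root: int | None = None
        self._next_id = 0

    # -- construction primitives -------------------------------------------------

    def _new_node(self, name: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = []
        if name is not None:
            if name in self._name_to_leaf:
                raise TreeError(f"duplicate leaf label: {name!r}")
            self._leaf_names[nid] = name
            self._name_to_leaf[name] = nid
        if self._root is None:
            self._root = nid
        return nid

    @staticmethod
    def _ekey(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    def _add_edge(self, u: int, v: int, length: float | None = None) -> None:
        if length is not None and length < 0:
            raise TreeError(f"negative branch length {length}")
        self._adj[u].append(v)
        self._adj[v].append(u)
        self._lengths[self._ekey(u, v)] = length

    def _remove_edge(self, u: int, v: int) -> None:
        self._adj[u].remove(v)
        self._adj[v].remove(u)
        del self._lengths[self._ekey(u, v)]

    def _delete_node(self, v: int) -> None:
        if self._adj[v]:
            raise TreeError("cannot delete a connected node")
        del self._adj[v]
        name = self._leaf_names.pop(v, None)
        if name is not None:
            del self._name_to_leaf[name]

    def _subdivide(self, u: int, v: int) -> int:
        """Replace edge (u,v) by u-w-v and return the new node w.

        Branch lengths on the two half edges are left unset; callers
        that care about lengths assign them afterwards.
        """
        self._remove_edge(u, v)
        w = self._new_node()
        self._add_edge(u, w)
        self._add_edge(w, v)
        return w

    def _suppress_degree2(self, x: int) -> tuple[int, int]:
        """Remove degree-2 node x, joining its neighbors; returns the new edge."""
        a, b = self._adj[x]
        la = self._lengths[self._ekey(x, a)]
        lb = self._lengths[self._ekey(x, b)]
        merged = None if (la is None and lb is None) else (la or 0.0) + (lb or 0.0)
        self._remove_edge(x, a)
        self._remove_edge(x, b)
        self._delete_node(x)
        self._add_edge(a, b, merged)
        if self._root == x:
            self._root = a if not self.is_leaf(a) else b
        return (a, b)

    def _fix_root(self) -> None:
        """Point the root at a deterministic valid node (prefer internal)."""
        internal = [v for v in self._adj if not self.is_leaf(v)]
        if internal:
            self._root = min(internal)
        elif self._adj:
            self._root = min(self._adj)

    def _component(self, start: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for w in self._adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    # -- basic queries -----------------------------------------------------------

    @property
    def taxa(self) -> tuple[str, ...]:
        """Leaf labels in sorted order."""
        return tuple(sorted(self._name_to_leaf))

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_names)

    def is_leaf(self, v: int) -> bool:
        return v in self._leaf_names

    def leaf_node(self, name: str) -> int:
        try:
            return self._name_to_leaf[name]
        except KeyError:
            raise TreeError(f"no leaf named {name!r}") from None

    def leaf_name(self, v: int) -> str:
        return self._leaf_names[v]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def neighbors(self, v: int) -> tuple[int, ...]:
        return tuple(self._adj[v])

    def edges(self) -> list[tuple[int, int]]:
        """Edges as (parent-side, child-side) pairs in deterministic DFS order."""
        if self._root is None:
            return []
        out = []
        stack = [(self._root, None)]
        while stack:
            v, parent = stack.pop()
            for w in self._adj[v]:
                if w != parent:
                    out.append((v, w))
                    stack.append((w, v))
        return out

    def edge_length(self, u: int, v: int) -> float | None:
        return self._lengths[self._ekey(u, v)]

    def set_edge_length(self, u: int, v: int, length: float | None) -> None:
        if length is not None and length < 0:
            raise TreeError(f"negative branch length {length}")
        key = self._ekey(u, v)
        if key not in self._lengths:
            raise TreeError(f"no edge between nodes {u} and {v}")
        self._lengths[key] = length

    @property
    def has_branch_lengths(self) -> bool:
        return bool(self._lengths) and all(x is not None for x in self._lengths.values())

    def tree_length(self) -> float:
        """Sum of all branch lengths."""
        if not self.has_branch_lengths:
            raise TreeError("tree has missing branch lengths")
        return float(sum(self._lengths.values()))

    def branch_lengths(self) -> list[float]:
        if not self.has_branch_lengths:
            raise TreeError("tree has missing branch lengths")
        return [self._lengths[self._ekey(u, v)] for u, v in self.edges()]

    def pendant_length(self, name: str) -> float | None:
        v = self.leaf_node(name)
        (u,) = self._adj[v]
        return self.edge_length(u, v)

    def copy(self, strip_lengths: bool = False) -> "Tree":
        t = Tree.__new__(Tree)
        t._adj = {v: list(ws) for v, ws in self._adj.items()}
        if strip_lengths:
            t._lengths = {k: None for k in self._lengths}
        else:
            t._lengths = dict(self._lengths)
        t._leaf_names = dict(self._leaf_names)
        t._name_to_leaf = dict(self._name_to_leaf)
        t._root = self._root
        t._next_id = self._next_id
        return t

    # -- traversal ---------------------------------------------------------------

    def rooted_structure(self, root: int | None = None):
        """Postorder node list, children map and parent map from ``root``.

        Rooting at a leaf is allowed (the leaf then has one child); this
        is how parsimony scoring obtains a strictly binary traversal.
        """
        if root is None:
            root = self._root
        parent: dict[int, int | None] = {root: None}
        children: dict[int, list[int]] = {}
        order = [root]
        stack = [root]
        while stack:
            v = stack.pop()
            kids = [w for w in self._adj[v] if w != parent[v]]
            children[v] = kids
            for w in kids:
                parent[w] = v
                order.append(w)
                stack.append(w)
        order.reverse()  # children before parents
        return order, children, parent

    # -- unrooted-view comparisons -----------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits of the unrooted view, canonical side chosen
        as the one not containing the alphabetically first taxon."""
        n = self.n_leaves
        if n < 4:
            return frozenset()
        all_taxa = frozenset(self._name_to_leaf)
        ref = min(all_taxa)
        order, children, parent = self.rooted_structure()
        below: dict[int, frozenset[str]] = {}
        splits = set()
        for v in order:
            if self.is_leaf(v) and not children[v]:
                below[v] = frozenset([self._leaf_names[v]])
            else:
                s = frozenset().union(*(below[c] for c in children[v]))
                if self.is_leaf(v):
                    s |= frozenset([self._leaf_names[v]])
                below[v] = s
            if parent[v] is not None:
                side = below[v]
                if 2 <= len(side) <= n - 2:
                    if ref in side:
                        side = all_taxa - side
                    splits.add(side)
        return frozenset(splits)

    def topology_key(self):
        """Hashable identifier of the unrooted topology."""
        return (frozenset(self._name_to_leaf), self.bipartitions())

    def rf_distance(self, other: "Tree") -> int:
        a, b = set(self.taxa), set(other.taxa)
        if a != b:
            raise TreeError(
                f"leaf sets differ: only in first {sorted(a - b)}, only in second {sorted(b - a)}"
            )
        return len(self.bipartitions() ^ other.bipartitions())

    def topologies_equal(self, other: "Tree") -> bool:
        return self.rf_distance(other) == 0

    # -- editing -----------------------------------------------------------------

    def prune_taxon(self, name: str) -> "Tree":
        """Remove a leaf and suppress its attachment node, summing the two
        incident branch lengths."""
        if name not in self._name_to_leaf:
            raise TreeError(f"no leaf named {name!r}")
        if self.n_leaves < 4:
            raise TreeError("pruning would leave fewer than 3 leaves")
        t = self.copy()
        v = t._name_to_leaf[name]
        (u,) = t._adj[v]
        t._remove_edge(u, v)
        t._delete_node(v)
        if t._root == v:
            t._root = u
        if not t.is_leaf(u) and t.degree(u) == 2:
            t._suppress_degree2(u)
        return t

    def rerooted_near(self, name: str) -> "Tree":
        """Same unrooted tree, traversal root moved next to the given leaf."""
        t = self.copy()
        v = t.leaf_node(name)
        (u,) = t._adj[v]
        t._root = u
        return t

    # -- Newick ------------------------------------------------------------------

    def newick(self, include_lengths: bool | None = None) -> str:
        if include_lengths is None:
            include_lengths = any(x is not None for x in self._lengths.values())

        def fmt(length):
            if not include_lengths or length is None:
                return ""
            return ":" + format(float(length), ".10g")

        if self.n_leaves == 1:
            (name,) = self._name_to_leaf
            return f"{name};"
        if self.n_leaves == 2:
            (a, b) = sorted(self._name_to_leaf)
            va, vb = self._name_to_leaf[a], self._name_to_leaf[b]
            return f"({a},{b}{fmt(self.edge_length(va, vb))});"

        root = self._root
        if self.is_leaf(root):
            (root,) = self._adj[root]

        def sub(v: int, parent: int) -> str:
            if self.is_leaf(v):
                s = self._leaf_names[v]
            else:
                kids = [w for w in self._adj[v] if w != parent]
                s = "(" + ",".join(sub(w, v) for w in kids) + ")"
            return s + fmt(self.edge_length(parent, v))

        kids = self._adj[root]
        return "(" + ",".join(sub(w, root) for w in kids) + ");"

    def __str__(self) -> str:
        return self.newick()

    def __repr__(self) -> str:
        return f"<Tree {self.n_leaves} leaves: {self.newick()}>"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from None
        t = cls()

        def conv(dnode) -> int:
            is_leaf = not dnode.child_nodes()
            name = None
            if is_leaf:
                name = dnode.taxon.label if dnode.taxon is not None else dnode.label
                if not name:
                    raise NewickError("leaf without a label")
            nid = t._new_node(name)
            for ch in dnode.child_nodes():
                cid = conv(ch)
                length = ch.edge.length
                if length is not None and length < 0:
                    raise TreeError(f"negative branch length {length}")
                t._add_edge(nid, cid, length)
            return nid

        rid = conv(dt.seed_node)
        t._root = rid
        if t.n_leaves == 0:
            raise NewickError("tree has no labelled leaves")
        # Suppress a rooted (degree-2) basal node so the stored form is the
        # unrooted view; a chain of unifurcations is rejected below.
        if not t.is_leaf(rid) and t.degree(rid) == 2:
            t._suppress_degree2(rid)
        for v in list(t._adj):
            if t.is_leaf(v):
                continue
            if t.degree(v) != 3 and t.n_leaves > 2:
                kind = "polytomy" if t.degree(v) > 3 else "unifurcation"
                raise TreeError(
                    f"only binary trees are supported: internal node of degree {t.degree(v)} ({kind})"
                )
        t._fix_root()
        return t


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into an unrooted binary :class:`Tree`."""
    return Tree.from_newick(text)


def write_newick(tree: Tree, include_lengths: bool | None = None) -> str:
    return tree.newick(include_lengths=include_lengths)


def rf_distance(a: Tree, b: Tree) -> int:
    """Unrooted Robinson-Foulds distance (count of splits in exactly one tree)."""
    return a.rf_distance(b)


def topologies_equal(a: Tree, b: Tree) -> bool:
    return a.rf_distance(b) == 0


def prune_taxon(tree: Tree, name: str) -> Tree:
    return tree.prune_taxon(name)


def enumerate_unrooted_topologies(taxa: Iterable[str] | TaxonSet) -> Iterator[Tree]:
    """Yield every unrooted binary topology on the taxa exactly once.

    Trees are produced by successive edge insertion in canonical taxon
    order, so the sequence is deterministic; the count is (2n-5)!!.
    Branch lengths are unset.
    """
    ts = taxa if isinstance(taxa, TaxonSet) else TaxonSet(taxa)
    n = len(ts)
    if not 3 <= n <= 9:
        hint = f" ({n_unrooted_topologies(n)} topologies)" if n > 9 else ""
        raise TreeError(f"refusing to enumerate topologies for {n} taxa{hint}; supported range is 3..9")
    base = Tree()
    center = base._new_node()
    for name in ts[:3]:
        base._add_edge(center, base._new_node(name))
    base._root = center

    def extend(tree: Tree, k: int) -> Iterator[Tree]:
        if k == n:
            yield tree.copy()
            return
        for (u, v) in tree.edges():
            t2 = tree.copy()
            w = t2._subdivide(u, v)
            t2._add_edge(w, t2._new_node(ts[k]))
            yield from extend(t2, k + 1)

    yield from extend(base, 3)
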