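"""Long Branch Shortening (LBS): shorten the suspect branch, watch it move.

The idea: reconstruct the ancestral sequence of the clade formed by all
taxa except the outgroup and the questionable taxon ("the combined
signal of that clade"), then replace a Bernoulli-sampled fraction p of
the questionable taxon's characters with the ancestor's.  If already a
small p relocates the taxon into that clade, its original placement was
held by weak (analogous) signal and LBA is suspected; if it takes
p near 1, the placement rests on strong signal.  The scan over p yields
p*, the smallest sampling frequency at which the hybridized taxon
clades with the hypothetical clade in a majority of runs; small p* is
evidence of LBA.

The ancestral sequence is a Fitch reconstruction rooted where the
questionable taxon attached (ties broken by the clade's column
frequencies, then fixed A<C<G<T order); a simple majority-consensus
alternative is available.  Hybridization is directional - the target is
overwritten from the ancestor, never the reverse - and per-site
independent (no crossing over).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP_CODE, Alignment
from .parsimony import SearchResult, exhaustive_mp_search, tbr_search
from .trees import Tree, TreeError

__all__ = ["LBSConfig", "LBSResult", "construct_clade_ancestor", "hybridize", "run_lbs"]

LBA = "LBA"
NOT_LBA = "NOT_LBA"

DEFAULT_FREQUENCIES = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class LBSConfig:
    outgroup: str
    qtaxa: str
    sampling_frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    runs_per_p: int = 3
    verdict_threshold: float = 0.5
    search_mode: str = "tbr"
    n_starts: int = 5
    ancestor_method: str = "fitch"  # or "consensus"

    def __post_init__(self):
        if self.outgroup == self.qtaxa:
            raise ValueError("outgroup and qtaxa must differ")
        freqs = tuple(float(p) for p in self.sampling_frequencies)
        if not freqs or any(not 0 <= p <= 1 for p in freqs):
            raise ValueError("sampling frequencies must lie in [0, 1]")
        if list(freqs) != sorted(freqs):
            raise ValueError("sampling frequencies must be ascending")
        if self.runs_per_p < 1:
            raise ValueError("runs_per_p must be >= 1")
        if self.search_mode not in ("tbr", "exhaustive"):
            raise ValueError(f"unknown search_mode {self.search_mode!r}")
        if self.ancestor_method not in ("fitch", "consensus"):
            raise ValueError(f"unknown ancestor_method {self.ancestor_method!r}")
        object.__setattr__(self, "sampling_frequencies", freqs)


@dataclass(frozen=True)
class LBSResult:
    """p*, per-p move rates over the scanned frequencies, and the verdict
    (LBA iff p* < verdict_threshold).  p* is ``inf`` when the taxon
    never consistently moved."""

    p_star: float
    per_p_move_rates: dict[float, float]
    verdict: str
    evidence: float = field(default=math.inf)


_BITS = np.array([1, 2, 4, 8, 15], dtype=np.uint8)


def _clade_attachment_root(tree: Tree, outgroup: str, qtaxa: str):
    """Root the pruned clade tree at the edge where qtaxa attached.

    Returns (clade_tree, (u, v)) where (u, v) is the attachment edge,
    or (clade_tree, None) when the attachment collapses onto a single
    region (e.g. qtaxa and outgroup were sisters).
    """
    clade = set(tree.taxa) - {outgroup, qtaxa}
    # split of clade members induced by qtaxa's attachment node
    q = tree.leaf_node(qtaxa)
    (u,) = tree.neighbors(q)
    sides = []
    for w in tree.neighbors(u):
        if w == q:
            continue
        comp = _leaves_beyond(tree, u, w)
        sides.append(frozenset(comp & clade))
    pruned = tree.prune_taxon(qtaxa).prune_taxon(outgroup)
    if all(sides) and len(sides) == 2:
        target = frozenset(sides)
        for (a, b) in pruned.edges():
            left = _leaves_beyond(pruned, a, b)
            if frozenset({frozenset(left), frozenset(clade - left)}) == target:
                return pruned, (a, b)
    return pruned, None


def _leaves_beyond(tree: Tree, block: int, start: int) -> set[str]:
    """Leaf names reachable from ``start`` without crossing ``block``."""
    seen = {block, start}
    stack = [start]
    names = set()
    while stack:
        v = stack.pop()
        if tree.is_leaf(v):
            names.add(tree.leaf_name(v))
        for w in tree.neighbors(v):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return names


def construct_clade_ancestor(
    aln: Alignment, tree: Tree, outgroup: str, qtaxa: str, method: str = "fitch"
) -> str:
    """Ancestral sequence of the clade excluding outgroup and qtaxa.

    ``method='fitch'`` runs a per-column Fitch reconstruction at the
    node adjacent to where the excluded taxa attached; ties in the root
    state set are broken by the highest observed frequency in the clade,
    then by A<C<G<T.  ``method='consensus'`` takes a per-column majority
    instead.  Columns gapped in every clade member yield '-'.
    """
    clade = [n for n in aln.taxa if n not in (outgroup, qtaxa)]
    if len(clade) < 2:
        raise TreeError("clade ancestor requires at least 2 remaining taxa")
    codes = aln.codes(clade)  # (n, L) in 0..4
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])  # (4, L)
    all_gap = (codes == GAP_CODE).all(axis=0)

    if method == "consensus":
        root_masks = np.full(aln.length, 15, dtype=np.uint8)
    else:
        pruned, root_edge = _clade_attachment_root(tree, outgroup, qtaxa)
        masks = {name: _BITS[aln.codes([name])[0]] for name in clade}
        if root_edge is None:
            # attachment collapsed to one region: root at the pendant edge of
            # the clade member nearest (in edges) to qtaxa's attachment
            nearest = _nearest_clade_leaf(tree, qtaxa, set(clade))
            v = pruned.leaf_node(nearest)
            (w,) = pruned.neighbors(v)
            root_edge = (v, w)
        down_a = _fitch_down(pruned, masks, root_edge[0], root_edge[1])
        down_b = _fitch_down(pruned, masks, root_edge[1], root_edge[0])
        inter = down_a & down_b
        root_masks = np.where(inter != 0, inter, down_a | down_b)

    # pick the allowed state with the highest clade frequency; np.argmax
    # breaks remaining ties toward A<C<G<T
    allowed = np.stack([(root_masks >> s) & 1 for s in range(4)]).astype(bool)
    score = np.where(allowed, counts, -1)
    choice = score.argmax(axis=0)
    out = np.array(list("ACGT"))[choice]
    out[all_gap] = "-"
    return "".join(out)


def _nearest_clade_leaf(tree: Tree, qtaxa: str, clade: set[str]) -> str:
    q = tree.leaf_node(qtaxa)
    from collections import deque

    dq = deque([q])
    seen = {q}
    while dq:
        v = dq.popleft()
        if tree.is_leaf(v) and tree.leaf_name(v) in clade:
            return tree.leaf_name(v)
        for w in tree.neighbors(v):
            if w not in seen:
                seen.add(w)
                dq.append(w)
    raise TreeError("no clade member found")  # pragma: no cover


def _fitch_down(tree: Tree, masks, toward: int, away: int) -> np.ndarray:
    """Fitch downpass state sets for the subtree on ``toward``'s side of
    the edge (toward, away)."""

    def rec(v, parent):
        if tree.is_leaf(v):
            return masks[tree.leaf_name(v)]
        kids = [w for w in tree.neighbors(v) if w != parent]
        parts = [rec(w, v) for w in kids]
        acc = parts[0]
        for p in parts[1:]:
            inter = acc & p
            acc = np.where(inter != 0, inter, acc | p)
        return acc

    return rec(toward, away)


def hybridize(target: str, ancestor: str, p: float, seed: int) -> str:
    """Replace each target site by the ancestor's with probability p."""
    if len(target) != len(ancestor):
        raise ValueError(
            f"sequence lengths differ: target {len(target)}, ancestor {len(ancestor)}"
        )
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p == 0:
        return target
    if p == 1:
        return ancestor
    rng = np.random.default_rng(seed)
    take = rng.random(len(target)) < p
    tgt = np.array(list(target))
    anc = np.array(list(ancestor))
    return "".join(np.where(take, anc, tgt))


def _attachment_signature(tree: Tree, taxon: str):
    """Partition of the other taxa induced by the leaf's attachment node."""
    v = tree.leaf_node(taxon)
    (u,) = tree.neighbors(v)
    parts = [
        frozenset(_leaves_beyond(tree, u, w)) for w in tree.neighbors(u) if w != v
    ]
    return frozenset(parts)


def _clades_with(tree: Tree, qtaxa: str, outgroup: str) -> bool:
    """True iff some non-trivial split groups qtaxa with clade members only."""
    return any(qtaxa in side and outgroup not in side for side in _both_sides(tree))


def _both_sides(tree: Tree):
    all_taxa = frozenset(tree.taxa)
    for side in tree.bipartitions():
        yield side
        yield all_taxa - side


def run_lbs(aln: Alignment, cfg: LBSConfig, seed: int = 0) -> LBSResult:
    """Scan sampling frequencies, re-searching with the hybridized taxon.

    A run counts as "moved" when the qtaxa attachment differs from the
    baseline parsimony tree AND the qtaxa groups inside the hypothetical
    clade (some split contains it together with clade members but not
    the outgroup).  The scan stops at the first p where a majority of
    runs moved; that p is p*.
    """
    for name in (cfg.outgroup, cfg.qtaxa):
        if name not in aln:
            raise TreeError(f"taxon {name!r} not in alignment")

    def search(sub_aln: Alignment, offset: int) -> SearchResult:
        if cfg.search_mode == "exhaustive":
            return exhaustive_mp_search(sub_aln)
        return tbr_search(sub_aln, n_starts=cfg.n_starts, seed=seed * 104729 + offset)

    baseline = search(aln, 0).best_trees[0]
    base_sig = _attachment_signature(baseline, cfg.qtaxa)
    ancestor = construct_clade_ancestor(
        aln, baseline, cfg.outgroup, cfg.qtaxa, method=cfg.ancestor_method
    )
    target = aln[cfg.qtaxa]
    majority = math.ceil(cfg.runs_per_p / 2)

    per_p: dict[float, float] = {}
    p_star = math.inf
    for ip, p in enumerate(cfg.sampling_frequencies):
        moves = 0
        for r in range(cfg.runs_per_p):
            hyb = hybridize(target, ancestor, p, seed=seed * 15485863 + ip * 1009 + r)
            if hyb == target:
                continue  # unchanged sequence cannot move the taxon
            res = search(aln.replace(cfg.qtaxa, hyb), 1000 + ip * 100 + r)
            t = res.best_trees[0]
            if _attachment_signature(t, cfg.qtaxa) != base_sig and _clades_with(
                t, cfg.qtaxa, cfg.outgroup
            ):
                moves += 1
        per_p[p] = moves / cfg.runs_per_p
        if moves >= majority:
            p_star = p
            break
    verdict = LBA if p_star < cfg.verdict_threshold else NOT_LBA
    return LBSResult(p_star, per_p, verdict, evidence=p_star)
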