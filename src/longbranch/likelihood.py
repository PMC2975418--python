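"""GTR maximum likelihood on small trees.

Log-likelihoods come from the pruning (conditional-likelihood)
recursion with per-node rescaling, so long branches and thousands of
sites never underflow.  Branch lengths are fitted by round-robin
univariate optimization: for one edge at a time the likelihood factors
as  L(t) = sum_xy pi_x A_x P_xy(t) B_y,  where B is the conditional
likelihood of the subtree below the edge and A collects everything on
the other side; a bounded Brent search then optimizes t with the rest
of the tree held fixed.  Sweeps repeat until the log-likelihood gain
drops below ``tol``.  The exhaustive topology search optimizes every
unrooted topology and keeps the best, which is feasible for the 4-9
taxon trees this toolkit targets.

The substitution model is taken as known (frequencies and
exchangeabilities fixed), matching a simulation study in which the
generating model is available; only topology and branch lengths are
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .gtr import GTRModel, _eigensystem, transition_matrix
from .trees import TaxonSet, Tree, TreeError, enumerate_unrooted_topologies

__all__ = ["MLResult", "log_likelihood", "optimize_branch_lengths", "exhaustive_ml_search"]

DEFAULT_MIN_BL = 1e-8
DEFAULT_MAX_BL = 20.0
DEFAULT_TOL = 1e-4
DEFAULT_MAX_SWEEPS = 20
_TIE_TOL = 1e-6


@dataclass(frozen=True)
class MLResult:
    """Maximum-likelihood fit: tree with optimized branch lengths, its
    log-likelihood, the number of topologies evaluated, convergence
    status, and whether the best topology was tied (within 1e-6)."""

    tree: Tree
    log_likelihood: float
    n_evaluated: int
    converged: bool
    tied: bool = False


def _leaf_partials(aln: Alignment, taxa) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-taxon (4, n_patterns) conditional likelihoods; gaps give ones."""
    codes = aln.codes(taxa)
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    eye = np.vstack([np.eye(4), np.ones(4)])  # row 4 = gap
    return (
        {name: np.ascontiguousarray(eye[patterns[i]].T) for i, name in enumerate(taxa)},
        weights.astype(float),
    )


class _TreeLikelihood:
    """Pruning-algorithm engine bound to one topology and one dataset."""

    def __init__(self, tree, model, partials, weights, min_bl=DEFAULT_MIN_BL, max_bl=DEFAULT_MAX_BL):
        if tree.n_leaves < 3:
            raise TreeError("engine requires >= 3 leaves")
        self.tree = tree
        self.model = model
        self.pi = np.asarray(model.pi)
        self.partials = partials
        self.weights = weights
        self.min_bl = min_bl
        self.max_bl = max_bl
        root = tree._root
        if tree.is_leaf(root):
            (root,) = tree.neighbors(root)
        self.root = root
        self.order, self.children, self.parent = tree.rooted_structure(root)
        self.npat = len(weights)
        # state filled by _down()
        self.B: dict[int, np.ndarray] = {}
        self.C: dict[int, np.ndarray] = {}
        self.ls: dict[int, np.ndarray] = {}

    def _edge_t(self, child: int) -> float:
        return self.tree.edge_length(self.parent[child], child)

    def _down(self) -> None:
        """Conditional likelihoods B, per-edge messages C = P(t) @ B, and
        per-site log scale factors ls, bottom-up."""
        for v in self.order:
            kids = self.children[v]
            if not kids:
                self.B[v] = self.partials[self.tree.leaf_name(v)]
                self.ls[v] = np.zeros(self.npat)
            else:
                raw = self.C[kids[0]].copy()
                lsv = self.ls[kids[0]].copy()
                for c in kids[1:]:
                    raw *= self.C[c]
                    lsv += self.ls[c]
                scale = np.maximum(raw.max(axis=0), 1e-300)
                self.B[v] = raw / scale
                self.ls[v] = lsv + np.log(scale)
            if self.parent[v] is not None:
                p = transition_matrix(self.model, self._edge_t(v))
                self.C[v] = p @ self.B[v]

    def log_likelihood(self) -> float:
        self._down()
        root_lik = self.pi @ self.B[self.root]
        return float(np.dot(self.weights, np.log(np.maximum(root_lik, 1e-300)) + self.ls[self.root]))

    def _optimize_edge(self, p_node: int, c: int, m: np.ndarray, ls_const: np.ndarray) -> None:
        """Maximize over one branch length with the rest of the tree fixed.

        ``m`` carries everything on the parent side of the edge (root
        prior included) so that L_site(t) = sum_x m_x (P(t) B_c)_x.
        A damped Newton iteration on the analytic gradient/curvature
        (cheap through the eigendecomposition of Q) does the work; a
        bounded Brent search is the fallback when curvature misbehaves.
        """
        b = self.B[c]
        w = self.weights
        lam, left, right = self._eig
        lo, hi = self.min_bl, self.max_bl

        def f_g_h(t):
            e = np.exp(lam * t)
            p = (left * e) @ right
            site = (m * (p @ b)).sum(axis=0)
            np.maximum(site, 1e-300, out=site)
            d1 = (m * ((left * (lam * e)) @ right @ b)).sum(axis=0) / site
            d2 = (m * ((left * (lam * lam * e)) @ right @ b)).sum(axis=0) / site
            f = float(np.dot(w, np.log(site) + ls_const))
            return f, float(np.dot(w, d1)), float(np.dot(w, d2 - d1 * d1))

        t0 = min(max(self._edge_t(c), lo), hi)
        t, (f, g, h) = t0, f_g_h(t0)
        f_init = f
        solved = False
        for _ in range(30):
            if (t == lo and g < 0) or (t == hi and g > 0) or abs(g) < 1e-7 * (abs(f) + 1):
                solved = True
                break
            if h >= -1e-12:
                break  # not locally concave: fall back to Brent
            tn = min(max(t - g / h, lo), hi)
            if abs(tn - t) < 1e-7 * (1 + t):
                solved = True
                break
            fn, gn, hn = f_g_h(tn)
            halved = 0
            while fn < f - 1e-12 and halved < 6:  # overshoot: damp toward t
                tn = 0.5 * (t + tn)
                fn, gn, hn = f_g_h(tn)
                halved += 1
            if fn < f - 1e-12:
                break
            t, f, g, h = tn, fn, gn, hn
        if not solved:
            def neg_ll(x):
                e = np.exp(lam * x)
                p = (left * e) @ right
                site = (m * (p @ b)).sum(axis=0)
                return -float(np.dot(w, np.log(np.maximum(site, 1e-300)) + ls_const))

            res = minimize_scalar(
                neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
            )
            if -res.fun >= f:
                t, f = float(res.x), -float(res.fun)
        # never accept a move that lowers the likelihood
        if f >= f_init:
            self.tree.set_edge_length(p_node, c, t)

    def _refresh_internal(self, v: int) -> None:
        """Recompute B (and C, if non-root) of an internal node from its
        children's messages after their lengths changed."""
        kids = self.children[v]
        raw = self.C[kids[0]].copy()
        lsv = self.ls[kids[0]].copy()
        for c in kids[1:]:
            raw *= self.C[c]
            lsv += self.ls[c]
        scale = np.maximum(raw.max(axis=0), 1e-300)
        self.B[v] = raw / scale
        self.ls[v] = lsv + np.log(scale)
        if self.parent[v] is not None:
            p = transition_matrix(self.model, self._edge_t(v))
            self.C[v] = p @ self.B[v]

    def _opt_subtree(self, v: int, out: np.ndarray, ls_out: np.ndarray) -> None:
        """DFS coordinate descent below ``v``; ``out`` is the outer partial
        of v (everything above it, root prior included).  Partials are
        patched in place after every length change, so each edge is
        optimized against the exact current likelihood."""
        for c in self.children[v]:
            m = out
            lsm = ls_out
            for s in self.children[v]:
                if s != c:
                    m = m * self.C[s]
                    lsm = lsm + self.ls[s]
            self._optimize_edge(v, c, m, lsm + self.ls[c])
            p = transition_matrix(self.model, self._edge_t(c))
            self.C[c] = p @ self.B[c]
            if self.children[c]:
                out_c = p.T @ m
                scale = np.maximum(out_c.max(axis=0), 1e-300)
                self._opt_subtree(c, out_c / scale, lsm + np.log(scale))
                self._refresh_internal(c)

    def optimize(self, tol=DEFAULT_TOL, max_sweeps=DEFAULT_MAX_SWEEPS):
        """Round-robin branch-length sweeps; monotone in log-likelihood."""
        self._eig = _eigensystem(self.model)
        prev = self.log_likelihood()
        converged = False
        root_out = self.pi[:, None] * np.ones((4, self.npat))
        zeros = np.zeros(self.npat)
        for _ in range(max_sweeps):
            self._opt_subtree(self.root, root_out, zeros)
            cur = self.log_likelihood()
            if cur - prev < tol:
                converged = True
                prev = max(cur, prev)
                break
            prev = cur
        return prev, converged


def _two_leaf_loglik(tree, model, partials, weights, t=None):
    a, b = tree.taxa
    if t is None:
        va, vb = tree.leaf_node(a), tree.leaf_node(b)
        t = tree.edge_length(va, vb)
        if t is None:
            raise TreeError("tree has missing branch lengths")
    pi = np.asarray(model.pi)
    p = transition_matrix(model, t)
    site = np.einsum("ij,ij->j", partials[a] * pi[:, None], p @ partials[b])
    return float(np.dot(weights, np.log(np.maximum(site, 1e-300))))


def log_likelihood(tree: Tree, model: GTRModel, aln: Alignment) -> float:
    """Pruning-algorithm log-likelihood; gaps contribute all-ones partials,
    and the value is invariant to where the traversal is rooted."""
    missing = [n for n in tree.taxa if n not in aln]
    if missing:
        raise TreeError(f"tree leaves without sequences: {missing}")
    partials, weights = _leaf_partials(aln, tree.taxa)
    if tree.n_leaves == 1:
        (name,) = tree.taxa
        pi = np.asarray(model.pi)
        return float(np.dot(weights, np.log(pi @ partials[name])))
    if tree.n_leaves == 2:
        return _two_leaf_loglik(tree, model, partials, weights)
    if not tree.has_branch_lengths:
        raise TreeError("tree has missing branch lengths")
    return _TreeLikelihood(tree, model, partials, weights).log_likelihood()


def _init_lengths(tree: Tree, init: float) -> Tree:
    t = tree.copy()
    for (u, v) in t.edges():
        if t.edge_length(u, v) is None:
            t.set_edge_length(u, v, init)
    return t


def optimize_branch_lengths(
    tree: Tree,
    model: GTRModel,
    aln: Alignment,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    min_bl: float = DEFAULT_MIN_BL,
    max_bl: float = DEFAULT_MAX_BL,
    init: float = 0.1,
) -> MLResult:
    """Fit branch lengths on a fixed topology.

    Existing lengths on the input tree seed the optimization; missing
    ones start at ``init`` (0.1, inside the simulated regime).
    """
    missing = [n for n in tree.taxa if n not in aln]
    if missing:
        raise TreeError(f"tree leaves without sequences: {missing}")
    partials, weights = _leaf_partials(aln, tree.taxa)
    work = _init_lengths(tree, init)
    if work.n_leaves == 2:
        a, b = work.taxa
        va, vb = work.leaf_node(a), work.leaf_node(b)
        res = minimize_scalar(
            lambda t: -_two_leaf_loglik(work, model, partials, weights, t),
            bounds=(min_bl, max_bl),
            method="bounded",
            options={"xatol": 1e-6},
        )
        work.set_edge_length(va, vb, float(res.x))
        return MLResult(work, -float(res.fun), 1, True)
    engine = _TreeLikelihood(work, model, partials, weights, min_bl, max_bl)
    start = engine.log_likelihood()
    if not np.isfinite(start):
        raise TreeError("non-finite log-likelihood at starting branch lengths")
    ll, converged = engine.optimize(tol=tol, max_sweeps=max_sweeps)
    return MLResult(work, ll, 1, converged)


def exhaustive_ml_search(
    aln: Alignment,
    model: GTRModel,
    taxa=None,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    init: float = 0.1,
) -> MLResult:
    """Optimize branch lengths on every topology; return the best.

    Ties closer than 1e-6 log-units are broken by enumeration order and
    flagged on the result.
    """
    ts = TaxonSet(taxa if taxa is not None else aln.taxa)
    if not 4 <= len(ts) <= 7:
        raise TreeError(f"exhaustive ML search supports 4..7 taxa, got {len(ts)}")
    partials, weights = _leaf_partials(aln, tuple(ts))
    best = None
    tied = False
    n_eval = 0
    for topo in enumerate_unrooted_topologies(ts):
        n_eval += 1
        work = _init_lengths(topo, init)
        engine = _TreeLikelihood(work, model, partials, weights)
        ll, converged = engine.optimize(tol=tol, max_sweeps=max_sweeps)
        if best is None or ll > best[0] + _TIE_TOL:
            best = (ll, work, converged)
            tied = False
        elif ll > best[0] - _TIE_TOL:
            tied = True
    ll, tree, converged = best
    return MLResult(tree, ll, n_eval, converged, tied)
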