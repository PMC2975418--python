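# Methods

## The zone topologies

All experiments run on leaf-labelled unrooted binary trees with two free
branch-length parameters. For six taxa the tree is the symmetric
"star shape": three cherries whose stems join a central node, every stem
and most pendant edges of length α, and two pendant edges of length β.
The long leaves are always T1 and T2; the two study conditions differ in
topology, not lengths:

- **Farris-like** — cherries (T1,T2), (T3,T4), (T5,T6): the long branches
  are sisters, so parsimony's grouping bias coincides with the truth;
- **Felsenstein-like** — cherries (T1,T3), (T2,T4), (T5,T6): the long
  branches are non-sisters, the regime in which parsimony is
  statistically inconsistent.

A six-leaf zone tree therefore has exactly 7 α edges (4 pendant +
3 internal) and 2 β edges; tree length is 7α + 2β. The four-taxon
variant is the classic quartet with one internal α edge. A six-taxon
"star shape" admits more than one geometry; the symmetric three-cherry
construction is the reading implemented here, chosen because it degrades
gracefully to the four-taxon quartet and keeps the two regimes
length-matched.

Branch lengths are expected substitutions per site; α and β range over
(0, 20], with 0.1–2.0 the studied regime.

## Substitution model and simulator

Sequences evolve under general time-reversible (GTR) substitution:
stationary frequencies π over (A, C, G, T) and six exchangeabilities
r(AC), r(AG), r(AT), r(CG), r(CT), r(GT). The rate matrix has
Q_ij = r_ij π_j off the diagonal and is rescaled so −Σ π_i Q_ii = 1 (one
unit of branch length = one expected substitution per site). Detailed
balance makes diag(π)^½ Q diag(π)^−½ symmetric, so P(t) = exp(Qt) is
computed through a real eigendecomposition, with entries clamped at 0.

`GTRModel.zone_study()` carries the study conditions: π = (0.2, 0.3, 0.2,
0.3) in ACGT order (the frequencies are conventionally quoted in A, C, T,
G order as 0.2/0.3/0.3/0.2 — the constructor re-orders explicitly to
avoid a silent G/T swap), exchangeabilities (1.5, 3.0, 0.9, 1.2, 2.5,
1.0), sequence length 2000, and indel rate λ = 0.1 (one indel event per
ten substitutions). The plain constructor defaults to λ = 0, which unit
tests use so that expectations have closed forms.

Simulation draws the root sequence from π at the central node (the choice
of root is immaterial by reversibility; fixing it aids reproducibility),
then samples each child site from the parent's P(t) row. The indel
process is a deliberately simple one — Poisson(λ·t·L) events per edge,
insertion or deletion with equal probability, geometric lengths with mean
`indel_length_mean` (default 1), inserted characters drawn from π (the
correct stationary marginal). Alignment columns are tracked exactly
through a global token order, so the output is a true gapped alignment;
columns deleted in every surviving lineage are dropped. Substitutions are
applied along an edge before its indel events rather than interleaved in
time; at the studied rates this changes nothing downstream, because every
inference method here treats gaps as missing data. Identical
(tree, model, length, seed) inputs produce byte-identical FASTA.

What the simulator does *not* emulate: rate heterogeneity across sites,
codon structure, selection, alignment error (the true alignment is
known). Passing tests therefore demonstrate the behaviour of the methods
under their own model assumptions, not robustness to real-data
violations of them.

## Parsimony

Fitch's set algorithm scores unordered, unit-cost changes; a gap is the
full state set {A,C,G,T} (missing data, never a fifth state — consistent
with how the likelihood side treats gaps). Identical columns are
collapsed to weighted patterns, which is provably score-neutral and makes
the exhaustive sweep over all (2n−5)!! topologies (105 for six taxa)
cheap. Scoring roots the tree at a leaf; the score is invariant to that
choice.

The heuristic search is random-order stepwise addition followed by hill
climbing over full tree-bisection-reconnection (TBR) neighborhoods,
accepting strict improvements until a local optimum; 5 independent starts
by default (the six-taxon space is tiny, and the exhaustive engine is
always available as the oracle). Search results carry *all* co-optimal
trees found; how ties count is decided by the consumer (see the grid
engine below).

## Likelihood

Log-likelihoods use the pruning (conditional-likelihood) recursion with
per-node rescaling of partials and accumulated per-site log factors, so
2000-site alignments on saturated branches stay finite. The inference
model is the *known* generating GTR model — the study evaluates topology
and branch-length inference, not model estimation — with an
empirical-frequency plug-in left to the caller if wanted.

Branch lengths are fitted coordinate-wise: for a single edge the
site likelihood factors as Σ_xy m_x P_xy(t) B_y with the rest of the tree
fixed, and a damped Newton iteration on the analytic gradient and
curvature (both cheap via the eigendecomposition) maximizes it, falling
back to bounded Brent search when the surface is not locally concave.
A sweep visits every edge depth-first, patching partials in place so each
edge is optimized against the exact current likelihood; sweeps repeat
until the gain drops below `tol`. No edge update is accepted that lowers
the likelihood, so the procedure is monotone.

Numerical choices: branch bounds [1e−8, 20] (the simulated regime is
0.1–2.0), initial lengths 0.1 unless the input tree carries lengths,
`tol` = 1e−4 log-units between sweeps, `max_sweeps` = 20. The exhaustive
topology search optimizes all topologies and breaks ties closer than 1e−6
log-units by enumeration order, flagging them on the result.

## Long Branch Extraction

Inputs: an alignment, the parsimony tree under suspicion, an outgroup and
a questionable taxon (in zone studies, the two β leaves — T1 as outgroup,
T2 as qtaxa, fixed by taxon order). Steps, each able to refute LBA:

1. drop the outgroup, re-search by parsimony; "same tree" as the pruned
   original refutes;
2. the same with the questionable taxon;
3. exhaustive ML search on the full data; agreement with the parsimony
   tree refutes;
4. otherwise LBA is accepted only if *both* candidate pendant branches
   rank in the top quartile of all branch lengths on the ML tree.

"Same tree" means Robinson–Foulds distance zero, and when a re-search
returns several co-optimal trees, all of them must equal the pruned
original (strict-consensus reading). The percentile rank of an edge is
(number of strictly shorter edges + half the tied others) / (number of
edges), over pendant *and* internal edges; the top-quartile cutoff is
rank ≥ 0.75, and both taxa must qualify (a conjunction). With
`use_ml_step=False` steps 3 *and* 4 are skipped — both depend on
branch-length estimation — so any dataset surviving steps 1–2 is called
LBA; since this removes refutation opportunities only, the no-ML variant
can add LBA verdicts but never remove them.

Step 3 compares full topologies (RF = 0), a stricter reading than
requiring only the questionable taxon's placement to match; a
fixed-topology branch-length-only mode is available through
`optimize_branch_lengths`.

## Long Branch Shortening

Step 1 reconstructs the ancestral sequence of the "hypothetical clade"
(all taxa minus outgroup and qtaxa) by Fitch reconstruction rooted at
the edge where the questionable taxon attached; ties in the root state
set break by the highest observed frequency among the clade's states in
that column, then by fixed A<C<G<T order. Columns gapped in every clade
member stay gaps. A per-column majority-consensus alternative
(`ancestor_method="consensus"`) is provided, since "a summary of that
clade" admits that reading. When the attachment region collapses (e.g.
outgroup and qtaxa were sisters) the reconstruction roots at the pendant
edge of the clade member nearest the attachment.

Step 2 hybridizes: each site of the questionable taxon is independently
replaced by the ancestor's character with probability p (binomial
overall); p = 0 returns the target exactly and p = 1 the ancestor
exactly. Replacement is directional (target ← ancestor) — the reading
consistent with "the characters for the questionable taxon are modified
by sampling from the hypothetical ancestor"; a symmetric character
*exchange* between the two sequences is a noted alternative, not
implemented, and crossover-style hybridization is explicitly out of
scope.

Step 3 re-runs the parsimony search with the hybridized sequence. A run
"moves" when the taxon's attachment differs from the baseline tree *and*
some split groups it with clade members to the exclusion of the
outgroup. Scanning p upward (default 0.0, 0.1, …, 1.0; 3 runs per p)
stops at the first p where a majority of runs move: that is p\*, the
evidence score. The default verdict cut p\* < 0.5 splits the verbal scale
("0.9–1.0 ⇒ no LBA", "very low ⇒ LBA"); it is configurable because no
numeric cut is canonical. Note our own experiments show p\* tracks the
questionable branch's *length* more than attraction (short-branch taxa
move at small p even without LBA) — the very failure mode that motivates
skepticism of the method; the test suite pins the defensible limits
(p = 0 never moves, p = 1 always moves, move rate grows with p).

## The grid engine

`run_grid` sweeps an α×β lattice; for each cell and replicate it
simulates an alignment on the zone tree and applies the requested
methods. Accuracy surfaces count a replicate correct only when the true
topology is the *unique* optimum (co-optimal ties indicate lost signal;
`tie_policy="count-if-included"` switches this). LBE surfaces use
heuristic-TBR input trees, matching a pipeline in which the diagnostic
consumes the heuristic search's output, while accuracy surfaces for
parsimony use the exhaustive engine. Diagnosis surfaces score a
replicate correct when (verdict = LBA) coincides with (the baseline
parsimony tree actually differs from the generating topology). For LBS
the grid offers the full p-scan (verdict via p\*) or a fixed sampling
frequency; in fixed-p mode a replicate is diagnosed LBA when a majority
of runs at that p move — the scan rule p\* < 0.5 would make any fixed
p ≥ 0.5 trivially negative, contradicting the intended
growing-detection-area behaviour.

Replicate seeds derive from (base seed, topology kind, α value, β value,
replicate index) through a seed sequence, so every cell is an independent
reproducible stream and any sub-grid of a study reproduces the full run's
cell values exactly.

Problem sizes: the shipped desk profile is a 5×5 lattice
(α, β ∈ {0.2, 0.6, 1.0, 1.4, 1.8}) with 20 replicates of length 1000;
the full-scale profile (20×20, 100 replicates, length 2000 — 40,000
datasets per topology kind) is provided but long-running. The acceptance
script uses the desk lattice with 10 replicates per cell.

## Known limitations

- Exhaustive enumeration and search are capped at 9 taxa (parsimony) and
  7 taxa (ML); the toolkit targets small zone studies, not general
  phylogenomics.
- The ML step never estimates model parameters; with a misspecified
  model its behaviour is unexplored here.
- The indel process is a stand-in with unstated-by-construction length
  distribution (geometric, mean 1); gap-aware conclusions should not
  lean on its fine structure.
- LBS's p\* is a heuristic evidence score, not a calibrated probability;
  its dependence on branch length (above) is inherent to the method.
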