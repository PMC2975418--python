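"""The alpha x beta branch-length grid experiment engine.

For every cell of a grid of (alpha, beta) branch lengths, datasets are
simulated on the corresponding zone tree and analyzed by the requested
methods; each cell records a percentage over replicates:

- ``mp_exhaustive`` / ``mp_tbr`` / ``ml``: topology accuracy (% of
  replicates whose inferred tree equals the generating topology; by
  default a replicate only counts as correct when the true topology is
  the *unique* optimum);
- ``lbe`` / ``lbe_no_ml``: % of replicates classified LBA, plus a
  correct-diagnosis surface (LBA verdict iff the baseline parsimony
  tree actually differs from the truth);
- ``lbs``: the same pair of surfaces for long-branch shortening, either
  with a full p-scan or at fixed sampling frequencies.

Replicate seeds are cell-local (derived from the base seed, the
topology kind, the cell's alpha/beta values and the replicate number),
so any sub-grid of a run reproduces exactly the same per-cell values.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gtr import GTRModel
from .lbe import LBEConfig, run_lbe
from .lbs import DEFAULT_FREQUENCIES, LBSConfig, run_lbs
from .likelihood import exhaustive_ml_search
from .parsimony import SearchResult, exhaustive_mp_search, tbr_search
from .simulate import FARRIS, FELSENSTEIN, ZoneSpec, make_zone_tree, simulate_alignment
from .trees import Tree, n_unrooted_topologies

KNOWN_METHODS = ("mp_exhaustive", "mp_tbr", "ml", "lbe", "lbe_no_ml", "lbs")
_KIND_CODE = {FELSENSTEIN: 0, FARRIS: 1}

__all__ = [
    "GridSpec",
    "GridResult",
    "run_grid",
    "mp_ml_agreement_grid",
    "write_grid_csv",
    "desk_profile",
    "full_profile",
    "random_guess_accuracy",
    "replicate_seed",
]


def _frange(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class GridSpec:
    """Configuration of one grid experiment."""

    alpha_values: tuple[float, ...] = _frange(0.1, 2.0, 0.1)
    beta_values: tuple[float, ...] = _frange(0.1, 2.0, 0.1)
    replicates: int = 100
    kind: str = FELSENSTEIN
    n_taxa: int = 6
    seq_length: int = 2000
    methods: tuple[str, ...] = ("mp_exhaustive",)
    model: GTRModel = field(default_factory=GTRModel.zone_study)
    base_seed: int = 0
    tie_policy: str = "strict"  # or "count-if-included"
    lbs_frequencies: tuple[float, ...] | None = None  # None = full scan
    lbs_runs_per_p: int = 3
    n_starts: int = 5

    def __post_init__(self):
        for vals, label in ((self.alpha_values, "alpha"), (self.beta_values, "beta")):
            vals = tuple(float(v) for v in vals)
            if not vals or any(not 0 < v <= 20 for v in vals):
                raise ValueError(f"{label} values must lie in (0, 20]")
            if list(vals) != sorted(vals):
                raise ValueError(f"{label} values must be ascending")
            object.__setattr__(self, f"{label}_values", vals)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = [m for m in self.methods if m not in KNOWN_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; known: {KNOWN_METHODS}")
        if self.kind not in _KIND_CODE:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.tie_policy not in ("strict", "count-if-included"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")

    @property
    def n_cells(self) -> int:
        return len(self.alpha_values) * len(self.beta_values)

    @property
    def n_datasets(self) -> int:
        """Total simulated datasets (cells x replicates)."""
        return self.n_cells * self.replicates


@dataclass(frozen=True)
class GridResult:
    """Per-method percentage matrices (alpha rows x beta columns)."""

    spec: GridSpec
    matrices: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)


def desk_profile(**overrides) -> GridSpec:
    """Reduced grid sized for a desk run: 5x5 cells, 20 replicates,
    sequence length 1000."""
    defaults = dict(
        alpha_values=(0.2, 0.6, 1.0, 1.4, 1.8),
        beta_values=(0.2, 0.6, 1.0, 1.4, 1.8),
        replicates=20,
        seq_length=1000,
    )
    defaults.update(overrides)
    return GridSpec(**defaults)


def full_profile(**overrides) -> GridSpec:
    """The full-scale study grid: 20x20 cells x 100 replicates x length
    2000 = 40,000 datasets per topology kind.  Long-running."""
    return GridSpec(**overrides)


def random_guess_accuracy(n_taxa: int) -> float:
    """Expected accuracy (%) of a uniform random topology pick."""
    return 100.0 / n_unrooted_topologies(n_taxa)


def replicate_seed(base_seed: int, kind: str, alpha: float, beta: float, rep: int) -> int:
    """Cell-local deterministic seed below 2**31.

    Keyed on the branch-length *values* (not grid indices) so that any
    sub-grid of a study reproduces exactly the same per-cell results.
    """
    ss = np.random.SeedSequence(
        entropy=int(base_seed) % (2**31),
        spawn_key=(_KIND_CODE[kind], int(round(alpha * 1e6)), int(round(beta * 1e6)), rep),
    )
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _is_correct(result: SearchResult, truth: Tree, tie_policy: str) -> bool:
    hits = any(t.topologies_equal(truth) for t in result.best_trees)
    if tie_policy == "strict":
        return hits and len(result.best_trees) == 1
    return hits


def run_grid(spec: GridSpec, progress: bool = False) -> GridResult:
    """Simulate and analyze every cell; returns percentage surfaces."""
    t_start = time.time()
    na, nb = len(spec.alpha_values), len(spec.beta_values)
    needs_tbr = any(m in spec.methods for m in ("mp_tbr", "lbe", "lbe_no_ml", "lbs"))
    counters = {}

    def bump(name, i, j, value):
        counters.setdefault(name, np.zeros((na, nb)))[i, j] += value

    for i, alpha in enumerate(spec.alpha_values):
        for j, beta in enumerate(spec.beta_values):
            zone = ZoneSpec(spec.kind, alpha, beta, spec.n_taxa)
            truth = make_zone_tree(zone)
            outgroup, qtaxa = zone.beta_taxa
            for r in range(spec.replicates):
                seed = replicate_seed(spec.base_seed, spec.kind, alpha, beta, r)
                aln = simulate_alignment(truth, spec.model, spec.seq_length, seed)
                tbr_res = (
                    tbr_search(aln, n_starts=spec.n_starts, seed=seed + 1)
                    if needs_tbr
                    else None
                )
                if "mp_exhaustive" in spec.methods:
                    res = exhaustive_mp_search(aln)
                    bump("mp_exhaustive_accuracy_pct", i, j, _is_correct(res, truth, spec.tie_policy))
                if "mp_tbr" in spec.methods:
                    bump("mp_tbr_accuracy_pct", i, j, _is_correct(tbr_res, truth, spec.tie_policy))
                if "ml" in spec.methods:
                    ml = exhaustive_ml_search(aln, spec.model)
                    ok = ml.tree.topologies_equal(truth) and not (
                        ml.tied and spec.tie_policy == "strict"
                    )
                    bump("ml_accuracy_pct", i, j, ok)
                for method, use_ml in (("lbe", True), ("lbe_no_ml", False)):
                    if method not in spec.methods:
                        continue
                    cfg = LBEConfig(
                        outgroup=outgroup,
                        qtaxa=qtaxa,
                        use_ml_step=use_ml,
                        search_mode="tbr",
                        n_starts=spec.n_starts,
                    )
                    mp_tree = tbr_res.best_trees[0]
                    out = run_lbe(aln, mp_tree, cfg, model=spec.model, seed=seed + 2)
                    is_lba = out.verdict == "LBA"
                    actually_lba = not mp_tree.topologies_equal(truth)
                    bump(f"{method}_lba_pct", i, j, is_lba)
                    bump(f"{method}_correct_pct", i, j, is_lba == actually_lba)
                if "lbs" in spec.methods:
                    freqs = spec.lbs_frequencies
                    cfg = LBSConfig(
                        outgroup=outgroup,
                        qtaxa=qtaxa,
                        sampling_frequencies=freqs if freqs else DEFAULT_FREQUENCIES,
                        runs_per_p=spec.lbs_runs_per_p,
                        search_mode="tbr",
                        n_starts=spec.n_starts,
                    )
                    out = run_lbs(aln, cfg, seed=seed + 3)
                    if freqs is not None and len(freqs) == 1:
                        # fixed-p diagnosis: moved in a majority of runs at that p
                        is_lba = out.per_p_move_rates[freqs[0]] >= 0.5
                    else:
                        is_lba = out.verdict == "LBA"
                    mp_tree = tbr_res.best_trees[0]
                    actually_lba = not mp_tree.topologies_equal(truth)
                    bump("lbs_lba_pct", i, j, is_lba)
                    bump("lbs_correct_pct", i, j, is_lba == actually_lba)
            if progress:
                print(f"cell alpha={alpha} beta={beta} done", flush=True)

    matrices = {k: 100.0 * v / spec.replicates for k, v in counters.items()}
    meta = {
        "n_datasets": spec.n_datasets,
        "runtime_s": round(time.time() - t_start, 2),
        "base_seed": spec.base_seed,
    }
    return GridResult(spec, matrices, meta)


def mp_ml_agreement_grid(spec: GridSpec) -> GridResult:
    """Per-cell comparison of parsimony and likelihood.

    Emits three surfaces: % of replicates where both methods return the
    same tree, % where only ML finds the truth, and % where only MP
    does; the remainder of each cell is "both wrong, differently".
    """
    t_start = time.time()
    na, nb = len(spec.alpha_values), len(spec.beta_values)
    same = np.zeros((na, nb))
    ml_only = np.zeros((na, nb))
    mp_only = np.zeros((na, nb))
    for i, alpha in enumerate(spec.alpha_values):
        for j, beta in enumerate(spec.beta_values):
            zone = ZoneSpec(spec.kind, alpha, beta, spec.n_taxa)
            truth = make_zone_tree(zone)
            for r in range(spec.replicates):
                seed = replicate_seed(spec.base_seed, spec.kind, alpha, beta, r)
                aln = simulate_alignment(truth, spec.model, spec.seq_length, seed)
                mp_res = exhaustive_mp_search(aln)
                ml_res = exhaustive_ml_search(aln, spec.model)
                mp_tree = mp_res.best_trees[0]
                mp_ok = _is_correct(mp_res, truth, spec.tie_policy)
                ml_ok = ml_res.tree.topologies_equal(truth) and not (
                    ml_res.tied and spec.tie_policy == "strict"
                )
                same[i, j] += mp_tree.topologies_equal(ml_res.tree)
                ml_only[i, j] += ml_ok and not mp_ok
                mp_only[i, j] += mp_ok and not ml_ok
    scale = 100.0 / spec.replicates
    matrices = {
        "both_same_pct": same * scale,
        "ml_correct_mp_wrong_pct": ml_only * scale,
        "mp_correct_ml_wrong_pct": mp_only * scale,
    }
    meta = {
        "n_datasets": spec.n_datasets,
        "runtime_s": round(time.time() - t_start, 2),
        "base_seed": spec.base_seed,
    }
    return GridResult(spec, matrices, meta)


def write_grid_csv(result: GridResult, directory) -> list:
    """One CSV per surface (rows=alpha, columns=beta, 1 decimal) plus a
    JSON metadata sidecar; returns the written paths."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = result.spec
    paths = []
    for name, mat in result.matrices.items():
        df = pd.DataFrame(mat, index=spec.alpha_values, columns=spec.beta_values)
        df.index.name = "alpha"
        path = directory / f"{name}.csv"
        df.to_csv(path, float_format="%.1f")
        paths.append(path)
    meta = {
        "spec": {
            "alpha_values": spec.alpha_values,
            "beta_values": spec.beta_values,
            "replicates": spec.replicates,
            "kind": spec.kind,
            "n_taxa": spec.n_taxa,
            "seq_length": spec.seq_length,
            "methods": spec.methods,
            "base_seed": spec.base_seed,
            "tie_policy": spec.tie_policy,
            "model": {
                "pi": spec.model.pi,
                "exch": spec.model.exch,
                "indel_rate": spec.model.indel_rate,
                "indel_length_mean": spec.model.indel_length_mean,
            },
        },
        **result.metadata,
    }
    meta_path = directory / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=list) + "\n")
    paths.append(meta_path)
    return paths


def plot_heatmap(result: GridResult, name: str, path) -> None:
    """Optional heatmap rendering of one surface (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = result.spec
    mat = result.matrices[name]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        mat,
        origin="lower",
        aspect="auto",
        vmin=0,
        vmax=100,
        cmap="viridis",
        extent=(
            spec.beta_values[0],
            spec.beta_values[-1],
            spec.alpha_values[0],
            spec.alpha_values[-1],
        ),
    )
    ax.set_xlabel("beta branch length")
    ax.set_ylabel("alpha branch length")
    ax.set_title(name)
    fig.colorbar(im, ax=ax, label="%")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
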