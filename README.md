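# longbranch

Tools for studying **long-branch attraction** (LBA) — the systematic error
where two long, non-sister branches of a phylogeny are erroneously grouped
as sisters — and for evaluating the two diagnostics proposed against it,
**Long Branch Extraction** (LBE) and **Long Branch Shortening** (LBS).

The package is built around six-taxon (and four-taxon) "zone" topologies:
three cherries joined to a central node, with internal and most pendant
edges of length α and two long pendant edges of length β (substitutions per
site). When the two β leaves are *not* sisters the tree is
**Felsenstein-like** (maximum parsimony is inconsistent there); when they
*are* sisters it is **Farris-like** (parsimony's bias masquerades as
accuracy). Everything needed to map these regimes is included:

- a GTR sequence simulator with an indel process (gaps as `-`),
- Fitch maximum parsimony with exhaustive (all (2n−5)!! topologies) and
  heuristic TBR searches,
- GTR maximum likelihood via the pruning algorithm with per-branch
  length optimization and exhaustive topology search,
- the LBE decision pipeline (outgroup extraction → qtaxa extraction → ML
  re-analysis → top-quartile branch test),
- the LBS pipeline (clade-ancestor reconstruction, binomial hybridization
  at sampling frequency *p*, re-search, and the scan producing *p\**),
- a grid engine that sweeps α, β over a lattice and emits per-cell
  percentage surfaces (accuracy, LBA-classification, correct diagnosis)
  as CSV matrices.

## Worked example

```python
import longbranch as lb

model = lb.GTRModel.zone_study()        # pi=(0.2,0.3,0.2,0.3) ACGT, lambda=0.1
truth = lb.make_zone_tree(lb.ZoneSpec("felsenstein_like", alpha=0.1, beta=1.8))
aln = lb.simulate_alignment(truth, model, length=1000, seed=22)

mp = lb.tbr_search(aln, seed=23)                 # heuristic parsimony
print(mp.best_score)                             # 1734
print(mp.best_trees[0].topologies_equal(truth))  # False  <- LBA artifact

res = lb.run_lbe(aln, mp.best_trees[0],
                 lb.LBEConfig(outgroup="T1", qtaxa="T2"),
                 model=model, seed=22)
print(res.verdict, res.terminated_at)            # LBA completed
print(res.branch_percentiles)                    # {'T1': 0.889, 'T2': 0.778}
```

The parsimony tree is wrong — the two β branches (T1, T2) were attracted —
and on this replicate LBE survives all four steps: both extraction
re-searches disagree with the pruned original, the ML tree disagrees with
the parsimony tree, and both suspect pendant branches rank in the top
quartile of the ML branch lengths (percentiles 0.889 and 0.778), so LBA is
the least refuted hypothesis. On most zone replicates, however, the
procedure stops early with `NOT_LBA` — reproducing the finding that LBE
masks the very region it was designed to detect.

A fuller sweep (the command-line interface mirrors the library):

```bash
longbranch simulate --kind farris_like --alpha 0.2 --beta 0.2 \
    --length 2000 --seed 1 --out aln.fasta
longbranch mp-search --aln aln.fasta --exhaustive
longbranch grid --profile desk --out-dir surfaces/
```

`grid` writes one CSV per surface (rows = α, columns = β, cell =
percentage) plus a `metadata.json` sidecar. The desk profile runs a 5×5
lattice with 20 replicates of length 1000; the `full` profile is the complete
20×20 × 100-replicate × length-2000 study (40,000 datasets per topology
kind — long-running).

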