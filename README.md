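# prer

Patient representations from **pairwise relative expression** of proteins on
protein–protein interaction (PPI) networks, with survival prediction and
feature-importance analysis built on top.

## The problem

Survival models for cancer cohorts are usually trained on individual
protein (or gene) expression levels. But proteins act through their
interactions: what often matters is not whether a protein is high or low in
absolute terms, but whether it is expressed *above or below its interaction
partners* in a given patient. This package encodes exactly that. For each
measured protein *i* and each measured protein *j* in *i*'s network
neighborhood, a patient *k* contributes the sign feature

```
x_{i,j}^(k) = +1  if  x_i^(k) > x_j^(k),   −1 otherwise
```

(with an optional ternary variant that assigns 0 when the two levels differ
by less than 10% of the compared neighbor). Neighborhoods are derived by
second-order biased random walks on the PPI network — the node2vec walk
with return parameter *p* and in-out parameter *q* (defaults
`p = q = 0.25`, walk length 100, 18 walks per source); a node belongs to
the neighborhood when it appears in at least two distinct walks. The
resulting sign matrix is a rank statistic: invariant to any monotone
per-patient transform, hence robust across platforms and normalisations.

On top of the representation the package provides the full evaluation
pipeline: univariate Cox screening (Wald p ≤ 0.05, fitted per training
split), random survival forests, Harrell's concordance index on repeated
80/20 holdouts, paired one-sided Wilcoxon signed-rank comparison of
representations with Benjamini–Hochberg correction, permutation feature
importance summed over models, protein-level aggregation
`s_i = (1/|P_i|) Σ f_{i,j}` with rank-difference analysis, Kaplan–Meier
grouping with log-rank tests, and a network-propagation baseline. A
synthetic-data module generates scale-free networks, edge-correlated
expression and right-censored survival whose hazard depends only on the
*ordering* of planted protein pairs, so every claim the package makes can
be tested end to end.

## Worked example

```python
from prer import SimConfig
from prer.benchmark import build_planted_study, paired_representation_benchmark

study = build_planted_study(SimConfig(n_proteins=400, n_measured=40,
                                      n_patients=200, seed=3))
bench = paired_representation_benchmark(study, repeats=25, n_trees=100, seed=3)
print(f"pairwise:   {bench['prer_mean']:.3f}")
print(f"individual: {bench['individual_mean']:.3f}")
print(f"p = {bench['p_prer_gt_individual']:.2g}")
```

prints

```
pairwise:   0.707
individual: 0.635
p = 1.1e-05
```

The cohort's hazard multiplies by `exp(1.5)` for each of three planted
network-adjacent pairs whose ordering is in its hazardous orientation —
survival depends on orderings, never on levels. Both representations are
evaluated on the same 25 random 80/20 splits; the pairwise sign features
reach a mean held-out C-index of 0.707 against 0.635 for raw expression
(0.5 would be chance), and the one-sided signed-rank test confirms the
improvement is systematic across splits rather than luck on a few.

The `examples/` directory has one short script per capability:
`01_simulate_and_encode.py` (generator → walks → encoding),
`02_survival_comparison.py` (the comparison above), and
`03_importance_analysis.py` (planted-pair recovery by summed permutation
importance, protein rank differences, KM grouping).

A `prer` command-line entry point mirrors the stages
(`simulate | walk | encode | evaluate | run`); `prer run --config run.yaml`
executes the whole pipeline on TSV inputs and writes C-index tables,
comparison verdicts, importance tables and a manifest that makes the run
reproducible.

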