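"""Recover planted pairs by permutation importance and rank proteins.

Fits several repeated-holdout survival forests on the pairwise features,
sums each feature's held-out permutation importance over the models, and
checks whether the planted pairs surface at the top.  Protein-level scores
(mean importance over a protein's pairs) are then ranked and compared with
the individual-expression ranking; a large positive rank difference marks a
protein that matters through its relative expression, not its level.
"""

from prer import SimConfig, SurvivalData, km_groups, protein_scores, rank_difference
from prer.benchmark import build_planted_study, planted_pair_recovery
from prer.encoding import pair_column
from prer.importance import importance_over_models
from prer.survival import SplitScheme, repeated_holdout

study = build_planted_study(SimConfig(n_proteins=400, n_measured=40,
                                      n_patients=250, seed=5))
planted = {pair_column(p) for p in study.truth.planted_pairs}
rec = planted_pair_recovery(study, n_models=5, top_k=10, seed=5)
table = rec["importance"].sort_values("importance", ascending=False)
print("top 10 pairwise features by summed permutation importance "
      "(* = planted):")
for name, row in table.head(10).iterrows():
    mark = " *" if name in planted else ""
    print(f"  {name:15s} {row['importance']:+.3f}{mark}")
print(f"recovered {rec['n_recovered']}/{rec['n_planted']} planted pairs in the top 10")

# protein-level ranking: pairwise score vs individual-expression importance
prot = protein_scores(table["importance"])
res_ind = repeated_holdout(study.expr, study.surv, SplitScheme(repeats=5, seed=5),
                           name="individual", n_trees=100, keep_models=True)
ind_imp = importance_over_models(res_ind, study.expr, study.surv, seed=5)
ranks = rank_difference(prot, ind_imp["importance"])
print("\nproteins ranked far higher by pairwise relations than by level "
      "(r_q - r_p > 0):")
print(ranks.head(5).round(3).to_string())

# the top planted feature splits patients into survival groups
top_col = next(c for c in table.index if c in planted)
p, _ = km_groups(study.prer[top_col], study.surv)
print(f"\nlog-rank p splitting patients by the sign of {top_col}: {p:.2g}")
print("patients with the pair in its hazardous orientation die measurably sooner")
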