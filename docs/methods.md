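# Methods

## The representation

Given an undirected protein–protein interaction (PPI) network `G = (V, E)`
and a measured panel `U ⊆ V` (e.g. an RPPA antibody panel), each patient is
encoded by pairwise relative expression: for every measured protein *i* and
every measured protein *j* in *i*'s network neighborhood,

```
x_{i,j} = +1  if x_i > x_j      (protein i above protein j in this patient)
          −1  otherwise          (ties fall in the −1 branch)
```

Because the features depend only on orderings, they are invariant to any
strictly increasing per-patient transform of the expression vector and
therefore portable across measurement platforms and normalisations.

A ternary variant maps a pair to 0 when `|x_i − x_j| < θ·|x_j|` (default
θ = 0.10), with *j* the compared neighbor. The absolute value in the
denominator keeps the dead-band well defined for the negative values that
replicate-normalised RPPA data can take. The boundary is strict: a
difference of exactly θ·|x_j| is outside the band.

### Neighborhoods from biased random walks

A protein's neighborhood is defined operationally by second-order
(node2vec-style) biased random walks. From current node *v* with previous
node *t*, the next node *x* is drawn with probability proportional to
`α_pq(t, x) · w_vx`, where `α = 1/p, 1, 1/q` for shortest-path distance
`d(t, x) = 0, 1, 2` respectively. Defaults: `p = q = 0.25`, walk length
`l = 100`, `r = 18` walks per source, unit edge weights (a flag allows the
confidence score as weight). Small *p* and *q* make walks community-seeking.
A node joins the neighborhood when it appears in **at least two distinct
walks** (distinct walks, not visits: a node visited many times in one walk
counts once). The threshold is exposed as `min_walks`. The first step of a
walk, which has no previous node, is uniform over the source's neighbors.
The source is excluded from its own neighborhood, since comparing a protein
with itself carries no information.

Walks are seeded per source — the stream for source *u* is keyed by
(global seed, CRC32 of *u*) — so neighborhoods do not depend on the order
in which sources are processed.

### Phospho-forms

Interaction databases do not represent phosphorylated states as separate
nodes, so a phospho-form (e.g. `STAT3PY705`) inherits the neighborhood of
its base node (`STAT3`), is paired with its own base protein and with all
measured proteins in the base node's neighborhood. Measured forms sharing a
base node are also paired with each other (switchable via
`pair_phospho_siblings`). An explicit measured-id → base-node mapping table
is preferred; when none is given, a `<base>P<residue-tokens>` suffix
heuristic (`…P` followed by `[STY]` + position groups) is used as fallback.

Ordered duplicates `(i, j)` / `(j, i)` encode the same comparison up to
sign, so only the canonical lexicographic orientation is kept; keeping both
would add perfectly anti-correlated columns that tree ensembles gain
nothing from.

## Network handling

Edge lists are TSV (`a<TAB>b[<TAB>confidence]`); missing confidence means
1.0. Self-loops are dropped, duplicate edges collapse to the maximum
confidence (conservative union of evidence), and edges below the confidence
threshold (default 0.1) are removed — an edge at exactly the threshold is
kept, reading "filtered if lower than" literally. Edge density is
`|E| / (|V|·(|V|−1)/2)`.

The propagation baseline diffuses expression per patient over the measured
subnetwork, `F ← αWF + (1−α)F₀` with `W = D^{−1/2} A D^{−1/2}`, α = 0.5,
tolerance 1e−6, iteration cap 1000. Measured proteins with no measured
interaction partner get an identity self-weight so their fixed point is the
observed value.

## Survival evaluation

The dataset is `D = {x, S, δ}` with observed time S and event indicator δ.
The protocol per repeat: simple random 80/20 train/test split, univariate
Cox proportional-hazards screen on the training split (Wald p ≤ 0.05
retained, boundary included), random survival forest on the retained
features, Harrell's C-index on the held-out split (risk ties credit 0.5;
pairs censored before the shorter time are not comparable). 100 repeats by
default. Splits are driven by a `SplitScheme` seed list so that two
representations evaluated under the same scheme see *identical* splits —
required for the paired signed-rank comparison. The screen is refit per
split, never on test outcomes; a split with fewer than two events on either
side is redrawn, and a repeat whose screen retains nothing falls back to the
full feature set (both logged).

The univariate screen is a Newton–Raphson fit of the Efron partial
likelihood, vectorised across all candidate features; it agrees with
lifelines' `CoxPHFitter` to ~1e−4 relative on coefficients (tested) and
makes screening thousands of pairwise features per split take milliseconds.
Constant features and non-convergent fits (|β| > 50, vanishing information —
typically complete separation) are skipped with a warning.

The forest delegates to scikit-survival's `RandomSurvivalForest` (log-rank
splitting, 1000 trees by default, `min_samples_leaf = 3`). The classical
`nsplit` knob (random candidate split points per variable) is accepted for
interface parity but the backend enumerates candidate splits exhaustively;
for sign-valued features the two strategies coincide, since each variable
admits at most two distinct thresholds.

Representations are compared with a one-sided Wilcoxon signed-rank test on
the paired C-index vectors, Benjamini–Hochberg adjusted across every test
in a report. "Win" means the adjusted p of the forward test is < 0.05,
"loss" the reverse, "tie" otherwise. Identical vectors short-circuit to
p = 1.

## Importance analysis

A feature's importance in one model is the drop in held-out C-index when
its column is permuted (`n_perm` permutations, default 1, seeded).
Importances are **summed** across the repeated-holdout models (features
screened out of a given model contribute 0 for it); a max-normalised column
is provided for display. A protein's score is the *mean* importance over
all pairs containing it, `s_i = (1/|P_i|) Σ_{(i,j)∈P_i} f_{i,j}`. Proteins
are ranked by descending score (dense 1-based ranks, ties broken
lexicographically for determinism); the rank difference `r_q − r_p`
(individual-expression rank minus pairwise rank) surfaces proteins whose
relative expression matters although their level does not. A phospho-form
and its base protein are ranked as separate entities. The top-k pairs by
summed importance (default k = 50) form an edge list for network
visualisation, and any sign feature can split patients into Kaplan–Meier
groups compared by a log-rank test (lifelines). Covariate-adjusted survival
curves are out of scope.

## Synthetic studies

The generator emulates the shape of a targeted proteomic survival study:

* **Network** — preferential attachment (Barabási–Albert, `m = 2`) for a
  heavy-tailed degree distribution, or a two-community planted partition;
  uniform [0, 1] edge confidences so the 0.1 filter is exercisable.
  Default 1000 nodes.
* **Panel** — 60 measured proteins by default, drawn around the planted
  pairs; with walk length 100 this yields ~900 pairwise features, matching
  the feature-per-protein ratio of a 131-protein panel producing ~1900.
  (On networks not much larger than the walk length, neighborhoods cover
  the whole graph and the pair set degenerates to all pairs.)
* **Expression** — multivariate normal with correlation ≈ 0.4 on network
  edges (correlation matrix `I + ρA` projected to PSD by clipping
  eigenvalues at 0.05 and renormalising), mimicking co-expression of
  interacting proteins.
* **Survival** — the hazard depends only on orderings:
  `h(k) = h₀ · exp(β · Σ_pairs 1[x_left > x_right])`, default h₀ = 0.1,
  β = 1.5, three disjoint network-adjacent planted pairs drawn from edges
  with confidence ≥ 0.5. Event times are exponential given the hazard;
  censoring is independent uniform on `[0, c]`, with `c` solved in closed
  form (`P(censor) = E[(1 − e^{−hc})/(hc)]`, decreasing in `c`, bisected)
  to hit the target rate, default 20%.

Because the signal is order-based, scaling any patient's expression by a
positive constant changes neither the true hazard nor any pairwise feature,
while it changes every individual-expression feature — the designed
separation that the benchmark exploits. What the generator does **not**
emulate: antibody-level measurement noise, batch structure, heavy-tailed or
missing expression values, informative censoring, and clinical covariates.
Passing benchmarks therefore show that the pipeline detects order-based
signal when it exists and stays honest when it does not — not that real
cohorts contain such signal.

## Benchmark problem sizes

The in-silico benchmarks (and the reproduction script) use 300-patient
cohorts with a 60-protein panel on a 1000-node network, 50 paired 80/20
repeats for the representation comparison, 5-model importance runs over 20
independent cohorts for planted-pair recovery, and 20 independent null
cohorts (β = 0, 10 repeats each) for the tie-rate control. Benchmark
forests use 100 trees (50 under the null) rather than 1000: across hundreds
of paired fits the comparison is driven by shared splits, and tree-sampling
noise cancels in the paired test, so the smaller ensembles leave the
conclusions unchanged while keeping a full benchmark run in minutes.

## Numerical and design notes

* Ties in expression map to −1 in the binary encoding (the "otherwise"
  branch); exposed as a knob.
* Walk dead-ends cannot occur on an undirected graph once a walk has moved,
  but are guarded: the walk is kept at its truncated length. An isolated
  source yields single-node walks plus a warning path.
* `d(t, x)` within one walk step is computed exactly: 0 iff `x = t`, 1 iff
  the edge `t–x` exists, else 2 — no other value is reachable.
* All stochastic components (walks, splits, forests, permutations,
  simulator) are seeded; derived seeds use `SeedSequence` spawning and stay
  below 2³¹.
* The evaluation protocol compares representations, not models: forest
  hyperparameters are fixed, not tuned per representation.

## Known limitations

* The pair-set conventions (unordered canonical pairs, phospho-sibling
  pairing) are one defensible reading of the construction; both switches
  are exposed because panel conventions differ.
* The Cox screen's Wald test is anti-conservative for sign features with
  very few events per level; the downstream forest is robust to a few
  falsely retained features, and the fallback path handles empty screens.
* Harrell's C with tied risks is capped well below 1 for a single binary
  predictor (within-group pairs score 0.5); model-quality checks therefore
  compare against the oracle ceiling of the true label rather than a fixed
  0.9 bound.
* The propagation baseline diffuses only over the measured subnetwork;
  diffusing over the full network and restricting afterwards is a
  reasonable alternative not implemented here.
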