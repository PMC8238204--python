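"""Permutation feature importance, protein-level aggregation and rank analysis.

A pairwise feature's importance in one fitted model is the drop in held-out
C-index when that feature's column is randomly permuted.  Importances are
summed over the repeated-holdout models; a protein's score is the mean
importance of all pairs it participates in,

    s_i = (1 / |P_i|) * sum_{(i,j) in P_i} f_{i,j},

and proteins are ranked by score in each representation.  The rank
difference r_q - r_p (individual-expression rank minus pairwise rank)
singles out proteins whose *relative* expression against their network
neighbors carries prognostic signal even though their own level does not.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .encoding import FeaturePair
from .survival import ModelResult, SurvivalData, concordance_index

__all__ = [
    "permutation_importance",
    "sum_model_importances",
    "protein_score",
    "protein_scores",
    "rank_proteins",
    "rank_difference",
    "prer_network",
    "km_groups",
]


def permutation_importance(
    model,
    X_test: pd.DataFrame,
    surv_test: SurvivalData,
    n_perm: int = 1,
    seed: int = 0,
) -> pd.Series:
    """Per-feature drop in test C-index under column permutation.

    Returns baseline C-index minus the mean C-index over ``n_perm``
    permutations of each feature column (positive = the model relied on it).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    X = X_test.to_numpy(dtype=float)
    baseline = concordance_index(model.predict(X), surv_test)
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j].copy()
        drops = np.empty(n_perm)
        for k in range(n_perm):
            X[:, j] = rng.permutation(col)
            drops[k] = baseline - concordance_index(model.predict(X), surv_test)
        X[:, j] = col
        out[j] = drops.mean()
    return pd.Series(out, index=X_test.columns, name="importance")


def importance_over_models(
    result: ModelResult,
    features: pd.DataFrame,
    surv: SurvivalData,
    n_perm: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of every feature, summed over a repeated-holdout run.

    ``result`` must have been produced with ``keep_models=True``.  Features a
    given model was not trained on (screened out on that split) contribute 0
    for that model.  The ``normalized`` column divides by the maximum summed
    importance (for display).
    """
    if result.models is None or result.test_indices is None:
        raise ValueError("ModelResult lacks fitted models; rerun with keep_models=True")
    total = pd.Series(0.0, index=features.columns)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(len(result.models)) >> 1]
    for model, te, retained, s in zip(
        result.models, result.test_indices, result.retained, child_seeds
    ):
        imp = permutation_importance(
            model, features.iloc[te][retained], surv.subset(te), n_perm=n_perm, seed=s
        )
        total = total.add(imp, fill_value=0.0)
    return sum_model_importances([total])


def sum_model_importances(per_model: Sequence[pd.Series]) -> pd.DataFrame:
    """Sum per-model importance series into a table with a max-normalized column."""
    total = per_model[0].astype(float).copy()
    for s in per_model[1:]:
        total = total.add(s, fill_value=0.0)
    maxval = total.abs().max()
    norm = total / maxval if maxval > 0 else total * 0.0
    return pd.DataFrame({"importance": total, "normalized": norm})


def _split_pair(col: str) -> tuple[str, str]:
    left, right = col.split("|", 1)
    return left, right


def protein_score(importances: pd.Series, protein: str) -> float:
    """Mean importance over all pairs containing the protein."""
    vals = [
        v for col, v in importances.items() if protein in _split_pair(col)
    ]
    if not vals:
        raise ValueError(f"protein {protein!r} participates in no pair")
    return float(np.mean(vals))


def protein_scores(importances: pd.Series) -> pd.Series:
    """Protein-level scores s_i for every protein appearing in a pair."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for col, v in importances.items():
        for prot in _split_pair(col):
            sums[prot] = sums.get(prot, 0.0) + float(v)
            counts[prot] = counts.get(prot, 0) + 1
    return pd.Series(
        {p: sums[p] / counts[p] for p in sums}, name="score"
    ).sort_index()


def rank_proteins(scores: pd.Series) -> pd.Series:
    """1-based ranks by descending score; ties broken by protein id."""
    order = sorted(scores.index, key=lambda p: (-scores[p], p))
    return pd.Series({p: r for r, p in enumerate(order, start=1)}, name="rank")


def rank_difference(
    prer_scores: pd.Series,
    individual_scores: pd.Series,
) -> pd.DataFrame:
    """Per-protein rank gap between the pairwise and individual representations.

    Ranks are computed within the shared protein universe; the frame is
    sorted by descending ``diff`` = r_q - r_p, so proteins that matter only
    through their pairwise relations come first.
    """
    shared = sorted(set(prer_scores.index) & set(individual_scores.index))
    if not shared:
        raise ValueError("the two rankings share no proteins")
    rp = rank_proteins(prer_scores[shared])
    rq = rank_proteins(individual_scores[shared])
    df = pd.DataFrame(
        {
            "prer_score": prer_scores[shared],
            "individual_score": individual_scores[shared],
            "r_p": rp[shared],
            "r_q": rq[shared],
        }
    )
    df["diff"] = df["r_q"] - df["r_p"]
    return df.sort_values(["diff", "r_p"], ascending=[False, True], kind="stable")


def prer_network(importances: pd.Series, k: int = 50) -> list[FeaturePair]:
    """Edges of the top-k pairwise features by importance.

    Returns one edge per top-k pair (ties broken by column name); the node
    set is exactly the proteins those pairs mention.  If fewer than k
    features exist, all are used.
    """
    if k > importances.size:
        import warnings

        warnings.warn(f"requested top {k} of {importances.size} features; using all")
        k = importances.size
    order = sorted(importances.index, key=lambda c: (-importances[c], c))
    return [FeaturePair(*_split_pair(c)) for c in order[:k]]


def km_groups(
    feature_column: pd.Series | np.ndarray,
    surv: SurvivalData,
) -> tuple[float, dict[int, KaplanMeierFitter]]:
    """Kaplan-Meier curves and a two-group log-rank test for a sign feature.

    Patients are grouped by the feature's value (-1 vs +1; a ternary 0 level
    forms its own group only if present, in which case the test compares the
    two sign groups).  Returns the log-rank p-value and fitted KM estimators
    keyed by group label.
    """
    vals = np.asarray(feature_column)
    if vals.shape[0] != surv.n:
        raise ValueError("feature column not aligned with survival data")
    groups = {}
    for lab in sorted(set(vals.tolist())):
        mask = vals == lab
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter(label=f"group {lab:+g}")
        km.fit(surv.time[mask], surv.event[mask])
        groups[int(lab)] = km
    sign_labels = [g for g in (-1, 1) if g in groups]
    if len(sign_labels) < 2:
        raise ValueError("need both -1 and +1 groups for a log-rank comparison")
    m_lo = vals == sign_labels[0]
    m_hi = vals == sign_labels[1]
    if surv.event[m_lo].sum() + surv.event[m_hi].sum() == 0:
        raise ValueError("no events in either group")
    res = logrank_test(
        surv.time[m_lo], surv.time[m_hi], surv.event[m_lo], surv.event[m_hi]
    )
    return float(res.p_value), groups
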