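"""End-to-end run orchestration: walk -> encode -> evaluate -> compare -> rank.

A run is described by a :class:`RunConfig` (loadable from YAML) naming the
input files, the walk and encoding parameters, the evaluation scheme, and
the representations to compare.  ``run_pipeline`` executes the stages,
logging counts at each one, and writes every result table plus a manifest
that echoes the full configuration, so a run is reproducible from its
manifest alone.

Representations:

  individual   raw per-protein expression values
  prer         binary pairwise sign features over walk neighborhoods
  prer-ternary ternary variant with a relative dead-band
  propagated   network-diffused expression (propagation baseline)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import importance as imp
from .encoding import (
    build_feature_pairs,
    encode_binary,
    encode_ternary,
    pair_column,
    propagate_expression,
)
from .network import (
    PPINetwork,
    ProteinMapping,
    load_edge_list,
    load_mapping,
    map_measured,
)
from .survival import ModelResult, SplitScheme, SurvivalData, compare_representations, repeated_holdout
from .walks import WalkConfig, build_neighborhoods, write_neighborhoods

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

KNOWN_REPRESENTATIONS = ("individual", "prer", "prer-ternary", "propagated")


@dataclass
class RunConfig:
    network: str = ""
    expression: str = ""
    survival: str = ""
    mapping: str | None = None
    outdir: str = "prer_run"
    confidence_threshold: float = 0.1
    walk: WalkConfig = field(default_factory=WalkConfig)
    ternary_threshold: float = 0.10
    propagation_alpha: float = 0.5
    repeats: int = 100
    train_fraction: float = 0.8
    cox_alpha: float = 0.05
    n_trees: int = 1000
    n_split: int = 10
    seed: int = 0
    representations: tuple[str, ...] = ("individual", "prer")
    importance_top_k: int = 50
    n_perm: int = 1
    compute_importance: bool = True

    def __post_init__(self) -> None:
        for rep in self.representations:
            if rep not in KNOWN_REPRESENTATIONS:
                raise ValueError(f"unknown representation {rep!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        walk = WalkConfig(**raw.pop("walk", {}))
        reps = tuple(raw.pop("representations", ("individual", "prer")))
        return cls(walk=walk, representations=reps, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["representations"] = list(self.representations)
        return d


def _load_inputs(cfg: RunConfig):
    net = load_edge_list(cfg.network, cfg.confidence_threshold)
    mapping = load_mapping(cfg.mapping) if cfg.mapping else ProteinMapping.identity()
    expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)
    surv_df = pd.read_csv(cfg.survival, sep="\t", index_col=0)
    surv_df = surv_df.loc[expr.index]  # align by patient id
    surv = SurvivalData.from_dataframe(surv_df.reset_index(), id_col=surv_df.index.name or "index")
    return net, mapping, expr, surv


def build_representations(
    expr: pd.DataFrame,
    net: PPINetwork,
    mapping: ProteinMapping,
    cfg: RunConfig,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Feature matrix per requested representation, plus stage diagnostics."""
    info: dict = {}
    measured_ids = list(expr.columns)
    U, unmapped = map_measured(measured_ids, mapping, net)
    if unmapped:
        logger.warning("unmapped measured proteins: %s", unmapped)
    info["n_measured"] = len(measured_ids)
    info["n_mapped_nodes"] = len(U)
    info["unmapped"] = unmapped

    features: dict[str, pd.DataFrame] = {}
    need_pairs = any(r.startswith("prer") for r in cfg.representations)
    if need_pairs:
        wcfg = dataclasses.replace(cfg.walk, seed=cfg.seed)
        nbrs = build_neighborhoods(sorted(U), net, wcfg, measured=U)
        pairs = build_feature_pairs(nbrs, measured_ids, mapping)
        logger.info("derived %d neighborhoods -> %d pairwise features", len(nbrs), len(pairs))
        info["n_pairs"] = len(pairs)
        info["_neighborhoods"] = nbrs
        if not pairs:
            raise ValueError("no pairwise features: every neighborhood is empty")
        if "prer" in cfg.representations:
            features["prer"] = encode_binary(expr, pairs)
        if "prer-ternary" in cfg.representations:
            features["prer-ternary"] = encode_ternary(expr, pairs, cfg.ternary_threshold)
    if "individual" in cfg.representations:
        features["individual"] = expr
    if "propagated" in cfg.representations:
        features["propagated"] = propagate_expression(
            expr, net, mapping, alpha=cfg.propagation_alpha
        )
    return features, info


def run_pipeline(cfg: RunConfig, inputs=None) -> Path:
    """Execute the full pipeline and return the run directory.

    ``inputs`` may supply pre-built ``(net, mapping, expr, surv)`` (e.g.
    from the simulator); otherwise they are read from the configured paths.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    net, mapping, expr, surv = inputs if inputs is not None else _load_inputs(cfg)
    logger.info("network: %s", net.summary())

    features, info = build_representations(expr, net, mapping, cfg)
    nbrs = info.pop("_neighborhoods", None)
    if nbrs is not None:
        write_neighborhoods(nbrs, out / "neighborhoods.tsv")

    scheme = SplitScheme(repeats=cfg.repeats, train_fraction=cfg.train_fraction, seed=cfg.seed)
    keep = cfg.compute_importance
    results: dict[str, ModelResult] = {}
    for rep in cfg.representations:
        logger.info("evaluating representation %r (%d features)", rep, features[rep].shape[1])
        results[rep] = repeated_holdout(
            features[rep],
            surv,
            scheme,
            name=rep,
            cox_alpha=cfg.cox_alpha,
            n_trees=cfg.n_trees,
            n_split=cfg.n_split,
            keep_models=keep and rep in ("prer", "individual"),
        )
    cidx = pd.DataFrame({rep: r.cindices for rep, r in results.items()})
    cidx.to_csv(out / "cindices.tsv", sep="\t", index_label="repeat")

    if len(results) >= 2:
        report = compare_representations(results)
        report.to_csv(out / "comparison.tsv", sep="\t", index=False)

    if cfg.compute_importance and "prer" in results:
        prer_imp = imp.importance_over_models(
            results["prer"], features["prer"], surv, n_perm=cfg.n_perm, seed=cfg.seed
        )
        prer_imp.to_csv(out / "prer_feature_importance.tsv", sep="\t", index_label="pair")
        prot = imp.protein_scores(prer_imp["importance"])
        if "individual" in results:
            ind_imp = imp.importance_over_models(
                results["individual"], features["individual"], surv,
                n_perm=cfg.n_perm, seed=cfg.seed,
            )
            ranks = imp.rank_difference(prot, ind_imp["importance"])
            ranks.to_csv(out / "protein_rank_difference.tsv", sep="\t", index_label="protein")
        top = imp.prer_network(prer_imp["importance"], k=min(cfg.importance_top_k, len(prer_imp)))
        with open(out / "prer_network.tsv", "w") as fh:
            for pair in top:
                fh.write(f"{pair.left}\t{pair.right}\n")

    manifest = {
        "config": cfg.to_dict(),
        "network_summary": net.summary(),
        "stage_info": {k: v for k, v in info.items() if not k.startswith("_")},
        "split_seeds": scheme.split_seeds(),
        "cindex_summary": {rep: r.summary() for rep, r in results.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
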