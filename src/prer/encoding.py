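"""Pairwise relative-expression (PRER) feature encoding and the diffusion baseline.

Given per-patient expression over a measured panel and walk-derived
neighborhoods on the interaction network, each feature compares one measured
protein against one measured protein in its network neighborhood:

    x_{i,j} = +1 if protein i is expressed above protein j in this patient,
              -1 otherwise (ties fall in the -1 branch).

The ternary variant adds a dead-band: the feature is 0 when the two levels
differ by less than a fraction (default 10%) of the compared neighbor's
level.  Because features depend only on orderings they are invariant to any
strictly increasing per-patient transform of the expression values.

Phospho-forms are not separate network nodes, so a phospho-form inherits its
base protein's neighborhood, is compared with its own base protein, and (by
default) with the other measured phospho-forms of the same base.

``propagate_expression`` implements the network-propagation baseline:
per-patient expression is diffused over the measured subnetwork by insulated
heat diffusion, F <- alpha W F + (1 - alpha) F0 with W the symmetrically
degree-normalized adjacency.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .network import PPINetwork, ProteinMapping
from .walks import Neighborhood

__all__ = [
    "FeaturePair",
    "build_feature_pairs",
    "encode_binary",
    "encode_ternary",
    "propagate_expression",
    "pair_column",
]


class FeaturePair(NamedTuple):
    """An unordered pair of measured protein ids in canonical (lexicographic) order."""

    left: str
    right: str

    @classmethod
    def canonical(cls, a: str, b: str) -> "FeaturePair":
        if a == b:
            raise ValueError(f"cannot pair protein {a!r} with itself")
        return cls(a, b) if a < b else cls(b, a)


def pair_column(pair: FeaturePair) -> str:
    return f"{pair.left}|{pair.right}"


def build_feature_pairs(
    neighborhoods: Mapping[str, Neighborhood],
    measured_ids: Sequence[str],
    mapping: ProteinMapping | None = None,
    *,
    pair_phospho_siblings: bool = True,
) -> list[FeaturePair]:
    """Enumerate the canonical feature pairs implied by the neighborhoods.

    ``neighborhoods`` is keyed by network base node (one neighborhood per
    measured base node).  A measured id pairs with every measured id whose
    base node lies in its base node's measured neighborhood.  Measured forms
    sharing a base node (a protein and its phospho-forms) are additionally
    paired with each other unless ``pair_phospho_siblings`` is False.

    The (i,j)/(j,i) duplicates encode the same comparison up to sign, so only
    the canonical orientation is kept; the output is sorted for determinism.
    """
    mapping = mapping or ProteinMapping.identity()
    by_base: dict[str, list[str]] = {}
    for mid in measured_ids:
        by_base.setdefault(mapping.base_node(mid), []).append(mid)

    pairs: set[FeaturePair] = set()
    for mid in measured_ids:
        base = mapping.base_node(mid)
        nbh = neighborhoods.get(base)
        if nbh is not None:
            for nbr_base in nbh.measured_members:
                for other in by_base.get(nbr_base, ()):
                    if other != mid:
                        pairs.add(FeaturePair.canonical(mid, other))
        if pair_phospho_siblings:
            for sibling in by_base.get(base, ()):
                if sibling != mid:
                    pairs.add(FeaturePair.canonical(mid, sibling))
    return sorted(pairs)


def _check_columns(expr: pd.DataFrame, pairs: Iterable[FeaturePair]) -> None:
    cols = set(expr.columns)
    for p in pairs:
        for prot in p:
            if prot not in cols:
                raise KeyError(f"protein {prot!r} has no expression column")


def encode_binary(expr: pd.DataFrame, pairs: Sequence[FeaturePair]) -> pd.DataFrame:
    """Sign-encode each pair: +1 where left > right, -1 otherwise (incl. ties)."""
    _check_columns(expr, pairs)
    data = {
        pair_column(p): np.where(expr[p.left].to_numpy() > expr[p.right].to_numpy(), 1, -1)
        for p in pairs
    }
    return pd.DataFrame(data, index=expr.index, dtype=np.int8)


def encode_ternary(
    expr: pd.DataFrame,
    pairs: Sequence[FeaturePair],
    rel_threshold: float = 0.10,
) -> pd.DataFrame:
    """Ternary encoding with a relative dead-band around equality.

    The entry is 0 when |x_i - x_j| < rel_threshold * |x_j|, where j is the
    pair's right (compared-neighbor) protein; the absolute value makes the
    band well defined for the negative values that normalized RPPA data can
    take.  Outside the band the entry is the binary sign.
    """
    if rel_threshold < 0:
        raise ValueError("rel_threshold must be >= 0")
    _check_columns(expr, pairs)
    data = {}
    for p in pairs:
        xi = expr[p.left].to_numpy(dtype=float)
        xj = expr[p.right].to_numpy(dtype=float)
        sign = np.where(xi > xj, 1, -1)
        band = np.abs(xi - xj) < rel_threshold * np.abs(xj)
        data[pair_column(p)] = np.where(band, 0, sign)
    return pd.DataFrame(data, index=expr.index, dtype=np.int8)


def propagate_expression(
    expr: pd.DataFrame,
    net: PPINetwork,
    mapping: ProteinMapping | None = None,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Diffuse expression over the measured subnetwork (propagation baseline).

    The graph is restricted to the measured proteins: two measured ids are
    adjacent when their base nodes interact.  Iterates
    ``F <- alpha W F + (1 - alpha) F0`` with W = D^{-1/2} A D^{-1/2} until the
    largest per-entry change drops below ``tol``.  A measured protein with no
    measured interaction partner keeps its observed value exactly.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    mapping = mapping or ProteinMapping.identity()
    cols = list(expr.columns)
    base = {c: mapping.base_node(c) for c in cols}
    n = len(cols)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if net.graph.has_node(base[cols[i]]) and net.has_edge(base[cols[i]], base[cols[j]]):
                A[i, j] = A[j, i] = 1.0
    deg = A.sum(axis=1)
    W = np.zeros_like(A)
    nz = deg > 0
    dinv = np.zeros(n)
    dinv[nz] = 1.0 / np.sqrt(deg[nz])
    W[np.ix_(nz, nz)] = A[np.ix_(nz, nz)] * np.outer(dinv[nz], dinv[nz])
    # isolated proteins: identity self-weight so the fixed point is F = F0
    W[~nz, ~nz] = 1.0

    F0 = expr.to_numpy(dtype=float).T  # proteins x patients
    F = F0.copy()
    for _ in range(max_iter):
        F_next = alpha * (W @ F) + (1 - alpha) * F0
        delta = np.abs(F_next - F).max()
        F = F_next
        if delta < tol:
            return pd.DataFrame(F.T, index=expr.index, columns=expr.columns)
    raise RuntimeError(f"propagation did not converge in {max_iter} iterations (residual {delta:.3g})")
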