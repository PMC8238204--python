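"""Second-order biased random walks and walk-derived neighborhoods.

A protein's neighborhood is defined operationally: run ``r`` biased random
walks of fixed length ``l`` from the protein's node and keep every other
node that shows up in at least two distinct walks.  The walk is the
second-order (node2vec-style) walk: the distribution of the next node x,
given current node v and previous node t, is proportional to

    alpha_pq(t, x) * w_vx,   alpha_pq = 1/p if d(t,x) = 0
                                        1   if d(t,x) = 1
                                        1/q if d(t,x) = 2

where d(t, x) is the shortest-path distance between the previous node and
the candidate (within one step it can only be 0, 1 or 2).  Small p and q
(default 0.25 each) bias walks toward revisiting and toward community
structure around the source.  The first step of a walk, which has no
previous node, is uniform over the source's neighbors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import PPINetwork

__all__ = [
    "WalkConfig",
    "WalkSet",
    "Neighborhood",
    "transition_bias",
    "transition_probs",
    "sample_walks",
    "derive_neighborhood",
    "build_neighborhoods",
]

NO_PREVIOUS = None  # sentinel: first step of a walk has no previous node


@dataclass(frozen=True)
class WalkConfig:
    """Walk hyperparameters.

    p : return parameter; small p steers walks back toward visited nodes.
    q : in-out parameter; small q lets walks range outward (DFS-like).
    l : number of nodes per walk, including the source.
    r : walks sampled per source node.
    min_walks : a node joins the neighborhood when it appears in at least
        this many distinct walks (default 2).
    """

    p: float = 0.25
    q: float = 0.25
    l: int = 100
    r: int = 18
    seed: int = 0
    min_walks: int = 2

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be > 0")
        if self.l < 2 or self.r < 1:
            raise ValueError("need walk length >= 2 and at least one walk")


@dataclass
class WalkSet:
    """The walks sampled from one source node."""

    source: str
    walks: list[list[str]]

    def __len__(self) -> int:
        return len(self.walks)


@dataclass
class Neighborhood:
    """Walk-derived neighborhood of a source protein.

    ``members`` is N_u (source excluded); ``measured_members`` is the subset
    of members that are also measured base nodes, M_u = N_u ∩ U.
    """

    source: str
    members: set[str] = field(default_factory=set)
    measured_members: set[str] = field(default_factory=set)


def transition_bias(d_tx: int, cfg: WalkConfig) -> float:
    """Second-order walk bias alpha_pq as a function of d(t, x)."""
    if d_tx == 0:
        return 1.0 / cfg.p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / cfg.q
    raise ValueError(f"d_tx must be 0, 1 or 2, got {d_tx}")


def transition_probs(
    t: str | None,
    v: str,
    net: PPINetwork,
    cfg: WalkConfig,
) -> dict[str, float]:
    """Next-step distribution over the neighbors of v given previous node t.

    With ``t is None`` (first step of a walk) the distribution is uniform
    over neighbors.  Otherwise each neighbor x is weighted by
    ``alpha_pq(t, x) * w_vx`` and the weights are normalized.
    """
    nbrs = net.neighbors(v)
    if not nbrs:
        raise ValueError(f"node {v!r} is isolated: walk hits a dead end")
    if t is NO_PREVIOUS:
        u = 1.0 / len(nbrs)
        return {x: u for x in nbrs}
    weights = {}
    for x in nbrs:
        if x == t:
            d = 0
        elif net.has_edge(t, x):
            d = 1
        else:
            d = 2
        weights[x] = transition_bias(d, cfg) * net.weight(v, x)
    z = sum(weights.values())
    return {x: w / z for x, w in weights.items()}


def _source_rng(source: str, seed: int) -> np.random.Generator:
    # keyed by (global seed, source id) so results don't depend on the order
    # in which sources are processed
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(source.encode())]))


def sample_walks(source: str, net: PPINetwork, cfg: WalkConfig) -> WalkSet:
    """Sample ``cfg.r`` biased walks of length ``cfg.l`` starting at source.

    Deterministic for a fixed (seed, source) pair.  An isolated source yields
    r single-node walks.
    """
    if source not in net.graph:
        raise KeyError(f"source {source!r} not in network")
    rng = _source_rng(source, cfg.seed)
    # cache per-(t, v) distributions: walks revisit the same transitions a lot
    cache: dict[tuple[str | None, str], tuple[list[str], np.ndarray]] = {}

    def step(t: str | None, v: str) -> str:
        key = (t, v)
        if key not in cache:
            probs = transition_probs(t, v, net, cfg)
            cache[key] = (list(probs.keys()), np.array(list(probs.values())))
        nodes, pvec = cache[key]
        return nodes[rng.choice(len(nodes), p=pvec)]

    walks: list[list[str]] = []
    isolated = net.degree(source) == 0
    for _ in range(cfg.r):
        walk = [source]
        if not isolated:
            prev: str | None = NO_PREVIOUS
            while len(walk) < cfg.l:
                cur = walk[-1]
                if net.degree(cur) == 0:  # defensive: cannot occur once moving
                    break
                nxt = step(prev, cur)
                walk.append(nxt)
                prev = cur
        walks.append(walk)
    return WalkSet(source=source, walks=walks)


def derive_neighborhood(
    ws: WalkSet,
    measured: Iterable[str] = (),
    min_walks: int = 2,
) -> Neighborhood:
    """Select nodes appearing in at least ``min_walks`` distinct walks.

    Counts distinct walks, not total visits: a node visited many times within
    a single walk still counts once.  The source itself is excluded.
    ``measured`` is the set U of measured base nodes used to compute M_u.
    """
    if len(ws.walks) < 2:
        raise ValueError("need at least 2 walks to derive a neighborhood")
    counts: dict[str, int] = {}
    for walk in ws.walks:
        for node in set(walk):
            counts[node] = counts.get(node, 0) + 1
    members = {n for n, c in counts.items() if c >= min_walks and n != ws.source}
    mset = set(measured)
    return Neighborhood(
        source=ws.source,
        members=members,
        measured_members=members & mset,
    )


def build_neighborhoods(
    sources: Sequence[str],
    net: PPINetwork,
    cfg: WalkConfig,
    measured: Iterable[str] | None = None,
) -> dict[str, Neighborhood]:
    """Walk-derived neighborhood for every source node (typically U itself)."""
    mset = set(measured) if measured is not None else set(sources)
    out: dict[str, Neighborhood] = {}
    for s in sources:
        ws = sample_walks(s, net, cfg)
        out[s] = derive_neighborhood(ws, mset, min_walks=cfg.min_walks)
    return out


def write_neighborhoods(nbrs: Mapping[str, Neighborhood], path) -> None:
    """TSV dump: source<TAB>comma-joined members (sorted for determinism)."""
    with open(path, "w") as fh:
        for s in sorted(nbrs):
            fh.write(f"{s}\t{','.join(sorted(nbrs[s].members))}\n")
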