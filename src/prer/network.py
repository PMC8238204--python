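"""Protein-protein interaction network I/O and queries.

The network is an undirected graph whose nodes are proteins and whose edges
are catalogued interactions, each carrying a confidence score in [0, 1].
Public PPI resources (InBioMap, IntAct, STRING, ...) all export some variant
of a tab-separated edge list, which is the input format here.  Low-confidence
edges are filtered at load time; by default every retained edge gets unit
weight for the random-walk machinery, with an option to use the confidence
score as the walk weight instead.

Measured proteins (e.g. an RPPA antibody panel) are mapped onto network
nodes through a :class:`ProteinMapping`.  Phosphorylated forms such as
``STAT3PY705`` do not exist as separate nodes in interaction databases, so
they map to their unphosphorylated base node (``STAT3``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "PPINetwork",
    "ProteinMapping",
    "EdgeListParseError",
    "load_edge_list",
    "write_edge_list",
    "edge_density",
    "map_measured",
    "load_mapping",
]

# Phospho-form ids like EGFRPY1173, 4EBP1PS65, P38PT180Y182: base followed by
# a single P and one or more residue tokens (amino-acid letter + position).
_PHOSPHO_RE = re.compile(r"^(?P<base>.+?)P(?P<sites>(?:[STY]\d+)+)$")


class EdgeListParseError(ValueError):
    """Raised when an edge-list row cannot be parsed; carries the line number."""


@dataclass
class PPINetwork:
    """Undirected confidence-scored interaction network.

    Wraps a :class:`networkx.Graph`; edge attributes are ``confidence``
    (in [0, 1]) and ``weight`` (strictly positive, 1.0 unless confidence
    weighting was requested at load time).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def neighbors(self, v: str) -> list[str]:
        return list(self.graph.neighbors(v))

    def degree(self, v: str) -> int:
        return self.graph.degree(v)

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def confidence(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["confidence"]

    def summary(self) -> str:
        return (
            f"|V|={self.n_nodes} |E|={self.n_edges} "
            f"density={edge_density(self):.6f}"
            if self.n_nodes >= 2
            else f"|V|={self.n_nodes} |E|={self.n_edges}"
        )


def load_edge_list(
    path: str | Path,
    confidence_threshold: float = 0.1,
    *,
    use_confidence_as_weight: bool = False,
) -> PPINetwork:
    """Read a TSV edge list and return the filtered network.

    Each row is ``protein_a<TAB>protein_b[<TAB>confidence]``.  Rows without a
    confidence column are treated as confidence 1.0.  Self-loops are dropped,
    duplicate edges are collapsed keeping the maximum confidence, and edges
    with confidence strictly below ``confidence_threshold`` are removed
    (an edge at exactly the threshold is kept).

    Raises
    ------
    EdgeListParseError
        If a row has fewer than two columns or a non-numeric confidence;
        the message names the offending line number.
    ValueError
        If the network is empty after filtering.
    """
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError(f"confidence_threshold must be in [0, 1], got {confidence_threshold}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListParseError(
                    f"line {lineno}: expected at least two tab-separated columns, got {line!r}"
                )
            a, b = parts[0].strip(), parts[1].strip()
            if len(parts) >= 3 and parts[2].strip():
                try:
                    conf = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"line {lineno}: confidence {parts[2]!r} is not a number"
                    ) from exc
            else:
                conf = 1.0
            if a == b:
                continue  # self-loop: a protein is never its own neighbor
            if g.has_edge(a, b):
                conf = max(conf, g.edges[a, b]["confidence"])
            g.add_edge(a, b, confidence=conf)
    # filter after collapsing duplicates so that max-confidence wins
    drop = [(u, v) for u, v, c in g.edges(data="confidence") if c < confidence_threshold]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        raise ValueError(
            f"no edges remain after filtering at confidence >= {confidence_threshold}"
        )
    for u, v, data in g.edges(data=True):
        data["weight"] = data["confidence"] if use_confidence_as_weight else 1.0
    return PPINetwork(g)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the network as ``a<TAB>b<TAB>confidence`` rows, canonically sorted."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\t{net.confidence(u, v):g}\n")


def edge_density(net: PPINetwork) -> float:
    """Fraction of realised edges: |E| / (|V| (|V|-1) / 2)."""
    n = net.n_nodes
    if n < 2:
        raise ValueError(f"edge density undefined for |V|={n} < 2")
    return net.n_edges / (n * (n - 1) / 2)


@dataclass
class ProteinMapping:
    """Maps measured protein ids onto network base nodes.

    ``table[measured_id] = base_node_id``.  A measured id is a phospho-form
    when its base node differs from the id itself (or when the fallback
    heuristic recognises a ``<base>P<residues>`` suffix).
    """

    table: dict[str, str] = field(default_factory=dict)

    def base_node(self, measured_id: str) -> str:
        if measured_id in self.table:
            return self.table[measured_id]
        m = _PHOSPHO_RE.match(measured_id)
        if m and not self.table:
            # heuristic only when no explicit table was supplied
            return m.group("base")
        return measured_id

    def is_phospho(self, measured_id: str) -> bool:
        return self.base_node(measured_id) != measured_id

    def phospho_label(self, measured_id: str) -> str:
        if not self.is_phospho(measured_id):
            return ""
        base = self.base_node(measured_id)
        return measured_id[len(base):] if measured_id.startswith(base) else measured_id

    @classmethod
    def identity(cls) -> "ProteinMapping":
        return cls({})


def load_mapping(path: str | Path) -> ProteinMapping:
    """Read a two-column TSV ``measured_id<TAB>base_node``."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise EdgeListParseError(f"line {lineno}: expected measured_id<TAB>base_node")
            measured, base = parts[0].strip(), parts[1].strip()
            if measured in table and table[measured] != base:
                raise ValueError(f"line {lineno}: {measured} mapped to two base nodes")
            table[measured] = base
    return ProteinMapping(table)


def map_measured(
    measured_ids: Sequence[str] | Iterable[str],
    mapping: ProteinMapping,
    net: PPINetwork,
) -> tuple[set[str], list[str]]:
    """Split measured ids into the mappable set U and the unmapped remainder.

    Returns ``(mapped, unmapped)`` where ``mapped`` is the set of network
    base nodes covered by at least one measured protein (the source set U)
    and ``unmapped`` lists, in input order, ids whose base node is absent
    from the network.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for mid in measured_ids:
        base = mapping.base_node(mid)
        if base in net.graph:
            mapped.add(base)
        else:
            unmapped.append(mid)
    return mapped, unmapped
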