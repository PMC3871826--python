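"""Trait association networks.

Nodes are traits annotated by expression level; edges carry a signed weight
(a Pearson correlation or an sPLS similarity score) and remember which method
produced them.  Networks are undirected: (a, b) and (b, a) denote the same
edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .panel import PanelError

EDGE_SOURCES = ("pearson", "spls")


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    weight: float
    source: str = "pearson"

    def key(self) -> tuple:
        return (min(self.node_a, self.node_b), max(self.node_a, self.node_b))


@dataclass
class TraitNetwork:
    """Weighted signed trait network.

    ``nodes`` maps trait_id -> level; ``edges`` is a list of :class:`Edge`.
    """

    nodes: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.node_a == e.node_b:
                raise PanelError(f"self-edge on {e.node_a!r}")
            if e.source not in EDGE_SOURCES:
                raise PanelError(f"unknown edge source {e.source!r}")
            if e.key() in seen:
                raise PanelError(f"duplicate edge {e.key()}")
            seen.add(e.key())
            for n in (e.node_a, e.node_b):
                self.nodes.setdefault(n, "unknown")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> set:
        return {e.key() for e in self.edges}

    def node_set(self) -> set:
        return set(self.nodes)

    def degree(self) -> dict:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            d[e.node_a] += 1
            d[e.node_b] += 1
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, level in self.nodes.items():
            g.add_node(node, level=level)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, weight=float(e.weight), source=e.source)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "TraitNetwork":
        nodes = {n: g.nodes[n].get("level", "unknown") for n in g.nodes}
        edges = [
            Edge(a, b, float(d["weight"]), d.get("source", "pearson"))
            for a, b, d in g.edges(data=True)
        ]
        return cls(nodes=nodes, edges=edges)
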