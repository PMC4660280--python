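"""Simple undirected protein network container.

A :class:`ProteinNetwork` is a labelled, simple (no self-loops, no parallel
edges), undirected, unweighted graph over protein identifier strings.  It is a
thin wrapper around :class:`networkx.Graph` so the rest of the package can use
the networkx algorithm suite while keeping the invariants in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = ["ProteinNetwork"]


@dataclass
class ProteinNetwork:
    """Labelled simple undirected graph over protein identifiers.

    Parameters
    ----------
    label:
        Provenance name, e.g. ``"autophagy"``, ``"mitochondrial"``,
        ``"union"`` or ``"background"``.
    graph:
        Underlying :class:`networkx.Graph`.  Self-loops are rejected;
        parallel edges cannot exist in a ``networkx.Graph``.
    """

    label: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(
                f"network {self.label!r} contains self-loops: {loops[:3]}"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        label: str,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "ProteinNetwork":
        """Build a network from unordered identifier pairs.

        ``(a, b)`` and ``(b, a)`` collapse to one edge; multiplicity is
        discarded; self-pairs ``(a, a)`` contribute the node but no edge.
        ``nodes`` may add isolated nodes.
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                g.add_node(a)
            else:
                g.add_edge(a, b)
        return cls(label, g)

    # -- views -------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as canonically ordered (sorted) identifier pairs."""
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __iter__(self) -> Iterator[str]:
        return iter(self.graph)

    def induced(self, nodes: Iterable[str], label: str) -> "ProteinNetwork":
        """Induced subgraph on ``nodes`` (every edge with both ends kept)."""
        return ProteinNetwork(label, nx.Graph(self.graph.subgraph(nodes)))

    # -- serialization -----------------------------------------------------

    def to_edgelist_tsv(self, path: str | Path) -> None:
        """Write a two-column TSV edge list in deterministic sorted order."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\n")
            for a, b in sorted(self.edge_set()):
                fh.write(f"{a}\t{b}\n")

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path), named_key_ids=True)
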