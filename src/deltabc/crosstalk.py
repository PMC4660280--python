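"""Union networks, betweenness centrality and the ΔBC crosstalk statistic.

Betweenness centrality (BC) of node *v* counts, over unordered node pairs
(s, t) with s ≠ v ≠ t, the fraction of shortest s–t paths on which *v* is an
interior node:

    BC(v) = Σ_{s<t} σ_st(v) / σ_st

with σ_st the number of shortest s–t paths and σ_st(v) those through *v*.
Pairs in different components contribute nothing.  Values are kept in raw
pair-count units by default; an optional display normalization divides by
(n−1)(n−2)/2.

The crosstalk statistic for two process sub-networks A and M and their
union U is

    ΔBC(v) = BC_U(v) − BC_A(v) − BC_M(v)

where a node absent from a sub-network contributes 0 for that term (it has
no BC there).  ΔBC is computed on unnormalized values only: the three
networks differ in size, so the subtraction is dimensionally coherent only
in raw pair counts.  High ΔBC marks nodes whose path-brokering role emerges
only when the two processes are combined — crosstalk candidates.

Two union constructions are provided.  ``union_network`` is the plain graph
union (node and edge sets united).  ``induced_union`` closes the united node
set over the background interactome's edges, the same "all edges between the
sampled nodes" convention the sampling step uses; it is the pipeline default
because two nearly node-disjoint sub-networks otherwise yield a disconnected
union in which ΔBC is identically zero and no crosstalk node is detectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .errors import ConsistencyError
from .network import ProteinNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityTable",
    "DeltaBCRecord",
    "union_network",
    "induced_union",
    "betweenness",
    "delta_bc",
    "rank_targets",
    "write_delta_table",
    "write_union_graphml",
]


@dataclass(frozen=True)
class CentralityTable:
    """Per-node betweenness values for one network."""

    network_label: str
    bc: dict[str, float]
    normalized: bool = False

    def __contains__(self, node: str) -> bool:
        return node in self.bc

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node\tbc\n")
            for node in sorted(self.bc):
                fh.write(f"{node}\t{self.bc[node]:.10g}\n")


@dataclass(frozen=True)
class DeltaBCRecord:
    """ΔBC bookkeeping for one union-network node.

    ``bc_auto``/``bc_mito`` are ``None`` when the node does not appear in
    that sub-network (then it has no BC there and contributes 0).
    """

    node: str
    bc_auto: float | None
    bc_mito: float | None
    bc_union: float
    delta_bc: float
    rank: int
    in_auto: bool
    in_mito: bool


def union_network(a: ProteinNetwork, b: ProteinNetwork) -> ProteinNetwork:
    """Plain graph union: nodes(a) ∪ nodes(b), edges(a) ∪ edges(b)."""
    return ProteinNetwork("union", nx.compose(a.graph, b.graph))


def induced_union(
    background: ProteinNetwork, a: ProteinNetwork, b: ProteinNetwork
) -> ProteinNetwork:
    """Union node set, closed over the background's edges.

    Every background edge whose two endpoints are sampled into either
    sub-network is included, mirroring the induced-subgraph convention of
    shortest-path sampling.

    Raises
    ------
    ConsistencyError
        If a sub-network node is missing from the background.
    """
    nodes = a.nodes | b.nodes
    stray = nodes - background.nodes
    if stray:
        raise ConsistencyError(
            f"sub-network nodes absent from background: {sorted(stray)[:5]}"
        )
    return background.induced(nodes, "union")


def betweenness(net: ProteinNetwork, normalized: bool = False) -> CentralityTable:
    """Betweenness centrality of every node (Brandes' algorithm).

    Unnormalized by default; endpoints earn no credit; networks with fewer
    than three nodes yield all-zero tables.
    """
    values = nx.betweenness_centrality(net.graph, normalized=normalized)
    return CentralityTable(
        network_label=net.label,
        bc={v: float(x) for v, x in values.items()},
        normalized=normalized,
    )


def _order(records: list[DeltaBCRecord]) -> list[DeltaBCRecord]:
    """Descending ΔBC, ties broken by identifier; ranks renumbered 1..N."""
    ordered = sorted(records, key=lambda r: (-r.delta_bc, r.node))
    return [
        DeltaBCRecord(
            node=r.node,
            bc_auto=r.bc_auto,
            bc_mito=r.bc_mito,
            bc_union=r.bc_union,
            delta_bc=r.delta_bc,
            rank=i,
            in_auto=r.in_auto,
            in_mito=r.in_mito,
        )
        for i, r in enumerate(ordered, start=1)
    ]


def delta_bc(
    union_tab: CentralityTable,
    auto_tab: CentralityTable,
    mito_tab: CentralityTable,
) -> list[DeltaBCRecord]:
    """ΔBC for every union-network node, ranked.

    All three tables must be unnormalized.  A node absent from a
    sub-network has no BC there and contributes 0.

    Raises
    ------
    ConsistencyError
        If any table is normalized, or a sub-network node is missing from
        the union table.
    """
    for tab in (union_tab, auto_tab, mito_tab):
        if tab.normalized:
            raise ConsistencyError(
                f"ΔBC requires unnormalized tables; {tab.network_label!r} is "
                "normalized (networks of different size are not comparable "
                "on the normalized scale)"
            )
    for tab in (auto_tab, mito_tab):
        stray = set(tab.bc) - set(union_tab.bc)
        if stray:
            raise ConsistencyError(
                f"nodes of sub-network {tab.network_label!r} missing from the "
                f"union table: {sorted(stray)[:5]}"
            )
    records = []
    for node, bc_u in union_tab.bc.items():
        in_a, in_m = node in auto_tab, node in mito_tab
        bc_a = auto_tab.bc[node] if in_a else None
        bc_m = mito_tab.bc[node] if in_m else None
        records.append(
            DeltaBCRecord(
                node=node,
                bc_auto=bc_a,
                bc_mito=bc_m,
                bc_union=bc_u,
                delta_bc=bc_u - (bc_a or 0.0) - (bc_m or 0.0),
                rank=0,
                in_auto=in_a,
                in_mito=in_m,
            )
        )
    return _order(records)


def rank_targets(
    records: list[DeltaBCRecord],
    top_k: int,
    path: str | Path | None = None,
) -> list[DeltaBCRecord]:
    """Top ``top_k`` candidates by ΔBC (full table optionally written).

    Re-sorts and renumbers defensively, writes the *full* ranked table to
    ``path`` when given, and returns the ``top_k`` prefix.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    ordered = _order(records)
    if path is not None:
        write_delta_table(ordered, path)
    return ordered[:top_k]


def write_delta_table(records: list[DeltaBCRecord], path: str | Path) -> None:
    """Ranked TSV; ``-`` marks a BC that does not exist (node not in
    sub-network), mirroring an N/A entry."""

    def fmt(x: float | None) -> str:
        return "-" if x is None else f"{x:.10g}"

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tbc_auto\tbc_mito\tbc_union\tdelta_bc\tin_auto\tin_mito\trank\n")
        for r in records:
            fh.write(
                f"{r.node}\t{fmt(r.bc_auto)}\t{fmt(r.bc_mito)}\t"
                f"{r.bc_union:.10g}\t{r.delta_bc:.10g}\t"
                f"{int(r.in_auto)}\t{int(r.in_mito)}\t{r.rank}\n"
            )


def write_union_graphml(
    union_net: ProteinNetwork,
    records: list[DeltaBCRecord],
    path: str | Path,
) -> None:
    """Union network with ``bc_union`` and ``delta_bc`` node attributes,
    ready for external layout tools."""
    g = nx.Graph(union_net.graph)
    by_node = {r.node: r for r in records}
    for v in g.nodes:
        r = by_node.get(v)
        if r is not None:
            g.nodes[v]["bc_union"] = r.bc_union
            g.nodes[v]["delta_bc"] = r.delta_bc
    nx.write_graphml(g, str(path), named_key_ids=True)
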