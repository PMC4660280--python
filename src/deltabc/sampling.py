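"""Shortest-path sub-network sampling from seed lists.

A biological process is represented by a seed list of proteins with a
literature-validated role in that process.  The process sub-network is cut
out of the background interactome by shortest-path sampling: take every node
that lies on *any* shortest path between *any* unordered pair of seeds
(seeds included), then the induced subgraph of the background on that node
set — an edge between two sampled nodes is kept even if it lies on no
shortest path.

All shortest paths between a pair are used, not one arbitrary
representative, which makes the sample deterministic and independent of
seed order.  Seeds absent from the background are reported and skipped;
seed pairs in different components contribute nothing and are counted as
disconnected; a seed isolated from every other seed still enters the node
set (it is an asserted process member).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx

from .errors import SamplingError, SeedListError
from .network import ProteinNetwork

logger = logging.getLogger(__name__)

__all__ = ["SeedList", "SamplingReport", "load_seed_list", "shortest_path_sample"]


@dataclass(frozen=True)
class SeedList:
    """Named, ordered, deduplicated protein identifiers for one process."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise SeedListError(f"seed list {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise SeedListError(f"seed list {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def load_seed_list(path: str | Path, name: str) -> SeedList:
    """Read one identifier per line; ``#`` starts a comment, blanks ignored.

    Duplicates are dropped with a warning, keeping first-occurrence order.

    Raises
    ------
    SeedListError
        If no identifier remains after cleaning, or the file is unreadable.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise SeedListError(f"cannot read seed list {path}: {exc}") from exc
    members: list[str] = []
    seen: set[str] = set()
    for line in text.splitlines():
        ident = line.split("#", 1)[0].strip()
        if not ident:
            continue
        if ident in seen:
            logger.warning("seed list %s: duplicate %r dropped", path.name, ident)
            continue
        seen.add(ident)
        members.append(ident)
    if not members:
        raise SeedListError(f"seed list {path} contains no identifiers")
    return SeedList(name=name, members=tuple(members))


@dataclass(frozen=True)
class SamplingReport:
    """Bookkeeping for one sampling run.

    ``seeds_found``/``seeds_missing`` partition the input seed list;
    ``pairs_connected + pairs_disconnected == C(len(seeds_found), 2)``.
    """

    seeds_found: tuple[str, ...]
    seeds_missing: tuple[str, ...]
    pairs_connected: int
    pairs_disconnected: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"seeds_found\t{','.join(self.seeds_found)}\n")
            fh.write(f"seeds_missing\t{','.join(self.seeds_missing)}\n")
            fh.write(f"pairs_connected\t{self.pairs_connected}\n")
            fh.write(f"pairs_disconnected\t{self.pairs_disconnected}\n")


def shortest_path_sample(
    background: ProteinNetwork,
    seeds: SeedList,
    label: str | None = None,
) -> tuple[ProteinNetwork, SamplingReport]:
    """Sample the process sub-network for ``seeds`` from ``background``.

    A node ``v`` lies on a shortest path between seeds ``s`` and ``t``
    exactly when ``d(s, v) + d(v, t) == d(s, t)``; collecting all such nodes
    over all seed pairs and inducing the background on them implements
    all-shortest-paths sampling without path enumeration.

    Returns the sub-network (labelled ``label`` or the seed-list name) and a
    :class:`SamplingReport`.

    Raises
    ------
    SamplingError
        If no seed is present in the background.
    """
    g = background.graph
    found = tuple(s for s in seeds if s in g)
    missing = tuple(s for s in seeds if s not in g)
    if missing:
        logger.warning(
            "sampling %r: %d seed(s) absent from background: %s",
            seeds.name,
            len(missing),
            ", ".join(missing),
        )
    if not found:
        raise SamplingError(
            f"no seed of list {seeds.name!r} is present in the background "
            f"({len(missing)} missing)"
        )

    dist = {s: nx.single_source_shortest_path_length(g, s) for s in found}
    sampled: set[str] = set(found)
    n_conn = n_disc = 0
    for s, t in combinations(found, 2):
        ds = dist[s]
        if t not in ds:
            n_disc += 1
            continue
        n_conn += 1
        d_st = ds[t]
        dt = dist[t]
        sampled.update(
            v for v, dsv in ds.items() if dsv <= d_st and dt.get(v, d_st + 1) + dsv == d_st
        )
    subnet = background.induced(sampled, label or seeds.name)
    report = SamplingReport(
        seeds_found=found,
        seeds_missing=missing,
        pairs_connected=n_conn,
        pairs_disconnected=n_disc,
    )
    logger.info(
        "sampling %r: %d/%d seeds found, %d/%d pairs connected, "
        "sub-network %d nodes / %d edges",
        seeds.name,
        len(found),
        len(seeds),
        n_conn,
        n_conn + n_disc,
        subnet.n_nodes,
        subnet.n_edges,
    )
    return subnet, report
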