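"""Synthetic interactomes with planted crosstalk bridges.

Real inputs to the pipeline — a consolidated interactome in MITAB and two
curated process seed lists — are large external downloads.  This module
generates structurally analogous instances with known ground truth so the
whole pipeline is testable offline: two densely connected communities
(mimicking two biological processes, e.g. autophagy and mitochondrial
dysfunction), joined *only* through a small number of planted bridge nodes
(the crosstalk proteins a ΔBC analysis should recover), serialized as MITAB
with taxon and detection-method fields, plus one seed list per community.

The writer can contaminate a fraction of rows with a non-human taxon and a
fraction with a predicted-interaction detection method, so the curation
filters have non-trivial work to do.

Everything is reproducible from one integer ``rng_seed`` through a single
numpy Generator stream; there is no global random state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .crosstalk import DeltaBCRecord
from .errors import GenerationError
from .network import ProteinNetwork
from .sampling import SeedList

__all__ = [
    "PlantedBridgeSpec",
    "SyntheticTruth",
    "MitabWriteReport",
    "generate_planted_bridge",
    "write_mitab",
    "write_seed_lists",
    "write_truth_tsv",
    "make_toy_barbell",
]

_MAX_RETRIES = 50
_DECOY_TAXID = 10090  # mouse
_CLEAN_METHOD = 'psi-mi:"MI:0018"(two hybrid)'
_PREDICTED_METHOD = 'psi-mi:"MI:0063"(interaction prediction)'

_MITAB_HEADER = (
    "#ID(s) interactor A\tID(s) interactor B\t"
    "Alt. ID(s) interactor A\tAlt. ID(s) interactor B\t"
    "Alias(es) interactor A\tAlias(es) interactor B\t"
    "Interaction detection method(s)\tPublication 1st author(s)\t"
    "Publication Identifier(s)\tTaxid interactor A\tTaxid interactor B\t"
    "Interaction type(s)\tSource database(s)\tInteraction identifier(s)\t"
    "Confidence value(s)"
)


@dataclass(frozen=True)
class PlantedBridgeSpec:
    """Parameters of the planted-bridge benchmark generator.

    Two Erdős–Rényi communities of ``n_per_community`` nodes with
    intra-community edge probability ``intra_edge_prob`` are joined only
    through ``n_bridges`` bridge nodes, each attached to
    ``bridge_degree_per_side`` uniformly chosen nodes in each community.
    ``n_seeds_per_community`` seeds are drawn uniformly without replacement
    from each community (never from the bridges).  The MITAB writer marks a
    ``decoy_taxon_fraction`` of rows non-human and a ``predicted_fraction``
    as computational predictions.
    """

    n_per_community: int = 30
    intra_edge_prob: float = 0.15
    n_bridges: int = 2
    bridge_degree_per_side: int = 3
    n_seeds_per_community: int = 5
    decoy_taxon_fraction: float = 0.0
    predicted_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_community < 1:
            raise ValueError("n_per_community must be positive")
        if not 0.0 < self.intra_edge_prob <= 1.0:
            raise ValueError("intra_edge_prob must be in (0, 1]")
        if self.n_bridges < 0:
            raise ValueError("n_bridges must be non-negative")
        if self.bridge_degree_per_side < 1:
            raise ValueError("bridge_degree_per_side must be positive")
        if self.bridge_degree_per_side > self.n_per_community:
            raise ValueError("bridge_degree_per_side exceeds community size")
        if not 1 <= self.n_seeds_per_community <= self.n_per_community:
            raise ValueError("n_seeds_per_community must be in [1, n_per_community]")
        for name in ("decoy_taxon_fraction", "predicted_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated instance."""

    community_of: dict[str, str]  # node -> "1" | "2" | "bridge"
    bridge_nodes: tuple[str, ...]
    seed_lists: tuple[SeedList, SeedList]


def _attempt(spec: PlantedBridgeSpec, rng: np.random.Generator):
    n = spec.n_per_community
    comm1 = [f"A{i:03d}" for i in range(n)]
    comm2 = [f"B{i:03d}" for i in range(n)]
    bridges = [f"X{i:02d}" for i in range(spec.n_bridges)]

    edges: list[tuple[str, str]] = []
    for comm in (comm1, comm2):
        pairs = list(itertools.combinations(comm, 2))
        mask = rng.random(len(pairs)) < spec.intra_edge_prob
        edges.extend(p for p, keep in zip(pairs, mask) if keep)
    for x in bridges:
        for comm in (comm1, comm2):
            picks = rng.choice(len(comm), size=spec.bridge_degree_per_side, replace=False)
            edges.extend((x, comm[i]) for i in picks)

    seeds1 = [comm1[i] for i in rng.choice(n, size=spec.n_seeds_per_community, replace=False)]
    seeds2 = [comm2[i] for i in rng.choice(n, size=spec.n_seeds_per_community, replace=False)]

    net = ProteinNetwork.from_edges("background", edges, nodes=comm1 + comm2 + bridges)
    truth = SyntheticTruth(
        community_of={
            **{v: "1" for v in comm1},
            **{v: "2" for v in comm2},
            **{v: "bridge" for v in bridges},
        },
        bridge_nodes=tuple(bridges),
        seed_lists=(
            SeedList("autophagy", tuple(seeds1)),
            SeedList("mitochondrial", tuple(seeds2)),
        ),
    )
    return net, truth


def _seeded_component_connected(net: ProteinNetwork, truth: SyntheticTruth) -> bool:
    """All seeds of both lists plus all bridges in one connected component."""
    import networkx as nx

    targets = set(truth.bridge_nodes)
    for sl in truth.seed_lists:
        targets.update(sl.members)
    comp = nx.node_connected_component(net.graph, next(iter(targets)))
    return targets <= comp


def generate_planted_bridge(
    spec: PlantedBridgeSpec,
) -> tuple[ProteinNetwork, SyntheticTruth]:
    """Generate one planted-bridge instance, fully reproducible from the seed.

    With ``n_bridges >= 1`` an instance whose seeded component (all seeds
    plus all bridges) is disconnected is discarded and regenerated from the
    same stream, up to a bounded retry count.

    Raises
    ------
    GenerationError
        If no connected instance emerges within the retry budget.
    """
    rng = np.random.default_rng(spec.rng_seed)
    for _ in range(_MAX_RETRIES):
        net, truth = _attempt(spec, rng)
        if spec.n_bridges == 0 or _seeded_component_connected(net, truth):
            return net, truth
    raise GenerationError(
        f"no connected seeded component within {_MAX_RETRIES} attempts "
        f"(spec seed {spec.rng_seed}); the spec is likely too sparse"
    )


@dataclass(frozen=True)
class MitabWriteReport:
    """Row-level composition of a written synthetic MITAB file.

    ``n_clean`` counts rows that are human on both sides *and* carry an
    experimental (non-predicted) detection method — exactly the rows that
    survive default curation (the generator never emits self-interactions).
    """

    n_rows: int
    n_decoy_taxon: int
    n_predicted: int
    n_clean: int


def write_mitab(
    net: ProteinNetwork,
    truth: SyntheticTruth,
    spec: PlantedBridgeSpec,
    path: str | Path,
) -> MitabWriteReport:
    """Serialize the network as MITAB 2.5/2.6-style rows, one per edge.

    Rows are written in sorted edge order.  Decoy-taxon and
    predicted-method contamination are independent Bernoulli draws per row
    from a stream derived from ``spec.rng_seed``, so a rewrite of the same
    instance is byte-identical.
    """
    rng = np.random.default_rng([spec.rng_seed & 0x7FFFFFFF, 9151])
    rows = sorted(net.edge_set())
    decoy = rng.random(len(rows)) < spec.decoy_taxon_fraction
    pred = rng.random(len(rows)) < spec.predicted_fraction
    human = "taxid:9606(Homo sapiens)"
    mouse = f"taxid:{_DECOY_TAXID}(Mus musculus)"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MITAB_HEADER + "\n")
        for i, (a, b) in enumerate(rows):
            tax = mouse if decoy[i] else human
            method = _PREDICTED_METHOD if pred[i] else _CLEAN_METHOD
            fh.write(
                f"uniprotkb:UP{a}\tuniprotkb:UP{b}\t-\t-\t"
                f"hgnc:{a}\thgnc:{b}\t{method}\t-\t-\t{tax}\t{tax}\t"
                f'psi-mi:"MI:0915"(physical association)\tsynthdb\t'
                f"synthdb:{i}\t-\n"
            )
    n_decoy = int(decoy.sum())
    n_pred = int(pred.sum())
    n_clean = int((~decoy & ~pred).sum())
    return MitabWriteReport(
        n_rows=len(rows), n_decoy_taxon=n_decoy, n_predicted=n_pred, n_clean=n_clean
    )


def write_seed_lists(truth: SyntheticTruth, out_dir: str | Path) -> list[Path]:
    """One plain-text seed file per process; returns the two paths."""
    out_dir = Path(out_dir)
    paths = []
    for sl in truth.seed_lists:
        p = out_dir / f"seeds_{sl.name}.txt"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(f"# seed list: {sl.name}\n")
            for m in sl.members:
                fh.write(m + "\n")
        paths.append(p)
    return paths


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tcommunity\tis_bridge\n")
        for node in sorted(truth.community_of):
            comm = truth.community_of[node]
            fh.write(f"{node}\t{comm}\t{int(comm == 'bridge')}\n")


# ---------------------------------------------------------------------------
# Deterministic documentation toy
# ---------------------------------------------------------------------------

_TOY_EDGES = [
    ("A1", "A2"),
    ("A2", "A3"),
    ("A1", "X"),
    ("A3", "X"),
    ("B1", "B2"),
    ("B2", "B3"),
    ("B1", "X"),
    ("B3", "X"),
]

#: Expected ranked ΔBC table of the toy, computed once by exhaustive
#: geodesic enumeration over the 7-node graph and frozen here.
TOY_EXPECTED: tuple[DeltaBCRecord, ...] = (
    DeltaBCRecord("X", 0.5, 0.5, 10.0, 9.0, 1, True, True),
    DeltaBCRecord("A1", 0.5, None, 2.0, 1.5, 2, True, False),
    DeltaBCRecord("A3", 0.5, None, 2.0, 1.5, 3, True, False),
    DeltaBCRecord("B1", None, 0.5, 2.0, 1.5, 4, False, True),
    DeltaBCRecord("B3", None, 0.5, 2.0, 1.5, 5, False, True),
    DeltaBCRecord("A2", 0.5, None, 0.5, 0.0, 6, True, False),
    DeltaBCRecord("B2", None, 0.5, 0.5, 0.0, 7, False, True),
)


def make_toy_barbell() -> tuple[ProteinNetwork, SeedList, SeedList, tuple[DeltaBCRecord, ...]]:
    """Fixed 7-node two-community toy with a unique crosstalk bridge.

    Two three-node chain communities, A1–A2–A3 and B1–B2–B3, are joined
    solely through the bridge hub X, which is attached to both ends of each
    chain (A1, A3, B1, B3).  Seed lists are the chain ends, {A1, A3} and
    {B1, B3}; because X offers one of the two geodesics between the ends of
    each chain, it is sampled into *both* process sub-networks with a small
    internal BC (0.5 each), and in the union it carries every cross-community
    shortest path, giving it the uniquely largest ΔBC (9.0).

    A clique-shaped community would not work here: seeds that are pairwise
    adjacent have single-edge geodesics, so no outside node — bridge
    included — is ever sampled.  The chain communities are the smallest
    structure that routes intra-process geodesics through the bridge.

    Returns the background network, the two seed lists, and the expected
    ranked ΔBC table (frozen from exhaustive path enumeration).  The toy is
    deterministic: repeated calls return identical structures.
    """
    net = ProteinNetwork.from_edges("background", _TOY_EDGES)
    auto = SeedList("autophagy", ("A1", "A3"))
    mito = SeedList("mitochondrial", ("B1", "B3"))
    return net, auto, mito, TOY_EXPECTED
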