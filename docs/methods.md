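# Methods

## Model and procedure

The pipeline treats a curated protein–protein interaction (PPI) table as a
simple, undirected, unweighted graph and asks which proteins broker the
communication between two biological processes, each given as a seed list
of known members.

**Curation.** MITAB records are kept only if both interactors carry the
required NCBI taxon (default 9606). The strict reading is deliberate: a
record with an unknown taxon on either side is dropped, because interologs
and host–pathogen rows otherwise leak into a nominally human interactome.
Records whose interaction-detection method falls in the PSI-MI
"interaction prediction" branch are removed; the packaged code list
(MI:0063, 0036, 0057, 0058, 0064, 0085, 0087, 0101, 0105) is a static
snapshot of that branch and can be overridden in the run config, since the
ontology evolves. Self-interactions are dropped by default — betweenness is
blind to loops, so they only distort edge counts. The curation report gives
both the raw record count and the unique node-pair count, because
"number of interactions" is ambiguous between the two.

**Identifier resolution.** MITAB uids from different source databases often
denote the same protein. Node identity uses a configurable preference order
over the record's columns, by default the first alias (gene-symbol-like)
with the raw uid as fallback. Two raw uids merge only when they resolve to
the same preferred identifier; resolution is deterministic and auditable
from the record.

**Shortest-path sampling.** The sub-network for a process is the background
subgraph induced on the set of nodes lying on *any* shortest path between
*any* unordered pair of seeds. Using all shortest paths (rather than one
representative per pair) makes the sample independent of seed order and of
tie-breaking, which a single-path variant would need to invent. Membership
of node *v* on a shortest s–t path is decided by the distance criterion
d(s,v) + d(v,t) = d(s,t), so the sampler runs one BFS per seed and never
enumerates paths. Seeds missing from the background are reported and
skipped; seed pairs in different components are counted as disconnected,
not treated as errors (real interactomes have singleton components); a seed
isolated from every other seed still enters the node set, as an asserted
process member. These inclusion conventions are recorded in the sampling
report and run manifest.

**Union.** Two union constructions are available. `union_network` is the
plain graph union (nodes and edges united) — the natural operation when the
two inputs are arbitrary graphs, and the one under which the algebraic
identities below are stated. The pipeline, however, defaults to the
*induced* union: the united node set closed over the background's edges,
i.e. the same "all edges between the sampled nodes" convention the sampling
step itself uses. The distinction matters when the two sub-networks barely
overlap: under a plain edge union a bridge protein sampled into only one
sub-network keeps only that side's edges, the union falls apart into two
components, and ΔBC is identically zero — the statistic degenerates exactly
in the regime it is meant to probe. On strongly overlapping sub-networks
(the realistic case for processes sampled from one interactome) the two
constructions approximately agree; on the toy fixture they agree exactly.
`union_mode: edges` selects the plain union for comparison.

**Betweenness and ΔBC.** BC is computed unnormalized (raw pair counts) with
the standard endpoint convention: endpoints of a path earn no credit.
Brandes' algorithm via networkx does the counting; the test suite checks it
against an independent brute-force geodesic enumerator on hundreds of small
random graphs. ΔBC(v) = BC_U(v) − BC_A(v) − BC_M(v), with a missing term
treated as 0 when v is absent from that sub-network (it has no BC there;
the output tables mark these with `-`). ΔBC is only computed on
unnormalized tables: the three networks differ in size, so normalized
values are not commensurable and the subtraction would be meaningless;
normalized tables can be emitted for display. Two consequences worth
knowing: sub-networks identical to each other give ΔBC = −BC everywhere,
and fully disjoint sub-networks give ΔBC = 0 everywhere (shortest-path
counting is component-local). Both identities are tested exactly.

**Ranking.** Candidates are ordered by descending ΔBC with ties broken
lexicographically by identifier — determinism is worth more here than any
pretence that exact ties carry information. Exactly two processes are
supported; the statistic as defined subtracts exactly two sub-network
terms, and generalizing it is out of scope.

## Synthetic benchmark

`generate_planted_bridge` emulates the structure the analysis assumes: two
Erdős–Rényi communities (one per process) joined *only* through a small
number of planted bridge nodes, each attached to a fixed number of
uniformly chosen partners per side; seeds are drawn uniformly without
replacement within each community. Defaults — 30 nodes per community,
intra-community edge probability 0.15, 2 bridges with degree 3 per side,
5 seeds per community — give sparse communities (mean degree ≈ 4.4) whose
seed-pair geodesics are long enough that bridges are sampled at a realistic
rate, at a size where twenty instances run in seconds. Contamination
fractions for non-human taxa and predicted detection methods default to 0
and are switched on where the curation filters are under test. A single
integer seed drives one `numpy` generator stream for all sampling; an
instance whose seeds-plus-bridges set is not connected (possible since ER
communities can fragment) is regenerated from the same stream, at most 50
times, with ≥1 bridge requested.

The generator emulates community-plus-bridge *cut structure*, not
interactome topology: no scale-free degree distribution, no clustering
spectrum, no protein-family redundancy. A passing recovery benchmark
therefore shows that the statistic finds cut-point crosstalk nodes under
the stated noise model, not that it would rank any particular protein first
in a real interactome.

Recovery is evaluated per instance as: every planted bridge that appears in
the union network ranks in the ΔBC top 5. Bridges absent from the union are
not scored — a bridge no shortest path touches is invisible to the method
by construction, which is a property of sampling, not of the statistic. On
the fixed 20-instance battery the criterion holds in 19 instances; the one
failure is an instance where a bridge enters only one sub-network and picks
up too few union edges to broker cross-community traffic.

## The toy fixture

The documented toy is the smallest graph on which the statistic does
something interesting: two three-node chains A1–A2–A3 and B1–B2–B3, a
bridge X adjacent to A1, A3, B1, B3, seed lists {A1, A3} and {B1, B3}.
X offers one of the two geodesics between each chain's ends, so it is
sampled into both sub-networks with BC 0.5 each, and in the union it
carries all nine cross-community pairs: ΔBC(X) = 10 − 0.5 − 0.5 = 9,
uniquely first. Clique-shaped communities cannot serve here: seeds that are
pairwise adjacent have single-edge geodesics, so sampling never picks up
any outside node and a bridge between two cliques never enters either
sub-network. The expected table shipped with the fixture was computed by
exhaustive path enumeration and is asserted verbatim in the tests.

## Numerical and design notes

* Distances and path counts are integer-exact; BC values are sums of small
  rationals accumulated in doubles. Equality against the enumeration oracle
  is asserted to 1e-9 per node; the observed discrepancy on 12-node graphs
  is ≲ 1e-14.
* Determinism: the analysis pipeline contains no randomness at all; all
  randomness lives in the synthetic generator behind one seeded stream.
  Outputs carry no timestamps, serialization is sorted, and reruns on
  identical inputs are byte-identical.
* Degenerate inputs: networks with fewer than three nodes have all-zero BC;
  an empty record set builds an empty network with a warning; a seed list
  with no member in the background is a fatal, stage-named error.
* Problem sizes in the shipped tests and the acceptance script (graphs of
  4–12 nodes for oracle comparisons, 62-node benchmark instances, batteries
  of 20–200) are chosen so the exhaustive oracles stay exact and the whole
  suite runs in well under a minute; the pipeline itself is limited only by
  one BFS per seed and one betweenness pass per network, and handles
  interactome-scale inputs (10⁴–10⁵ edges) in minutes.

## Known limitations

* ΔBC carries no significance measure; a permutation test over seed lists
  would be the natural extension and is deliberately not included.
* Interaction confidence scores, directions and weights are discarded; the
  statistic is defined on unweighted geodesics.
* Identifier resolution does no ortholog mapping or cross-database
  reconciliation beyond the alias preference order.
* The edge-union/induced-union choice matters precisely when sub-network
  overlap is small; users comparing against tools that form a plain graph
  union should set `union_mode: edges` and expect ΔBC ≈ 0 if their
  sub-networks are nearly disjoint.
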