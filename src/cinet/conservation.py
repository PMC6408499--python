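"""Cross-species conservation analysis of collective influencers.

Three questions, all driven by an ortholog map (source-network ID →
organism ID, many-to-many):

1. Are CI proteins more likely than chance to have an ortholog at all?
   (:func:`conservation_feature` builds the conserved-node feature set that
   feeds the generic enrichment statistic.)
2. Which part of the network is conserved as a network?  An interaction is
   considered conserved — an *interolog* — when both interacting proteins
   have orthologs in the other organism; :func:`infer_interolog_network`
   keeps exactly those edges.  Inferred networks keep source-side IDs: the
   downstream overlap test compares against the source CI set and needs a
   common namespace, and a many-to-many projection onto organism IDs would
   multiply edges.
3. Are CI proteins conserved *as* CI proteins?  Rerun the CI algorithm on
   the interolog network and cross-tabulate membership against the source
   CI set; significance by a one-sided Fisher's exact test
   (:func:`conserved_ci_overlap`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import fisher_exact

from cinet.enrichment import DEFAULT_RANDOMIZATIONS, EdgeClassResult, edge_class_enrichment
from cinet.io import AnnotationSet, InteractionNetwork, OrthologMap


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for source-CI (rows) × conserved-CI (columns) membership."""

    a: int  # CI and conserved-CI
    b: int  # CI, not conserved-CI
    c: int  # non-CI, conserved-CI
    d: int  # neither

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def conservation_feature(map: OrthologMap, universe: Iterable[str]) -> AnnotationSet:
    """Nodes of *universe* with at least one ortholog, as a feature set.

    Feeds :func:`cinet.enrichment.enrichment_score` directly (e.g. group =
    CI set, feature = conserved nodes).
    """
    members = map.conserved_ids & frozenset(universe)
    return AnnotationSet(name=f"conserved:{map.organism}", members=members)


def infer_interolog_network(
    net: InteractionNetwork, map: OrthologMap
) -> InteractionNetwork:
    """Subnetwork of interactions whose both endpoints have orthologs.

    Node IDs stay in the source namespace.  Idempotent: applying the same
    map twice changes nothing.
    """
    conserved = map.conserved_ids
    return net.subgraph([v for v in net if v in conserved]).copy()


def edge_conservation_enrichment(
    net: InteractionNetwork,
    marked: AnnotationSet,
    conserved: AnnotationSet,
    R: int = DEFAULT_RANDOMIZATIONS,
    seed: int = 0,
) -> EdgeClassResult:
    """Class enrichment restricted to conserved edges.

    An edge is conserved when both endpoints are in *conserved*; those edges
    form the ``edge_subset`` of :func:`edge_class_enrichment`, with the
    marked set randomized over the whole network.
    """
    conserved_nodes = conserved.members & set(net.nodes)
    subset = [
        (a, b) for a, b in net.edges() if a in conserved_nodes and b in conserved_nodes
    ]
    return edge_class_enrichment(net, marked, R=R, seed=seed, edge_subset=subset)


def conserved_ci_overlap(
    source_ci: AnnotationSet,
    organism_ci: AnnotationSet,
    universe: Iterable[str],
) -> tuple[ContingencyTable2x2, float]:
    """2×2 overlap of source CI membership vs conserved-network CI membership.

    Both sets are intersected with *universe*; returns the table and the
    one-sided (greater) Fisher's exact p-value — the probability under the
    hypergeometric null of an overlap at least as large as observed.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    h = source_ci.members & universe
    o = organism_ci.members & universe
    a = len(h & o)
    b = len(h - o)
    c = len(o - h)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(a=a, b=b, c=c, d=d)
    _, p = fisher_exact(table.as_rows(), alternative="greater")
    return table, float(p)
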