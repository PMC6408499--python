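"""Seeded generators for networks, annotations, links and ortholog maps.

Every analysis stage of the package is exercisable without database
downloads: the generators emulate the statistical structure the pipeline
assumes —

* :func:`generate_network` — a preferential-attachment graph with the
  heavy-tailed degree distribution characteristic of protein interaction
  networks; connected by construction, which the CI algorithm's LCC focus
  relies on;
* :func:`generate_annotation` — annotation sets with a planted sampling
  weight toward a chosen node subset (weight 1 = uniform null);
* :func:`planted_feature` — exact relative-risk planting: group members are
  included with probability ρ·s/N, so the enrichment statistic's expected
  score is log2(ρ) by construction;
* :func:`generate_ortholog_map` — class-dependent conservation (target
  nodes conserved with one probability, the rest with another);
* :func:`generate_links` — directed regulator→target links with sources
  drawn from a pool;
* :func:`worked_example_fixture` — a hand-traceable 7-node network with its
  known CI removal log, for exact regression tests.

All generators are pure functions of their configuration: the same seed
yields byte-identical output.  Each call owns its own
``numpy.random.Generator``; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

from cinet.influence import CIRanking, RemovalStep
from cinet.io import AnnotationSet, DirectedLinkSet, InteractionNetwork, OrthologMap


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    ``n_nodes``/``attachment_m`` size the preferential-attachment network
    (defaults 1000 and 2 give a sparse, hub-dominated topology comparable
    in density to curated interactome extracts); ``feature_size`` and
    ``enrichment_factor`` ρ shape planted annotations (ρ = 1 is the uniform
    null); ``conserve_p_target``/``conserve_p_other`` are the per-node
    conservation probabilities of the ortholog-map generator; ``n_links``
    sizes directed link sets.
    """

    n_nodes: int = 1000
    attachment_m: int = 2
    seed: int = 0
    feature_size: int = 100
    enrichment_factor: float = 1.0
    conserve_p_target: float = 0.9
    conserve_p_other: float = 0.3
    n_links: int = 500

    def __post_init__(self) -> None:
        if self.feature_size > self.n_nodes:
            raise ValueError("feature_size must not exceed n_nodes")
        for p in (self.conserve_p_target, self.conserve_p_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"conservation probability {p} outside [0, 1]")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")


def _node_id(i: int) -> str:
    # zero-padded so lexicographic tie-breaks are deterministic and stable
    return f"P{i + 1:06d}"


def generate_network(config: SyntheticConfig) -> InteractionNetwork:
    """Connected preferential-attachment network with heavy-tailed degrees.

    Construction: a complete graph on the first m+1 nodes, then each new
    node attaches to m distinct existing nodes chosen proportionally to
    degree.  Edge count is therefore exactly C(m+1, 2) + m·(n − m − 1);
    n = 3, m = 2 gives a triangle.  Node IDs are "P000001"…, zero-padded.
    """
    n, m = config.n_nodes, config.attachment_m
    if m < 1:
        raise ValueError("attachment_m must be >= 1")
    if n < m + 1:
        raise ValueError("n_nodes must be at least attachment_m + 1")
    rng = np.random.default_rng(config.seed)

    net: InteractionNetwork = nx.Graph()
    # seed clique; each of its nodes starts with degree m
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            net.add_edge(_node_id(i), _node_id(j))
    # one entry per incident edge end → sampling from it is degree-biased
    repeated: list[int] = [i for i in range(m + 1) for _ in range(m)]
    for new in range(m + 1, n):
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(repeated[rng.integers(len(repeated))])
        for target in sorted(chosen):
            net.add_edge(_node_id(new), _node_id(target))
            repeated.append(target)
        repeated.extend([new] * m)
    return net


def generate_annotation(
    net: InteractionNetwork,
    target: AnnotationSet,
    config: SyntheticConfig,
) -> AnnotationSet:
    """Annotation of ``feature_size`` nodes with sampling weight ρ on *target*.

    Weighted sampling without replacement (Efraimidis–Spirakis exponential
    keys): nodes in *target* carry weight ρ = ``enrichment_factor``, all
    others weight 1.  ρ = 1 reduces to a uniform random subset; ρ = 0
    excludes target nodes unless the requested size forces them in.
    """
    nodes = sorted(net.nodes)
    size = config.feature_size
    if size > len(nodes):
        raise ValueError(f"feature_size {size} exceeds network size {len(nodes)}")
    rng = np.random.default_rng(config.seed)
    weights = np.array(
        [config.enrichment_factor if v in target.members else 1.0 for v in nodes]
    )
    with np.errstate(divide="ignore"):
        # maximize u^(1/w) ⇔ maximize log(u)/w; w = 0 → key = −inf (picked last)
        keys = np.log(rng.random(len(nodes))) / weights
    order = np.argsort(-keys, kind="stable")
    members = frozenset(nodes[i] for i in order[:size])
    return AnnotationSet(
        name=f"planted:w={config.enrichment_factor:g}", members=members
    )


def planted_feature(
    universe: Iterable[str],
    group: AnnotationSet,
    size: int,
    relative_risk: float,
    seed: int = 0,
) -> AnnotationSet:
    """Feature with exact relative risk ρ toward *group*.

    The number of feature members inside the group is fixed at
    round(ρ·size·|group|/|universe|) and the strata are sampled uniformly,
    so f_obs/E[f_rand] = ρ exactly (up to the single rounding), and the
    enrichment score recovers log2(ρ).  Contrast with
    :func:`generate_annotation`, whose sampling *weight* ρ equals the odds
    ratio, not the risk ratio.

    Requires ρ·size·|group|/|universe| ≤ min(size, |group|) and the
    remainder to fit outside the group.
    """
    nodes = sorted(frozenset(universe))
    in_group = sorted(group.members & set(nodes))
    out_group = sorted(set(nodes) - group.members)
    k = round(relative_risk * size * len(in_group) / len(nodes))
    if k > min(size, len(in_group)):
        raise ValueError(
            f"relative risk {relative_risk} infeasible: needs {k} group members"
        )
    if size - k > len(out_group):
        raise ValueError("not enough non-group nodes for the requested size")
    rng = np.random.default_rng(seed)
    picked = list(rng.choice(in_group, size=k, replace=False)) + list(
        rng.choice(out_group, size=size - k, replace=False)
    )
    return AnnotationSet(
        name=f"planted:rr={relative_risk:g}", members=frozenset(picked)
    )


def generate_ortholog_map(
    net: InteractionNetwork,
    target: AnnotationSet,
    config: SyntheticConfig,
    organism: str = "synthetic",
) -> OrthologMap:
    """Ortholog map with class-dependent conservation probability.

    Each node is conserved independently with probability
    ``conserve_p_target`` if it belongs to *target*, else
    ``conserve_p_other``; a conserved node v maps to "org_<v>".
    """
    rng = np.random.default_rng(config.seed)
    pairs = set()
    for v in sorted(net.nodes):
        p = config.conserve_p_target if v in target.members else config.conserve_p_other
        if rng.random() < p:
            pairs.add((v, f"org_{v}"))
    return OrthologMap(organism=organism, pairs=frozenset(pairs))


def generate_links(
    net: InteractionNetwork,
    source_pool: AnnotationSet,
    config: SyntheticConfig,
    name: str = "synthetic-links",
) -> DirectedLinkSet:
    """Directed regulator→target links with sources from *source_pool*.

    Draws ``n_links`` (source, target) pairs — source uniform over the pool
    (restricted to the network), target uniform over all nodes — dropping
    self-links and collapsing duplicates, so the realized count can fall
    short of ``n_links`` on tiny networks.
    """
    sources = sorted(source_pool.members & set(net.nodes))
    if not sources:
        raise ValueError("source pool has no members in the network")
    nodes = sorted(net.nodes)
    rng = np.random.default_rng(config.seed)
    links = set()
    for _ in range(config.n_links):
        s = sources[rng.integers(len(sources))]
        t = nodes[rng.integers(len(nodes))]
        if s != t:
            links.add((s, t))
    return DirectedLinkSet(name=name, links=frozenset(links))


def worked_example_fixture() -> tuple[InteractionNetwork, CIRanking]:
    """The 7-node barbell network and its hand-traced CI removal log.

    Two triangles {1,2,3} and {5,6,7} joined through bridge node 4
    (edges 3–4 and 4–5): 7 nodes, 8 edges.  Under defaults (ell = 1,
    stop_threshold = 2, batch 1, degree-then-lexicographic ties) the
    algorithm removes node 3 (CI = 6, tie with node 5 broken
    lexicographically), then node 5 (CI = 4), leaving an LCC of size 2.
    Hard-coded — seed-independent — for exact regression testing.
    """
    net: InteractionNetwork = nx.Graph()
    net.add_edges_from(
        [
            ("1", "2"), ("1", "3"), ("2", "3"),
            ("3", "4"), ("4", "5"),
            ("5", "6"), ("5", "7"), ("6", "7"),
        ]
    )
    expected = CIRanking(
        steps=[
            RemovalStep(index=1, node="3", score=6.0, lcc_before=7, lcc_after=4),
            RemovalStep(index=2, node="5", score=4.0, lcc_before=4, lcc_after=2),
        ],
        ell=1,
        stop_threshold=2,
        initial_lcc=7,
        n_nodes=7,
    )
    return net, expected
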