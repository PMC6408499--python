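"""Randomization-based enrichment statistics.

All tests here share one null model: uniform resampling of a node set of
fixed size from the node universe, repeated R times (default 10,000).

* :func:`enrichment_score` — the fraction f_obs of a *group* of proteins
  that carries a *feature* is compared round by round against the fraction
  f_rand obtained with a random same-size feature; the score is the mean
  over rounds of log2(f_obs / f_rand), so > 0 flags enrichment and < 0
  depletion.
* :func:`edge_class_enrichment` — edges are classified by whether both, one
  or neither endpoint belongs to a marked set (e.g. the CI set); the marked
  set is randomized.
* :func:`directed_link_class_enrichment` — the 4-way analogue for directed
  regulator→target links (TF→target, kinase→substrate).
* :func:`giant_component_test` — is the subnetwork induced by a node set
  more connected than same-size random sets?  One-sided on the induced-LCC
  size.

Zero counts would make the log-ratio undefined; whenever either count in a
round is zero, a half-count (Haldane-style) correction replaces both
fractions by (count + 0.5)/(n + 1), keeping every round finite without
discarding it.  Empirical p-values use the add-one estimator
(1 + #extreme)/(R + 1), two-sided around the null mean for enrichment
scores and one-sided (greater) for the giant-component test.  All
randomness flows from a single integer seed, so results are reproducible
bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _sparse_cc

from cinet.io import AnnotationSet, DirectedLinkSet, InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_RANDOMIZATIONS = 10_000


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of a node-set enrichment test."""

    group_name: str
    feature_name: str
    f_obs: float
    f_rand_mean: float
    score: float  # mean over rounds of log2(f_obs / f_rand)
    p_value: float
    n_randomizations: int
    seed: int


@dataclass(frozen=True)
class ClassStats:
    """Observed vs null summary for one edge/link class."""

    observed: int
    null_mean: float
    log2_enrichment: float
    p_value: float


@dataclass(frozen=True)
class EdgeClassResult:
    """Per-class enrichment of edges or directed links by endpoint marking."""

    marked_name: str
    classes: Mapping[str, ClassStats]
    n_edges: int
    n_randomizations: int
    seed: int


@dataclass(frozen=True)
class GiantComponentTest:
    """Significance of the induced giant component of a node set."""

    set_size: int
    observed_lcc: int
    null_mean: float
    null_max: int
    p_value: float
    n_randomizations: int
    seed: int


def _corrected_log2_ratio(
    k_obs: int, k_rand: np.ndarray, denom: int
) -> np.ndarray:
    """Per-round log2 ratio with the half-count correction on zero counts."""
    needs_fix = (k_rand == 0) | (k_obs == 0)
    f_obs = np.where(needs_fix, (k_obs + 0.5) / (denom + 1), k_obs / denom)
    f_rand = np.where(needs_fix, (k_rand + 0.5) / (denom + 1), k_rand / denom)
    return np.log2(f_obs / f_rand)


def _two_sided_p(observed: float, null: np.ndarray) -> float:
    """Add-one two-sided empirical p around the null mean."""
    center = float(null.mean())
    n_extreme = int(np.sum(np.abs(null - center) >= abs(observed - center)))
    return (1 + n_extreme) / (len(null) + 1)


def enrichment_score(
    universe: Iterable[str],
    group_d: AnnotationSet,
    feature_i: AnnotationSet,
    R: int = DEFAULT_RANDOMIZATIONS,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of *feature* members inside *group*, against random features.

    Both sets are intersected with *universe* first.  f_obs is the fraction
    of group members carrying the feature; each of the R rounds replaces the
    feature by a uniform random subset of the universe of the same size and
    recomputes the fraction.  Under uniform sampling the random intersection
    count is exactly hypergeometric, which is how the null is drawn.

    Raises ``ValueError`` when either intersection with the universe is
    empty, or R < 1.
    """
    universe = frozenset(universe)
    group = group_d.members & universe
    feature = feature_i.members & universe
    if not group:
        raise ValueError(f"group {group_d.name!r} has no members in the universe")
    if not feature:
        raise ValueError(f"feature {feature_i.name!r} has no members in the universe")
    if R < 1:
        raise ValueError("R must be >= 1")

    n, g, s = len(universe), len(group), len(feature)
    k_obs = len(group & feature)

    rng = np.random.default_rng(seed)
    # |group ∩ random feature| for a uniform size-s subset of the universe
    k_rand = rng.hypergeometric(g, n - g, s, size=R)

    per_round = _corrected_log2_ratio(k_obs, k_rand, g)
    f_rand = k_rand / g
    return EnrichmentResult(
        group_name=group_d.name,
        feature_name=feature_i.name,
        f_obs=k_obs / g,
        f_rand_mean=float(f_rand.mean()),
        score=float(per_round.mean()),
        p_value=_two_sided_p(k_obs / g, f_rand),
        n_randomizations=R,
        seed=seed,
    )


UNDIRECTED_CLASSES = ("marked-marked", "marked-unmarked", "unmarked-unmarked")
DIRECTED_CLASSES = (
    "marked->marked",
    "marked->unmarked",
    "unmarked->marked",
    "unmarked->unmarked",
)


def _class_result(
    name: str,
    class_names: tuple[str, ...],
    observed: np.ndarray,
    null_counts: np.ndarray,
    n_items: int,
    R: int,
    seed: int,
) -> EdgeClassResult:
    classes = {}
    for idx, cname in enumerate(class_names):
        obs = int(observed[idx])
        null = null_counts[:, idx]
        null_mean = float(null.mean())
        if obs == 0 or null_mean == 0.0:
            log2_enr = float(np.log2((obs + 0.5) / (null_mean + 0.5)))
        else:
            log2_enr = float(np.log2(obs / null_mean))
        classes[cname] = ClassStats(
            observed=obs,
            null_mean=null_mean,
            log2_enrichment=log2_enr,
            p_value=_two_sided_p(obs, null.astype(float)),
        )
    return EdgeClassResult(
        marked_name=name,
        classes=classes,
        n_edges=n_items,
        n_randomizations=R,
        seed=seed,
    )


def edge_class_enrichment(
    net: InteractionNetwork,
    marked: AnnotationSet,
    R: int = DEFAULT_RANDOMIZATIONS,
    seed: int = 0,
    edge_subset: Iterable[tuple[str, str]] | None = None,
) -> EdgeClassResult:
    """Enrichment of marked–marked / marked–unmarked / unmarked–unmarked edges.

    Each edge (of ``edge_subset`` when given, else all edges of *net*) is
    classified by how many endpoints lie in the marked set; the null
    redraws the marked set uniformly from the network's nodes R times.
    Class counts always sum to the number of edges under analysis.

    Raises ``ValueError`` if the marked set misses the network entirely or
    an ``edge_subset`` edge is not an edge of *net*.
    """
    nodes = sorted(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    marked_nodes = marked.members & set(nodes)
    if not marked_nodes:
        raise ValueError(f"marked set {marked.name!r} has no members in the network")

    if edge_subset is None:
        edges = list(net.edges())
    else:
        edges = [tuple(e) for e in edge_subset]
        for a, b in edges:
            if not net.has_edge(a, b):
                raise ValueError(f"edge ({a!r}, {b!r}) not present in the network")
    u_idx = np.array([index[a] for a, _ in edges], dtype=np.intp)
    v_idx = np.array([index[b] for _, b in edges], dtype=np.intp)

    n, m = len(nodes), len(marked_nodes)
    mask = np.zeros(n, dtype=np.int8)
    mask[[index[v] for v in marked_nodes]] = 1
    # class index = number of unmarked endpoints (0, 1 or 2)
    observed = np.bincount(2 - mask[u_idx] - mask[v_idx], minlength=3)

    rng = np.random.default_rng(seed)
    null_counts = np.empty((R, 3), dtype=np.int64)
    rmask = np.zeros(n, dtype=np.int8)
    for r in range(R):
        rmask[:] = 0
        rmask[rng.choice(n, size=m, replace=False)] = 1
        null_counts[r] = np.bincount(2 - rmask[u_idx] - rmask[v_idx], minlength=3)

    return _class_result(
        marked.name, UNDIRECTED_CLASSES, observed, null_counts, len(edges), R, seed
    )


def directed_link_class_enrichment(
    links: DirectedLinkSet,
    marked: AnnotationSet,
    universe: Iterable[str],
    R: int = DEFAULT_RANDOMIZATIONS,
    seed: int = 0,
) -> EdgeClassResult:
    """4-way enrichment of directed links by source/target marking.

    Links with an endpoint outside the universe are dropped (logged); the
    marked set is randomized within the universe.  An empty link set is not
    an error: all counts are 0 and every p-value is 1.
    """
    nodes = sorted(frozenset(universe))
    if not nodes:
        raise ValueError("universe is empty")
    index = {v: i for i, v in enumerate(nodes)}
    marked_nodes = marked.members & set(nodes)
    if not marked_nodes:
        raise ValueError(f"marked set {marked.name!r} has no members in the universe")

    kept = [(s, t) for s, t in links.links if s in index and t in index]
    n_dropped = len(links.links) - len(kept)
    if n_dropped:
        logger.info(
            "dropped %d link(s) with endpoints outside the universe", n_dropped
        )
    s_idx = np.array([index[s] for s, _ in kept], dtype=np.intp)
    t_idx = np.array([index[t] for _, t in kept], dtype=np.intp)

    n, m = len(nodes), len(marked_nodes)
    mask = np.zeros(n, dtype=np.int8)
    mask[[index[v] for v in marked_nodes]] = 1
    # class index = 2·(source unmarked) + (target unmarked)
    observed = np.bincount(
        2 * (1 - mask[s_idx]) + (1 - mask[t_idx]), minlength=4
    )

    rng = np.random.default_rng(seed)
    null_counts = np.empty((R, 4), dtype=np.int64)
    rmask = np.zeros(n, dtype=np.int8)
    for r in range(R):
        rmask[:] = 0
        rmask[rng.choice(n, size=m, replace=False)] = 1
        null_counts[r] = np.bincount(
            2 * (1 - rmask[s_idx]) + (1 - rmask[t_idx]), minlength=4
        )

    return _class_result(
        marked.name, DIRECTED_CLASSES, observed, null_counts, len(kept), R, seed
    )


def _induced_lcc_sizes(
    adjacency: sp.csr_array, node_indices: np.ndarray
) -> int:
    """LCC size of the subgraph induced on ``node_indices`` (0 when empty)."""
    if len(node_indices) == 0:
        return 0
    sub = adjacency[node_indices][:, node_indices]
    n_comp, labels = _sparse_cc(sub, directed=False)
    return int(np.bincount(labels, minlength=n_comp).max())


def giant_component_test(
    net: InteractionNetwork,
    node_set: AnnotationSet,
    R: int = DEFAULT_RANDOMIZATIONS,
    seed: int = 0,
) -> GiantComponentTest:
    """Is the node set's induced giant component larger than chance?

    Null: R uniform same-size node sets; p = (1 + #{null ≥ observed})/(R+1),
    one-sided greater (the direction of the connectivity claim).
    """
    nodes = sorted(net.nodes)
    members = node_set.members & set(nodes)
    if not members:
        raise ValueError(f"node set {node_set.name!r} has no members in the network")
    if R < 1:
        raise ValueError("R must be >= 1")

    index = {v: i for i, v in enumerate(nodes)}
    adjacency = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csr")
    member_idx = np.array(sorted(index[v] for v in members), dtype=np.intp)
    observed = _induced_lcc_sizes(adjacency, member_idx)

    rng = np.random.default_rng(seed)
    n, m = len(nodes), len(members)
    null = np.empty(R, dtype=np.int64)
    for r in range(R):
        null[r] = _induced_lcc_sizes(adjacency, rng.choice(n, size=m, replace=False))

    return GiantComponentTest(
        set_size=m,
        observed_lcc=observed,
        null_mean=float(null.mean()),
        null_max=int(null.max()),
        p_value=(1 + int(np.sum(null >= observed))) / (R + 1),
        n_randomizations=R,
        seed=seed,
    )
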