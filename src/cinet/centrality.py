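"""Betweenness centrality and bottleneck extraction.

Betweenness c_B(v) = Σ_{s≠t≠v} σ_st(v)/σ_st sums, over unordered pairs of
distinct connected nodes, the fraction of shortest s–t paths that pass
through v (endpoints excluded).  Raw, unnormalized values are reported: the
downstream analysis only uses the ranking, and normalization by
(N−1)(N−2) or the ordered-pair factor of 2 cannot change which nodes land
in the top fraction.  Disconnected pairs contribute nothing.

Bottlenecks are the top 20% of nodes by betweenness (the fraction is a
parameter); the cutoff count is ⌈fraction·N⌉ with ties at the boundary
broken lexicographically so the set is deterministic.
"""

from __future__ import annotations

import math

import networkx as nx

from cinet.io import AnnotationSet, InteractionNetwork

#: node → raw betweenness value
CentralityTable = dict[str, float]


def betweenness(net: InteractionNetwork) -> CentralityTable:
    """Exact unnormalized betweenness for every node (Brandes' algorithm)."""
    return dict(nx.betweenness_centrality(net, normalized=False))


def bottlenecks(table: CentralityTable, fraction: float = 0.2) -> AnnotationSet:
    """The ⌈fraction·N⌉ highest-betweenness nodes, as an annotation set.

    Raises ``ValueError`` on an empty table or a fraction outside (0, 1].
    """
    if not table:
        raise ValueError("centrality table is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    count = math.ceil(fraction * len(table))
    ranked = sorted(table.items(), key=lambda item: (-item[1], item[0]))
    return AnnotationSet(
        name="bottlenecks", members=frozenset(v for v, _ in ranked[:count])
    )
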