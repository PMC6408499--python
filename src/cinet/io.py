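"""Readers/writers for interaction networks, ID sets and pair files.

File dialects are deliberately plain so that database extracts (e.g. HINT
interaction tables, one-gene-per-line essentiality lists, OMA ortholog pair
dumps) can be fed in without conversion:

* edge lists — whitespace- or tab-delimited, first two columns are node IDs,
  ``#`` starts a comment, extra columns silently ignored;
* ID sets — one identifier per line;
* pair files — two columns, either directed links (TF→target,
  kinase→substrate) or ortholog correspondences (human ID, organism ID).

Identifiers are opaque, case-sensitive strings; mapping between accession
namespaces is the caller's job.  Networks are held as :class:`networkx.Graph`,
which enforces the structural invariants (no duplicate edges, undirected
edge identity); self-loops are dropped at load with a logged count because
interaction databases routinely contain both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import networkx as nx

logger = logging.getLogger(__name__)

#: An undirected simple graph over opaque string protein identifiers.
InteractionNetwork = nx.Graph

Source = Union[str, Path, IO[str], Iterable[str]]


@dataclass(frozen=True)
class AnnotationSet:
    """A named set of protein identifiers (a "feature" or a "group").

    Members may contain IDs absent from any particular network; operations
    restrict to the relevant node universe explicitly via :meth:`restrict`.
    """

    name: str
    members: frozenset[str]

    def restrict(self, universe: Iterable[str]) -> frozenset[str]:
        """Members present in *universe*."""
        return self.members & frozenset(universe)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


@dataclass(frozen=True)
class DirectedLinkSet:
    """A named set of ordered (source, target) links, e.g. TF→target."""

    name: str
    links: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.links)


@dataclass(frozen=True)
class OrthologMap:
    """Many-to-many correspondences between source IDs and organism IDs.

    A node is *conserved* iff it has at least one ortholog pair.
    """

    organism: str
    pairs: frozenset[tuple[str, str]]

    @property
    def conserved_ids(self) -> frozenset[str]:
        return frozenset(src for src, _ in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            yield from handle
    else:
        yield from source


def read_edge_list(
    source: Source,
    delimiter: str | None = None,
    comment_prefix: str = "#",
) -> InteractionNetwork:
    """Load an undirected interaction network from a two-column edge list.

    Parameters
    ----------
    source
        Path, open text handle, or iterable of lines.
    delimiter
        Column separator; ``None`` splits on any whitespace run (accepts
        both space- and tab-delimited files).
    comment_prefix
        Lines starting with this prefix are skipped.

    Returns
    -------
    networkx.Graph
        Sanitized network: self-loops dropped, duplicate edges collapsed,
        extra columns ignored.  An empty stream yields an empty network.

    Raises
    ------
    ValueError
        If a non-comment line has fewer than two fields (the message names
        the offending line number).
    """
    net: InteractionNetwork = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ValueError(
                f"malformed edge-list line {lineno}: expected at least 2 "
                f"fields, got {len(fields)}: {line!r}"
            )
        a, b = fields[0], fields[1]
        if a == b:
            n_self_loops += 1
            net.add_node(a)
            continue
        if net.has_edge(a, b):
            n_duplicates += 1
            continue
        net.add_edge(a, b)
    if n_self_loops or n_duplicates:
        logger.info(
            "edge-list sanitization: dropped %d self-loop(s), collapsed %d "
            "duplicate edge(s)",
            n_self_loops,
            n_duplicates,
        )
    return net


def read_id_set(source: Source, name: str = "ids", comment_prefix: str = "#") -> AnnotationSet:
    """Load a one-ID-per-line annotation set.

    Whitespace is trimmed, blank and comment lines are skipped, duplicates
    collapse; an empty stream yields an empty set.
    """
    members = set()
    for raw in _iter_lines(source):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        members.add(line)
    return AnnotationSet(name=name, members=frozenset(members))


def read_pairs(
    source: Source,
    kind: str = "links",
    name: str = "pairs",
    comment_prefix: str = "#",
) -> DirectedLinkSet | OrthologMap:
    """Load a two-column pair file as directed links or an ortholog map.

    Parameters
    ----------
    kind
        ``"links"`` returns a :class:`DirectedLinkSet` (self-links dropped);
        ``"orthologs"`` returns an :class:`OrthologMap` (self-pairs kept —
        identical IDs across namespaces are legitimate).
    name
        Label for the resulting set (the organism for ortholog maps).

    Raises
    ------
    ValueError
        On a line with fewer than two fields, naming the line number.
    """
    if kind not in ("links", "orthologs"):
        raise ValueError(f"kind must be 'links' or 'orthologs', got {kind!r}")
    pairs: set[tuple[str, str]] = set()
    n_self = 0
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(
                f"malformed pair line {lineno}: expected 2 fields: {line!r}"
            )
        src, dst = fields[0], fields[1]
        if kind == "links" and src == dst:
            n_self += 1
            continue
        pairs.add((src, dst))
    if n_self:
        logger.info("dropped %d self-link(s)", n_self)
    if kind == "links":
        return DirectedLinkSet(name=name, links=frozenset(pairs))
    return OrthologMap(organism=name, pairs=frozenset(pairs))


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subnetwork on a maximum-cardinality connected node set.

    Ties between equal-sized components are broken deterministically by the
    component whose lexicographically smallest node ID is smallest.  An empty
    network maps to an empty network.
    """
    if net.number_of_nodes() == 0:
        return nx.Graph()
    best = min(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    return net.subgraph(best).copy()


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Write a network as a two-column TSV with a ``#`` header line.

    Edges are emitted with sorted endpoints in sorted order, so identical
    networks always serialize byte-identically.
    """
    with open(path, "wt", encoding="utf-8") as out:
        out.write("#node_a\tnode_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            out.write(f"{a}\t{b}\n")


def write_id_set(ids: AnnotationSet | Iterable[str], path: str | Path) -> None:
    """Write an ID set, one per line, sorted, with a ``#`` header."""
    members = ids.members if isinstance(ids, AnnotationSet) else frozenset(ids)
    with open(path, "wt", encoding="utf-8") as out:
        out.write("#id\n")
        for member in sorted(members):
            out.write(f"{member}\n")


def write_pairs(pairs: DirectedLinkSet | OrthologMap, path: str | Path) -> None:
    """Write directed links or an ortholog map as a two-column TSV."""
    if isinstance(pairs, DirectedLinkSet):
        header, rows = "#source\ttarget", pairs.links
    else:
        header, rows = "#source_id\torganism_id", pairs.pairs
    with open(path, "wt", encoding="utf-8") as out:
        out.write(header + "\n")
        for a, b in sorted(rows):
            out.write(f"{a}\t{b}\n")
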