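"""Graph and complex-catalog data model, file I/O and summary statistics.

Protein-protein interaction (PPI) networks are held as simple undirected
:class:`networkx.Graph` objects whose nodes are opaque, case-sensitive
protein-ID strings.  Edge reliability weights, when present, live in the
``"weight"`` edge attribute.  Complex catalogs are ordered lists of protein
sets (MIPS-style one-complex-per-line files).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

logger = logging.getLogger("pewcc")


class ParseError(ValueError):
    """Raised for malformed edge-list or catalog input, with a line number."""


@dataclass(frozen=True)
class NeighborhoodGraph:
    """The subgraph induced on a seed protein's neighbours, seed excluded.

    ``members`` are exactly the neighbours of ``seed`` in the parent network;
    ``graph`` holds every parent edge with both endpoints among the members.
    An edge between two members closes a triangle through the seed, so the
    member-edge count equals the number of 3-cliques containing the seed.
    """

    seed: str
    graph: nx.Graph

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_members(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_member_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ComplexSet:
    """An ordered collection of protein complexes (sets of protein IDs).

    Order is preserved for reporting only; membership semantics are pure
    sets.  ``labels``, when present, parallels ``complexes``.
    """

    complexes: list[frozenset[str]] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if any(len(c) == 0 for c in self.complexes):
            raise ValueError("complexes must be non-empty sets")
        if self.labels is not None and len(self.labels) != len(self.complexes):
            raise ValueError("labels must parallel complexes")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    def dedup(self) -> "ComplexSet":
        """Drop exact-duplicate complexes, keeping the first occurrence."""
        seen: set[frozenset[str]] = set()
        kept: list[frozenset[str]] = []
        kept_labels: list[str] = []
        for i, c in enumerate(self.complexes):
            if c in seen:
                continue
            seen.add(c)
            kept.append(c)
            if self.labels is not None:
                kept_labels.append(self.labels[i])
        return ComplexSet(kept, kept_labels if self.labels is not None else None)

    def filter_min_size(self, min_size: int) -> "ComplexSet":
        """Keep only complexes with at least ``min_size`` proteins."""
        kept = [(i, c) for i, c in enumerate(self.complexes) if len(c) >= min_size]
        labels = [self.labels[i] for i, _ in kept] if self.labels is not None else None
        return ComplexSet([c for _, c in kept], labels)


def read_edge_list(source: IO[str], comment_prefix: str = "#") -> nx.Graph:
    """Read a 2- or 3-column whitespace-separated edge list into a graph.

    Duplicate lines and reversed duplicates collapse to a single edge (the
    last weight seen wins); self-loops are dropped with a logged count.  A
    third column, when present, must parse as a non-negative number and is
    stored as the edge ``weight``.
    """
    graph = nx.Graph()
    self_loops = 0
    multi_edges = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"line {lineno}: expected at least 2 columns, got {len(tokens)}")
        u, v = tokens[0], tokens[1]
        weight: float | None = None
        if len(tokens) >= 3:
            try:
                weight = float(tokens[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: weight {tokens[2]!r} is not numeric") from exc
            if not weight >= 0 or weight != weight or weight == float("inf"):
                raise ParseError(f"line {lineno}: weight must be finite and >= 0")
        if u == v:
            self_loops += 1
            graph.add_node(u)
            continue
        if graph.has_edge(u, v):
            multi_edges += 1
        if weight is None:
            graph.add_edge(u, v)
        else:
            graph.add_edge(u, v, weight=weight)
    if self_loops:
        logger.info("dropped %d self-loop(s)", self_loops)
    if multi_edges:
        logger.info("collapsed %d duplicate edge line(s), keeping the last weight seen", multi_edges)
    return graph


def write_edge_list(network: nx.Graph, sink: IO[str]) -> None:
    """Write one edge per line, endpoints in lexicographic order.

    Edges carrying a ``weight`` attribute get a third column with six
    decimals.  Reading the output back reproduces the node and edge sets
    (isolated nodes excepted: an edge list cannot represent them).
    """
    lines = []
    for u, v, data in network.edges(data=True):
        a, b = sorted((u, v))
        if "weight" in data:
            lines.append(f"{a}\t{b}\t{data['weight']:.6f}")
        else:
            lines.append(f"{a}\t{b}")
    for line in sorted(lines):
        sink.write(line + "\n")


def read_complexes(source: IO[str], labeled: bool = False) -> ComplexSet:
    """Read a MIPS-style catalog: one complex per line, whitespace-separated IDs.

    With ``labeled=True`` the first column of each line is the complex name.
    Empty lines are skipped; within-line duplicate IDs collapse with a logged
    warning.
    """
    complexes: list[frozenset[str]] = []
    labels: list[str] = []
    for lineno, raw in enumerate(source, start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if labeled:
            if len(tokens) < 2:
                raise ParseError(f"line {lineno}: labeled line needs a name and at least one ID")
            label, ids = tokens[0], tokens[1:]
        else:
            label, ids = f"line{lineno}", tokens
        members = frozenset(ids)
        if len(members) < len(ids):
            logger.warning("line %d: %d duplicate ID(s) collapsed", lineno, len(ids) - len(members))
        complexes.append(members)
        labels.append(label)
    return ComplexSet(complexes, labels)


def write_complexes(cset: ComplexSet, sink: IO[str], labeled: bool = False) -> None:
    """Write one complex per line, members in lexicographic order."""
    for i, members in enumerate(cset):
        ids = "\t".join(sorted(members))
        if labeled and cset.labels is not None:
            sink.write(f"{cset.labels[i]}\t{ids}\n")
        else:
            sink.write(ids + "\n")


def neighborhood_subgraph(network: nx.Graph, seed: str) -> NeighborhoodGraph:
    """Induce the subgraph on ``seed``'s neighbours, excluding the seed itself.

    Raises ``KeyError`` if the seed is not a node of the network.
    """
    if seed not in network:
        raise KeyError(f"seed {seed!r} not in network")
    members = set(network.neighbors(seed))
    sub = nx.Graph()
    sub.add_nodes_from(members)
    for u, v in network.subgraph(members).edges():
        sub.add_edge(u, v)
    return NeighborhoodGraph(seed=seed, graph=sub)


def network_stats(network: nx.Graph) -> dict[str, float]:
    """Node/edge counts, density, average clustering, mean degree, isolates.

    Density is 2|E| / (N(N-1)) (0 when N < 2); the clustering coefficient is
    the unweighted average of per-node clustering coefficients; mean degree
    is 2|E| / N.
    """
    n = network.number_of_nodes()
    e = network.number_of_edges()
    return {
        "nodes": n,
        "edges": e,
        "density": (2.0 * e / (n * (n - 1))) if n >= 2 else 0.0,
        "clustering_coefficient": nx.average_clustering(network) if n else 0.0,
        "mean_degree": (2.0 * e / n) if n else 0.0,
        "isolated": sum(1 for _, d in network.degree() if d == 0),
    }


def from_edges(edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> nx.Graph:
    """Build a simple undirected graph from an edge iterable (helper)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g
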