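"""Edge-reliability scoring and unreliable-edge filtering.

The PE-measure treats every common neighbour l of an interacting pair (i, j)
as independent probabilistic "support" for the edge: starting from a prior
of 0.5 on every observed interaction, each synchronous iteration sets

    p_ij  <-  1 - prod_l (1 - p_il * p_jl),

the product running over common neighbours of i and j.  Edges that close no
triangle receive probability 0 (the empty product is 1) and edges whose
score falls strictly below the average score at either endpoint are removed
as likely noise.

The classical common-neighbour scores are also provided: the CD-distance,
its degree-adjusted variant AdjstCD, and the iterated AdjstCD weighting that
propagates 3-clique support through the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx


@dataclass
class ReliabilityMatrix:
    """Symmetric edge -> probability map, with an iteration counter.

    Entries exist exactly for the edges of the underlying network; pairs
    that do not interact carry probability 0 implicitly and are never
    stored.
    """

    entries: dict[frozenset[str], float] = field(default_factory=dict)
    iteration: int = 0

    def value(self, u: str, v: str) -> float:
        """Reliability of pair (u, v); 0 for non-edges."""
        return self.entries.get(frozenset((u, v)), 0.0)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()


def pe_initialize(network: nx.Graph) -> ReliabilityMatrix:
    """Prior reliability 0.5 on every edge (iteration 0)."""
    return ReliabilityMatrix(
        entries={frozenset((u, v)): 0.5 for u, v in network.edges()},
        iteration=0,
    )


def pe_iterate(matrix: ReliabilityMatrix, network: nx.Graph) -> ReliabilityMatrix:
    """One synchronous PE update of every edge from the previous matrix.

    All right-hand-side probabilities are read from ``matrix`` (Jacobi-style
    update); an edge with no common neighbours gets 0.
    """
    adj = {node: set(network.neighbors(node)) for node in network.nodes}
    new_entries: dict[frozenset[str], float] = {}
    for u, v in network.edges():
        prod = 1.0
        for l in adj[u] & adj[v]:
            prod *= 1.0 - matrix.value(u, l) * matrix.value(v, l)
        new_entries[frozenset((u, v))] = 1.0 - prod
    return ReliabilityMatrix(entries=new_entries, iteration=matrix.iteration + 1)


def pe_score(network: nx.Graph, k: int = 2) -> ReliabilityMatrix:
    """PE-measure after k synchronous iterations from the 0.5 prior.

    k = 2 is the default used throughout; larger k brings no further
    benefit in practice.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    matrix = pe_initialize(network)
    for _ in range(k):
        matrix = pe_iterate(matrix, network)
    return matrix


def node_average(matrix: ReliabilityMatrix, network: nx.Graph) -> dict[str, float]:
    """Mean reliability of each node's incident edges.

    Isolated nodes have no entry: an average over zero edges is undefined.
    """
    avg: dict[str, float] = {}
    for node in network.nodes:
        neighbors = list(network.neighbors(node))
        if not neighbors:
            continue
        avg[node] = sum(matrix.value(node, l) for l in neighbors) / len(neighbors)
    return avg


def filter_unreliable(network: nx.Graph, matrix: ReliabilityMatrix) -> nx.Graph:
    """Remove every edge scoring strictly below the average at either endpoint.

    All averages are computed on the unfiltered network first, then every
    removal is applied at once, so the outcome does not depend on scan
    order.  Ties (score equal to the average) survive.  Nodes are never
    removed and may become isolated.  Surviving edges carry their
    reliability score as the ``weight`` attribute.
    """
    avg = node_average(matrix, network)
    filtered = nx.Graph()
    filtered.add_nodes_from(network.nodes)
    for u, v in network.edges():
        p = matrix.value(u, v)
        if p < avg[u] or p < avg[v]:
            continue
        filtered.add_edge(u, v, weight=p)
    return filtered


def cd_distance(network: nx.Graph, u: str, v: str) -> float:
    """Czekanowski-Dice distance: 1 - 2|Nu n Nv| / (|Nu| + |Nv|).

    Neighbour sets do not include the node itself.  Undefined (domain
    error) when both nodes are isolated.
    """
    nu = set(network.neighbors(u))
    nv = set(network.neighbors(v))
    denom = len(nu) + len(nv)
    if denom == 0:
        raise ValueError(f"CD-distance undefined: {u!r} and {v!r} are both isolated")
    return 1.0 - 2.0 * len(nu & nv) / denom


def _mean_degree(network: nx.Graph) -> float:
    n = network.number_of_nodes()
    return (2.0 * network.number_of_edges() / n) if n else 0.0


def adjstcd(network: nx.Graph, u: str, v: str) -> float:
    """Degree-adjusted common-neighbour similarity.

    2|Nu n Nv| / (max(|Nu|, N_avg) + max(|Nv|, N_avg)), where N_avg is the
    mean degree over all nodes (isolated nodes included).  The max() floors
    penalise proteins with too few observed interactions.
    """
    nu = set(network.neighbors(u))
    nv = set(network.neighbors(v))
    n_avg = _mean_degree(network)
    denom = max(len(nu), n_avg) + max(len(nv), n_avg)
    if denom == 0:
        return 0.0
    return 2.0 * len(nu & nv) / denom


def adjstcd_iterate(network: nx.Graph, k: int = 2) -> ReliabilityMatrix:
    """Iterated AdjstCD weights on the network's edges after k steps.

    w^0 is the adjacency indicator; each step computes, synchronously,

        w^k(u,v) = sum_{x in Nu n Nv} (w^{k-1}(x,u) + w^{k-1}(x,v))
                   / [ max(sum_{x in Nu} w^{k-1}(x,u), w_avg^{k-1})
                     + max(sum_{x in Nv} w^{k-1}(x,v), w_avg^{k-1}) ],

    with w_avg^{k-1} the grand mean sum_x sum_{y in Nx} w^{k-1}(x,y) / n
    over the n nodes.  The first step reproduces AdjstCD exactly.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    adj = {node: set(network.neighbors(node)) for node in network.nodes}
    n = network.number_of_nodes()
    w: dict[frozenset[str], float] = {frozenset((u, v)): 1.0 for u, v in network.edges()}
    for _ in range(k):
        def wv(a: str, b: str) -> float:
            return w.get(frozenset((a, b)), 0.0)

        strength = {node: sum(wv(node, y) for y in adj[node]) for node in network.nodes}
        w_avg = (sum(strength.values()) / n) if n else 0.0
        new_w: dict[frozenset[str], float] = {}
        for u, v in network.edges():
            num = sum(wv(x, u) + wv(x, v) for x in adj[u] & adj[v])
            denom = max(strength[u], w_avg) + max(strength[v], w_avg)
            new_w[frozenset((u, v))] = (num / denom) if denom > 0 else 0.0
        w = new_w
    assert all(math.isfinite(x) for x in w.values())
    return ReliabilityMatrix(entries=w, iteration=k)
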