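"""Complex detection by lowest-degree peeling of neighbourhood graphs.

For each seed protein the subgraph induced on its neighbours (seed
excluded) is peeled one member at a time — always the member of minimum
degree within the current member subgraph — down to 3 members, scoring
every intermediate subgraph with the weighted clustering coefficient

    c = 2 * N_3cliques / (N_i^2 * (N_i - 1)),

where N_i is the member count and N_3cliques the number of triangles
through the seed, i.e. the number of edges among the members.  The
best-scoring member set (plus the seed) is the core complex; neighbours
interacting with strictly more than a fraction t of the core are then
rejoined in a single pass.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

from pewcc.ppi_graph import ComplexSet, NeighborhoodGraph, neighborhood_subgraph


@dataclass(frozen=True)
class PeelStep:
    members: frozenset[str]
    n_3cliques: int
    c: float


@dataclass
class PeelTrace:
    """The sequence of (member set, 3-clique count, c) states of one peel.

    Member sets shrink by exactly one node per step; the last state has 3
    members (the trace is the single initial state when it starts at 3).
    ``argmax`` is the index of the highest c, earliest state on ties.
    """

    steps: list[PeelStep]

    @property
    def argmax(self) -> int:
        best = 0
        for i, step in enumerate(self.steps):
            if step.c > self.steps[best].c:
                best = i
        return best


@dataclass
class PredictedComplex:
    """A predicted complex with its provenance (seed, core, core score)."""

    members: frozenset[str]
    seed: str
    core: frozenset[str]
    c_core: float

    def __post_init__(self) -> None:
        assert self.core <= self.members and self.seed in self.members
        assert 0.0 <= self.c_core <= 1.0


def wcc(neigh: NeighborhoodGraph) -> float:
    """Weighted clustering coefficient of a neighbourhood graph.

    c = 2 * N_3cliques / (N_i^2 * (N_i - 1)) with N_i the member count
    (seed excluded) and N_3cliques the member-edge count.  Undefined for
    fewer than 2 members.
    """
    n_i = neigh.n_members
    if n_i < 2:
        raise ValueError(f"weighted clustering coefficient undefined for {n_i} member(s)")
    return 2.0 * neigh.n_member_edges / (n_i * n_i * (n_i - 1))


def _pick_min_degree(graph: nx.Graph, tie_break: str, rng: random.Random | None) -> str:
    degrees = dict(graph.degree())
    min_deg = min(degrees.values())
    candidates = sorted(node for node, d in degrees.items() if d == min_deg)
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-break requires an rng")
        return rng.choice(candidates)
    if tie_break == "lex":
        return candidates[0]
    raise ValueError(f"unknown tie_break policy {tie_break!r}")


def peel(
    neigh: NeighborhoodGraph,
    tie_break: str = "lex",
    rng: random.Random | None = None,
) -> PeelTrace:
    """Peel the minimum-degree member off until 3 members remain.

    Degrees are counted within the member-induced subgraph only (the edge
    to the seed never counts).  Ties go to the lexicographically smallest
    member under the default ``"lex"`` policy, or to a uniformly random
    minimum-degree member under ``"random"``.
    """
    if neigh.n_members < 3:
        raise ValueError(f"peeling needs >= 3 members, got {neigh.n_members}")
    work = neigh.graph.copy()
    seed = neigh.seed

    def snapshot() -> PeelStep:
        g = NeighborhoodGraph(seed=seed, graph=work)
        return PeelStep(frozenset(work.nodes), work.number_of_edges(), wcc(g))

    steps = [snapshot()]
    while work.number_of_nodes() > 3:
        victim = _pick_min_degree(work, tie_break, rng)
        work.remove_node(victim)
        steps.append(snapshot())
    return PeelTrace(steps=steps)


def extract_core(
    network: nx.Graph,
    seed: str,
    tie_break: str = "lex",
    rng: random.Random | None = None,
) -> tuple[frozenset[str], float] | None:
    """Best-scoring peeled member set, with the seed added back.

    Returns ``(core, c)`` where core = {seed} + members at the peel step of
    highest c, or ``None`` for seeds of degree < 3 (nothing to peel).
    """
    if network.degree(seed) < 3:
        return None
    neigh = neighborhood_subgraph(network, seed)
    trace = peel(neigh, tie_break=tie_break, rng=rng)
    best = trace.steps[trace.argmax]
    return frozenset(best.members | {seed}), best.c


def rejoin(
    network: nx.Graph,
    neigh: NeighborhoodGraph,
    core: frozenset[str],
    t: float = 0.3,
) -> frozenset[str]:
    """Re-admit original neighbourhood members well-connected to the core.

    A member outside the core joins iff its network neighbours cover
    strictly more than fraction ``t`` of the core (seed included in the
    denominator).  Single pass: every candidate is judged against the
    pre-rejoin core, so admissions never cascade.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    joined = set(core)
    for candidate in neigh.members - core:
        overlap = len(set(network.neighbors(candidate)) & core)
        if overlap / len(core) > t:
            joined.add(candidate)
    return frozenset(joined)


def predict_all(
    network: nx.Graph,
    t: float = 0.3,
    tie_break: str = "lex",
    rng_seed: int = 0,
) -> list[PredictedComplex]:
    """Run core extraction + rejoin from every seed of degree >= 3.

    Seeds are visited in sorted node order, so the output is deterministic
    given the tie-break policy and ``rng_seed``.
    """
    rng = random.Random(rng_seed)
    out: list[PredictedComplex] = []
    for seed in sorted(network.nodes):
        result = extract_core(network, seed, tie_break=tie_break, rng=rng)
        if result is None:
            continue
        core, c = result
        neigh = neighborhood_subgraph(network, seed)
        members = rejoin(network, neigh, core, t=t)
        out.append(PredictedComplex(members=members, seed=seed, core=core, c_core=c))
    return out


def detect_complexes(
    network: nx.Graph,
    t: float = 0.3,
    min_size: int = 4,
    tie_break: str = "lex",
    rng_seed: int = 0,
) -> ComplexSet:
    """Predicted complexes of size >= ``min_size``, exact duplicates dropped.

    Defaults t = 0.3 and min_size = 4; the first occurrence (by sorted seed
    order) of each duplicate member set is kept, labelled by its seed.
    """
    predictions = predict_all(network, t=t, tie_break=tie_break, rng_seed=rng_seed)
    kept = [p for p in predictions if len(p.members) >= min_size]
    cset = ComplexSet([p.members for p in kept], labels=[f"seed:{p.seed}" for p in kept])
    return cset.dedup()
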