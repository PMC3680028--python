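"""Fixture networks and synthetic planted-complex benchmarks.

Two tiny hand-specified networks reproduce the worked examples used
throughout the documentation and tests: a 5-protein/6-interaction network
for the reliability step and a 6-protein/12-interaction network for the
detection step.  The planted-complex generator builds larger benchmarks
with known ground truth — dense vertex groups (the "complexes") on a
sparse random background — plus helpers that inject or delete random
edges to emulate noisy interaction screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from pewcc.ppi_graph import ComplexSet, from_edges


def fixture_fig2() -> nx.Graph:
    """5 proteins, 6 interactions; the reliability-scoring worked example.

    Edge (3,5) closes no triangle, so the PE-measure sends it to 0 and the
    filter removes it.
    """
    return from_edges([("1", "2"), ("1", "3"), ("2", "3"), ("2", "4"), ("1", "4"), ("3", "5")])


def fixture_fig3() -> nx.Graph:
    """6 proteins, 12 interactions; the peeling worked example.

    Seed 1's neighbourhood {2,3,4,5,6} has 7 member edges; node 5 is the
    unique minimum-degree member, after which 3 and 4 tie.
    """
    return from_edges(
        [
            ("1", "2"), ("1", "3"), ("1", "4"), ("1", "5"), ("1", "6"),
            ("2", "3"), ("2", "4"), ("2", "6"),
            ("3", "6"), ("4", "6"),
            ("3", "5"), ("4", "5"),
        ]
    )


def add_random_edges(network: nx.Graph, count: int, rng_seed: int) -> nx.Graph:
    """Add ``count`` uniformly sampled absent, non-self pairs among existing nodes.

    Reproducible from ``rng_seed``; raises when fewer than ``count`` pairs
    are absent.
    """
    nodes = sorted(network.nodes)
    absent = [
        (u, v) for u, v in combinations(nodes, 2) if not network.has_edge(u, v)
    ]
    if count > len(absent):
        raise ValueError(f"cannot add {count} edges: only {len(absent)} pairs are absent")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(absent), size=count, replace=False)
    noisy = network.copy()
    noisy.add_edges_from(absent[i] for i in chosen)
    return noisy


def remove_random_edges(network: nx.Graph, count: int, rng_seed: int) -> nx.Graph:
    """Delete ``count`` uniformly sampled edges; reproducible from ``rng_seed``."""
    edges = sorted(tuple(sorted(e)) for e in network.edges())
    if count > len(edges):
        raise ValueError(f"cannot remove {count} edges: network has {len(edges)}")
    rng = np.random.default_rng(rng_seed)
    chosen = set(rng.choice(len(edges), size=count, replace=False).tolist())
    thinned = network.copy()
    thinned.remove_edges_from(edges[i] for i in chosen)
    return thinned


@dataclass
class PlantedBenchmark:
    """A synthetic network with known dense vertex groups as ground truth."""

    network: nx.Graph
    truth: ComplexSet
    params: dict


def planted_complex_network(
    n_complexes: int = 10,
    size_min: int = 5,
    size_max: int = 8,
    p_in: float = 0.9,
    background_nodes: int = 40,
    p_out: float = 0.01,
    noise_edges: int = 0,
    rng_seed: int = 0,
) -> PlantedBenchmark:
    """Generate a planted-complex benchmark.

    ``n_complexes`` disjoint vertex groups with sizes uniform in
    [size_min, size_max] get within-group edges with probability ``p_in``;
    every other node pair (including pairs touching the ``background_nodes``
    extra proteins) appears with probability ``p_out``; ``noise_edges``
    additional uniformly random absent pairs are then injected.  The truth
    catalog is exactly the planted groups.  Byte-identical output for a
    fixed seed.
    """
    if size_min < 4 or size_max < size_min:
        raise ValueError("complex sizes must satisfy 4 <= size_min <= size_max")
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_complexes < 1 or background_nodes < 0 or noise_edges < 0:
        raise ValueError("counts must be non-negative (and n_complexes >= 1)")
    rng = np.random.default_rng(rng_seed)
    sizes = rng.integers(size_min, size_max + 1, size=n_complexes)
    groups: list[frozenset[str]] = []
    network = nx.Graph()
    member_of: dict[str, int] = {}
    for c, size in enumerate(sizes):
        ids = [f"C{c:02d}_{j:02d}" for j in range(size)]
        groups.append(frozenset(ids))
        network.add_nodes_from(ids)
        member_of.update({i: c for i in ids})
    network.add_nodes_from(f"B{j:03d}" for j in range(background_nodes))

    nodes = sorted(network.nodes)
    for u, v in combinations(nodes, 2):
        same_group = u in member_of and v in member_of and member_of[u] == member_of[v]
        p = p_in if same_group else p_out
        if p > 0 and rng.random() < p:
            network.add_edge(u, v)
    if noise_edges:
        network = add_random_edges(network, noise_edges, rng_seed=int(rng.integers(2**31)))
    params = {
        "n_complexes": n_complexes,
        "size_min": size_min,
        "size_max": size_max,
        "p_in": p_in,
        "background_nodes": background_nodes,
        "p_out": p_out,
        "noise_edges": noise_edges,
        "rng_seed": rng_seed,
    }
    return PlantedBenchmark(network=network, truth=ComplexSet(groups), params=params)
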