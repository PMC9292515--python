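"""Shared fixtures: small hand-built networks, random instances, brute-force oracles."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from nichespotter.network_io import SignalingNetwork


def make_network(edges, layers=None) -> SignalingNetwork:
    """Build a SignalingNetwork from (u, v, sign) triples.

    Layers default to the standard inference: no in-edge -> receptor,
    no out-edge -> tf, otherwise intermediate.
    """
    g = nx.DiGraph()
    for u, v, s in edges:
        g.add_edge(u, v, sign=s)
    if layers is None:
        layers = {}
        for n in g.nodes:
            if g.in_degree(n) == 0:
                layers[n] = "receptor"
            elif g.out_degree(n) == 0:
                layers[n] = "tf"
            else:
                layers[n] = "intermediate"
    net = SignalingNetwork(graph=g, layer=dict(layers))
    net.validate()
    return net


def random_network(rng: np.random.Generator, n: int, p: float = 0.25) -> SignalingNetwork:
    """Random signed digraph with no isolated nodes; layers inferred."""
    nodes = [f"n{i:03d}" for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(nodes[i], nodes[j], sign=1 if rng.random() < 0.5 else -1)
    # connect any isolated node into a chain so every node has an edge
    for i, node in enumerate(nodes):
        if g.degree(node) == 0:
            other = nodes[(i + 1) % n]
            g.add_edge(node, other, sign=1)
    layers = {}
    for node in g.nodes:
        if g.in_degree(node) == 0:
            layers[node] = "receptor"
        elif g.out_degree(node) == 0:
            layers[node] = "tf"
        else:
            layers[node] = "intermediate"
    net = SignalingNetwork(graph=g, layer=layers)
    net.validate()
    return net


def random_expression(rng: np.random.Generator, network: SignalingNetwork,
                      low: float = 0.5, high: float = 20.0) -> dict[str, float]:
    return {n: float(rng.uniform(low, high)) for n in network.nodes}


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package's BFS/DAG machinery)


def dfs_shortest_paths(network: SignalingNetwork, source: str, target: str):
    """All minimum-hop paths by exhaustive DFS over simple paths."""
    g = network.graph
    out = []

    def walk(node, path, seen):
        if node == target:
            out.append(tuple(path))
            return
        for nxt in g.successors(node):
            if nxt not in seen:
                walk(nxt, path + [nxt], seen | {nxt})

    walk(source, [source], {source})
    if not out:
        return []
    m = min(len(p) for p in out)
    return sorted(p for p in out if len(p) == m)


def oracle_pair_score(network: SignalingNetwork, source: str, tf: str,
                      direction: int, pi: dict[str, float]):
    """Recompute the pair compatibility score from scratch via DFS enumeration.

    Returns (score, n_paths, n_compatible) or None when no path exists.
    Deliberately sums the compatible-class Omega directly (no complement
    shortcut) so it is an independent route to the same number.
    """
    paths = dfs_shortest_paths(network, source, tf)
    if not paths:
        return None
    raws = []
    for p in paths:
        interior = p[1:-1]
        if not interior:
            raws.append(1.0)
        else:
            raws.append(math.prod(pi[n] for n in interior) ** (1.0 / len(interior)))
    total = sum(raws)
    if total == 0:
        raws = [1.0] * len(paths)
        total = float(len(paths))
    score = 0.0
    n_compat = 0
    for p, r in zip(paths, raws):
        s = 1
        for u, v in zip(p, p[1:]):
            s *= network.sign(u, v)
        if s == direction:
            score += r / total
            n_compat += 1
    return score, len(paths), n_compat


@pytest.fixture
def diamond():
    """A -> {B, C} -> T with mixed signs: two length-2 shortest paths."""
    return make_network(
        [("A", "B", 1), ("A", "C", 1), ("B", "T", 1), ("C", "T", -1)]
    )
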