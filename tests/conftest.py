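"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from math import comb, sqrt

import networkx as nx
import numpy as np
import pytest


def oracle_max_module_score(g: nx.Graph, seed) -> float:
    """Exhaustive maximum of sum(z)/sqrt(k) over all connected subgraphs
    containing ``seed``.  Enumerates connected supersets recursively; only
    usable on small graphs (<= ~12 nodes)."""
    z = {n: float(g.nodes[n]["z"]) for n in g.nodes}
    best = [z[seed]]

    def recurse(members: set, frontier: list):
        score = sum(z[m] for m in members) / sqrt(len(members))
        if score > best[0]:
            best[0] = score
        for i, node in enumerate(frontier):
            new_members = members | {node}
            new_frontier = frontier[i + 1:] + [
                nb for nb in g.neighbors(node)
                if nb not in new_members and nb not in frontier]
            recurse(new_members, new_frontier)

    recurse({seed}, sorted(g.neighbors(seed)))
    return best[0]


def hypergeom_tail_exact(a: int, N: int, K: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n), by explicit summation
    of binomial-coefficient ratios (exact integer arithmetic)."""
    lo = max(a, max(0, K + n - N))
    hi = min(K, n)
    if lo > hi:
        return 0.0
    total = comb(N, n)
    return float(sum(comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1)) / total)


def weighted_graph(edges, z_values) -> nx.Graph:
    """Small node-weighted graph for search tests."""
    g = nx.Graph()
    for node, z in z_values.items():
        g.add_node(node, z=float(z), weighted=True)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def star_fixture():
    """Star: center z=2.0, two leaves z=2.0, three leaves z=-5."""
    z = {"c": 2.0, "l1": 2.0, "l2": 2.0, "m1": -5.0, "m2": -5.0, "m3": -5.0}
    edges = [("c", leaf) for leaf in z if leaf != "c"]
    return weighted_graph(edges, z)


@pytest.fixture
def toy_interactions(tmp_path):
    """Five interactions with publication counts [1, 2, 3, 1, 2]."""
    lines = [
        "A\tB\tpmid:1",
        "B\tC\tpmid:2|pmid:3",
        "C\tD\tpmid:4|pmid:5|pmid:6",
        "D\tE\tpmid:7",
        "E\tF\tpmid:8|pmid:9",
    ]
    path = tmp_path / "toy_interactions.tsv"
    path.write_text("".join(line + "\n" for line in lines))
    return path


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The default synthetic study: 500-node scale-free network, planted
    8-gene module with P ~ U(0, 1e-3), 20 mock-MHC genes."""
    from netgwas import simulate as sim

    return sim.simulate_dataset(sim.SyntheticConfig(seed=11))
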