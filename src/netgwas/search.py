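"""Dense module search on the node-weighted interactome.

Greedy seed-and-grow maximisation of the module score

    Zm = (sum of member z-scores) / sqrt(k)

for a module of k genes, where each gene's z is the inverse-normal
transform of its gene-level P-value.  Starting from every eligible seed,
the module repeatedly absorbs the candidate node (within graph distance
``d`` of the current module) that maximises the new score, and a step is
accepted only if it raises the score by more than the factor ``1 + r``
(r = 0.1 by default).  Unweighted nodes (sigMHC genes) are never seeds and
are never absorbed; they rejoin at the merge stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import networkx as nx
import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = ["SearchParams", "Module", "z_transform", "module_score",
           "grow_module", "search_all", "write_modules", "read_modules"]

Z_P_FLOOR = 1e-16


def z_transform(p: float) -> float:
    """Inverse-normal transform Phi^{-1}(1 - p); strictly decreasing in p."""
    if not 0 < p <= 1:
        raise DataError(f"P-value {p} outside (0, 1]")
    return float(stats.norm.isf(max(p, Z_P_FLOOR)))


def module_score(z_values) -> float:
    """Normalised sum-of-z module score, Zm = sum(z) / sqrt(k)."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise DataError("module score of an empty gene set")
    return float(z.sum() / sqrt(z.size))


@dataclass(frozen=True)
class SearchParams:
    """Growth parameters: increment rate ``r`` and candidate distance ``d``."""

    r: float = 0.1
    d: int = 1
    exclude_seeds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.r < 0:
            raise ConfigurationError("r must be non-negative")
        if self.d not in (1, 2):
            raise ConfigurationError("d must be 1 or 2")


@dataclass(frozen=True)
class Module:
    seed: str
    genes: frozenset[str]
    score: float
    p_norm: float | None = None
    p_topo: float | None = None

    @property
    def k(self) -> int:
        return len(self.genes)


def _weighted(g: nx.Graph, node) -> bool:
    return bool(g.nodes[node].get("weighted", False))


def _growth_options(g: nx.Graph, members: set[str], d: int):
    """Admissible growth steps: (node_tuple, added_z) pairs.

    At d=1 a step adds one weighted neighbor of the module.  At d=2 a
    weighted node two hops away may be added together with its best
    (highest-z) weighted bridging neighbor, so the module always stays
    connected.
    """
    ring1 = {n for m in members for n in g.neighbors(m)} - members
    ring1_w = {n for n in ring1 if _weighted(g, n)}
    options = [((n,), float(g.nodes[n]["z"])) for n in sorted(ring1_w)]
    if d == 2:
        ring2 = {n for m in ring1_w for n in g.neighbors(m)} - members - ring1
        for node in sorted(n for n in ring2 if _weighted(g, n)):
            bridges = [b for b in g.neighbors(node) if b in ring1_w]
            if not bridges:
                continue
            bridge = max(bridges, key=lambda b: (float(g.nodes[b]["z"]), b))
            options.append(((bridge, node),
                            float(g.nodes[node]["z"]) + float(g.nodes[bridge]["z"])))
    return options


def grow_module(network: nx.Graph, seed: str, params: SearchParams | None = None) -> Module:
    """Grow one module greedily from ``seed``.

    Each step admits the growth option maximising the new score, but only
    if ``Z_new > Z_old * (1 + r)``; ties go to the lexicographically
    smallest gene id for determinism.  The module stays connected.
    """
    params = params or SearchParams()
    if seed not in network:
        raise DataError(f"seed gene {seed!r} not in network")
    if not _weighted(network, seed):
        raise DataError(f"seed gene {seed!r} has no z-weight")
    members = {seed}
    z_sum = float(network.nodes[seed]["z"])
    score = z_sum  # k=1
    while True:
        options = _growth_options(network, members, params.d)
        if not options:
            break
        best_nodes, best_score = None, -np.inf
        for nodes, added in options:
            s = (z_sum + added) / sqrt(len(members) + len(nodes))
            if s > best_score:
                best_nodes, best_score = nodes, s
        if best_score > score * (1.0 + params.r):
            members.update(best_nodes)
            z_sum += sum(float(network.nodes[n]["z"]) for n in best_nodes)
            score = best_score
        else:
            break
    return Module(seed=seed, genes=frozenset(members), score=score)


def search_all(network: nx.Graph, params: SearchParams | None = None) -> list[Module]:
    """One greedy growth per eligible seed, deduplicated by gene set.

    Every weighted node except those in ``params.exclude_seeds`` (the
    sigMHC genes) seeds one growth.  Modules with identical gene sets
    collapse to the one whose seed sorts first; the output is ordered by
    descending score, then seed id.
    """
    params = params or SearchParams()
    seen: dict[frozenset[str], Module] = {}
    for seed in sorted(n for n in network.nodes
                       if _weighted(network, n) and n not in params.exclude_seeds):
        mod = grow_module(network, seed, params)
        if mod.genes not in seen:
            seen[mod.genes] = mod
    return sorted(seen.values(), key=lambda m: (-m.score, m.seed))


def write_modules(modules: list[Module], path) -> None:
    import pandas as pd
    rows = [(m.seed, m.k, m.score, ",".join(sorted(m.genes))) for m in modules]
    pd.DataFrame(rows, columns=["SEED", "K", "SCORE", "GENES"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_modules(path) -> list[Module]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t", dtype={"SEED": str, "GENES": str})
    return [Module(seed=r.SEED, genes=frozenset(r.GENES.split(",")), score=float(r.SCORE))
            for r in df.itertuples(index=False)]
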