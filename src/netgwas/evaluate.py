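"""Two-stage significance evaluation of candidate modules.

Stage 1 (score test): module scores are median-centered and an empirical
null normal N(mu, sigma) is fitted to the central bulk of the centered
distribution by quantile (central) matching, so that a minority of truly
enriched modules in the right tail does not inflate the null scale.  Each
module's upper-tail P-value ``p_norm`` comes from the fitted normal.

Stage 2 (topology test): to control for the tendency of the greedy search
to favour well-connected genes, network nodes are split into four degree
groups (quartiles of the degree distribution).  For an observed module,
random gene sets of the same size and the same degree-group profile are
drawn (without replacement within a draw) and scored; ``p_topo`` is the
(+1)/(+1)-corrected fraction of random sets scoring at least as high.

Modules passing both tests at ``alpha`` are merged; the union re-admits
the unweighted sigMHC genes together with all induced interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import substream
from .errors import ConfigurationError, DataError, EstimationError, SamplingError
from .search import Module, module_score

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution", "DegreeBins", "EvaluatedModule",
    "fit_empirical_null", "normal_stage_pvalues", "assign_degree_bins",
    "topo_permutation_pvalue", "evaluate_modules", "select_and_merge",
    "write_evaluated", "sample_null_module",
]


@dataclass(frozen=True)
class NullDistribution:
    mu: float
    sigma: float
    method: str
    n_scores: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise EstimationError("null sigma must be positive")


def fit_empirical_null(scores, method: str = "central_matching",
                       band: tuple[float, float] = (0.25, 0.75)) -> NullDistribution:
    """Fit N(mu, sigma) to the bulk of median-centered module scores.

    ``central_matching`` regresses the empirical quantiles of the centered
    scores, over the central ``band``, on standard normal quantiles; the
    intercept estimates mu and the slope sigma.  This is resistant to a
    minority of signal modules in the right tail.  ``mle`` fits a
    truncated normal to the scores inside the band by maximum likelihood.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2 or np.ptp(s) == 0:
        raise EstimationError("cannot fit a null to constant or near-empty scores")
    if s.size < 50:
        logger.warning("fitting empirical null to only %d scores", s.size)
    centered = s - np.median(s)
    lo, hi = band
    if not 0 <= lo < hi <= 1:
        raise ConfigurationError("quantile band must satisfy 0 <= lo < hi <= 1")
    if method == "central_matching":
        q = np.linspace(lo, hi, 101)
        emp = np.quantile(centered, q)
        theo = stats.norm.ppf(q)
        sigma, mu = np.polyfit(theo, emp, 1)
        if sigma <= 0:
            raise EstimationError("central matching produced non-positive sigma")
        return NullDistribution(float(mu), float(sigma), "central_matching", s.size)
    if method == "mle":
        a, b = np.quantile(centered, [lo, hi])
        x = centered[(centered >= a) & (centered <= b)]
        if x.size < 10:
            raise EstimationError("too few scores inside the trimmed band")

        def nll(theta):
            mu, log_sigma = theta
            sigma = np.exp(log_sigma)
            z = (x - mu) / sigma
            denom = stats.norm.cdf((b - mu) / sigma) - stats.norm.cdf((a - mu) / sigma)
            if denom <= 0:
                return np.inf
            return float(np.sum(0.5 * z**2 + log_sigma) + x.size * np.log(denom))

        res = optimize.minimize(nll, x0=[float(np.mean(x)), float(np.log(np.std(x) + 1e-9))],
                                method="Nelder-Mead")
        mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
        return NullDistribution(mu, sigma, "mle", s.size)
    raise ConfigurationError(f"unknown null-fitting method {method!r}")


def normal_stage_pvalues(scores, null: NullDistribution) -> np.ndarray:
    """Upper-tail P-values of median-centered scores under the fitted null."""
    s = np.asarray(scores, dtype=float)
    centered = s - np.median(s)
    return stats.norm.sf((centered - null.mu) / null.sigma)


@dataclass(frozen=True)
class DegreeBins:
    """Four degree groups (quartiles of the degree distribution)."""

    boundaries: tuple[float, float, float]
    assignment: dict[str, int]  # gene id -> bin index 0..3

    def counts(self) -> list[int]:
        c = [0, 0, 0, 0]
        for b in self.assignment.values():
            c[b] += 1
        return c


def assign_degree_bins(network: nx.Graph,
                       boundaries: tuple[float, float, float] | None = None) -> DegreeBins:
    """Partition all network nodes into 4 groups by degree.

    Boundaries default to the 25/50/75% quantiles of the degree values;
    a node whose degree equals a boundary goes to the lower bin.
    """
    if network.number_of_nodes() == 0:
        raise DataError("empty network")
    degrees = dict(network.degree())
    if boundaries is None:
        vals = np.array(list(degrees.values()), dtype=float)
        boundaries = tuple(np.quantile(vals, [0.25, 0.5, 0.75]))
    b = np.asarray(boundaries, dtype=float)
    assignment = {n: int(np.sum(d > b)) for n, d in degrees.items()}
    return DegreeBins(tuple(float(x) for x in b), assignment)


def _bin_pools(network: nx.Graph, bins: DegreeBins) -> dict[int, tuple[list[str], np.ndarray]]:
    """Weighted nodes and their z-values per degree bin (sorted for determinism)."""
    pools: dict[int, list[str]] = {}
    for node, b in bins.assignment.items():
        if node in network and network.nodes[node].get("weighted", False):
            pools.setdefault(b, []).append(node)
    out = {}
    for b, nodes in pools.items():
        nodes.sort()
        out[b] = (nodes, np.array([float(network.nodes[n]["z"]) for n in nodes]))
    return out


def topo_permutation_pvalue(network: nx.Graph, module: Module, bins: DegreeBins,
                            n_perm: int = 10_000, seed: int | np.random.Generator = 0,
                            _pools=None) -> float:
    """Degree-matched permutation P-value of a module score.

    Each resample replaces every module gene by a random distinct weighted
    gene from its degree group (without replacement within one resample)
    and scores the set; ``p = (#{random >= observed} + 1)/(n_perm + 1)``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be positive")
    missing = [g for g in module.genes if g not in network]
    if missing:
        raise DataError(f"module genes not in network: {missing}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pools = _pools if _pools is not None else _bin_pools(network, bins)
    profile: dict[int, int] = {}
    for g in module.genes:
        profile[bins.assignment[g]] = profile.get(bins.assignment[g], 0) + 1
    k = module.k
    total = np.zeros(n_perm)
    for b in sorted(profile):
        need = profile[b]
        if b not in pools or len(pools[b][0]) < need:
            have = len(pools[b][0]) if b in pools else 0
            raise SamplingError(
                f"degree bin {b} holds {have} weighted genes but the module needs {need}")
        _, z = pools[b]
        if need == len(z):
            total += z.sum()
            continue
        keys = rng.random((n_perm, z.size))
        idx = np.argpartition(keys, need - 1, axis=1)[:, :need]
        total += z[idx].sum(axis=1)
    null_scores = total / sqrt(k)
    return float((np.count_nonzero(null_scores >= module.score) + 1) / (n_perm + 1))


def sample_null_module(network: nx.Graph, bins: DegreeBins, profile: dict[int, int],
                       rng: np.random.Generator, _pools=None) -> Module:
    """Draw one random gene set with the given degree-bin profile.

    Used for calibration studies of the stage-2 test: a module produced by
    this sampler is itself a draw from the permutation null.
    """
    pools = _pools if _pools is not None else _bin_pools(network, bins)
    genes: list[str] = []
    for b, need in sorted(profile.items()):
        nodes, _ = pools[b]
        if len(nodes) < need:
            raise SamplingError(f"degree bin {b} too small for profile")
        pick = rng.choice(len(nodes), size=need, replace=False)
        genes.extend(nodes[i] for i in pick)
    z = [float(network.nodes[g]["z"]) for g in genes]
    return Module(seed=min(genes), genes=frozenset(genes), score=module_score(z))


@dataclass(frozen=True)
class EvaluatedModule:
    module: Module
    score_centered: float
    score_standardized: float
    p_norm: float
    p_topo: float | None
    n_perm: int

    def survives(self, alpha: float = 0.05) -> bool:
        return (self.p_norm < alpha
                and self.p_topo is not None and self.p_topo < alpha)


def evaluate_modules(network: nx.Graph, modules: list[Module], *,
                     alpha: float = 0.05, n_perm: int = 10_000,
                     seed: int = 0, null_method: str = "central_matching",
                     bins: DegreeBins | None = None) -> list[EvaluatedModule]:
    """Run both evaluation stages over a module list.

    Stage-2 permutations are spent only on modules that pass stage 1
    (``p_norm < alpha``); the rest keep ``p_topo = None``.
    """
    if not modules:
        return []
    scores = np.array([m.score for m in modules])
    null = fit_empirical_null(scores, method=null_method)
    med = float(np.median(scores))
    p_norm = normal_stage_pvalues(scores, null)
    bins = bins or assign_degree_bins(network)
    pools = _bin_pools(network, bins)
    out = []
    for m, pn in zip(modules, p_norm):
        pt = None
        if pn < alpha:
            rng = substream(seed, "topo_perm", m.seed)
            pt = topo_permutation_pvalue(network, m, bins, n_perm=n_perm,
                                         seed=rng, _pools=pools)
        centered = m.score - med
        out.append(EvaluatedModule(
            module=m, score_centered=centered,
            score_standardized=(centered - null.mu) / null.sigma,
            p_norm=float(pn), p_topo=pt, n_perm=n_perm))
    return out


def select_and_merge(evaluated: list[EvaluatedModule], network: nx.Graph,
                     sig_mhc_genes, alpha: float = 0.05) -> tuple[nx.Graph, nx.Graph]:
    """Union of surviving modules, plus the sigMHC-extended subnetwork.

    Returns ``(core, extended)``: the induced subgraph on the union of
    surviving modules' genes, and the induced subgraph on that union plus
    the sigMHC genes (which may enter as singletons).  Node attribute
    ``role`` is ``module_gene`` or ``sigMHC_gene``.
    """
    union: set[str] = set()
    for ev in evaluated:
        if ev.survives(alpha):
            union |= ev.module.genes
    if not union:
        logger.info("no module survived both evaluation stages")
    core = network.subgraph(union).copy()
    nx.set_node_attributes(core, "module_gene", "role")
    sig = [g for g in sig_mhc_genes if g in network]
    extended = network.subgraph(union | set(sig)).copy()
    roles = {n: ("sigMHC_gene" if n in set(sig) and n not in union else "module_gene")
             for n in extended.nodes}
    nx.set_node_attributes(extended, roles, "role")
    return core, extended


def write_evaluated(evaluated: list[EvaluatedModule], path, alpha: float = 0.05) -> None:
    rows = [(ev.module.seed, ev.module.k, ev.module.score, ev.p_norm,
             "" if ev.p_topo is None else ev.p_topo, ev.survives(alpha))
            for ev in evaluated]
    pd.DataFrame(rows, columns=["SEED", "K", "SCORE", "P_NORM", "P_TOPO", "PASS"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")
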