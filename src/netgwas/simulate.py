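"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a degree-
heterogeneous interaction network with per-edge publication support, a
planted connected module of genes with small P-values, a mock MHC region,
uniform-null background P-values, and AR(1)-correlated SNP blocks for the
LD-aware gene test.  All randomness flows from a single integer seed.

The generator emulates the statistical features the pipeline's tests
rely on (heavy-tailed degrees, block LD, uniform nulls, a connected
enriched module); it makes no attempt at realistic human LD maps, allele
frequency spectra or genome-wide SNP counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import derive_int_seed, substream
from .errors import ConfigurationError

__all__ = ["SyntheticConfig", "SyntheticDataset", "simulate_network",
           "plant_module", "simulate_dataset", "simulate_snp_block",
           "write_fixture", "annotate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the benchmark scenario used throughout the test
    suite: a 500-node preferential-attachment network with an 8-gene
    planted module whose P-values are Uniform(0, 1e-3), 20 mock-MHC
    genes, and 2-8 supporting publications per retained edge with 15% of
    edges left under-supported to exercise the filter.
    """

    n_nodes: int = 500
    attach_edges: int = 3
    planted_size: int = 8
    signal_p_max: float = 1e-3
    n_mhc: int = 20
    pub_count_range: tuple[int, int] = (2, 8)
    low_support_fraction: float = 0.15
    topology: str = "ba"  # "ba" (preferential attachment) or "er"
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < self.attach_edges + 1:
            raise ConfigurationError("n_nodes must exceed attach_edges")
        if not 2 <= self.planted_size <= self.n_nodes:
            raise ConfigurationError("planted_size must be in [2, n_nodes]")
        if not 0 < self.signal_p_max <= 1:
            raise ConfigurationError("signal_p_max must be in (0, 1]")
        if self.n_mhc < 0 or self.n_mhc + self.planted_size > self.n_nodes:
            raise ConfigurationError("n_mhc out of range")
        lo, hi = self.pub_count_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("pub_count_range must satisfy 1 <= lo <= hi")
        if not 0 <= self.low_support_fraction < 1:
            raise ConfigurationError("low_support_fraction must be in [0, 1)")
        if self.topology not in ("ba", "er"):
            raise ConfigurationError("topology must be 'ba' or 'er'")


@dataclass(frozen=True)
class SyntheticDataset:
    network: nx.Graph
    planted_genes: frozenset[str]
    mhc_genes: frozenset[str]
    gene_pvalues: dict[str, float]
    truth_labels: dict[str, str]  # gene -> "signal" | "background"
    config: SyntheticConfig
    seed: int


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def simulate_network(config: SyntheticConfig) -> nx.Graph:
    """Simple connected undirected graph with publication-count edges.

    Preferential attachment ("ba") yields the heavy-tailed degree
    distribution of real interactomes; Erdős–Rényi ("er") is available
    for calibration tests on degree-homogeneous graphs.  Each edge gets
    ``n_pubs`` drawn uniformly from ``pub_count_range``, except a
    ``low_support_fraction`` of edges set to one publication so that
    support filtering has something to remove.
    """
    rng = substream(config.seed, "network")
    nx_seed = derive_int_seed(config.seed, "network_topology")
    if config.topology == "ba":
        g = nx.barabasi_albert_graph(config.n_nodes, config.attach_edges, seed=nx_seed)
    else:
        p_edge = min(1.0, 2.0 * config.attach_edges / (config.n_nodes - 1))
        for attempt in range(100):
            g = nx.gnp_random_graph(config.n_nodes, p_edge, seed=nx_seed + attempt)
            if nx.is_connected(g):
                break
        else:
            raise ConfigurationError("could not draw a connected Erdős–Rényi graph")
    g = nx.relabel_nodes(g, {i: _gene_id(i) for i in g.nodes})
    lo, hi = config.pub_count_range
    edges = sorted(g.edges)
    counts = rng.integers(lo, hi + 1, size=len(edges))
    low = rng.random(len(edges)) < config.low_support_fraction
    counts[low] = 1
    for (a, b), c in zip(edges, counts):
        g.edges[a, b]["n_pubs"] = int(c)
    return g


def _random_connected_subset(g: nx.Graph, size: int, rng: np.random.Generator,
                             candidates: frozenset[str] | None = None) -> set[str]:
    nodes = sorted(candidates if candidates is not None else g.nodes)
    for _ in range(200):
        start = nodes[rng.integers(len(nodes))]
        members = {start}
        frontier = sorted(set(g.neighbors(start)) - members)
        if candidates is not None:
            frontier = [n for n in frontier if n in candidates]
        while frontier and len(members) < size:
            pick = frontier[rng.integers(len(frontier))]
            members.add(pick)
            new = set(g.neighbors(pick)) - members
            if candidates is not None:
                new &= set(candidates)
            frontier = sorted((set(frontier) | new) - members)
        if len(members) == size:
            return members
    raise ConfigurationError(f"could not grow a connected subset of size {size}")


def plant_module(network: nx.Graph, size: int | None = None,
                 signal_p_max: float | None = None, seed: int | None = None,
                 config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Plant a connected module of significant genes and label the truth.

    The planted genes' P-values are Uniform(0, signal_p_max); all other
    genes are Uniform(0, 1).  Mock-MHC genes are chosen disjoint from the
    planted module so that module recovery and sigMHC handling can be
    assessed independently.  ``signal_p_max=1`` effectively plants no
    signal (the module is uniform like the background).
    """
    config = config or SyntheticConfig()
    if size is not None:
        config = replace(config, planted_size=size)
    if signal_p_max is not None:
        config = replace(config, signal_p_max=signal_p_max)
    if seed is not None:
        config = replace(config, seed=seed)
    if config.planted_size > network.number_of_nodes():
        raise ConfigurationError("planted_size exceeds network size")
    rng = substream(config.seed, "planting")
    planted = _random_connected_subset(network, config.planted_size, rng)
    non_planted = sorted(set(network.nodes) - planted)
    mhc = set()
    if config.n_mhc:
        idx = rng.choice(len(non_planted), size=config.n_mhc, replace=False)
        mhc = {non_planted[i] for i in idx}
    pvals: dict[str, float] = {}
    for node in sorted(network.nodes):
        u = float(rng.random())
        pvals[node] = max(u * config.signal_p_max if node in planted else u,
                          np.nextafter(0, 1))
    labels = {n: ("signal" if n in planted else "background")
              for n in sorted(network.nodes)}
    return SyntheticDataset(network=network, planted_genes=frozenset(planted),
                            mhc_genes=frozenset(mhc), gene_pvalues=pvals,
                            truth_labels=labels, config=config, seed=config.seed)


def simulate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Network plus planted module in one call."""
    config = config or SyntheticConfig()
    return plant_module(simulate_network(config), config=config)


def simulate_snp_block(n_snps: int, rho: float, n_samples: int,
                       effect: float = 0.0, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """A block of SNP dosages with AR(1) LD, and per-SNP P-values.

    Dosages are Gaussian around 1 with inter-SNP correlation
    ``rho**|i-j|`` (fractional dosages, which the pipeline accepts); a
    continuous phenotype loads on the first SNP with the given effect
    (noncentrality) and each SNP is tested by Pearson correlation.  With
    ``effect=0`` the P-values are marginally Uniform(0, 1).
    """
    if not abs(rho) < 1:
        raise ConfigurationError("rho must satisfy |rho| < 1")
    if n_snps < 1 or n_samples < 3:
        raise ConfigurationError("need n_snps >= 1 and n_samples >= 3")
    if n_samples <= n_snps:
        warnings.warn("n_samples <= n_snps: LD estimates will be rank-deficient")
    rng = substream(seed, "snp_block")
    e = rng.standard_normal((n_snps, n_samples))
    x = np.empty_like(e)
    x[0] = e[0]
    for i in range(1, n_snps):
        x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * e[i]
    dosages = 1.0 + 0.5 * x
    y = effect * x[0] + rng.standard_normal(n_samples)
    # Pearson correlation test of each SNP against the phenotype
    xc = dosages - dosages.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    r = (xc @ yc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(yc))
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n_samples - 2) / (1 - r**2))
    from scipy import stats
    pvals = 2 * stats.t.sf(np.abs(t), df=n_samples - 2)
    return dosages, np.maximum(pvals, np.nextafter(0, 1))


def annotate_dataset(dataset: SyntheticDataset, alpha_mhc: float = 0.05):
    """Node-weighted graph straight from a synthetic dataset.

    Applies the same annotation rules as the network-builder stage (z
    from the inverse-normal transform, sigMHC flagging for mock-MHC genes
    with p < alpha_mhc) using the dataset's synthetic gene coordinates.
    Returns ``(graph, sig_mhc_genes)``.
    """
    from .network import annotate_weights

    scores = pd.DataFrame({"GENE": sorted(dataset.gene_pvalues),
                           "P": [dataset.gene_pvalues[g]
                                 for g in sorted(dataset.gene_pvalues)]})
    return annotate_weights(dataset.network, scores, _gene_coordinates(dataset),
                            alpha_mhc=alpha_mhc)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

_GENE_SPACING = 100_000
_GENE_LENGTH = 50_000
_MHC_START = 28_500_000  # inside the default GRCh37 MHC interval


def _gene_coordinates(dataset: SyntheticDataset) -> pd.DataFrame:
    """Synthetic coordinates: non-MHC genes tile chr1, MHC genes chr6."""
    rows = []
    i_auto = i_mhc = 0
    for gene in sorted(dataset.network.nodes):
        if gene in dataset.mhc_genes:
            start = _MHC_START + i_mhc * _GENE_SPACING
            rows.append((gene, "6", start, start + _GENE_LENGTH - 1))
            i_mhc += 1
        else:
            start = 1 + i_auto * _GENE_SPACING
            rows.append((gene, "1", start, start + _GENE_LENGTH - 1))
            i_auto += 1
    return pd.DataFrame(rows, columns=["GENE", "CHR", "START", "END"])


def write_fixture(dataset: SyntheticDataset, directory, *,
                  n_samples: int = 200, include_gmt: bool = False) -> dict[str, str]:
    """Write the pipeline's input files for a synthetic dataset.

    Emits an association table (one SNP per gene, at the gene midpoint,
    carrying the gene's P-value), a gene-model table, a dosage matrix, an
    interaction file with synthetic publication ids, and a truth-label
    table; optionally a small GMT whose first term is the planted module.
    Round-trips losslessly through the pipeline readers.
    """
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    genes = _gene_coordinates(dataset)
    paths = {k: str(out / v) for k, v in {
        "assoc": "assoc.tsv", "genes": "genes.tsv", "dosages": "dosages.tsv",
        "interactions": "interactions.tsv", "truth": "truth.tsv"}.items()}
    coords = {r.GENE: (r.CHR, r.START) for r in genes.itertuples(index=False)}
    assoc = pd.DataFrame(
        [(f"rs_{g}", coords[g][0], coords[g][1] + _GENE_LENGTH // 2,
          dataset.gene_pvalues[g]) for g in sorted(dataset.network.nodes)],
        columns=["SNP", "CHR", "POS", "P"])
    assoc.to_csv(paths["assoc"], sep="\t", index=False, float_format="%.17g")
    genes.to_csv(paths["genes"], sep="\t", index=False)
    rng = substream(dataset.seed, "fixture_dosages")
    mafs = rng.uniform(0.1, 0.5, size=len(assoc))
    dose = rng.binomial(2, mafs[:, None], size=(len(assoc), n_samples))
    pd.DataFrame(dose, index=assoc["SNP"]).to_csv(paths["dosages"], sep="\t")
    with open(paths["interactions"], "w") as fh:
        fh.write("A\tB\tPUBS\n")
        for a, b in sorted(dataset.network.edges):
            n = dataset.network.edges[a, b]["n_pubs"]
            pubs = "|".join(f"pmid:{a}_{b}_{j}" for j in range(n))
            fh.write(f"{a}\t{b}\t{pubs}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("GENE\tLABEL\n")
        for g in sorted(dataset.truth_labels):
            fh.write(f"{g}\t{dataset.truth_labels[g]}\n")
    if include_gmt:
        paths["gmt"] = str(out / "sets.gmt")
        rng_sets = substream(dataset.seed, "fixture_gmt")
        nodes = sorted(dataset.network.nodes)
        with open(paths["gmt"], "w") as fh:
            planted = sorted(dataset.planted_genes)
            fh.write("PLANTED\tplanted module genes\t" + "\t".join(planted) + "\n")
            for i in range(9):
                size = int(rng_sets.integers(10, 40))
                idx = rng_sets.choice(len(nodes), size=size, replace=False)
                members = sorted(nodes[j] for j in idx)
                fh.write(f"RANDOM{i}\trandom set\t" + "\t".join(members) + "\n")
    return paths
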