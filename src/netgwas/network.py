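"""Node-weighted interactome construction.

Interactions are read from a simple three-column TSV or from MITAB,
canonicalized to unordered gene pairs with a merged set of supporting
publications, filtered by publication support (>= 2 publications by
default), and annotated with gene-level association evidence: each node
with a gene P-value *p* receives the weight ``z = Phi^{-1}(1 - p)``.

Genes inside the MHC region with p below ``alpha_mhc`` are treated
specially ("sigMHC" genes): the MHC is gene-dense and in strong LD, so
their signals would dominate a module search.  They stay in the graph to
preserve its integrity but carry no weight and are never used as seeds;
they re-enter the candidate list when significant modules are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, EmptyNetworkError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "MhcRegion",
    "DEFAULT_MHC",
    "parse_interactions",
    "filter_edges",
    "annotate_weights",
    "write_edge_list",
    "write_graphml",
    "read_network",
]


@dataclass(frozen=True)
class InteractionRecord:
    protein_a: str
    protein_b: str
    publications: frozenset[str]


@dataclass(frozen=True)
class MhcRegion:
    """Genomic interval used to flag MHC genes (gene body overlap)."""

    chrom: str = "6"
    start: int = 28_477_797
    end: int = 33_448_354

    def __post_init__(self):
        if self.start >= self.end:
            raise ConfigurationError("MhcRegion start must be < end")

    def contains_gene(self, chrom: str, start: int, end: int) -> bool:
        return str(chrom) == self.chrom and start <= self.end and end >= self.start


#: Classical MHC on GRCh37 chromosome 6.
DEFAULT_MHC = MhcRegion()


def _parse_simple_line(parts: list[str]) -> tuple[str, str, set[str]]:
    a, b, pubs = parts[0], parts[1], parts[2]
    return a, b, {p for p in pubs.split("|") if p}


def _parse_mitab_line(parts: list[str], alias_cols=(2, 3, 4)) -> tuple[str, str, set[str]]:
    # columns: 0,1 interactor ids; 8 publications (0-based)
    def strip_db(field: str) -> str:
        token = field.split("|")[0]
        return token.split(":", 1)[1] if ":" in token else token

    a, b = strip_db(parts[0]), strip_db(parts[1])
    pubs = {p for p in parts[8].split("|") if p and p != "-"}
    return a, b, pubs


def parse_interactions(path, *, mitab: bool = False) -> list[InteractionRecord]:
    """Parse an interaction file into canonical unordered records.

    Duplicate pairs are merged by publication-set union; self-loops are
    dropped (their count is logged).  Simple format: ``A<TAB>B<TAB>
    pmid:1|pmid:2``; MITAB 2.5/2.6 uses columns 1, 2 and 9.
    """
    pairs: dict[tuple[str, str], set[str]] = {}
    n_loops = 0
    min_cols = 9 if mitab else 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and not mitab and parts[:3] == ["A", "B", "PUBS"]:
                continue  # optional header
            if len(parts) < min_cols:
                raise DataError(f"{path}: malformed line {lineno} "
                                f"({len(parts)} columns, expected >= {min_cols})")
            a, b, pubs = (_parse_mitab_line(parts) if mitab
                          else _parse_simple_line(parts))
            if not pubs:
                raise DataError(f"{path}: line {lineno} has no publication ids")
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            pairs.setdefault(key, set()).update(pubs)
    if n_loops:
        logger.info("dropped %d self-loop interactions", n_loops)
    return [InteractionRecord(a, b, frozenset(p)) for (a, b), p in sorted(pairs.items())]


def filter_edges(records: list[InteractionRecord], min_pubs: int = 2) -> nx.Graph:
    """Keep interactions supported by at least ``min_pubs`` publications.

    Nodes left without any edge are dropped.  An empty result is an error:
    the downstream analysis is meaningless without a network.
    """
    if min_pubs < 1:
        raise ConfigurationError("min_pubs must be >= 1")
    g = nx.Graph()
    for rec in records:
        n = len(rec.publications)
        if n >= min_pubs:
            g.add_edge(rec.protein_a, rec.protein_b, n_pubs=n)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no interaction has >= {min_pubs} supporting publications")
    logger.info("filtered network: %d nodes, %d edges (min_pubs=%d)",
                g.number_of_nodes(), g.number_of_edges(), min_pubs)
    return g


def annotate_weights(network: nx.Graph, gene_scores: pd.DataFrame,
                     gene_models: pd.DataFrame | None = None,
                     mhc: MhcRegion | None = DEFAULT_MHC,
                     alpha_mhc: float = 0.05) -> tuple[nx.Graph, list[str]]:
    """Attach gene P-values and z-weights to network nodes.

    A node with gene P-value *p* gets ``z = Phi^{-1}(1-p)`` and
    ``weighted=True`` — unless its gene body overlaps the MHC region and
    ``p < alpha_mhc``, in which case it is flagged ``sig_mhc`` and left
    unweighted (but kept in the graph).  Nodes with no gene P-value at all
    are removed.  Returns the annotated graph and the sorted sigMHC list.
    """
    g = network.copy()
    pmap = dict(zip(gene_scores["GENE"].astype(str), gene_scores["P"]))
    in_mhc: set[str] = set()
    if mhc is not None and gene_models is not None:
        for row in gene_models.itertuples(index=False):
            if mhc.contains_gene(row.CHR, row.START, row.END):
                in_mhc.add(str(row.GENE))
    unmatched = [n for n in g.nodes if n not in pmap]
    if unmatched:
        logger.info("removing %d network nodes without a gene P-value", len(unmatched))
        g.remove_nodes_from(unmatched)
    sig_mhc: list[str] = []
    for node in g.nodes:
        p = float(pmap[node])
        if not 0 < p <= 1:
            raise DataError(f"gene {node}: P-value {p} outside (0, 1]")
        attrs = {"p_value": p, "in_mhc": node in in_mhc}
        if node in in_mhc and p < alpha_mhc:
            attrs.update(sig_mhc=True, weighted=False)
            sig_mhc.append(node)
        else:
            attrs.update(sig_mhc=False, weighted=True,
                         z=float(stats.norm.isf(p)))
        g.nodes[node].update(attrs)
    sig_mhc.sort()
    logger.info("annotated network: %d nodes (%d sigMHC)", g.number_of_nodes(), len(sig_mhc))
    return g, sig_mhc


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_edge_list(g: nx.Graph, path) -> None:
    rows = [(a, b, d.get("n_pubs", "")) for a, b, d in sorted(g.edges(data=True))]
    pd.DataFrame(rows, columns=["A", "B", "N_PUBS"]).to_csv(path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def read_network(path) -> nx.Graph:
    """Read a network back from GraphML."""
    return nx.read_graphml(path)
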