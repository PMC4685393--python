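"""Gene-set over-representation analysis.

One-sided Fisher exact tests (hypergeometric upper tail) of a query gene
list against a GMT collection, with Benjamini-Hochberg adjustment.  Terms
with adjusted P below a threshold (0.25 by default) are reported.  The
background defaults to the set of weighted genes in the analysis network,
i.e. the universe actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "overrep_pvalue",
           "fisher_enrichment", "bh_adjust", "select_enriched",
           "write_enrichment"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Term id -> (term name, member gene set)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term, description, then tab-separated gene ids."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: GMT line {lineno} has < 3 fields")
            term, desc, genes = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
            if not genes:
                raise DataError(f"{path}: GMT term {term!r} is empty")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets)


def overrep_pvalue(a: int, n_bg: int, set_size: int, query_size: int) -> float:
    """One-sided Fisher exact P for an overlap of ``a`` genes.

    Upper tail of the hypergeometric distribution with population
    ``n_bg``, ``set_size`` successes and ``query_size`` draws.
    """
    return float(min(stats.hypergeom.sf(a - 1, n_bg, set_size, query_size), 1.0))


def fisher_enrichment(query, collection: GeneSetCollection, background,
                      ease: bool = False) -> pd.DataFrame:
    """One-sided over-representation P-value per term.

    For a term of size K (within the background of size N), a query of
    size n and an overlap of a genes, p = P(X >= a) for X hypergeometric
    (N, K, n) — identical to the one-sided Fisher exact test on the 2x2
    table.  With ``ease=True`` the overlap is deflated by one (a
    conservative variant used by some annotation servers).
    """
    background = frozenset(background)
    query = frozenset(query)
    outside = query - background
    if outside:
        logger.warning("dropping %d query genes outside the background", len(outside))
        query &= background
    if not query:
        raise DataError("query is empty after intersecting with the background")
    n_bg, n_q = len(background), len(query)
    rows = []
    for term in sorted(collection.sets):
        name, genes = collection.sets[term]
        term_bg = genes & background
        k = len(term_bg)
        if k == 0:
            continue
        a = len(term_bg & query)
        a_eff = max(a - 1, 0) if ease else a
        p = overrep_pvalue(a_eff, n_bg, k, n_q)
        rows.append((term, name, a, n_q, k, n_bg, p))
    df = pd.DataFrame(rows, columns=["TERM", "NAME", "OVERLAP", "QUERY_SIZE",
                                     "SET_SIZE", "BACKGROUND_SIZE", "P"])
    df["P_ADJ"] = bh_adjust(df["P"].to_numpy()) if len(df) else []
    return df.sort_values(["P_ADJ", "P", "TERM"], kind="stable").reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DataError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_enriched(results: pd.DataFrame, threshold: float = 0.25) -> pd.DataFrame:
    """Terms with adjusted P strictly below ``threshold``, sorted."""
    out = results[results["P_ADJ"] < threshold]
    return out.sort_values(["P_ADJ", "P", "TERM"], kind="stable").reset_index(drop=True)


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
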