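"""Gene-level association testing from SNP-level GWAS P-values.

The gene statistic is the sum, over all SNPs mapped to a gene (gene body
extended by a flank, 20 kb by default), of the upper-tail 1-df chi-square
quantile of each SNP P-value.  Its null distribution is obtained by Monte
Carlo: vectors are drawn from a zero-mean multivariate normal whose
covariance is the inter-SNP linkage-disequilibrium (LD) correlation matrix
estimated from a reference dosage panel, and the sum of squared components
of each draw is compared with the observed statistic.  The empirical
P-value uses the (+1)/(+1) correction so it can never be exactly zero, and
the number of draws escalates adaptively for small P-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import ConfigurationError, DataError, EstimationError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSchedule",
    "LdMatrix",
    "GeneScore",
    "read_assoc_table",
    "read_gene_models",
    "read_dosage_matrix",
    "filter_autosomal",
    "map_snps_to_genes",
    "gene_statistic",
    "ld_correlation",
    "simulate_null_sums",
    "gene_pvalue",
    "score_all_genes",
    "write_gene_scores",
    "read_gene_scores",
]

#: SNP P-values are clamped to this floor before the chi-square quantile
#: transform, so a printed "0" P-value cannot produce an infinite statistic.
P_FLOOR = 1e-16

AUTOSOMES = {str(i) for i in range(1, 23)}


def _norm_chrom(label) -> str:
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


# ---------------------------------------------------------------------------
# input tables
# ---------------------------------------------------------------------------

def read_assoc_table(path) -> pd.DataFrame:
    """Read a SNP association table: TSV with header ``SNP CHR POS P``."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    required = {"SNP", "CHR", "POS", "P"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"association table {path} lacks columns: {sorted(missing)}")
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise DataError(f"duplicate SNP id in association table: {dup!r}")
    bad = (df["P"] <= 0) | (df["P"] > 1)
    if bad.any():
        raise DataError(f"{int(bad.sum())} SNP P-values outside (0, 1]")
    df["CHR"] = df["CHR"].map(_norm_chrom)
    return df


def read_gene_models(path, *, bed: bool = False) -> pd.DataFrame:
    """Read gene models.

    Default format is TSV ``GENE CHR START END`` with 1-based closed
    coordinates.  With ``bed=True`` a headerless 4-column BED file
    (0-based half-open) is accepted and converted on read.
    """
    if bed:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                         names=["CHR", "START", "END", "GENE"],
                         dtype={"CHR": str, "GENE": str})
        df["START"] = df["START"] + 1  # 0-based half-open -> 1-based closed
        df = df[["GENE", "CHR", "START", "END"]]
    else:
        df = pd.read_csv(path, sep="\t", dtype={"GENE": str, "CHR": str})
        missing = {"GENE", "CHR", "START", "END"} - set(df.columns)
        if missing:
            raise DataError(f"gene model table {path} lacks columns: {sorted(missing)}")
    if (df["START"] > df["END"]).any():
        raise DataError("gene model with START > END")
    df["CHR"] = df["CHR"].map(_norm_chrom)
    return df


def read_dosage_matrix(path) -> pd.DataFrame:
    """Read a dosage matrix: TSV, rows = SNPs (first column SNP id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise DataError("duplicate SNP id in dosage matrix")
    return df


def filter_autosomal(snps: pd.DataFrame) -> pd.DataFrame:
    """Keep autosomal SNPs (chromosomes 1-22); log what was dropped."""
    keep = snps["CHR"].isin(AUTOSOMES)
    n_drop = int((~keep).sum())
    if n_drop:
        labels = sorted(snps.loc[~keep, "CHR"].unique())
        logger.warning("dropping %d non-autosomal SNPs (chromosomes %s)", n_drop, labels)
    return snps.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP-to-gene mapping
# ---------------------------------------------------------------------------

def map_snps_to_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                      flank: int = 20_000) -> dict[str, list[str]]:
    """Map SNPs to genes whose flanked window contains them.

    SNP *s* maps to gene *g* iff ``start - flank <= pos(s) <= end + flank``
    on the same chromosome (1-based closed window).  A SNP may map to
    several genes; genes with zero mapped SNPs are omitted from the result.
    """
    if flank < 0:
        raise ConfigurationError("flank must be non-negative")
    if snps["SNP"].duplicated().any():
        raise DataError("duplicate SNP ids")
    snps = filter_autosomal(snps)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in snps.groupby("CHR"):
        order = np.argsort(grp["POS"].to_numpy(), kind="stable")
        by_chrom[chrom] = (grp["POS"].to_numpy()[order], grp["SNP"].to_numpy()[order])
    result: dict[str, list[str]] = {}
    unknown = set(genes["CHR"].unique()) - set(by_chrom)
    if unknown:
        logger.warning("gene chromosomes with no SNPs are skipped: %s", sorted(unknown))
    for row in genes.itertuples(index=False):
        entry = by_chrom.get(row.CHR)
        if entry is None:
            continue
        pos, ids = entry
        lo = np.searchsorted(pos, row.START - flank, side="left")
        hi = np.searchsorted(pos, row.END + flank, side="right")
        if hi > lo:
            result[row.GENE] = list(ids[lo:hi])
    return result


# ---------------------------------------------------------------------------
# the gene statistic and its Monte-Carlo null
# ---------------------------------------------------------------------------

def gene_statistic(snp_pvalues) -> float:
    """Sum of upper-tail 1-df chi-square quantiles of the SNP P-values."""
    p = np.asarray(snp_pvalues, dtype=float)
    if p.size == 0:
        raise DataError("gene with no SNP P-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise DataError("SNP P-values must lie in (0, 1]")
    p = np.maximum(p, P_FLOOR)
    return float(stats.chi2.isf(p, df=1).sum())


@dataclass(frozen=True)
class LdMatrix:
    """Inter-SNP correlation matrix, repaired to positive semi-definite."""

    snp_ids: tuple[str, ...]
    matrix: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def _repair_psd(r: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues to ``eps`` and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh((r + r.T) / 2.0)
    if vals.min() >= eps:
        out = r.copy()
    else:
        vals = np.maximum(vals, eps)
        out = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def ld_correlation(dosages: np.ndarray, snp_ids=None) -> LdMatrix:
    """Pairwise Pearson correlation of dosage rows (SNPs × samples).

    Monomorphic SNPs (zero variance) are dropped with a warning; an
    all-missing SNP raises.  The result is PSD-repaired so downstream
    Cholesky factorisation always succeeds.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d[None, :]
    if d.shape[1] < 2:
        raise DataError("LD estimation needs at least 2 samples")
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(d.shape[0])]
    snp_ids = [str(s) for s in snp_ids]
    all_nan = np.all(np.isnan(d), axis=1)
    if all_nan.any():
        raise DataError(f"SNP {snp_ids[int(np.argmax(all_nan))]!r} has no observed dosages")
    var = np.nanvar(d, axis=1)
    keep = var > 0
    if not keep.all():
        dropped = [s for s, k in zip(snp_ids, keep) if not k]
        logger.warning("dropping %d monomorphic SNPs from LD: %s", len(dropped), dropped)
        d = d[keep]
        snp_ids = [s for s, k in zip(snp_ids, keep) if k]
    if d.shape[0] == 0:
        raise DataError("all SNPs monomorphic; LD undefined")
    if d.shape[0] == 1:
        return LdMatrix((snp_ids[0],), np.array([[1.0]]))
    r = np.corrcoef(d)
    return LdMatrix(tuple(snp_ids), _repair_psd(r))


@dataclass(frozen=True)
class SimulationSchedule:
    """Adaptive Monte-Carlo schedule.

    Stage *i* uses ``n_draws[i]`` simulations; the result escalates to the
    next stage while the current P-value estimate falls below
    ``thresholds[i]``.  The last stage is the cap.
    """

    n_draws: tuple[int, ...] = (1_000, 10_000, 1_000_000)
    thresholds: tuple[float, ...] = (0.1, 0.005)

    def __post_init__(self):
        if len(self.thresholds) != len(self.n_draws) - 1:
            raise ConfigurationError("need one threshold per escalation step")
        if any(n <= 0 for n in self.n_draws):
            raise ConfigurationError("n_draws must be positive")


def _cholesky_factor(ld: LdMatrix) -> np.ndarray:
    try:
        return np.linalg.cholesky(_repair_psd(ld.matrix))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - repair should prevent
        raise EstimationError("LD matrix not PSD after repair") from exc


def simulate_null_sums(ld: LdMatrix, n_draws: int, rng: np.random.Generator,
                       chunk: int = 262_144) -> np.ndarray:
    """Draw null statistics: sum of squares of MVN(0, LD) vectors."""
    L = _cholesky_factor(ld)
    k = ld.n_snps
    out = np.empty(n_draws)
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        u = rng.standard_normal((m, k))
        out[done:done + m] = np.einsum("ij,ij->i", u @ L.T, u @ L.T)
        done += m
    return out


def gene_pvalue(statistic: float, ld: LdMatrix,
                schedule: SimulationSchedule | None = None,
                seed: int | np.random.Generator = 0) -> tuple[float, int]:
    """Empirical P-value of a gene statistic under the MVN(0, LD) null.

    Returns ``(p, n_sims_used)`` with ``p = (#{null >= statistic} + 1) /
    (n_sims + 1)``, escalating through the schedule while the estimate is
    small.  ``p >= 1/(n_sims_used + 1)`` always.
    """
    if statistic < 0:
        raise DataError("gene statistic must be non-negative")
    schedule = schedule or SimulationSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, n = 1.0, 0
    for i, n_draws in enumerate(schedule.n_draws):
        sums = simulate_null_sums(ld, n_draws, rng)
        p = (int(np.count_nonzero(sums >= statistic)) + 1) / (n_draws + 1)
        n = n_draws
        if i >= len(schedule.thresholds) or p >= schedule.thresholds[i]:
            break
    return p, n


@dataclass(frozen=True)
class GeneScore:
    """One gene's association evidence."""

    gene_id: str
    n_snps: int
    statistic: float
    p_value: float
    n_sims_used: int
    in_mhc: bool = False
    is_weighted: bool = field(default=True)


def score_all_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                    dosages: pd.DataFrame, *,
                    flank: int = 20_000,
                    schedule: SimulationSchedule | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Score every gene with at least one mapped SNP.

    Per-gene RNG sub-streams are derived from the master seed and the gene
    id, so the result is independent of gene evaluation order.  Returns a
    DataFrame ``GENE NSNPS STAT P NSIMS`` sorted by gene id.
    """
    schedule = schedule or SimulationSchedule()
    mapping = map_snps_to_genes(snps, genes, flank=flank)
    pmap = dict(zip(snps["SNP"], snps["P"]))
    rows = []
    for gene_id in sorted(mapping):
        snp_ids = [s for s in mapping[gene_id] if s in dosages.index]
        lost = len(mapping[gene_id]) - len(snp_ids)
        if lost:
            logger.warning("gene %s: %d mapped SNPs absent from dosage panel", gene_id, lost)
        if not snp_ids:
            continue
        try:
            ld = ld_correlation(dosages.loc[snp_ids].to_numpy(), snp_ids)
        except DataError as exc:
            raise DataError(f"gene {gene_id}: {exc}") from exc
        pvals = [pmap[s] for s in ld.snp_ids]  # monomorphic SNPs already dropped
        stat = gene_statistic(pvals)
        rng = substream(seed, "gene_scoring", gene_id)
        p, n_sims = gene_pvalue(stat, ld, schedule, rng)
        rows.append((gene_id, len(ld.snp_ids), stat, p, n_sims))
    return pd.DataFrame(rows, columns=["GENE", "NSNPS", "STAT", "P", "NSIMS"])


def write_gene_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"GENE": str})
    missing = {"GENE", "P"} - set(df.columns)
    if missing:
        raise DataError(f"gene score table {path} lacks columns: {sorted(missing)}")
    return df
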