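"""End-to-end orchestration of the network-assisted GWAS analysis.

Stages: gene scoring -> network building -> module search -> two-stage
module evaluation -> connectivity test -> enrichment.  One master seed
drives everything; each stage derives its own sub-stream by name, so
changing the number of permutations in one stage does not shift the
random draws of another.  All intermediates are persisted as headed TSV
so any stage can be re-run or resumed from saved output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import connectivity as conn
from . import enrichment as enr
from . import evaluate as ev
from . import gene_scoring as gs
from . import network as nb
from . import search as ms
from ._rng import derive_int_seed
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "validate_inputs", "run_network_analysis"]


@dataclass
class PipelineConfig:
    """Everything a full run needs.  Defaults mirror the reference analysis:

    20 kb gene flank, edges supported by >= 2 publications, MHC
    significance cut 0.05, growth rate r = 0.1 with distance-1 candidate
    neighbourhoods, 10,000 permutations for both permutation nulls,
    per-stage module threshold 0.05 and enrichment FDR threshold 0.25.
    """

    assoc_path: str = ""
    gene_models_path: str = ""
    dosages_path: str = ""
    interactions_path: str = ""
    gmt_path: str | None = None
    gene_scores_path: str | None = None  # resume: skip the scoring stage
    out_dir: str = "netgwas_out"
    flank: int = 20_000
    min_pubs: int = 2
    alpha_mhc: float = 0.05
    mhc_chrom: str = "6"
    mhc_start: int = 28_477_797
    mhc_end: int = 33_448_354
    r: float = 0.1
    d: int = 1
    n_perm_topo: int = 10_000
    n_perm_conn: int = 10_000
    alpha_module: float = 0.05
    enrichment_threshold: float = 0.25
    sim_draws: tuple[int, ...] = (1_000, 10_000, 1_000_000)
    sim_thresholds: tuple[float, ...] = (0.1, 0.005)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sim_draws", "sim_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sim_draws"] = list(d["sim_draws"])
        d["sim_thresholds"] = list(d["sim_thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @property
    def mhc(self) -> nb.MhcRegion:
        return nb.MhcRegion(self.mhc_chrom, self.mhc_start, self.mhc_end)

    @property
    def schedule(self) -> gs.SimulationSchedule:
        return gs.SimulationSchedule(tuple(self.sim_draws), tuple(self.sim_thresholds))


def validate_inputs(config: PipelineConfig) -> dict:
    """Pre-flight checks; returns a report and never mutates inputs."""
    fatal, warnings_ = [], []
    required = {"association table": config.assoc_path,
                "gene model table": config.gene_models_path,
                "interaction file": config.interactions_path}
    if config.gene_scores_path:
        required.pop("association table")
    else:
        required["dosage matrix"] = config.dosages_path
    for name, path in required.items():
        if not path or not Path(path).is_file():
            fatal.append(f"missing {name}: {path!r}")
    if config.gmt_path and not Path(config.gmt_path).is_file():
        fatal.append(f"missing gene-set file: {config.gmt_path!r}")
    if not fatal:
        try:
            genes = gs.read_gene_models(config.gene_models_path)
            records = nb.parse_interactions(config.interactions_path)
            net_ids = {r.protein_a for r in records} | {r.protein_b for r in records}
            overlap = len(set(genes["GENE"]) & net_ids)
            frac = overlap / max(len(net_ids), 1)
            if frac < 0.5:
                warnings_.append(
                    f"only {frac:.0%} of network genes appear in the gene models; "
                    "check the identifier namespace")
        except DataError as exc:
            fatal.append(str(exc))
    return {"fatal": fatal, "warnings": warnings_, "ok": not fatal}


def run_network_analysis(graph: nx.Graph, sig_mhc: list[str], *,
                         r: float = 0.1, d: int = 1, n_perm_topo: int = 10_000,
                         alpha: float = 0.05, seed: int = 0) -> dict:
    """Module search, two-stage evaluation and merge on an annotated network.

    The in-memory core of the pipeline, shared by ``run_all`` and by
    simulation studies that enter with gene-level P-values already on the
    graph.  Returns modules, evaluations, and the merged subnetworks.
    """
    params = ms.SearchParams(r=r, d=d, exclude_seeds=frozenset(sig_mhc))
    modules = ms.search_all(graph, params)
    evaluated = ev.evaluate_modules(graph, modules, alpha=alpha,
                                    n_perm=n_perm_topo,
                                    seed=derive_int_seed(seed, "evaluation"))
    core, extended = ev.select_and_merge(evaluated, graph, sig_mhc, alpha=alpha)
    return {"modules": modules, "evaluated": evaluated,
            "core": core, "extended": extended,
            "n_modules": len(modules),
            "n_stage1": sum(1 for e in evaluated if e.p_norm < alpha),
            "n_final": sum(1 for e in evaluated if e.survives(alpha)),
            "module_genes": sorted(core.nodes)}


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns the run report (also written as ``report.json``).  Stage
    failures propagate with the stage named; outputs written before the
    failure are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    report: dict = {"stages": {}}

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    stage = _stage("gene_scoring")
    try:
        genes = gs.read_gene_models(config.gene_models_path)
        if config.gene_scores_path:
            scores = gs.read_gene_scores(config.gene_scores_path)
        else:
            snps = gs.read_assoc_table(config.assoc_path)
            dosages = gs.read_dosage_matrix(config.dosages_path)
            scores = gs.score_all_genes(
                snps, genes, dosages, flank=config.flank,
                schedule=config.schedule,
                seed=derive_int_seed(config.seed, "gene_scoring"))
        gs.write_gene_scores(scores, out / "gene_scores.tsv")
        report["stages"]["gene_scoring"] = {"genes_scored": int(len(scores))}

        stage = _stage("network_builder")
        records = nb.parse_interactions(config.interactions_path)
        filtered = nb.filter_edges(records, min_pubs=config.min_pubs)
        graph, sig_mhc = nb.annotate_weights(filtered, scores, genes,
                                             mhc=config.mhc,
                                             alpha_mhc=config.alpha_mhc)
        nb.write_edge_list(graph, out / "network_edges.tsv")
        nb.write_graphml(graph, out / "network.graphml")
        (out / "sigmhc_genes.txt").write_text("".join(f"{g}\n" for g in sig_mhc))
        report["stages"]["network_builder"] = {
            "records": len(records),
            "nodes_filtered": filtered.number_of_nodes(),
            "edges_filtered": filtered.number_of_edges(),
            "nodes_weighted_net": graph.number_of_nodes(),
            "edges_weighted_net": graph.number_of_edges(),
            "n_sigmhc": len(sig_mhc)}

        stage = _stage("module_search_and_evaluation")
        res = run_network_analysis(graph, sig_mhc, r=config.r, d=config.d,
                                   n_perm_topo=config.n_perm_topo,
                                   alpha=config.alpha_module, seed=config.seed)
        ms.write_modules(res["modules"], out / "modules.tsv")
        ev.write_evaluated(res["evaluated"], out / "modules_evaluated.tsv",
                           alpha=config.alpha_module)
        nb.write_edge_list(res["core"], out / "merged_edges.tsv")
        nb.write_graphml(res["extended"], out / "merged_extended.graphml")
        union = res["module_genes"]
        candidates = sorted(set(union) | set(sig_mhc))
        (out / "candidate_genes.txt").write_text("".join(f"{g}\n" for g in candidates))
        report["stages"]["module_search"] = {
            "modules_found": res["n_modules"],
            "modules_after_stage1": res["n_stage1"],
            "modules_final": res["n_final"],
            "module_genes": len(union),
            "candidate_genes": len(candidates)}

        stage = _stage("connectivity_test")
        if len(union) >= 2:
            cres = conn.connectivity_pvalue(
                graph, union, n_perm=config.n_perm_conn,
                seed=derive_int_seed(config.seed, "connectivity"))
            conn.write_connectivity_result(cres, out / "connectivity.json",
                                           out / "connectivity_null.tsv")
            report["stages"]["connectivity"] = {
                "observed_edges": cres.observed_edges, "p_value": cres.p_value}
        else:
            logger.info("fewer than 2 module genes; connectivity test skipped")
            report["stages"]["connectivity"] = {"skipped": True}

        stage = _stage("enrichment")
        if config.gmt_path and union:
            collection = enr.read_gmt(config.gmt_path)
            background = [n for n in graph.nodes
                          if graph.nodes[n].get("weighted", False)]
            results = enr.fisher_enrichment(union, collection, background)
            enr.write_enrichment(results, out / "enrichment.tsv")
            selected = enr.select_enriched(results, config.enrichment_threshold)
            report["stages"]["enrichment"] = {
                "terms_tested": int(len(results)),
                "terms_enriched": int(len(selected))}
        else:
            report["stages"]["enrichment"] = {"skipped": True}
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return report
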