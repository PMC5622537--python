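"""End-to-end orchestration: per-list and joint prioritizations.

A single-list run calibrates epsilon for the 1:1 input/predicted balance,
scores all network genes, keeps the top-2n "n*" list, profiles connectivity
by network resampling, extracts the module and (optionally) runs pathway
over-representation on the n* list.  The joint run combines all lists into
one weighted seed vector (maximum weight wins for shared genes), fixes
epsilon at 1 — the aim being a prioritization of the inputs themselves
rather than prediction — and reports the module with its per-source
membership breakdown plus an input/predicted co-occurrence summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import resampling as nr
from . import smoothing as sm
from .network import GeneNetwork, load_edge_list, read_gene_list, restrict_to_network

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_single_list", "run_joint", "co_occurrence",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults follow the standard analysis settings
    (alpha 0.7, K 999, q 200, pathway sizes 10-200, adjusted p < 0.01,
    overlap coefficient > 0.5, top 5 enrichment-map links)."""

    network: str = ""
    score_threshold: int = 700
    weighted: bool = False
    lists: dict[str, str] = field(default_factory=dict)   # name -> path
    weights: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.7
    K: int = 999
    epsilon: float | str = "auto"      # per-list analyses
    joint_epsilon: float = 1.0
    q: int = 200
    nr_significance: float = 0.05
    swaps_per_edge: int = 10
    m_grid: list[int] | None = None
    top_multiplier: int = 2
    pathways: str | None = None
    size_filter: tuple[int, int] = (10, 200)
    background: str = "network"        # or "lists+network"
    padj_threshold: float = 0.01
    o_threshold: float = 0.5
    top_k: int = 5
    rng_seed: int = 7
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.size_filter, list):
            cfg.size_filter = tuple(cfg.size_filter)
        return cfg


def _stage_seed(rng_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    digest = hashlib.sha256(f"{rng_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_single_list(net: GeneNetwork, name: str, genes: list[str],
                    cfg: PipelineConfig | None = None,
                    pathway_db: enr.PathwayDB | None = None,
                    background: set[str] | None = None) -> dict:
    """Score, select top-2n, extract the module and run ORA for one list."""
    cfg = cfg or PipelineConfig()
    kept, dropped = restrict_to_network(genes, net)
    logger.info("[%s] %d input genes, %d kept in network", name, len(genes),
                len(kept))
    seed_vec = sm.build_seed_vector({name: kept}, {name: 1.0}, net)
    scores = sm.score_genes(net, seed_vec, alpha=cfg.alpha,
                            epsilon=cfg.epsilon, K=cfg.K,
                            rng_seed=_stage_seed(cfg.rng_seed, f"score:{name}"))
    top = sm.select_top(scores, multiplier=cfg.top_multiplier)
    profile = nr.nr_profile(scores, net, m_grid=cfg.m_grid, q=cfg.q,
                            rng_seed=_stage_seed(cfg.rng_seed, f"nr:{name}"),
                            swaps_per_edge=cfg.swaps_per_edge)
    module = nr.extract_module(profile, scores, net,
                               significance=cfg.nr_significance)
    ora_res = None
    if pathway_db is not None:
        bg = background if background is not None else set(net.nodes)
        ora_res = enr.ora(set(top["gene"]), pathway_db, bg,
                          background_label=cfg.background)
    return {"name": name, "kept": kept, "dropped": dropped, "scores": scores,
            "top": top, "profile": profile, "module": module, "ora": ora_res}


def run_joint(net: GeneNetwork, lists: dict[str, list[str]],
              weights: dict[str, float] | None = None,
              cfg: PipelineConfig | None = None,
              pathway_db: enr.PathwayDB | None = None,
              background: set[str] | None = None) -> dict:
    """Joint prioritization of the union of all lists (max-weight seeding)."""
    cfg = cfg or PipelineConfig()
    if len(lists) < 2:
        raise ValueError("joint analysis needs at least two lists")
    restricted = {}
    for name, genes in lists.items():
        kept, _ = restrict_to_network(genes, net)
        restricted[name] = kept
    seed_vec = sm.build_seed_vector(restricted, weights, net)
    scores = sm.score_genes(net, seed_vec, alpha=cfg.alpha,
                            epsilon=cfg.joint_epsilon, K=cfg.K,
                            rng_seed=_stage_seed(cfg.rng_seed, "score:joint"))
    profile = nr.nr_profile(scores, net, m_grid=cfg.m_grid, q=cfg.q,
                            rng_seed=_stage_seed(cfg.rng_seed, "nr:joint"),
                            swaps_per_edge=cfg.swaps_per_edge)
    module = nr.extract_module(profile, scores, net,
                               significance=cfg.nr_significance)
    breakdown = None
    if not module.is_empty:
        rows = []
        for name, kept in restricted.items():
            inside = len(set(kept) & set(module.genes))
            rows.append((name, len(kept), inside,
                         100.0 * inside / len(kept) if kept else 0.0))
        breakdown = pd.DataFrame(
            rows, columns=["list", "n_network_genes", "n_in_module",
                           "pct_in_module"])
    ora_res = None
    if pathway_db is not None:
        bg = background if background is not None else set(net.nodes)
        query = set(module.genes) if not module.is_empty else set()
        if query:
            ora_res = enr.ora(query, pathway_db, bg,
                              background_label=cfg.background)
    return {"name": "joint", "scores": scores, "profile": profile,
            "module": module, "breakdown": breakdown, "ora": ora_res,
            "lists": restricted}


def co_occurrence(single_results: list[dict]) -> pd.DataFrame:
    """Cross-tabulate, per gene, in how many lists it is an input vs predicted.

    A gene is "predicted" for a list when it appears in that list's top-2n
    table without being one of its inputs.  Rows: number of lists predicting
    the gene (>= 1); columns: number of lists containing it as input.
    """
    n_input: dict[str, int] = {}
    n_pred: dict[str, int] = {}
    for res in single_results:
        top = res["top"]
        for gene, is_input in zip(top["gene"], top["is_input"]):
            if is_input:
                n_input[gene] = n_input.get(gene, 0) + 1
            else:
                n_pred[gene] = n_pred.get(gene, 0) + 1
    rows = [(g, n_pred[g], n_input.get(g, 0)) for g in sorted(n_pred)]
    df = pd.DataFrame(rows, columns=["gene", "n_predicted", "n_input"])
    if df.empty:
        return pd.DataFrame()
    return pd.crosstab(df["n_predicted"], df["n_input"], margins=True,
                       margins_name="total")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-level driver: load inputs, run every list plus the joint pass,
    write self-describing TSVs and a manifest under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = load_edge_list(cfg.network, score_threshold=cfg.score_threshold,
                         weighted=cfg.weighted)
    logger.info("network: %d genes, %d edges", net.n, net.n_edges)
    raw_lists = {name: read_gene_list(p) for name, p in cfg.lists.items()}
    pathway_db = (enr.read_gmt(cfg.pathways, size_filter=cfg.size_filter)
                  if cfg.pathways else None)
    background = set(net.nodes)
    if cfg.background == "lists+network":
        for genes in raw_lists.values():
            background |= set(genes)

    singles = []
    for name, genes in raw_lists.items():
        res = run_single_list(net, name, genes, cfg, pathway_db, background)
        res["scores"].table.to_csv(out / f"scores_{name}.tsv", sep="\t",
                                   index=False)
        res["top"].to_csv(out / f"top_{name}.tsv", sep="\t", index=False)
        res["profile"].to_frame().to_csv(out / f"profile_{name}.tsv",
                                         sep="\t", index=False)
        res["module"].to_frame(res["scores"]).to_csv(
            out / f"module_{name}.tsv", sep="\t", index=False)
        if res["ora"] is not None:
            res["ora"].to_csv(out / f"ora_{name}.tsv", sep="\t", index=False)
        singles.append(res)

    joint = None
    if len(raw_lists) >= 2:
        joint = run_joint(net, raw_lists, cfg.weights or None, cfg,
                          pathway_db, background)
        joint["scores"].table.to_csv(out / "scores_joint.tsv", sep="\t",
                                     index=False)
        joint["profile"].to_frame().to_csv(out / "profile_joint.tsv",
                                           sep="\t", index=False)
        joint["module"].to_frame(joint["scores"]).to_csv(
            out / "module_joint.tsv", sep="\t", index=False)
        if joint["breakdown"] is not None:
            joint["breakdown"].to_csv(out / "module_breakdown.tsv", sep="\t",
                                      index=False)
        cooc = co_occurrence(singles)
        if not cooc.empty:
            cooc.to_csv(out / "co_occurrence.tsv", sep="\t")

    emap = None
    if pathway_db is not None:
        all_ora = [r["ora"] for r in singles if r["ora"] is not None]
        if joint is not None and joint["ora"] is not None:
            all_ora.append(joint["ora"])
        if all_ora:
            emap = enr.build_enrichment_map(
                all_ora, pathway_db, o_threshold=cfg.o_threshold,
                top_k=cfg.top_k, padj_threshold=cfg.padj_threshold)
            emap.nodes.to_csv(out / "emap_nodes.tsv", sep="\t", index=False)
            emap.edges.to_csv(out / "emap_edges.tsv", sep="\t", index=False)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "inputs": {str(p): _sha256(p)
                   for p in [cfg.network, *cfg.lists.values()]
                   + ([cfg.pathways] if cfg.pathways else [])},
        "network": {"n_genes": net.n, "n_edges": net.n_edges},
        "epsilons": {r["name"]: r["scores"].epsilon for r in singles},
        "m_star": {r["name"]: r["module"].m_star for r in singles},
    }
    if joint is not None:
        manifest["m_star"]["joint"] = joint["module"].m_star
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    return {"network": net, "singles": singles, "joint": joint,
            "enrichment_map": emap, "manifest": manifest}
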