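"""Hypergeometric over-representation and module-annotation overlap tests.

All tests are upper-tail hypergeometric: drawing n_q genes from a background
of N_b that contains K_p annotation members, the p-value is P(X >= k) for
the observed overlap k.  Pathway-level tests are corrected with
Benjamini-Hochberg; pathway-pathway similarity uses the overlap coefficient
o = |A n B| / min(|A|, |B|), which drives the enrichment-map construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["PathwayDB", "OverlapTest", "EnrichmentMap", "hypergeom_tail",
           "module_overlap_test", "interaction_excess_test", "bh_adjust",
           "overlap_coefficient", "ora", "build_enrichment_map", "read_gmt"]

DEFAULT_SIZE_FILTER = (10, 200)


@dataclass
class PathwayDB:
    """Named gene sets with an inclusive size filter (default 10-200)."""

    pathways: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    size_filter: tuple[int, int] = DEFAULT_SIZE_FILTER

    def __post_init__(self) -> None:
        lo, hi = self.size_filter
        before = len(self.pathways)
        self.pathways = {name: genes for name, genes in self.pathways.items()
                         if lo <= len(genes) <= hi}
        if len(self.pathways) < before:
            logger.info("size filter [%d, %d] dropped %d of %d pathways",
                        lo, hi, before - len(self.pathways), before)

    def __len__(self) -> int:
        return len(self.pathways)

    def restricted_to(self, background: set[str]) -> dict[str, set[str]]:
        return {name: genes & background for name, genes in self.pathways.items()}

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.pathways):
                desc = self.descriptions.get(name, "na")
                genes = "\t".join(sorted(self.pathways[name]))
                fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path, size_filter: tuple[int, int] = DEFAULT_SIZE_FILTER) -> PathwayDB:
    """Parse a GMT file (name, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 fields")
            pathways[parts[0]] = set(parts[2:])
            descriptions[parts[0]] = parts[1]
    return PathwayDB(pathways, descriptions, size_filter)


def hypergeom_tail(k: int, K_p: int, n_q: int, N_b: int) -> float:
    """Upper tail P(X >= k), population N_b with K_p successes, n_q draws."""
    if not (0 <= k <= min(K_p, n_q)):
        raise ValueError(f"infeasible overlap k={k} for K_p={K_p}, n_q={n_q}")
    if K_p > N_b or n_q > N_b:
        raise ValueError("annotation or query larger than background")
    return float(hypergeom.sf(k - 1, N_b, K_p, n_q))


@dataclass
class OverlapTest:
    module_size: int
    complement_size: int
    annotation_size: int
    observed: int
    expected: float
    p: float


def module_overlap_test(module_genes: set[str], annotation: set[str],
                        background: set[str]) -> OverlapTest:
    """Is an annotation over-represented in a gene module?

    Annotation genes outside the background are dropped (with a warning);
    the expected overlap under the null is |M| * |annotation| / |background|.
    """
    module_genes = set(module_genes) & set(background)
    ann_in_bg = set(annotation) & set(background)
    if not ann_in_bg:
        raise ValueError("annotation is disjoint from the background")
    if len(ann_in_bg) < len(set(annotation)):
        logger.warning("%d annotation genes absent from background dropped",
                       len(set(annotation)) - len(ann_in_bg))
    observed = len(module_genes & ann_in_bg)
    n_bg, n_mod, n_ann = len(set(background)), len(module_genes), len(ann_in_bg)
    expected = n_mod * n_ann / n_bg
    p = hypergeom_tail(observed, n_ann, n_mod, n_bg)
    return OverlapTest(module_size=n_mod, complement_size=n_bg - n_mod,
                       annotation_size=n_ann, observed=observed,
                       expected=expected, p=p)


def interaction_excess_test(gene: str, net: GeneNetwork, risk_genes: set[str],
                            background_size: int | None = None) -> OverlapTest:
    """Does a gene interact with more risk genes than expected by chance?

    Draws are the gene's interactors; successes are the risk genes present
    in the background (the network by default, minus the tested gene).
    """
    if gene not in net.index:
        raise KeyError(f"gene {gene!r} not in network")
    row = net.A[net.index[gene]]
    neighbors = {net.nodes[j] for j in row.indices}
    background = set(net.nodes) - {gene}
    n_bg = background_size if background_size is not None else len(background)
    risk_in_bg = risk_genes & background
    observed = len(neighbors & risk_in_bg)
    n_i = len(neighbors)
    if n_i == 0:
        return OverlapTest(0, n_bg, len(risk_in_bg), 0,
                           expected=0.0, p=1.0)
    expected = n_i * len(risk_in_bg) / n_bg
    p = hypergeom_tail(observed, len(risk_in_bg), n_i, n_bg)
    return OverlapTest(module_size=n_i, complement_size=n_bg - n_i,
                       annotation_size=len(risk_in_bg), observed=observed,
                       expected=expected, p=p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def overlap_coefficient(set_a: set[str], set_b: set[str]) -> float:
    """o = |A n B| / min(|A|, |B|)."""
    if not set_a or not set_b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(set_a & set_b) / min(len(set_a), len(set_b))


def ora(query: set[str], db: PathwayDB, background: set[str],
        background_label: str = "network") -> pd.DataFrame:
    """Over-representation of every pathway in a query gene list.

    Query and pathways are restricted to the background before testing.
    Returns one row per pathway: pathway, size, overlap, query size,
    background size, p, p_adj (BH), background label; sorted by p.
    """
    background = set(background)
    query = set(query) & background
    if not query:
        raise ValueError("query has no gene in the background")
    rows = []
    for name in sorted(db.pathways):
        genes = db.pathways[name] & background
        if not genes:
            continue
        k = len(query & genes)
        rows.append((name, len(genes), k, len(query), len(background),
                     hypergeom_tail(k, len(genes), len(query), len(background))))
    out = pd.DataFrame(rows, columns=["pathway", "size", "overlap", "n_query",
                                      "n_background", "p"])
    out["p_adj"] = bh_adjust(out["p"]) if len(out) else []
    out["background"] = background_label
    return out.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)


@dataclass
class EnrichmentMap:
    """Pathway-similarity graph over significant pathways.

    ``nodes``: pathway, neg_log10_padj, cluster.  ``edges``: pathway_a,
    pathway_b, o — only pairs with o above the threshold that rank within
    either endpoint's top-k most similar pathways.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame


def _cluster_pathways(names: list[str], sets: dict[str, set[str]],
                      cut: float) -> np.ndarray:
    if len(names) == 1:
        return np.array([1])
    dist = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            dist[i, j] = dist[j, i] = 1.0 - overlap_coefficient(
                sets[a], sets[names[j]])
    z = linkage(squareform(dist, checks=False), method="single")
    return fcluster(z, t=cut, criterion="distance")


def build_enrichment_map(results: pd.DataFrame | list[pd.DataFrame],
                         db: PathwayDB, o_threshold: float = 0.5,
                         top_k: int = 5, max_per_cluster: int = 20,
                         padj_threshold: float = 0.01) -> EnrichmentMap:
    """Enrichment map over the significant pathways of one or more ORA runs.

    Pathways with adjusted p below ``padj_threshold`` are clustered by
    single linkage on (1 - o) cut at (1 - o_threshold); at most
    ``max_per_cluster`` representatives per cluster (most significant first)
    are kept as nodes, weighted by -log10(adjusted p).  Candidate edges need
    o > o_threshold and must rank within the top-k most similar pathways of
    at least one endpoint (ties broken by pathway name).
    """
    if isinstance(results, pd.DataFrame):
        results = [results]
    best: dict[str, float] = {}
    for res in results:
        sig = res[res["p_adj"] < padj_threshold]
        for _, row in sig.iterrows():
            p = float(row["p_adj"])
            if row["pathway"] not in best or p < best[row["pathway"]]:
                best[row["pathway"]] = p
    if not best:
        return EnrichmentMap(
            nodes=pd.DataFrame(columns=["pathway", "neg_log10_padj", "cluster"]),
            edges=pd.DataFrame(columns=["pathway_a", "pathway_b", "o"]))

    names = sorted(best)
    clusters = _cluster_pathways(names, db.pathways, cut=1.0 - o_threshold)
    nodes = pd.DataFrame({
        "pathway": names,
        "neg_log10_padj": [-np.log10(best[n]) for n in names],
        "cluster": clusters,
    })
    nodes = (nodes.sort_values(["cluster", "neg_log10_padj", "pathway"],
                               ascending=[True, False, True], kind="stable")
                  .groupby("cluster", group_keys=False)
                  .head(max_per_cluster)
                  .sort_values("pathway", kind="stable")
                  .reset_index(drop=True))

    kept = nodes["pathway"].tolist()
    sims: dict[str, list[tuple[float, str]]] = {n: [] for n in kept}
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            o = overlap_coefficient(db.pathways[a], db.pathways[b])
            if o > o_threshold:
                sims[a].append((o, b))
                sims[b].append((o, a))
    edge_set = set()
    for a, cand in sims.items():
        cand.sort(key=lambda t: (-t[0], t[1]))
        for o, b in cand[:top_k]:
            edge_set.add((min(a, b), max(a, b)))
    rows = [(a, b, overlap_coefficient(db.pathways[a], db.pathways[b]))
            for a, b in sorted(edge_set)]
    edges = pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "o"])
    return EnrichmentMap(nodes=nodes, edges=edges)
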