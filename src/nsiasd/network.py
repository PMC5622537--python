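"""Gene-network container and I/O.

The network is an undirected, unweighted (by default) graph built from a
STRING-style edge list with per-edge confidence scores in [0, 1000].  All
downstream diffusion operates on the symmetrically normalized adjacency
matrix ``W = D^{-1/2} A D^{-1/2}``, whose spectral radius is at most 1, so
the diffusion recurrence converges for any retention parameter alpha < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["GeneNetwork", "load_edge_list", "network_from_edges",
           "read_gene_list", "restrict_to_network"]


class EdgeListParseError(ValueError):
    """Raised when an edge-list row cannot be parsed."""


@dataclass
class GeneNetwork:
    """Indexed undirected gene network.

    Attributes
    ----------
    nodes : list of str
        Gene identifiers in lexicographic order; defines the row/column
        order of all matrices.
    edges : pandas.DataFrame
        Columns ``gene_a``, ``gene_b``, ``score`` with gene_a < gene_b.
    A : scipy.sparse.csr_matrix
        Symmetric adjacency, zero diagonal.  Binary unless the network was
        loaded with ``weighted=True`` (then entries are score/1000).
    """

    nodes: list[str]
    edges: pd.DataFrame
    A: sp.csr_matrix
    weighted: bool = False
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _W: sp.csr_matrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {g: i for i, g in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def index(self) -> dict[str, int]:
        return self._index

    @property
    def degree(self) -> np.ndarray:
        """Per-node incident-edge count (unweighted, regardless of A)."""
        binary = self.A.copy()
        binary.data = np.ones_like(binary.data)
        return np.asarray(binary.sum(axis=1)).ravel().astype(int)

    @property
    def W(self) -> sp.csr_matrix:
        if self._W is None:
            self._W = normalize_adjacency(self)
        return self._W

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            self.edges[["gene_a", "gene_b", "score"]].itertuples(index=False),
            weight="score",
        )
        return g

    def subgraph_adjacency(self, genes: list[str]) -> sp.csr_matrix:
        """Adjacency of the induced subgraph, aligned to ``genes`` order."""
        idx = np.array([self._index[g] for g in genes])
        return self.A[np.ix_(idx, idx)].tocsr()

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# gene_a\tgene_b\tscore\n")
            self.edges.to_csv(fh, sep="\t", index=False, header=False)


def _build_network(pairs: pd.DataFrame, weighted: bool) -> GeneNetwork:
    nodes = sorted(set(pairs["gene_a"]) | set(pairs["gene_b"]))
    index = {g: i for i, g in enumerate(nodes)}
    i = pairs["gene_a"].map(index).to_numpy()
    j = pairs["gene_b"].map(index).to_numpy()
    vals = (pairs["score"].to_numpy() / 1000.0) if weighted else np.ones(len(pairs))
    n = len(nodes)
    a = sp.coo_matrix((vals, (i, j)), shape=(n, n))
    a = (a + a.T).tocsr()
    return GeneNetwork(nodes=nodes, edges=pairs.reset_index(drop=True), A=a,
                       weighted=weighted, _index=index)


def network_from_edges(pairs, weighted: bool = False) -> GeneNetwork:
    """Build a network from (gene_a, gene_b, score) triples.

    Pairs are canonicalized (gene_a < gene_b), self-pairs dropped and
    duplicates collapsed to the highest score; no threshold is applied.
    """
    df = pd.DataFrame(list(pairs), columns=["gene_a", "gene_b", "score"])
    df = df[df["gene_a"] != df["gene_b"]]
    swap = df["gene_a"] > df["gene_b"]
    df.loc[swap, ["gene_a", "gene_b"]] = df.loc[swap, ["gene_b", "gene_a"]].values
    df = (df.sort_values("score", ascending=False)
            .drop_duplicates(["gene_a", "gene_b"])
            .sort_values(["gene_a", "gene_b"], kind="stable"))
    if df.empty:
        raise ValueError("no edges supplied")
    return _build_network(df, weighted)


def load_edge_list(path, score_threshold: int = 700, mapping=None,
                   weighted: bool = False) -> GeneNetwork:
    """Load a three-column (idA, idB, score) TSV into a :class:`GeneNetwork`.

    Rules applied, in order: optional ID mapping (unmapped rows dropped with
    a warning), score threshold (``score >= threshold`` kept), self-pair
    removal, and duplicate-pair collapse keeping the maximum score.

    Parameters
    ----------
    score_threshold : int
        Inclusive lower bound on the confidence score, on the 0-1000 scale.
    mapping : dict or path, optional
        source-ID -> gene-ID map (two-column TSV if a path is given).
    weighted : bool
        If True, adjacency entries carry score/1000 instead of 1.
    """
    if not 0 <= score_threshold <= 1000:
        raise ValueError(f"score_threshold must be in [0, 1000], got {score_threshold}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: non-numeric score {parts[2]!r}") from exc
            rows.append((parts[0], parts[1], score))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])

    if mapping is not None:
        if not isinstance(mapping, dict):
            mtab = pd.read_csv(mapping, sep="\t", comment="#", header=None,
                               names=["source_id", "gene_id"], dtype=str)
            mapping = dict(zip(mtab["source_id"], mtab["gene_id"]))
        before = len(df)
        df["gene_a"] = df["gene_a"].map(mapping)
        df["gene_b"] = df["gene_b"].map(mapping)
        df = df.dropna(subset=["gene_a", "gene_b"])
        if len(df) < before:
            logger.warning("dropped %d edges with unmapped identifiers",
                           before - len(df))

    df = df[df["score"] >= score_threshold]
    df = df[df["gene_a"] != df["gene_b"]]
    # canonical unordered pair, then keep the highest-scoring duplicate
    swap = df["gene_a"] > df["gene_b"]
    df.loc[swap, ["gene_a", "gene_b"]] = df.loc[swap, ["gene_b", "gene_a"]].values
    df = (df.sort_values("score", ascending=False)
            .drop_duplicates(["gene_a", "gene_b"])
            .sort_values(["gene_a", "gene_b"], kind="stable"))
    if df.empty:
        raise ValueError(
            f"no edges remain after applying threshold {score_threshold}")
    return _build_network(df, weighted)


def normalize_adjacency(net: GeneNetwork) -> sp.csr_matrix:
    """Symmetric normalization W = D^{-1/2} A D^{-1/2}.

    Weighted degrees (row sums of A) are used; isolated nodes keep all-zero
    rows and columns rather than being removed.
    """
    deg = np.asarray(net.A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(deg)
    inv_sqrt[~np.isfinite(inv_sqrt)] = 0.0
    d = sp.diags(inv_sqrt)
    return (d @ net.A @ d).tocsr()


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one identifier per line, '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def restrict_to_network(gene_list: list[str], net: GeneNetwork
                        ) -> tuple[list[str], list[str]]:
    """Intersect a gene list with the network node set.

    Returns (kept, dropped); kept preserves input order and is deduplicated.
    Raises if no gene survives — there would be nothing to diffuse.
    """
    seen: set[str] = set()
    kept, dropped = [], []
    for g in gene_list:
        if g in seen:
            continue
        seen.add(g)
        (kept if g in net.index else dropped).append(g)
    if not kept:
        raise ValueError("no input gene occurs in the network")
    if dropped:
        logger.info("restricted list: %d kept, %d not in network",
                    len(kept), len(dropped))
    return kept, dropped
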