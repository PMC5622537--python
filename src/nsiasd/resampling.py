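"""Network resampling: significance of connectivity among top-ranked genes.

For the top m genes of an Sp ranking, the score-weighted connectivity is

    Omega(m) = Sp(m)^T . A_m . Sp(m)

(the quadratic form counts every undirected edge twice).  Its significance
p_NR(m) is estimated against q randomizations of the induced subgraph A_m
that preserve every node's degree (double edge swaps), so a small p_NR(m)
means the specific placement of edges among high-scoring genes — not their
number or the degree sequence — concentrates score-weighted links.  Scanning
m over a rank grid profiles where the ranked list stops being significantly
self-connected; the extracted gene module is the longest prefix whose tail
of grid points stays significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import GeneNetwork
from .smoothing import SmoothingResult

logger = logging.getLogger(__name__)

__all__ = ["NRProfile", "GeneModule", "omega", "degree_preserving_rewire",
           "nr_profile", "extract_module", "default_m_grid"]

DEFAULT_Q = 200
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class NRProfile:
    """Omega, prefix p-values and increment p-values over the rank grid.

    ``p_nr[i]`` tests the whole top-m_grid[i] prefix; ``p_inc[i]`` tests
    only the connectivity added since the previous grid point (edges
    touching the newly added genes), against the same rewired nulls.
    """

    m_grid: np.ndarray
    omega: np.ndarray
    p_nr: np.ndarray
    q: int
    swaps_per_edge: int
    rng_seed: int
    p_inc: np.ndarray | None = None
    pseudocount: bool = True

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"m": self.m_grid, "omega": self.omega,
                            "p_nr": self.p_nr})
        if self.p_inc is not None:
            out["p_inc"] = self.p_inc
        return out


@dataclass
class GeneModule:
    m_star: int
    genes: list[str]
    induced_edges: list[tuple[str, str]]
    components: list[list[str]]
    membership_breakdown: dict[str, int]
    status: str = "ok"

    @property
    def is_empty(self) -> bool:
        return self.m_star == 0

    def to_frame(self, ranked: SmoothingResult) -> pd.DataFrame:
        comp_of = {g: ci for ci, comp in enumerate(self.components) for g in comp}
        sub = ranked.table.head(self.m_star)[
            ["gene", "rank", "Sp", "source_lists"]].copy()
        sub["component_id"] = sub["gene"].map(comp_of)
        return sub


def omega(sp_m: np.ndarray, a_m) -> float:
    """Quadratic connectivity score Sp^T A Sp (each edge counted twice)."""
    sp_m = np.asarray(sp_m, dtype=float)
    if a_m.shape != (sp_m.size, sp_m.size):
        raise ValueError(
            f"adjacency {a_m.shape} does not match score vector of size {sp_m.size}")
    return float(sp_m @ (a_m @ sp_m))


def _edges_from_adjacency(a_m) -> np.ndarray:
    coo = sp.coo_matrix(sp.triu(a_m, k=1))
    return np.column_stack([coo.row, coo.col]).astype(np.int64)


def _sorted_contains(sorted_keys: np.ndarray, keys: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(sorted_keys, keys)
    pos = np.minimum(pos, sorted_keys.size - 1)
    return (sorted_keys.size > 0) & (sorted_keys[pos] == keys)


def _rewire_edges(edges: np.ndarray, swaps_per_edge: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Double edge swaps on an (m, 2) integer edge array.

    swaps_per_edge*m swaps are attempted in vectorized batches: each
    proposal picks two distinct edges, orients them at random and exchanges
    endpoints; proposals creating a self-loop or a duplicate edge, or
    conflicting with an earlier proposal of the same batch, are rejected.
    The degree sequence is invariant by construction.
    """
    m = len(edges)
    if m < 2:
        return edges.copy()
    edges = edges.copy()
    span = np.int64(edges.max()) + 1

    def key(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        lo = np.minimum(u, v).astype(np.int64)
        hi = np.maximum(u, v).astype(np.int64)
        return lo * span + hi

    keys = np.sort(key(edges[:, 0], edges[:, 1]))
    n_attempts = swaps_per_edge * m
    batch = max(1, m // 4)
    done = 0
    while done < n_attempts:
        b = min(batch, n_attempts - done)
        done += b
        i = rng.integers(0, m, b)
        j = rng.integers(0, m, b)
        orient = rng.random(b) < 0.5
        a, bb = edges[i, 0], edges[i, 1]
        c = np.where(orient, edges[j, 1], edges[j, 0])
        d = np.where(orient, edges[j, 0], edges[j, 1])
        # proposal: (a, bb), (c, d) -> (a, d), (c, bb)
        k1 = key(a, d)
        k2 = key(c, bb)
        ok = (i != j) & (a != d) & (c != bb) & (k1 != k2)
        ok &= ~_sorted_contains(keys, k1) & ~_sorted_contains(keys, k2)
        # an edge index may participate in at most one proposal per batch
        used = np.stack([i, j], axis=1).ravel()
        first = np.zeros(used.size, dtype=bool)
        first[np.unique(used, return_index=True)[1]] = True
        ok &= first.reshape(-1, 2).all(axis=1)
        # proposed keys must be unique across the batch
        allk = np.concatenate([k1, k2])
        firstk = np.zeros(allk.size, dtype=bool)
        firstk[np.unique(allk, return_index=True)[1]] = True
        ok &= firstk[:b] & firstk[b:]
        sel = np.flatnonzero(ok)
        if sel.size == 0:
            continue
        old = np.concatenate([key(edges[i[sel], 0], edges[i[sel], 1]),
                              key(edges[j[sel], 0], edges[j[sel], 1])])
        edges[i[sel], 0] = np.minimum(a[sel], d[sel])
        edges[i[sel], 1] = np.maximum(a[sel], d[sel])
        edges[j[sel], 0] = np.minimum(c[sel], bb[sel])
        edges[j[sel], 1] = np.maximum(c[sel], bb[sel])
        keys = np.sort(np.concatenate(
            [keys[~np.isin(keys, old)], k1[sel], k2[sel]]))
    return edges


def degree_preserving_rewire(a_m, swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                             rng_seed: int = 0) -> sp.csr_matrix:
    """Degree-preserving randomization of a simple undirected adjacency.

    Graphs with fewer than two edges admit no swap and are returned
    unchanged.  The result is simple (no self-loops or multi-edges) with
    the identical degree sequence.
    """
    a_m = sp.csr_matrix(a_m)
    n = a_m.shape[0]
    edges = _edges_from_adjacency(a_m)
    rewired = _rewire_edges(edges, swaps_per_edge,
                            np.random.default_rng(rng_seed))
    return _adjacency_from_edges(rewired, n)


def _adjacency_from_edges(edges: np.ndarray, n: int) -> sp.csr_matrix:
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    data = np.ones(len(edges))
    a = sp.coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
    return (a + a.T).tocsr()


def default_m_grid(n_seed: int, n_nodes: int,
                   step_near: int = 10, step_far: int = 25) -> np.ndarray:
    """Rank grid: every ``step_near`` up to 2x the seed count, then every
    ``step_far`` up to 5x, capped at the network size."""
    near = np.arange(step_near, 2 * n_seed + 1, step_near)
    far = np.arange(2 * n_seed + step_far, 5 * n_seed + 1, step_far)
    grid = np.concatenate([near, far])
    grid = grid[grid <= n_nodes]
    if grid.size == 0:
        grid = np.array([min(n_seed, n_nodes)])
    return grid.astype(int)


def nr_profile(ranked: SmoothingResult, net: GeneNetwork,
               m_grid: np.ndarray | None = None, q: int = DEFAULT_Q,
               rng_seed: int = 0,
               swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
               pseudocount: bool = True) -> NRProfile:
    """Omega and empirical p_NR over a grid of rank cutoffs.

    For each m the induced subgraph on the top-m genes is rewired q times;
    p_NR(m) = (1 + #{Omega^k >= Omega}) / (q + 1) by default, or the plain
    exceedance fraction #/q with ``pseudocount=False``.
    """
    if q < 1:
        raise ValueError("q must be at least 1")
    if m_grid is None:
        m_grid = default_m_grid(ranked.n_input, net.n)
    m_grid = np.asarray(m_grid, dtype=int)
    if np.any(m_grid < 1) or np.any(m_grid > net.n):
        raise ValueError("m_grid values must lie in 1..n")
    rng = np.random.default_rng(rng_seed)

    genes_all = ranked.table["gene"].tolist()
    sp_all = ranked.table["Sp"].to_numpy()
    omegas = np.empty(len(m_grid))
    p_nr = np.empty(len(m_grid))
    p_inc = np.empty(len(m_grid))

    def _increment(edge_arr: np.ndarray, scores: np.ndarray,
                   m_prev: int) -> float:
        # connectivity contributed by edges touching genes ranked > m_prev
        # (node indices equal rank order within the induced subgraph)
        if len(edge_arr) == 0:
            return 0.0
        mask = (edge_arr[:, 0] >= m_prev) | (edge_arr[:, 1] >= m_prev)
        return 2.0 * float(np.sum(scores[edge_arr[mask, 0]]
                                  * scores[edge_arr[mask, 1]]))

    for gi, m in enumerate(m_grid):
        a_m = net.subgraph_adjacency(genes_all[:m])
        scores = sp_all[:m]
        obs = omega(scores, a_m)
        edges = _edges_from_adjacency(a_m)
        m_prev = int(m_grid[gi - 1]) if gi > 0 else 0
        obs_inc = _increment(edges, scores, m_prev)
        exceed = 0
        exceed_inc = 0
        for _ in range(q):
            rew = _rewire_edges(edges, swaps_per_edge, rng)
            om_k = 2.0 * np.sum(scores[rew[:, 0]] * scores[rew[:, 1]])
            if om_k >= obs - 1e-12:
                exceed += 1
            if _increment(rew, scores, m_prev) >= obs_inc - 1e-12:
                exceed_inc += 1
        omegas[gi] = obs
        if pseudocount:
            p_nr[gi] = (1 + exceed) / (q + 1)
            p_inc[gi] = (1 + exceed_inc) / (q + 1)
        else:
            p_nr[gi] = exceed / q
            p_inc[gi] = exceed_inc / q
    return NRProfile(m_grid=m_grid, omega=omegas, p_nr=p_nr, q=q,
                     swaps_per_edge=swaps_per_edge, rng_seed=rng_seed,
                     p_inc=p_inc, pseudocount=pseudocount)


def extract_module(profile: NRProfile, ranked: SmoothingResult,
                   net: GeneNetwork, significance: float = 0.05,
                   window: int = 3) -> GeneModule:
    """Module cutoff from the significance onset plus significant increments.

    The onset is the start of the first consecutive run of significant
    prefix p-values (p_NR <= significance) confirmed by at least ``window``
    grid points (fewer if the grid ends first) — a single noisy dip cannot
    seed a module.  From the onset the cutoff extends to larger grid points
    as long as the prefix stays significant and — when increment p-values
    are available — each added rank chunk contributes significantly more
    connectivity than the degree-preserving null (p_inc <= significance);
    the extension stops at the first chunk explainable by chance.  Without
    increment p-values, the rule degrades to the largest sustained-
    significant prefix.  The module is the full top-m* prefix with its
    induced edges and connected components; an empty module (no qualifying
    m) is a valid outcome.
    """
    sig = profile.p_nr <= significance
    onset = None
    for i in range(len(profile.m_grid)):
        lo = max(0, i - window + 1)
        if sig[lo:i + 1].all():
            onset = i
            break
    m_star = 0
    if onset is not None:
        while onset > 0 and sig[onset - 1]:
            onset -= 1  # back to the start of the confirmed run
        i_star = onset
        for i in range(onset + 1, len(profile.m_grid)):
            if not sig[i]:
                break
            if profile.p_inc is not None and profile.p_inc[i] > significance:
                break
            i_star = i
        m_star = int(profile.m_grid[i_star])
    if m_star == 0:
        return GeneModule(0, [], [], [], {},
                          status="no significantly connected prefix")
    genes = ranked.table["gene"].head(m_star).tolist()
    a_m = net.subgraph_adjacency(genes)
    edges_idx = _edges_from_adjacency(a_m)
    induced_edges = [(genes[u], genes[v]) for u, v in edges_idx]
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(induced_edges)
    components = [sorted(c) for c in
                  sorted(nx.connected_components(g), key=len, reverse=True)]
    breakdown: dict[str, int] = {}
    head = ranked.table.head(m_star)
    # each gene counted once, keyed by its source-list combination,
    # so the breakdown sums exactly to m*
    for sources in head["source_lists"]:
        key = sources if sources else "predicted"
        breakdown[key] = breakdown.get(key, 0) + 1
    logger.info("module: m*=%d, %d components, breakdown=%s",
                m_star, len(components), breakdown)
    return GeneModule(m_star=m_star, genes=genes, induced_edges=induced_edges,
                      components=components, membership_breakdown=breakdown)
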