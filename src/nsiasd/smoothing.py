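"""Network smoothing index and its permutation adjustment.

For a seed vector X0 diffused to X*, each gene g gets

    S(g)  = X*(g) / (X0(g) + epsilon)
    pS(g) = (1 + #{S^k(g) >= S(g)}) / (K + 1)
    Sp(g) = -log10(pS(g)) * S(g)

where S^k is the index recomputed after the k-th random reassignment of the
X0 values over the node labels.  The permutation term penalizes genes (hubs
in particular) that collect diffused mass regardless of where the seeds sit,
so that a high Sp requires specific network proximity to the actual seeds.

epsilon tunes how strongly the input genes themselves dominate the ranking:
large epsilon shrinks the index of non-seeds relative to seeds.  It can be
calibrated so that the top of the Sp ranking contains input and predicted
(non-input) genes in a 1:1 ratio, or fixed (e.g. to 1 for a joint analysis
whose aim is prioritizing the inputs themselves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .diffusion import (DEFAULT_ALPHA, DEFAULT_MAX_ITER, DEFAULT_TOL,
                        SeedVector, diffuse_iterative)
from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["SmoothingResult", "build_seed_vector", "smoothing_index",
           "adjusted_index", "PermutationNull", "permutation_null",
           "calibrate_epsilon", "score_genes", "rank_genes", "select_top"]

DEFAULT_K = 999


@dataclass
class SmoothingResult:
    """Per-gene scores plus the parameters that produced them.

    ``table`` columns: gene, x0, x_star, S, pS, Sp, rank, is_input,
    source_lists.  Rows are ordered by rank (descending Sp; ties broken by
    descending S, then lexicographic gene identifier).
    """

    table: pd.DataFrame
    epsilon: float
    K: int
    alpha: float
    rng_seed: int
    null_exceed_counts: np.ndarray = field(repr=False, default=None)

    @property
    def n_input(self) -> int:
        return int(self.table["is_input"].sum())

    def top(self, m: int) -> pd.DataFrame:
        return self.table.head(m)


def build_seed_vector(lists: dict[str, list[str]],
                      weights: dict[str, float] | None,
                      net: GeneNetwork) -> SeedVector:
    """Combine named gene lists into one seed vector.

    A gene occurring in several lists gets the maximum weight over the lists
    containing it; membership is retained for per-source reporting.  Lists
    must already be restricted to network genes.
    """
    weights = weights or {name: 1.0 for name in lists}
    x0 = np.zeros(net.n)
    membership: dict[str, set[str]] = {}
    for name, genes in lists.items():
        w = weights.get(name, 1.0)
        if not 0 < w <= 1:
            raise ValueError(f"weight for list {name!r} must be in (0, 1], got {w}")
        for g in genes:
            if g not in net.index:
                raise KeyError(f"gene {g!r} not in network; restrict lists first")
            x0[net.index[g]] = max(x0[net.index[g]], w)
            membership.setdefault(g, set()).add(name)
    return SeedVector(x0=x0, list_membership=membership)


def smoothing_index(x_star: np.ndarray, x0: np.ndarray,
                    epsilon: float) -> np.ndarray:
    """Elementwise ratio S = x_star / (x0 + epsilon)."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    return np.asarray(x_star) / (np.asarray(x0) + epsilon)


def adjusted_index(S: np.ndarray, pS: np.ndarray) -> np.ndarray:
    """Sp = -log10(pS) * S; zero where pS = 1."""
    pS = np.asarray(pS, dtype=float)
    if np.any(pS <= 0) or np.any(pS > 1):
        raise ValueError("pS values must lie in (0, 1]")
    return -np.log10(pS) * np.asarray(S)


class PermutationNull:
    """Diffused permutations of a seed vector, reusable across epsilons.

    Each of the K permutations reassigns the multiset of X0 values uniformly
    at random over all node labels, preserving the seed count and the weight
    alphabet.  X* of a permutation does not depend on epsilon, so the same
    diffusions serve every epsilon candidate during calibration.
    """

    def __init__(self, W: sp.spmatrix, x0: SeedVector | np.ndarray,
                 K: int = DEFAULT_K, rng_seed: int = 0,
                 alpha: float = DEFAULT_ALPHA, tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER):
        if K < 1:
            raise ValueError("K must be at least 1")
        x0 = x0.x0 if isinstance(x0, SeedVector) else np.asarray(x0, float)
        self.K = K
        self.rng_seed = rng_seed
        rng = np.random.default_rng(rng_seed)
        n = x0.shape[0]
        perm_idx = np.argsort(rng.random((K, n)), axis=1)
        self.x0_perm = x0[perm_idx].T  # (n, K)
        self.xstar_perm = diffuse_iterative(
            W, self.x0_perm, alpha=alpha, tol=tol, max_iter=max_iter).x_star

    def exceed_counts(self, S: np.ndarray, epsilon: float) -> np.ndarray:
        """#{k : S^k(g) >= S(g)} per gene; ties count as exceedances."""
        s_null = self.xstar_perm / (self.x0_perm + epsilon)
        return (s_null >= np.asarray(S)[:, None]).sum(axis=1)

    def p_values(self, S: np.ndarray, epsilon: float) -> np.ndarray:
        return (1.0 + self.exceed_counts(S, epsilon)) / (self.K + 1.0)


def permutation_null(W: sp.spmatrix, x0: SeedVector, K: int, rng_seed: int,
                     epsilon: float, alpha: float = DEFAULT_ALPHA,
                     tol: float = DEFAULT_TOL
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Exceedance counts and empirical pS for a single epsilon.

    Convenience wrapper around :class:`PermutationNull`.
    """
    x_star = diffuse_iterative(W, x0, alpha=alpha, tol=tol).x_star
    S = smoothing_index(x_star, x0.x0, epsilon)
    null = PermutationNull(W, x0, K=K, rng_seed=rng_seed, alpha=alpha, tol=tol)
    counts = null.exceed_counts(S, epsilon)
    return counts, (1.0 + counts) / (K + 1.0)


def rank_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking: Sp desc, then S desc, then gene ID asc."""
    out = table.sort_values(["Sp", "S", "gene"],
                            ascending=[False, False, True],
                            kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _assemble(net: GeneNetwork, seed: SeedVector, x_star, S, pS, Sp
              ) -> pd.DataFrame:
    membership = seed.list_membership or {}
    genes = net.nodes
    table = pd.DataFrame({
        "gene": genes,
        "x0": seed.x0,
        "x_star": x_star,
        "S": S,
        "pS": pS,
        "Sp": Sp,
        "is_input": seed.x0 > 0,
        "source_lists": [",".join(sorted(membership.get(g, ()))) for g in genes],
    })
    return rank_genes(table)


def _count_inputs_in_window(table: pd.DataFrame, window: int) -> int:
    return int(table.head(window)["is_input"].sum())


def calibrate_epsilon(net: GeneNetwork, seed: SeedVector,
                      alpha: float = DEFAULT_ALPHA, K: int = DEFAULT_K,
                      rng_seed: int = 0, target_window: int | None = None,
                      tol: float = DEFAULT_TOL,
                      eps_range: tuple[float, float] = (1e-4, 64.0),
                      max_bisect: int = 40,
                      _precomputed: tuple | None = None) -> float:
    """Calibrate epsilon for a 1:1 input/predicted balance at the top of the ranking.

    With N input genes and the default window of 2N, epsilon is chosen (by
    bisection on log-epsilon) so that the top-2N genes ranked by Sp split
    into N input and N predicted genes.  Larger epsilon pushes seeds up the
    ranking, so the input count in the window is non-decreasing in epsilon
    and bisection is valid; the same permutation null is reused for every
    candidate.  Balance within +/-1 input gene is accepted.
    """
    n_input = int((seed.x0 > 0).sum())
    if n_input == net.n:
        raise ValueError("all genes are seeds: 1:1 balance is unattainable")
    window = target_window if target_window is not None else 2 * n_input
    if window > net.n:
        raise ValueError(f"target window {window} exceeds network size {net.n}")
    if n_input > window // 2 + 1:
        raise ValueError("seed list larger than half the calibration window")

    if _precomputed is not None:
        x_star, null = _precomputed
    else:
        x_star = diffuse_iterative(net.W, seed, alpha=alpha, tol=tol).x_star
        null = PermutationNull(net.W, seed, K=K, rng_seed=rng_seed,
                               alpha=alpha, tol=tol)

    def count_at(eps: float) -> int:
        S = smoothing_index(x_star, seed.x0, eps)
        pS = null.p_values(S, eps)
        table = _assemble(net, seed, x_star, S, pS, adjusted_index(S, pS))
        return _count_inputs_in_window(table, window)

    # balanced window: half inputs, half predicted (capped by available inputs)
    target = min(window // 2, n_input)
    lo, hi = eps_range
    c_lo, c_hi = count_at(lo), count_at(hi)
    if c_hi < target - 1:
        raise ValueError(
            f"1:1 balance unattainable: input count in top-{window} is "
            f"{c_lo} at epsilon={lo} and {c_hi} at epsilon={hi}")
    if c_lo >= target:
        return lo
    for _ in range(max_bisect):
        mid = float(np.sqrt(lo * hi))
        if count_at(mid) >= target:
            hi = mid
        else:
            lo = mid
    eps = hi
    achieved = count_at(eps)
    if abs(achieved - target) > 1:
        raise ValueError(
            f"calibration failed: {achieved} inputs in top-{window} at "
            f"epsilon={eps:.4g} (target {target})")
    logger.info("calibrated epsilon=%.4g (%d inputs in top-%d)",
                eps, achieved, window)
    return eps


def score_genes(net: GeneNetwork, seed: SeedVector,
                alpha: float = DEFAULT_ALPHA, epsilon: float | str = "auto",
                K: int = DEFAULT_K, rng_seed: int = 0,
                tol: float = DEFAULT_TOL,
                target_window: int | None = None) -> SmoothingResult:
    """Full scoring pass: diffusion, permutation null, S/pS/Sp, ranking.

    ``epsilon="auto"`` triggers the 1:1 calibration; the diffusions are
    shared between calibration and the final scores.
    """
    x_star = diffuse_iterative(net.W, seed, alpha=alpha, tol=tol).x_star
    null = PermutationNull(net.W, seed, K=K, rng_seed=rng_seed,
                           alpha=alpha, tol=tol)
    if epsilon == "auto":
        epsilon = calibrate_epsilon(net, seed, alpha=alpha, K=K,
                                    rng_seed=rng_seed,
                                    target_window=target_window,
                                    _precomputed=(x_star, null))
    epsilon = float(epsilon)
    S = smoothing_index(x_star, seed.x0, epsilon)
    counts = null.exceed_counts(S, epsilon)
    pS = (1.0 + counts) / (K + 1.0)
    Sp = adjusted_index(S, pS)
    table = _assemble(net, seed, x_star, S, pS, Sp)
    order = [net.index[g] for g in table["gene"]]
    return SmoothingResult(table=table, epsilon=epsilon, K=K, alpha=alpha,
                           rng_seed=rng_seed,
                           null_exceed_counts=counts[order])


def select_top(result: SmoothingResult, multiplier: int = 2) -> pd.DataFrame:
    """Top multiplier*n genes by Sp, n being the input-list size.

    Mirrors the "2n" selection used to define network-based gene lists that
    contain both input and predicted genes.
    """
    m = multiplier * result.n_input
    if m > len(result.table):
        logger.warning("requested top %d exceeds network size %d; truncating",
                       m, len(result.table))
        m = len(result.table)
    return result.table.head(m).copy()
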