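import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import nsiasd as ns
from nsiasd.resampling import (NRProfile, _edges_from_adjacency,
                               _rewire_edges, default_m_grid)
from nsiasd.smoothing import SmoothingResult
from conftest import random_network


def adjacency(edges, n):
    a = np.zeros((n, n))
    for u, v in edges:
        a[u, v] = a[v, u] = 1
    return sp.csr_matrix(a)


class TestOmega:
    def test_edgeless_is_zero(self):
        assert ns.omega(np.array([1.0, 2.0]), sp.csr_matrix((2, 2))) == 0

    def test_single_edge_counts_twice(self):
        a = adjacency([(0, 1)], 2)
        assert ns.omega(np.array([2.0, 3.0]), a) == pytest.approx(12.0)

    def test_quadratic_scaling(self):
        a = adjacency([(0, 1), (1, 2)], 3)
        v = np.array([1.0, 2.0, 3.0])
        assert ns.omega(2 * v, a) == pytest.approx(4 * ns.omega(v, a))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ns.omega(np.ones(3), sp.csr_matrix((2, 2)))


class TestRewire:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_degree_sequence_and_simplicity(self, seed):
        net = random_network(40, 0.1, seed)
        a = net.A
        r = ns.degree_preserving_rewire(a, rng_seed=seed)
        assert np.array_equal(np.asarray(a.sum(axis=1)).ravel(),
                              np.asarray(r.sum(axis=1)).ravel())
        assert r.diagonal().max() == 0
        assert r.max() == 1

    def test_triangle_unchanged(self):
        a = adjacency([(0, 1), (1, 2), (0, 2)], 3)
        r = ns.degree_preserving_rewire(a, rng_seed=5)
        assert (a != r).nnz == 0

    def test_single_edge_unchanged(self):
        a = adjacency([(0, 1)], 4)
        r = ns.degree_preserving_rewire(a, rng_seed=5)
        assert (a != r).nnz == 0

    def test_four_cycle_reaches_both_configurations(self):
        """The labeled 2-regular graphs on {0,1,2,3} containing a perfect
        matching pair swap: a 4-cycle can only be rewired into one of the
        three labeled 4-cycles."""
        cycle = adjacency([(0, 1), (1, 2), (2, 3), (0, 3)], 4)
        valid = set()
        for perm in [[(0, 1), (1, 2), (2, 3), (0, 3)],
                     [(0, 2), (2, 1), (1, 3), (0, 3)],
                     [(0, 1), (1, 3), (3, 2), (0, 2)]]:
            valid.add(frozenset(tuple(sorted(e)) for e in perm))
        seen = set()
        for seed in range(10):
            r = ns.degree_preserving_rewire(cycle, rng_seed=seed)
            e = _edges_from_adjacency(r)
            seen.add(frozenset(map(tuple, e)))
            # reproducibility
            r2 = ns.degree_preserving_rewire(cycle, rng_seed=seed)
            assert (r != r2).nnz == 0
        assert seen <= valid
        assert len(seen) >= 2


def _ranked_from(net, sp_values):
    """SmoothingResult stub with prescribed Sp values (already ranked)."""
    table = pd.DataFrame({
        "gene": net.nodes, "x0": 0.0, "x_star": 0.0,
        "S": sp_values, "pS": 0.5, "Sp": sp_values,
        "is_input": [v > 0 for v in sp_values],
        "source_lists": [""] * net.n,
    })
    return SmoothingResult(table=ns.rank_genes(table), epsilon=1.0, K=9,
                           alpha=0.7, rng_seed=0)


class TestProfile:
    def test_constant_sp_never_significant(self):
        """Omega depends only on the edge count when scores are constant,
        and rewiring preserves the edge count."""
        net = random_network(30, 0.15, 7)
        ranked = _ranked_from(net, np.ones(net.n))
        prof = ns.nr_profile(ranked, net, m_grid=[10, 20, 30], q=99,
                             rng_seed=1)
        assert (prof.p_nr == 1.0).all()

    def test_p_bounds_and_omega_monotone(self, small_scenario):
        net = small_scenario.network
        rng = np.random.default_rng(0)
        ranked = _ranked_from(net, np.sort(rng.random(net.n))[::-1])
        prof = ns.nr_profile(ranked, net, m_grid=[20, 40, 60], q=49,
                             rng_seed=2)
        assert (prof.p_nr >= 1 / 50).all() and (prof.p_nr <= 1).all()
        assert (np.diff(prof.omega) >= -1e-12).all()

    def test_planted_module_significant_near_true_size(self, small_scenario):
        net = small_scenario.network
        sv = ns.build_seed_vector(
            {n: small_scenario.lists[n] for n in small_scenario.lists}, None, net)
        scores = ns.score_genes(net, sv, K=99, rng_seed=3, epsilon=1.0)
        prof = ns.nr_profile(scores, net,
                             m_grid=[20, 30, 40, 50, 60], q=99, rng_seed=4)
        near = prof.p_nr[np.abs(prof.m_grid - 45) <= 15]
        assert (near <= 0.05).any()

    def test_exact_null_oracle_tiny_graph(self):
        """p_nr agrees with exhaustive enumeration of all simple graphs
        sharing the degree sequence of a 5-node, 4-edge graph."""
        edges = [(0, 1), (1, 2), (2, 3), (3, 4)]
        n = 5
        genes = [f"g{i}" for i in range(n)]
        net = ns.network_from_edges([(genes[u], genes[v], 900)
                                     for u, v in edges])
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        # lexicographic gene order matches index order here
        deg = np.asarray(net.A.sum(axis=1)).ravel()
        obs = ns.omega(scores, net.A)
        exceed = total = 0
        for combo in itertools.combinations(
                itertools.combinations(range(n), 2), len(edges)):
            a = adjacency(combo, n)
            if not np.array_equal(np.asarray(a.sum(axis=1)).ravel(), deg):
                continue
            total += 1
            if ns.omega(scores, a) >= obs - 1e-12:
                exceed += 1
        exact_p = exceed / total
        ranked = _ranked_from(net, scores)
        prof = ns.nr_profile(ranked, net, m_grid=[n], q=999, rng_seed=0,
                             pseudocount=False)
        assert prof.p_nr[0] == pytest.approx(exact_p, abs=0.1)


class TestExtractModule:
    def _profile(self, m_grid, p_nr, p_inc=None):
        m_grid = np.asarray(m_grid)
        return NRProfile(m_grid=m_grid, omega=np.arange(len(m_grid), dtype=float),
                         p_nr=np.asarray(p_nr), q=200, swaps_per_edge=10,
                         rng_seed=0,
                         p_inc=None if p_inc is None else np.asarray(p_inc))

    def test_no_significant_m_gives_empty_module(self, small_scenario):
        net = small_scenario.network
        ranked = _ranked_from(net, np.linspace(1, 0, net.n))
        prof = self._profile([10, 20, 30], [0.5, 0.3, 0.4])
        mod = ns.extract_module(prof, ranked, net)
        assert mod.is_empty
        assert "no significantly connected" in mod.status

    def test_sustained_prefix_rule_without_increments(self, small_scenario):
        net = small_scenario.network
        ranked = _ranked_from(net, np.linspace(1, 0, net.n))
        grid = [50, 75, 100, 125, 150, 175, 200, 225, 250, 275]
        p = [0.5, 0.5, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.2]
        mod = ns.extract_module(self._profile(grid, p), ranked, net)
        assert mod.m_star == 250

    def test_increment_rule_stops_at_chance_additions(self, small_scenario):
        net = small_scenario.network
        ranked = _ranked_from(net, np.linspace(1, 0, net.n))
        grid = [50, 75, 100, 125, 150]
        p = [0.01, 0.01, 0.01, 0.01, 0.01]
        p_inc = [0.01, 0.01, 0.01, 0.8, 0.01]
        mod = ns.extract_module(self._profile(grid, p, p_inc), ranked, net)
        assert mod.m_star == 100

    def test_module_accounting(self, small_scenario):
        net = small_scenario.network
        sv = ns.build_seed_vector(
            {n: g for n, g in small_scenario.lists.items()}, None, net)
        scores = ns.score_genes(net, sv, K=99, rng_seed=3, epsilon=1.0)
        prof = ns.nr_profile(scores, net, m_grid=[20, 30, 40, 50, 60], q=99,
                             rng_seed=4)
        mod = ns.extract_module(prof, scores, net)
        if not mod.is_empty:
            assert mod.genes == scores.table["gene"].head(mod.m_star).tolist()
            assert sum(mod.membership_breakdown.values()) == mod.m_star
            assert sum(len(c) for c in mod.components) == mod.m_star


def test_default_m_grid_spacing():
    grid = default_m_grid(50, 1000)
    assert grid[0] == 10
    assert (np.diff(grid[grid <= 100]) == 10).all()
    assert (np.diff(grid[grid > 100]) == 25).all()
    assert grid.max() <= 250
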