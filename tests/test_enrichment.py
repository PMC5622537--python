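import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nsiasd as ns
from nsiasd.enrichment import PathwayDB, read_gmt


def brute_tail(k, K_p, n_q, N_b):
    """Exact upper tail by direct summation of hypergeometric masses."""
    total = math.comb(N_b, n_q)
    acc = 0
    for x in range(k, min(K_p, n_q) + 1):
        acc += math.comb(K_p, x) * math.comb(N_b - K_p, n_q - x)
    return acc / total


class TestHypergeomTail:
    def test_at_zero_is_one(self):
        assert ns.hypergeom_tail(0, 5, 4, 20) == 1.0

    def test_exact_small_example(self):
        # C(20,4) enumeration gives 155/4845
        assert ns.hypergeom_tail(3, 5, 4, 20) == pytest.approx(155 / 4845,
                                                               rel=1e-12)

    def test_published_annotation_row(self):
        p = ns.hypergeom_tail(2, 216, 10, 11381)
        assert p == pytest.approx(1.46e-2, rel=5e-3)

    def test_infeasible_counts_raise(self):
        with pytest.raises(ValueError):
            ns.hypergeom_tail(6, 5, 4, 20)
        with pytest.raises(ValueError):
            ns.hypergeom_tail(1, 30, 4, 20)

    @given(st.integers(2, 25), st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, N_b, data):
        K_p = data.draw(st.integers(0, N_b))
        n_q = data.draw(st.integers(0, N_b))
        k = data.draw(st.integers(0, min(K_p, n_q)))
        assert ns.hypergeom_tail(k, K_p, n_q, N_b) == pytest.approx(
            brute_tail(k, K_p, n_q, N_b), rel=1e-9, abs=1e-12)


class TestModuleOverlap:
    def _background(self, n):
        return {f"g{i:05d}" for i in range(n)}

    def test_published_expected_and_p(self):
        bg = self._background(11381)
        ann = set(list(bg)[:216])
        module = set(list(ann)[:2]) | set(list(bg - ann)[:8])
        res = ns.module_overlap_test(module, ann, bg)
        assert res.expected == pytest.approx(0.190, abs=5e-4)
        assert res.p == pytest.approx(1.46e-2, rel=5e-3)
        assert res.module_size + res.complement_size == 11381

    def test_module_equals_annotation_is_extreme(self):
        bg = self._background(100)
        ann = set(list(bg)[:10])
        res = ns.module_overlap_test(ann, ann, bg)
        assert res.observed == 10
        assert res.p == pytest.approx(brute_tail(10, 10, 10, 100), rel=1e-9)

    def test_disjoint_annotation_raises(self):
        with pytest.raises(ValueError):
            ns.module_overlap_test({"a"}, {"x"}, {"a", "b"})


class TestInteractionExcess:
    def test_no_risk_neighbors_p_one(self, star_net):
        res = ns.interaction_excess_test("l1", star_net, {"l2"})
        assert res.observed == 0 or res.p == 1.0

    def test_toy_against_brute_force(self):
        # gene with 10 interactors, 6 of them risk genes, background 100
        genes = [f"g{i:03d}" for i in range(101)]
        hub = "hub"
        edges = [(hub, g, 900) for g in genes[:10]]
        edges += [(genes[i], genes[i + 10], 900) for i in range(80)]
        net = ns.network_from_edges(edges)
        risk = set(genes[:6]) | set(genes[50:64])  # 20 risk genes
        res = ns.interaction_excess_test(hub, net, risk,
                                         background_size=100)
        assert res.observed == 6
        assert res.p == pytest.approx(brute_tail(6, 20, 10, 100), rel=1e-9)


class TestBH:
    def test_all_equal_stay_equal(self):
        adj = ns.bh_adjust([0.04, 0.04, 0.04])
        assert np.allclose(adj, 0.04)

    def test_step_up_example(self):
        adj = ns.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert ns.bh_adjust([0.2])[0] == pytest.approx(0.2)

    @staticmethod
    def step_up_oracle(pvals):
        """Direct implementation of the step-up formula:
        adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
        p = np.asarray(pvals, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        scaled = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1)
        out = np.empty(m)
        out[order] = adj_sorted
        return out

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_oracle_and_never_decreases(self, pvals):
        adj = ns.bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        assert np.allclose(adj, self.step_up_oracle(pvals))


class TestOverlapCoefficient:
    def test_subset_is_one(self):
        assert ns.overlap_coefficient({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_disjoint_is_zero(self):
        assert ns.overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_arithmetic(self):
        a = {"g1", "g2", "g3", "g4"}
        b = {"g1", "g2"} | {f"x{i}" for i in range(8)}
        assert ns.overlap_coefficient(a, b) == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ns.overlap_coefficient(set(), {"a"})


class TestGmtAndOra:
    def test_gmt_round_trip_and_size_filter(self, tmp_path):
        db = PathwayDB({"small": set("ab"),
                        "ok": {f"g{i}" for i in range(15)}},
                       size_filter=(10, 200))
        assert "small" not in db.pathways and len(db) == 1
        out = tmp_path / "p.gmt"
        db.write_gmt(out)
        back = read_gmt(out)
        assert back.pathways == db.pathways

    def test_ora_columns_and_adjustment(self, small_scenario):
        net = small_scenario.network
        res = ns.ora(small_scenario.planted, small_scenario.pathways,
                     set(net.nodes))
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert res["p"].is_monotonic_increasing
        assert (res["overlap"] <= res[["size", "n_query"]].min(axis=1)).all()

    def test_ora_enriched_pathways_rank_first(self, small_scenario):
        res = ns.ora(small_scenario.planted, small_scenario.pathways,
                     set(small_scenario.network.nodes))
        top = set(res.head(len(small_scenario.enriched_pathways))["pathway"])
        assert top == small_scenario.enriched_pathways


class TestEnrichmentMap:
    def _results(self, pvals):
        import pandas as pd
        return pd.DataFrame({"pathway": list(pvals), "p": 1e-6,
                             "p_adj": list(pvals.values())})

    def _db(self, sets):
        return PathwayDB(dict(sets), size_filter=(1, 10**6))

    def test_below_threshold_no_edge(self):
        sets = {"p1": {f"g{i}" for i in range(10)},
                "p2": {f"g{i}" for i in range(6, 16)}}  # o = 0.4
        emap = ns.build_enrichment_map(self._results({"p1": 1e-4, "p2": 1e-4}),
                                       self._db(sets))
        assert len(emap.edges) == 0 and len(emap.nodes) == 2

    def test_single_pathway_map(self):
        sets = {"p1": {"a", "b", "c"}}
        emap = ns.build_enrichment_map(self._results({"p1": 1e-3}),
                                       self._db(sets))
        assert len(emap.nodes) == 1 and len(emap.edges) == 0
        assert emap.nodes["neg_log10_padj"].iloc[0] == pytest.approx(3.0)

    def test_top_k_caps_edges(self):
        base = {f"g{i}" for i in range(9)}
        sets = {"p1": base | {"x1"}, "p2": base | {"x2"}, "p3": base | {"x3"}}
        emap = ns.build_enrichment_map(
            self._results({"p1": 1e-4, "p2": 1e-4, "p3": 1e-4}),
            self._db(sets), top_k=1)
        assert len(emap.edges) <= 3
        # every node keeps at least its single best link
        touched = set(emap.edges["pathway_a"]) | set(emap.edges["pathway_b"])
        assert touched == {"p1", "p2", "p3"}

    def test_no_significant_pathways_empty_map(self):
        emap = ns.build_enrichment_map(self._results({"p1": 0.5}),
                                       self._db({"p1": {"a"}}))
        assert emap.nodes.empty and emap.edges.empty

    def test_edge_set_invariant_to_input_order(self):
        base = {f"g{i}" for i in range(9)}
        sets = {"p1": base | {"x1"}, "p2": base | {"x2"}, "p3": base | {"x3"}}
        pv = {"p1": 1e-4, "p2": 1e-5, "p3": 1e-3}
        e1 = ns.build_enrichment_map(self._results(pv), self._db(sets))
        rev = dict(reversed(list(pv.items())))
        e2 = ns.build_enrichment_map(self._results(rev), self._db(sets))
        assert e1.edges.equals(e2.edges)
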