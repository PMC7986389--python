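"""Exact ILP solvers: worked examples, oracle equivalence, pipeline."""

import pytest

from fvsnet import (
    WeightedDigraph,
    WeightTable,
    full_pipeline,
    penalty_transform,
    solve_mfvs_size,
    solve_wfvs_penalty,
    solve_wfvs_shift,
    solve_wmfvs,
    verify_fvs,
)
from fvsnet.fvs_ilp import DEFAULT_PENALTY_CAP, InfeasibleSizeError, PenaltyTable
from fvsnet.synthetic import (
    SyntheticSpec,
    brute_force_all_mfvs,
    brute_force_wfvs,
    random_digraph,
)


class TestMfvsSize:
    def test_triangle(self, triangle):
        size, sol = solve_mfvs_size(triangle)
        assert size == 1 and sol.verified and len(sol.members) == 1

    def test_two_disjoint_cycles(self, two_triangles):
        size, sol = solve_mfvs_size(two_triangles)
        assert size == 2
        assert sol.members & {"a", "b", "c"} and sol.members & {"x", "y", "z"}

    def test_dag_is_zero(self, dag):
        size, sol = solve_mfvs_size(dag)
        assert size == 0 and sol.members == frozenset()

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(20):
            g = random_digraph(SyntheticSpec(
                n_vertices=9, arc_probability=0.1 + 0.02 * (seed % 5), seed=seed))
            assert solve_mfvs_size(g)[0] == brute_force_all_mfvs(g)[0]


class TestWmfvs:
    def test_triangle_picks_heaviest(self, triangle):
        sol = solve_wmfvs(triangle, 1)
        assert sol.members == {"c"} and sol.total_weight == 3.0
        assert sol.objective_value == sol.total_weight

    def test_equal_weights_degenerate_tie(self, two_triangles):
        g = two_triangles.with_weights({v: 2.0 for v in two_triangles.vertices})
        sol = solve_wmfvs(g, 2)
        assert sol.total_weight == 4.0  # s * w whatever the members

    def test_size_below_minimum_infeasible(self, two_triangles):
        with pytest.raises(InfeasibleSizeError):
            solve_wmfvs(two_triangles, 1)

    def test_monotone_in_member_weight(self, triangle):
        base = solve_wmfvs(triangle, 1).objective_value
        g2 = triangle.with_weights({"a": 1, "b": 2, "c": 9})
        assert solve_wmfvs(g2, 1).objective_value >= base


class TestPenaltyTransform:
    @pytest.mark.parametrize(
        "w, expected",
        [
            (2.0, 0.5),                      # plain reciprocal
            (0.0, DEFAULT_PENALTY_CAP),      # zero weight -> cap
            (1e-5, DEFAULT_PENALTY_CAP),     # below 1/l -> cap
            (-1.0, DEFAULT_PENALTY_CAP),     # negative -> cap (warned)
            (1.0 / DEFAULT_PENALTY_CAP, DEFAULT_PENALTY_CAP),  # boundary: 1/w = l
        ],
    )
    def test_branches(self, w, expected):
        p = penalty_transform(WeightTable(entries={"v": w}))
        assert p.entries["v"] == pytest.approx(expected)

    def test_penalties_validated_positive(self):
        with pytest.raises(ValueError):
            PenaltyTable(entries={"v": 0.0})
        with pytest.raises(ValueError):
            PenaltyTable(entries={"v": 1e9})


class TestWfvsPenalty:
    def test_triangle_minimum_penalty(self, triangle):
        p = penalty_transform(WeightTable(entries=triangle.weights))
        sol = solve_wfvs_penalty(triangle, p)
        assert sol.members == {"c"}
        assert sol.objective_value == pytest.approx(1 / 3)
        assert sol.total_weight == 3.0

    def test_dag_empty(self, dag):
        p = penalty_transform(WeightTable(entries=dag.weights))
        sol = solve_wfvs_penalty(dag, p)
        assert sol.members == frozenset() and sol.objective_value == 0.0

    def test_missing_penalty_raises(self, triangle):
        with pytest.raises(KeyError):
            solve_wfvs_penalty(triangle, PenaltyTable(entries={"a": 1.0}))


class TestWfvsShift:
    def test_negative_weights_prefer_two_light_vertices(self, shared_hub):
        # breaking both 2-cycles at the light endpoints (-4 total) beats
        # the single heavy hub (-20)
        sol = solve_wfvs_shift(shared_hub)
        assert sol.members == {"a", "c"} and sol.total_weight == -4.0

    def test_positive_weights_shifted_to_single_heaviest(self, triangle):
        sol = solve_wfvs_shift(triangle, epsilon=1e-3)
        assert sol.members == {"c"} and sol.total_weight == 3.0

    def test_dag_empty(self, dag):
        assert solve_wfvs_shift(dag).members == frozenset()

    def test_epsilon_validated(self, triangle):
        with pytest.raises(ValueError):
            solve_wfvs_shift(triangle, epsilon=0.0)


class TestVerifyFvs:
    def test_examples(self, triangle, two_triangles):
        assert verify_fvs(triangle, {"a"})
        assert not verify_fvs(triangle, set())
        assert verify_fvs(two_triangles, {"a", "x"})

    def test_rejects_foreign_vertices(self, triangle):
        with pytest.raises(ValueError):
            verify_fvs(triangle, {"zz"})

    def test_ordering_constraints_satisfiable_by_any_fvs(self):
        """Feasibility self-test: for any FVS, x = its indicator and k = a
        topological order of the residual DAG satisfy every arc constraint."""
        import networkx as nx

        for seed in range(8):
            g = random_digraph(SyntheticSpec(n_vertices=8, arc_probability=0.2, seed=seed))
            _, cat = brute_force_all_mfvs(g)
            fvs = cat[0]
            residual = g.without(fvs)
            topo = list(nx.topological_sort(residual.copy_nx()))
            n = g.n_vertices
            # k decreases along residual arcs; removed vertices sit at 0,
            # residual vertices at 1..|residual| (<= n-1 when the FVS is
            # non-empty), so every arc constraint holds
            base = 0 if not fvs else 1
            k = {v: 0 for v in fvs}
            for i, v in enumerate(topo):
                k[v] = base + len(topo) - 1 - i
            x = {v: int(v in fvs) for v in g.vertices}
            assert all(0 <= kv <= n - 1 for kv in k.values())
            for u, v in g.arcs:
                assert k[u] - k[v] + n * x[u] >= 1


class TestFullPipeline:
    def test_dag_all_methods_empty(self, dag):
        w = WeightTable(entries={v: 1.0 for v in dag.vertices})
        for method in ("MFVS", "WMFVS", "WFVS"):
            sol = full_pipeline(dag, w, method)
            assert sol.members == frozenset() and sol.verified

    def test_wmfvs_pipeline_matches_oracle(self):
        for seed in range(12):
            g = random_digraph(SyntheticSpec(
                n_vertices=10, arc_probability=0.15,
                weight_distribution=("uniform", 0.2, 3.0), seed=seed))
            w = WeightTable(entries=g.weights)
            sol = full_pipeline(g, w, "WMFVS")
            _, cat = brute_force_all_mfvs(g)
            best = max(sum(g.weight(v) for v in c) for c in cat)
            assert sol.verified
            assert sol.size == brute_force_all_mfvs(g)[0]
            assert sol.total_weight == pytest.approx(best)

    def test_wfvs_pipeline_matches_penalty_oracle(self):
        for seed in range(8):
            g = random_digraph(SyntheticSpec(
                n_vertices=9, arc_probability=0.18,
                weight_distribution=("uniform", 0.2, 3.0), seed=seed))
            w = WeightTable(entries=g.weights)
            sol = full_pipeline(g, w, "WFVS")
            pen = penalty_transform(w).entries
            _, bf_val = brute_force_wfvs(g, "min_penalty", penalties=pen)
            assert sol.verified
            assert sol.objective_value == pytest.approx(bf_val)

    def test_wfvs_at_least_as_large_as_mfvs(self):
        """Dropping the size constraint can only grow (or keep) the set; with
        positive weights the penalty solution's weight is non-negative."""
        for seed in range(8):
            g = random_digraph(SyntheticSpec(
                n_vertices=9, arc_probability=0.15,
                weight_distribution=("uniform", 0.2, 3.0), seed=seed))
            w = WeightTable(entries=g.weights)
            mfvs = full_pipeline(g, w, "MFVS")
            wfvs = full_pipeline(g, w, "WFVS")
            assert wfvs.size >= mfvs.size
            assert wfvs.total_weight >= 0

    def test_forced_self_loops_in_every_method(self):
        g = WeightedDigraph(
            arcs=[("s", "s"), ("a", "b"), ("b", "a")],
            weights={"s": 0.01, "a": 5.0, "b": 4.0},
        )
        w = WeightTable(entries=g.weights)
        for method in ("MFVS", "WMFVS", "WFVS"):
            sol = full_pipeline(g, w, method)
            assert "s" in sol.members, method
            assert "s" in sol.forced

    def test_wmfvs_with_zero_weights_falls_back_safely(self, triangle):
        # zero weights void the weighted-bypass hypothesis; the pipeline
        # must still return a verified maximum-weight MFVS
        w = WeightTable(entries={"a": 0.0, "b": 2.0, "c": 3.0})
        sol = full_pipeline(triangle, w, "WMFVS")
        assert sol.verified and sol.size == 1 and sol.total_weight == 3.0
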