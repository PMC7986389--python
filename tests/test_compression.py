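"""Reduction rules: correctness of each rule and preservation guarantees."""

import pytest

from fvsnet import (
    WeightedDigraph,
    compress,
    compress_scc,
    ignore,
    ignore_w,
    is_acyclic,
    lift_solution,
    rule_c1,
    rule_c2,
    verify_fvs,
)
from fvsnet.synthetic import (
    SyntheticSpec,
    brute_force_all_mfvs,
    random_digraph,
)


class TestRuleC1:
    def test_self_loop_forced(self):
        g = WeightedDigraph(arcs=[("a", "a"), ("a", "b"), ("b", "a")])
        g2, forced = rule_c1(g, "a")
        assert forced == "a"
        assert g2.vertices == {"b"} and g2.n_arcs == 0

    def test_traced_on_four_arc_instance(self):
        # a->b, b->c, c->a, b->b: forcing b leaves only c->a among {a, c}
        g = WeightedDigraph(arcs=[("a", "b"), ("b", "c"), ("c", "a"), ("b", "b")])
        g2, forced = rule_c1(g, "b")
        assert forced == "b"
        assert g2.vertices == {"a", "c"}
        assert g2.arcs == {("c", "a")}

    def test_two_self_loops_both_forced(self):
        g = WeightedDigraph(arcs=[("a", "a"), ("b", "b"), ("a", "b")])
        g2, f1 = rule_c1(g, "a")
        g3, f2 = rule_c1(g2, "b")
        assert {f1, f2} == {"a", "b"} and g3.n_vertices == 0

    def test_requires_self_loop(self, triangle):
        with pytest.raises(ValueError):
            rule_c1(triangle, "a")


class TestRuleC2:
    def test_path_fully_drains(self):
        g = WeightedDigraph(arcs=[("a", "b"), ("b", "c")])
        for v in ["c", "b", "a"]:  # sink, then newly exposed sinks
            g = rule_c2(g, v)
        assert g.n_vertices == 0

    def test_not_applicable_on_cycle(self, triangle):
        with pytest.raises(ValueError):
            rule_c2(triangle, "a")

    def test_star_leaves_removable(self):
        g = WeightedDigraph(arcs=[("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        for v in ["l1", "l2", "l3"]:
            g = rule_c2(g, v)
        assert g.vertices == {"hub"}


class TestIgnore:
    def test_triangle_bypass_preserves_mfvs_size(self, triangle):
        g2 = ignore(triangle, "a")  # |a.suc| = 1
        assert g2.vertices == {"b", "c"}
        assert g2.arcs == {("c", "b"), ("b", "c")}
        assert brute_force_all_mfvs(g2)[0] == brute_force_all_mfvs(triangle)[0] == 1

    def test_two_cycle_collapses_to_self_loop(self):
        g = WeightedDigraph(arcs=[("a", "b"), ("b", "a")])
        g2 = ignore(g, "a")
        assert g2.arcs == {("b", "b")}

    def test_rejects_self_loop_vertex(self):
        g = WeightedDigraph(arcs=[("a", "a"), ("a", "b"), ("b", "a")])
        with pytest.raises(ValueError):
            ignore(g, "a")

    def test_preserves_cycle_vertices_other_than_target(self):
        for seed in range(8):
            g = random_digraph(SyntheticSpec(n_vertices=8, arc_probability=0.15, seed=seed))
            candidates = [
                v for v in g.sorted_vertices()
                if not g.has_self_loop(v)
                and (len(g.successors(v)) == 1 or len(g.predecessors(v)) == 1)
            ]
            if not candidates:
                continue
            v = candidates[0]
            g2 = ignore(g, v)
            assert g2.n_vertices == g.n_vertices - 1

            def on_cycle(graph):
                from fvsnet import scc_partition
                out = set()
                for block in scc_partition(graph):
                    if len(block) > 1:
                        out |= set(block)
                    else:
                        (u,) = block
                        if graph.has_self_loop(u):
                            out.add(u)
                return out

            assert on_cycle(g2) == on_cycle(g) - {v}


class TestIgnoreW:
    def test_lighter_than_sole_successor_applicable(self, triangle):
        # a(1) -> b(5): bypassing a must keep the max-weight MFVS {b}
        g = triangle.with_weights({"a": 1, "b": 5, "c": 1})
        g2 = ignore_w(g, "a")
        size, cat = brute_force_all_mfvs(g2)
        best = max(sum(g2.weight(v) for v in c) for c in cat)
        assert size == 1 and best == 5.0

    def test_heavier_vertex_not_applicable(self, triangle):
        g = triangle.with_weights({"a": 1, "b": 5, "c": 1})
        with pytest.raises(ValueError):
            ignore_w(g, "b")  # 5 < 1 fails both ways

    def test_equal_weights_not_compressed(self, triangle):
        g = triangle.with_weights({"a": 2, "b": 2, "c": 2})
        with pytest.raises(ValueError):
            ignore_w(g, "a")  # strict inequality required

    def test_requires_positive_weights(self, triangle):
        g = triangle.with_weights({"a": 0, "b": 5, "c": 1})
        with pytest.raises(ValueError, match="positive"):
            ignore_w(g, "a")


class TestCompressScc:
    def test_inter_component_arc_removed(self):
        g = WeightedDigraph(arcs=[("a", "b"), ("b", "a"), ("b", "c")])
        assert compress_scc(g).arcs == {("a", "b"), ("b", "a")}

    def test_dag_loses_all_arcs(self, dag):
        g2 = compress_scc(dag)
        assert g2.n_arcs == 0 and g2.vertices == dag.vertices

    def test_single_cycle_unchanged(self, triangle):
        assert compress_scc(triangle).arcs == triangle.arcs


class TestCompress:
    def test_dag_compresses_to_empty(self, dag):
        tr = compress(dag, "unweighted")
        assert tr.compressed.n_vertices == 0 and tr.delta_m == set()

    def test_self_loop_plus_tail(self):
        g = WeightedDigraph(arcs=[("a", "a"), ("a", "b"), ("b", "c")])
        tr = compress(g, "unweighted")
        assert tr.delta_m == {"a"} and tr.compressed.n_vertices == 0

    def test_triangle_fully_resolves_to_one_forced_vertex(self, triangle):
        tr = compress(triangle, "unweighted")
        assert tr.compressed.n_vertices == 0
        assert len(tr.delta_m) == 1  # |dM| + 0 = brute-force MFVS size
        assert brute_force_all_mfvs(triangle)[0] == 1

    def test_weighted_mode_rejects_nonpositive(self, triangle):
        g = triangle.with_weights({"a": 1, "b": 0, "c": 1})
        with pytest.raises(ValueError, match="'b'"):
            compress(g, "weighted")

    def test_idempotent(self):
        for seed in range(10):
            g = random_digraph(SyntheticSpec(n_vertices=10, arc_probability=0.15, seed=seed))
            tr = compress(g, "unweighted")
            tr2 = compress(tr.compressed, "unweighted")
            assert tr2.compressed.vertices == tr.compressed.vertices
            assert tr2.compressed.arcs == tr.compressed.arcs
            assert tr2.delta_m == set()

    def test_safe_mode_preserves_all_fvs(self):
        """Safe mode (C1+C2+scc) removes no vertex that lies on a cycle
        except forced self-loops, so every FVS of the original survives."""
        for seed in range(6):
            g = random_digraph(SyntheticSpec(n_vertices=9, arc_probability=0.2, seed=seed))
            tr = compress(g, "safe")
            size, cat = brute_force_all_mfvs(g)
            for sol in cat:
                assert tr.delta_m <= sol
                assert sol - tr.delta_m <= tr.compressed.vertices

    def test_size_preservation_random_corpus(self):
        for seed in range(25):
            g = random_digraph(SyntheticSpec(
                n_vertices=6 + seed % 6,
                arc_probability=0.1 + 0.03 * (seed % 4),
                n_planted_cycles=1 + seed % 2,
                seed=seed,
            ))
            s_orig, _ = brute_force_all_mfvs(g)
            tr = compress(g, "unweighted")
            s_comp = (
                brute_force_all_mfvs(tr.compressed)[0]
                if tr.compressed.n_vertices else 0
            )
            assert len(tr.delta_m) + s_comp == s_orig

    def test_weight_preservation_theorem(self):
        """With strictly positive weights, weighted compression preserves
        the maximum MFVS weight (exchange-argument soundness)."""
        for seed in range(25):
            g = random_digraph(SyntheticSpec(
                n_vertices=5 + seed % 5,
                arc_probability=0.12 + 0.03 * (seed % 3),
                weight_distribution=("uniform", 0.1, 4.0),
                seed=seed,
            ))
            _, cat = brute_force_all_mfvs(g)
            best = max(sum(g.weight(v) for v in c) for c in cat)
            tr = compress(g, "weighted")
            if tr.compressed.n_vertices:
                _, cat2 = brute_force_all_mfvs(tr.compressed)
                sub_best = max(sum(tr.compressed.weight(v) for v in c) for c in cat2)
            else:
                sub_best = 0.0
            forced_w = sum(g.weight(v) for v in tr.delta_m)
            assert abs(sub_best + forced_w - best) < 1e-9


class TestLiftSolution:
    def test_union_with_delta_m(self, triangle):
        tr = compress(triangle, "unweighted")
        assert lift_solution(tr, set()) == tr.delta_m

    def test_rejects_stray_vertices(self, triangle):
        tr = compress(triangle, "unweighted")
        with pytest.raises(ValueError):
            lift_solution(tr, {"not-there"})

    def test_lifted_set_is_fvs_of_original(self):
        for seed in range(15):
            g = random_digraph(SyntheticSpec(n_vertices=9, arc_probability=0.18, seed=seed))
            tr = compress(g, "unweighted")
            if tr.compressed.n_vertices:
                _, cat = brute_force_all_mfvs(tr.compressed)
                sol = cat[0]
            else:
                sol = frozenset()
            lifted = lift_solution(tr, set(sol))
            assert verify_fvs(g, lifted)
            assert is_acyclic(g.without(lifted))
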