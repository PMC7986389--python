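"""Size- and weight-preserving reduction of directed graphs.

Finding a minimum feedback vertex set (MFVS) is NP-hard, so before handing a
graph to the exact ILP solver we shrink it with reduction rules that provably
preserve the quantity being optimised:

C1 (self-loop)
    A vertex with a self-loop belongs to *every* FVS; it is recorded in the
    forced set ΔM and removed.
C2 (source/sink)
    A vertex with no successors or no predecessors lies on no cycle and can
    be removed outright.
C3 (bypass, ``ignore``)
    A vertex v with a single successor (or single predecessor) can be
    bypassed: every cycle through v also passes through that neighbour, so
    breaking the cycle at the neighbour is at least as good.  All
    predecessors of v are wired to all successors, then v is removed.  This
    preserves the MFVS *size* but may discard some individual MFVSs.
C3w (weighted bypass, ``ignore_w``)
    For the maximum-weight MFVS the bypass is only sound when, additionally,
    v's weight is strictly below its sole neighbour's (all weights positive):
    the exchange argument then shows v is in no maximum-weight MFVS.
SCC pruning
    Arcs between distinct strongly connected components lie on no cycle and
    are deleted.

``compress`` sweeps these rules to a fixed point.  The result is a
:class:`CompressionTrace` carrying the compressed graph, the forced set ΔM,
and a step log; ``lift_solution`` unions ΔM back into any solution of the
compressed graph to obtain a solution of the original graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx

from .graph_core import WeightedDigraph

__all__ = [
    "CompressionTrace",
    "rule_c1",
    "rule_c2",
    "ignore",
    "ignore_w",
    "compress_scc",
    "compress",
    "lift_solution",
    "Mode",
]

#: Compression modes.  "unweighted" uses the plain bypass (preserves MFVS
#: size); "weighted" uses the weight-restricted bypass (additionally
#: preserves the maximum-weight MFVS; requires strictly positive weights);
#: "safe" applies only C1, C2 and SCC pruning, which preserve the full set
#: of feedback vertex sets of any size — the right mode when optimising
#: weight without a size constraint.
Mode = Literal["unweighted", "weighted", "safe"]


@dataclass
class CompressionTrace:
    """Outcome of compressing a graph to a fixed point."""

    compressed: WeightedDigraph
    delta_m: set[str]
    steps: list[tuple[str, str]]
    mode: Mode
    original_vertices: frozenset[str]

    @property
    def removed(self) -> set[str]:
        return set(self.original_vertices) - set(self.compressed.vertices)


# ---------------------------------------------------------------------------
# Single-rule operations (pure: return new graphs)
# ---------------------------------------------------------------------------

def rule_c1(g: WeightedDigraph, v: str) -> tuple[WeightedDigraph, str]:
    """Remove self-loop vertex ``v``; it is forced into every FVS."""
    if not g.has_self_loop(v):
        raise ValueError(f"rule C1 requires a self-loop at {v!r}")
    return g.without([v]), v


def rule_c2(g: WeightedDigraph, v: str) -> WeightedDigraph:
    """Remove ``v``, which lies on no cycle (no successors or no predecessors)."""
    if v not in g:
        raise KeyError(f"vertex {v!r} not in graph")
    if g.successors(v) and g.predecessors(v):
        raise ValueError(
            f"rule C2 requires {v!r} to have no successors or no predecessors"
        )
    return g.without([v])


def _ignore_nx(g: nx.DiGraph, v: str) -> None:
    """In-place bypass on a networkx graph: pre(v) × suc(v) arcs, then drop v."""
    preds = [p for p in g.predecessors(v) if p != v]
    sucs = [s for s in g.successors(v) if s != v]
    g.remove_node(v)
    g.add_edges_from((p, s) for p in preds for s in sucs)


def _ignore_applicable(g: nx.DiGraph, v: str) -> bool:
    if g.has_edge(v, v):
        return False
    return g.out_degree(v) == 1 or g.in_degree(v) == 1


def _ignore_w_applicable(g: nx.DiGraph, v: str) -> bool:
    if g.has_edge(v, v):
        return False
    w = g.nodes[v]["weight"]
    if g.in_degree(v) == 1:
        (p,) = g.predecessors(v)
        if w < g.nodes[p]["weight"]:
            return True
    if g.out_degree(v) == 1:
        (s,) = g.successors(v)
        if w < g.nodes[s]["weight"]:
            return True
    return False


def ignore(g: WeightedDigraph, v: str) -> WeightedDigraph:
    """Bypass ``v`` (single successor or single predecessor, no self-loop).

    Every predecessor is connected to every successor — duplicates merge, and
    a predecessor that is also a successor gains a self-loop, to be picked up
    by C1 — then ``v`` is removed.  MFVS size is preserved.
    """
    h = g.copy_nx()
    if v not in h:
        raise KeyError(f"vertex {v!r} not in graph")
    if not _ignore_applicable(h, v):
        raise ValueError(
            f"ignore requires {v!r} to have exactly one successor or one "
            "predecessor and no self-loop"
        )
    _ignore_nx(h, v)
    return WeightedDigraph._wrap(h)


def ignore_w(g: WeightedDigraph, v: str) -> WeightedDigraph:
    """Weight-restricted bypass: sound for the maximum-weight MFVS.

    Requires all weights strictly positive and ``v``'s weight strictly below
    its sole predecessor's or sole successor's.  The exchange argument (swap
    v for its heavier forced neighbour) shows the removed vertex is in no
    maximum-weight MFVS, so compression with this rule preserves the optimum.
    """
    nonpos = [u for u in g.sorted_vertices() if g.weight(u) <= 0]
    if nonpos:
        raise ValueError(
            f"ignore_w requires strictly positive weights; offending vertex "
            f"{nonpos[0]!r} has weight {g.weight(nonpos[0])}"
        )
    h = g.copy_nx()
    if v not in h:
        raise KeyError(f"vertex {v!r} not in graph")
    if not _ignore_w_applicable(h, v):
        raise ValueError(
            f"ignore_w not applicable at {v!r}: needs a single predecessor or "
            "successor of strictly larger weight and no self-loop"
        )
    _ignore_nx(h, v)
    return WeightedDigraph._wrap(h)


def compress_scc(g: WeightedDigraph) -> WeightedDigraph:
    """Delete every arc joining two distinct strongly connected components.

    Such arcs lie on no cycle, so no feedback vertex set changes.  The
    vertex set is unchanged.
    """
    h = g.copy_nx()
    _compress_scc_nx(h)
    return WeightedDigraph._wrap(h)


def _compress_scc_nx(g: nx.DiGraph) -> int:
    comp_of: dict[str, int] = {}
    for i, block in enumerate(nx.strongly_connected_components(g)):
        for v in block:
            comp_of[v] = i
    crossing = [(u, v) for u, v in g.edges if comp_of[u] != comp_of[v]]
    g.remove_edges_from(crossing)
    return len(crossing)


# ---------------------------------------------------------------------------
# Full fixed-point compression
# ---------------------------------------------------------------------------

def compress(g: WeightedDigraph, mode: Mode = "unweighted") -> CompressionTrace:
    """Apply C1, C2, the mode's C3 bypass and SCC pruning to a fixed point.

    Sweep order within a pass: C1, then C2, then C3, then SCC pruning;
    passes repeat until one makes no change.  Candidates are visited in
    lexicographic vertex order, so the result is deterministic.

    In ``"weighted"`` mode all vertex weights must be strictly positive
    (the hypothesis of the weighted-bypass soundness theorem); otherwise a
    ``ValueError`` names an offending vertex.  ΔM collects exactly the
    vertices removed by C1; ΔM ∪ (any MFVS of the compressed graph) is an
    MFVS of the original graph, and in weighted mode the maximum-weight
    MFVS is preserved as well.
    """
    if mode not in ("unweighted", "weighted", "safe"):
        raise ValueError(f"unknown compression mode {mode!r}")
    if mode == "weighted":
        nonpos = [v for v in g.sorted_vertices() if g.weight(v) <= 0]
        if nonpos:
            raise ValueError(
                "weighted compression requires strictly positive weights; "
                f"vertex {nonpos[0]!r} has weight {g.weight(nonpos[0])}"
            )

    h = g.copy_nx()
    delta_m: set[str] = set()
    steps: list[tuple[str, str]] = []

    changed = True
    while changed:
        changed = False
        # C1: self-loops are forced vertices.
        for v in sorted(h.nodes):
            if h.has_edge(v, v):
                delta_m.add(v)
                h.remove_node(v)
                steps.append(("C1", v))
                changed = True
        # C2: sources and sinks lie on no cycle.  Removing one can expose
        # another, so drain to a local fixed point.
        local = True
        while local:
            local = False
            for v in sorted(h.nodes):
                if h.out_degree(v) == 0 or h.in_degree(v) == 0:
                    h.remove_node(v)
                    steps.append(("C2", v))
                    local = changed = True
        # C3: bypass, plain or weight-restricted.  A bypass can create a
        # self-loop, which must go to C1 (forced) before further bypassing.
        if mode != "safe":
            applicable = _ignore_applicable if mode == "unweighted" else _ignore_w_applicable
            rule = "C3-ignore" if mode == "unweighted" else "C3-ignore_w"
            for v in sorted(h.nodes):
                if v in h and applicable(h, v):
                    _ignore_nx(h, v)
                    steps.append((rule, v))
                    changed = True
        # SCC pruning: arcs between components lie on no cycle.
        n_cross = _compress_scc_nx(h)
        if n_cross:
            steps.append(("scc-prune", f"{n_cross} arcs"))
            changed = True

    return CompressionTrace(
        compressed=WeightedDigraph._wrap(h),
        delta_m=delta_m,
        steps=steps,
        mode=mode,
        original_vertices=g.vertices,
    )


def lift_solution(trace: CompressionTrace, sol: set[str]) -> set[str]:
    """Union a compressed-graph solution with the forced set ΔM.

    ``sol`` must be a subset of the compressed graph's vertices; vertices
    eliminated during compression cannot be part of a compressed solution.
    """
    stray = set(sol) - set(trace.compressed.vertices)
    if stray:
        raise ValueError(
            f"solution contains vertices not in the compressed graph: {sorted(stray)}"
        )
    return set(sol) | set(trace.delta_m)
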