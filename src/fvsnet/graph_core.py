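"""Weighted directed graph model, text I/O and elementary graph predicates.

The central object is :class:`WeightedDigraph`: a simple directed graph
(self-loops allowed, no parallel arcs) whose vertices are opaque,
case-sensitive string identifiers carrying one real weight each.  Every
algorithm in this package — compression, ILP solving, evaluation — acts on
this type.  Vertex weights are dimensionless scores (in the cancer-gene
application, absolute mean log2 fold changes between tumour and normal
expression).

Graphs are immutable from the caller's point of view: operations such as
:func:`remove_vertex` return new objects.  Iteration over vertices is
lexicographic everywhere, so all downstream algorithms are reproducible
run to run.

File formats (all plain text, ``#`` comments skipped):

* edge list — two whitespace/tab-separated columns, source then target;
* weight table — two columns, vertex id then real weight;
* vertex list — one id per line (used for forced-vertex sets).

An edge list cannot express isolated vertices; those can only enter a graph
through an explicit vertex collection or a weight table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedDigraph",
    "WeightTable",
    "GraphParseError",
    "read_edge_list",
    "write_edge_list",
    "read_weight_table",
    "write_weight_table",
    "read_vertex_list",
    "write_vertex_list",
    "apply_weights",
    "is_acyclic",
    "scc_partition",
    "remove_vertex",
]


class GraphParseError(ValueError):
    """A text input file could not be parsed; the message names the line."""


class WeightedDigraph:
    """A directed graph with real vertex weights.

    Parameters
    ----------
    arcs:
        Iterable of ``(source, target)`` pairs.  Duplicates collapse;
        ``(v, v)`` self-loops are admitted (a self-loop is a cycle).
    vertices:
        Optional extra vertices (isolated vertices cannot be expressed
        through arcs alone).
    weights:
        Optional mapping vertex id -> weight.  Vertices without an entry
        get weight 0.
    """

    __slots__ = ("_g",)

    def __init__(
        self,
        arcs: Iterable[tuple[str, str]] = (),
        vertices: Iterable[str] = (),
        weights: Mapping[str, float] | None = None,
    ) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(vertices)
        g.add_edges_from(arcs)
        weights = weights or {}
        for v in g.nodes:
            g.nodes[v]["weight"] = float(weights.get(v, 0.0))
        self._g = g

    @classmethod
    def _wrap(cls, g: nx.DiGraph) -> "WeightedDigraph":
        obj = cls.__new__(cls)
        obj._g = g
        return obj

    # -- basic accessors -------------------------------------------------

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def arcs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._g.edges)

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self._g.number_of_edges()

    def sorted_vertices(self) -> list[str]:
        """Vertices in lexicographic order (the canonical iteration order)."""
        return sorted(self._g.nodes)

    def sorted_arcs(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges)

    def __contains__(self, v: str) -> bool:
        return v in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"WeightedDigraph(|V|={self.n_vertices}, |A|={self.n_arcs})"

    def weight(self, v: str) -> float:
        return self._g.nodes[v]["weight"]

    @property
    def weights(self) -> dict[str, float]:
        return {v: d["weight"] for v, d in self._g.nodes(data=True)}

    def successors(self, v: str) -> set[str]:
        return set(self._g.successors(v))

    def predecessors(self, v: str) -> set[str]:
        return set(self._g.predecessors(v))

    def has_arc(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def has_self_loop(self, v: str) -> bool:
        return self._g.has_edge(v, v)

    def self_loop_vertices(self) -> set[str]:
        return {v for v in self._g.nodes if self._g.has_edge(v, v)}

    # -- derived graphs --------------------------------------------------

    def copy_nx(self) -> nx.DiGraph:
        """A mutable networkx copy (weights as the ``weight`` node attribute)."""
        return self._g.copy()

    def with_weights(self, weights: Mapping[str, float]) -> "WeightedDigraph":
        """Same topology, weights replaced (missing vertices default to 0)."""
        g = self._g.copy()
        for v in g.nodes:
            g.nodes[v]["weight"] = float(weights.get(v, 0.0))
        return WeightedDigraph._wrap(g)

    def without(self, members: Iterable[str]) -> "WeightedDigraph":
        """The graph with all vertices in ``members`` (and incident arcs) removed."""
        members = set(members)
        missing = members - set(self._g.nodes)
        if missing:
            raise KeyError(f"vertices not in graph: {sorted(missing)}")
        g = self._g.copy()
        g.remove_nodes_from(members)
        return WeightedDigraph._wrap(g)


@dataclass
class WeightTable:
    """Vertex -> weight map, tracking which vertices were defaulted to 0.

    ``defaulted`` records vertices that received weight 0 because no datum
    was available for them (the "weight-loss" case), so downstream reports
    can distinguish a measured zero from a missing value.
    """

    entries: dict[str, float] = field(default_factory=dict)
    defaulted: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = [v for v in self.defaulted if self.entries.get(v, 0.0) != 0.0]
        if bad:
            raise ValueError(f"defaulted vertices must carry weight 0: {sorted(bad)}")

    def __getitem__(self, v: str) -> float:
        return self.entries[v]

    def __contains__(self, v: str) -> bool:
        return v in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, v: str, default: float = 0.0) -> float:
        return self.entries.get(v, default)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path):
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


_EDGE_HEADERS = {("source", "target"), ("from", "to"), ("src", "dst")}


def read_edge_list(path: str | Path) -> WeightedDigraph:
    """Read a two-column directed edge list into a graph.

    Columns are tab- or whitespace-separated; extra columns are ignored;
    duplicate arc lines collapse to one arc; an optional header row
    (``source<TAB>target`` and common variants) is tolerated.  All weights
    are 0 — use :func:`apply_weights` to attach a :class:`WeightTable`.
    An empty file yields the empty graph.
    """
    arcs: list[tuple[str, str]] = []
    first = True
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise GraphParseError(
                f"{path}:{lineno}: expected two columns (source, target), got {line!r}"
            )
        if first and (tokens[0].lower(), tokens[1].lower()) in _EDGE_HEADERS:
            first = False
            continue
        first = False
        arcs.append((tokens[0], tokens[1]))
    return WeightedDigraph(arcs=arcs)


def write_edge_list(g: WeightedDigraph, path: str | Path) -> None:
    """Write the arcs of ``g`` as a two-column TSV, lexicographically sorted."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in g.sorted_arcs():
            fh.write(f"{u}\t{v}\n")


def read_weight_table(path: str | Path) -> WeightTable:
    """Read a two-column ``id<TAB>weight`` table; a non-numeric first row is
    treated as a header."""
    entries: dict[str, float] = {}
    first = True
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise GraphParseError(
                f"{path}:{lineno}: expected two columns (id, weight), got {line!r}"
            )
        try:
            w = float(tokens[1])
        except ValueError:
            if first:
                first = False
                continue
            raise GraphParseError(
                f"{path}:{lineno}: cannot parse weight {tokens[1]!r}"
            ) from None
        first = False
        entries[tokens[0]] = w
    return WeightTable(entries=entries)


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for v in sorted(table.entries):
            fh.write(f"{v}\t{table.entries[v]!r}\n")


def read_vertex_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line vertex set (forced-vertex / gene-set layout)."""
    out: set[str] = set()
    for _lineno, line in _data_lines(path):
        out.add(line.split()[0])
    return out


def write_vertex_list(vertices: Iterable[str], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for v in sorted(set(vertices)):
            fh.write(f"{v}\n")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def apply_weights(g: WeightedDigraph, table: WeightTable) -> tuple[WeightedDigraph, set[str]]:
    """Attach weights from ``table`` to ``g``.

    Graph vertices absent from the table get weight 0; they are returned as
    the ``defaulted`` set (missing data is a defaulting mechanism, never an
    error).  Table entries for ids not in the graph are ignored with a log
    message.  Topology is unchanged.
    """
    defaulted = set(g.vertices) - set(table.entries)
    extraneous = set(table.entries) - set(g.vertices)
    if extraneous:
        logger.info(
            "weight table has %d entries not in the graph (ignored), e.g. %s",
            len(extraneous), sorted(extraneous)[:5],
        )
    return g.with_weights(table.entries), defaulted


def is_acyclic(g: WeightedDigraph) -> bool:
    """True iff ``g`` has no directed cycle (a self-loop counts as a cycle)."""
    return nx.is_directed_acyclic_graph(g._g)


def scc_partition(g: WeightedDigraph) -> list[frozenset[str]]:
    """The unique partition of the vertex set into maximal strongly connected
    components, sorted by smallest member for reproducibility."""
    blocks = [frozenset(c) for c in nx.strongly_connected_components(g._g)]
    return sorted(blocks, key=lambda b: min(b))


def remove_vertex(g: WeightedDigraph, v: str) -> WeightedDigraph:
    """``g`` minus ``v`` and all arcs incident to it; ``g`` is not mutated."""
    if v not in g:
        raise KeyError(f"vertex {v!r} not in graph")
    return g.without([v])
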