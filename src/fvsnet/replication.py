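"""Benchmark runs on pre-compressed interactome inputs supplied by the user.

The published benchmark for these methods is a directed human protein
interaction network (6338 genes, 34814 arcs) weighted by absolute log2 fold
changes from TCGA breast tumour/normal RNA-seq.  Its distributed inputs are
three pre-compressed edge lists (one per method), the matching forced-vertex
(ΔM) lists, and the full gene-weight table.  Those files are too large to
bundle here, so this module *loads* them from a user-provided directory and
recomputes the headline numbers — minimum FVS size, maximum-weight-MFVS
total weight, and penalty-form WFVS size and weight — exactly as the
pipeline would.

Expected directory layout (tab-separated, see :mod:`fvsnet.graph_core` for
formats)::

    mfvs_edges.tsv     edge list compressed with the plain bypass (C3 ignore)
    mfvs_deltam.txt    forced vertices matching mfvs_edges.tsv
    wmfvs_edges.tsv    edge list compressed with the weighted bypass
    wmfvs_deltam.txt   forced vertices matching wmfvs_edges.tsv
    wfvs_edges.tsv     edge list compressed with the always-safe rules only
    gene_weights.tsv   vertex id -> weight, covering the whole network
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .fvs_ilp import penalty_transform, solve_mfvs_size, solve_wfvs_penalty, solve_wmfvs
from .graph_core import (
    apply_weights,
    read_edge_list,
    read_vertex_list,
    read_weight_table,
)

__all__ = ["BenchmarkResult", "run_benchmark", "REQUIRED_FILES"]

REQUIRED_FILES = (
    "mfvs_edges.tsv",
    "mfvs_deltam.txt",
    "wmfvs_edges.tsv",
    "wmfvs_deltam.txt",
    "wfvs_edges.tsv",
    "gene_weights.tsv",
)


@dataclass
class BenchmarkResult:
    """Headline numbers of a full benchmark run (sizes and total weights
    refer to the lifted, original-network solutions)."""

    mfvs_size: int
    wmfvs_size: int
    wmfvs_total_weight: float
    wfvs_size: int
    wfvs_total_weight: float


def run_benchmark(data_dir: str | Path) -> BenchmarkResult:
    """Solve all three formulations on pre-compressed benchmark inputs.

    Raises ``FileNotFoundError`` listing whatever required files are absent.
    """
    data_dir = Path(data_dir)
    missing = [f for f in REQUIRED_FILES if not (data_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"benchmark inputs missing from {data_dir}: {missing}"
        )

    weights = read_weight_table(data_dir / "gene_weights.tsv")

    # Minimum FVS on the bypass-compressed graph, lifted by its forced set.
    g_mfvs = read_edge_list(data_dir / "mfvs_edges.tsv")
    dm_mfvs = read_vertex_list(data_dir / "mfvs_deltam.txt")
    size, _sol = solve_mfvs_size(g_mfvs)
    mfvs_size = size + len(dm_mfvs)

    # Maximum-weight MFVS on the weighted-bypass-compressed graph.
    g_wm = read_edge_list(data_dir / "wmfvs_edges.tsv")
    dm_wm = read_vertex_list(data_dir / "wmfvs_deltam.txt")
    g_wm, _ = apply_weights(g_wm, weights)
    s, _ = solve_mfvs_size(g_wm)
    wm = solve_wmfvs(g_wm, s)
    wmfvs_size = wm.size + len(dm_wm)
    wmfvs_weight = wm.total_weight + sum(weights.get(v, 0.0) for v in dm_wm)

    # Penalty-form WFVS on the safely compressed graph (no bypass, so no
    # separate forced list: self-loops, if any, are solved in place).
    g_wf = read_edge_list(data_dir / "wfvs_edges.tsv")
    g_wf, _ = apply_weights(g_wf, weights)
    ptab = penalty_transform(weights)
    wf = solve_wfvs_penalty(
        g_wf, type(ptab)(entries={v: ptab.entries[v] for v in g_wf.vertices},
                         cap=ptab.cap)
    )

    return BenchmarkResult(
        mfvs_size=mfvs_size,
        wmfvs_size=wmfvs_size,
        wmfvs_total_weight=wmfvs_weight,
        wfvs_size=wf.size,
        wfvs_total_weight=wf.total_weight,
    )
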