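"""Synthetic instance generators and exhaustive ground-truth solvers.

Everything in this package is testable without external data through two
generators and two brute-force oracles:

* :func:`random_digraph` builds sparse Erdős–Rényi-style directed graphs
  with planted vertex-disjoint cycles, so instances are guaranteed to have a
  non-trivial feedback vertex set of controllable expected size — the shape
  of a compressed biological interaction network at toy scale.
* :func:`simulate_expression` builds tumour/normal count matrices with known
  planted log2 effect sizes and Gaussian noise on the log scale, the input
  structure of the fold-change weighting.
* :func:`brute_force_all_mfvs` and :func:`brute_force_wfvs` enumerate vertex
  subsets exhaustively (capped instance size — exponential by construction)
  and return provably optimal answers, the independent oracles against which
  the ILP solvers and compression rules are differentially tested.

All generation is a pure function of the spec: same spec, same instance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .graph_core import WeightedDigraph, is_acyclic
from .weights import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "ExpressionSimSpec",
    "random_digraph",
    "brute_force_all_mfvs",
    "brute_force_wfvs",
    "simulate_expression",
    "corpus_specs",
    "BRUTE_FORCE_CAP",
]

#: Hard cap on instance size for the exhaustive oracles.
BRUTE_FORCE_CAP = 15


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a random weighted digraph.

    ``weight_distribution`` is ``("uniform", lo, hi)``,
    ``("lognormal", mu, sigma)`` (parameters of the underlying normal) or
    ``("constant", c)``.
    """

    n_vertices: int = 10
    arc_probability: float = 0.15
    n_planted_cycles: int = 2
    weight_distribution: tuple = ("uniform", 0.5, 3.0)
    seed: int = 0


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Recipe for a tumour/normal expression matrix with planted effects.

    ``effect_sizes`` maps gene id -> signed log2 shift applied to tumour
    samples only; genes not listed get effect 0.  ``noise_sd`` is the
    standard deviation of Gaussian noise added per sample on the log2
    scale.  ``baseline_log2`` is the mean log2 abundance of unperturbed
    genes (counts around 2**baseline).
    """

    n_genes: int = 50
    n_tumour: int = 20
    n_normal: int = 10
    effect_sizes: tuple = ()  # tuple of (gene_id, shift) pairs, hashable
    noise_sd: float = 0.5
    baseline_log2: float = 8.0
    seed: int = 0


def _draw_weights(rng: np.random.Generator, n: int, dist: tuple) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if kind == "lognormal":
        return rng.lognormal(dist[1], dist[2], size=n)
    if kind == "constant":
        return np.full(n, float(dist[1]))
    raise ValueError(f"unknown weight distribution {dist!r}")


def random_digraph(spec: SyntheticSpec) -> WeightedDigraph:
    """A random digraph with planted cycles and per-spec vertex weights.

    Planted cycles use vertex-disjoint runs (length 3 when room allows,
    else 2) over a seeded shuffle of the vertex list, so each contributes
    at least one independent feedback vertex; background arcs are then
    added independently with ``arc_probability`` over all ordered pairs of
    distinct vertices (no random self-loops).
    """
    n = spec.n_vertices
    if n < 1:
        raise ValueError("need at least one vertex")
    k = spec.n_planted_cycles
    if 2 * k > n:
        raise ValueError(
            f"cannot plant {k} vertex-disjoint cycles in {n} vertices"
        )
    rng = np.random.default_rng(spec.seed)
    width = len(str(n - 1))
    verts = [f"v{i:0{width}d}" for i in range(n)]
    order = list(rng.permutation(n))

    arcs: list[tuple[str, str]] = []
    # Disjoint runs: length 3 if 3k <= n, else 2.
    run = 3 if 3 * k <= n else 2
    pos = 0
    for _ in range(k):
        cyc = [verts[order[pos + j]] for j in range(run)]
        arcs.extend((cyc[j], cyc[(j + 1) % run]) for j in range(run))
        pos += run

    p = spec.arc_probability
    if p > 0:
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        arcs.extend(
            (verts[i], verts[j]) for i, j in zip(*np.nonzero(mask))
        )

    weights = dict(zip(verts, _draw_weights(rng, n, spec.weight_distribution)))
    return WeightedDigraph(arcs=arcs, vertices=verts, weights=weights)


def corpus_specs(count: int = 200, seed: int = 0) -> list[SyntheticSpec]:
    """The standard differential-testing corpus: ``count`` small random
    digraphs (4-10 vertices, varying density, 1-2 planted cycles, strictly
    positive uniform weights) with seeds derived deterministically from
    ``seed``.  Sized so exhaustive oracles stay instant on every instance."""
    return [
        SyntheticSpec(
            n_vertices=4 + (i % 7),
            arc_probability=0.08 + 0.03 * (i % 5),
            n_planted_cycles=1 + (i % 2),
            weight_distribution=("uniform", 0.2, 3.0),
            seed=(seed * 1009 + i) % (2**31 - 1),
        )
        for i in range(count)
    ]


# ---------------------------------------------------------------------------
# Exhaustive oracles
# ---------------------------------------------------------------------------

def _check_cap(g: WeightedDigraph, cap: int) -> None:
    if g.n_vertices > cap:
        raise ValueError(
            f"brute force capped at {cap} vertices; graph has {g.n_vertices}"
        )


def brute_force_all_mfvs(
    g: WeightedDigraph, cap: int = BRUTE_FORCE_CAP
) -> tuple[int, list[frozenset[str]]]:
    """The MFVS size and the complete catalogue of minimum FVSs.

    Subsets are enumerated in increasing size; the first size at which some
    removal leaves an acyclic graph is the optimum, and *all* subsets of
    that size achieving it are returned.  Exponential — guarded by ``cap``.
    """
    _check_cap(g, cap)
    verts = g.sorted_vertices()
    for size in range(len(verts) + 1):
        catalogue = [
            frozenset(sub)
            for sub in combinations(verts, size)
            if is_acyclic(g.without(sub))
        ]
        if catalogue:
            return size, catalogue
    raise AssertionError("unreachable: the full vertex set is always an FVS")


def brute_force_wfvs(
    g: WeightedDigraph,
    objective: str = "max_weight",
    penalties: dict[str, float] | None = None,
    cap: int = BRUTE_FORCE_CAP,
) -> tuple[frozenset[str], float]:
    """Exhaustive optimum over ALL feedback vertex sets of any size.

    ``objective="max_weight"`` maximises the sum of the graph's vertex
    weights over the set; ``objective="min_penalty"`` minimises the sum of
    ``penalties`` (required in that case).  Ties break toward smaller sets,
    then lexicographically, so the result is unique and reproducible.
    """
    _check_cap(g, cap)
    if objective not in ("max_weight", "min_penalty"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "min_penalty" and penalties is None:
        raise ValueError("min_penalty requires a penalties mapping")
    verts = g.sorted_vertices()
    best: tuple | None = None
    for size in range(len(verts) + 1):
        for sub in combinations(verts, size):
            if not is_acyclic(g.without(sub)):
                continue
            if objective == "max_weight":
                value = sum(g.weight(v) for v in sub)
                key = (-value, size, sub)
            else:
                value = sum(penalties[v] for v in sub)
                key = (value, size, sub)
            if best is None or key < best[0]:
                best = (key, frozenset(sub), value)
    assert best is not None
    return best[1], float(best[2])


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(spec: ExpressionSimSpec) -> ExpressionMatrix:
    """Simulate a tumour/normal count matrix with planted log2 effects.

    On the log2 scale each gene has a baseline drawn around
    ``baseline_log2``, tumour samples additionally receive the gene's
    planted signed shift, and every sample gets independent Gaussian noise
    of sd ``noise_sd``; values are then exponentiated back to the count
    scale (so they are strictly positive).  Deterministic per seed.
    """
    if spec.n_genes < 1 or spec.n_tumour < 1 or spec.n_normal < 1:
        raise ValueError("need at least one gene, one tumour and one normal sample")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes - 1))
    genes = [f"g{i:0{width}d}" for i in range(spec.n_genes)]
    effects = dict(spec.effect_sizes)
    unknown = set(effects) - set(genes)
    if unknown:
        raise ValueError(f"effect sizes for unknown genes: {sorted(unknown)[:5]}")

    baseline = spec.baseline_log2 + rng.normal(0.0, 1.0, size=spec.n_genes)
    shift = np.array([effects.get(gid, 0.0) for gid in genes])

    t_log = (
        baseline[:, None]
        + shift[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_tumour))
    )
    n_log = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, spec.n_normal)
    )
    t_samples = [f"t{j}" for j in range(spec.n_tumour)]
    n_samples = [f"n{j}" for j in range(spec.n_normal)]
    values = pd.DataFrame(
        np.hstack([np.exp2(t_log), np.exp2(n_log)]),
        index=genes,
        columns=t_samples + n_samples,
    )
    labels = {s: "tumour" for s in t_samples} | {s: "normal" for s in n_samples}
    return ExpressionMatrix(values=values, labels=labels)
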