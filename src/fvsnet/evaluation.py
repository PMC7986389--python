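"""Scoring FVS predictions against reference gene sets.

Predictions are scored only on "common genes" — members of a reference set
that also occur in the network — since genes outside the network can never
be selected.  Significance against a permutation null uses an ensemble of
random minimum feedback vertex sets, produced by re-running the
maximum-weight-MFVS pipeline with the multiset of vertex weights randomly
shuffled over the vertices; the empirical p-value of an observed recall is
the fraction of ensemble recalls at least as large.

The enrichment score (ES) quantifies how strongly a reference set
concentrates at the top of the weight-ranked gene list: walking the ranking,
a running sum gains 1/h at each reference gene (h hits total) and loses
1/(N - h) at each non-member, so it always returns to 0 at the end of the
list; the ES is the signed extreme of the excursion.  "Dark genes" are
reference cancer genes that are not differentially expressed — exactly the
ones a ranking-by-fold-change method cannot find but a network-level method
still can.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .fvs_ilp import FvsSolution, SolverError, full_pipeline, verify_fvs
from .graph_core import WeightedDigraph, WeightTable, read_vertex_list

__all__ = [
    "GeneSet",
    "EnsembleResult",
    "EvalReport",
    "recall_precision",
    "random_mfvs_ensemble",
    "empirical_p",
    "enrichment_score",
    "dark_gene_split",
    "frequency_gene_set",
    "top_k_by_weight",
    "rank_by_weight",
    "evaluate",
]


@dataclass(frozen=True)
class GeneSet:
    """A named reference gene set and its restriction to the network."""

    name: str
    members: frozenset[str]
    common: frozenset[str]

    @classmethod
    def bind(cls, name: str, members: Iterable[str],
             network_vertices: Iterable[str]) -> "GeneSet":
        members = frozenset(members)
        return cls(name=name, members=members,
                   common=members & frozenset(network_vertices))

    @classmethod
    def from_file(cls, path: str | Path,
                  network_vertices: Iterable[str]) -> "GeneSet":
        return cls.bind(Path(path).stem, read_vertex_list(path), network_vertices)


@dataclass
class EnsembleResult:
    """Random-MFVS ensemble with filtered-replicate accounting.

    ``attempted`` counts all replicates run; ``solutions`` holds only those
    whose output verified as an FVS of the original graph at the true MFVS
    size (failures are discarded, mirroring the post-hoc filtering any MILP
    pipeline needs).
    """

    solutions: list[FvsSolution]
    attempted: int
    mfvs_size: int

    @property
    def approved(self) -> int:
        return len(self.solutions)


@dataclass
class EvalReport:
    """Per-gene-set metrics for one predicted vertex set."""

    recall: dict[str, float | None]
    precision: dict[str, float | None]
    p_values: dict[str, float] = field(default_factory=dict)
    es: dict[str, float] = field(default_factory=dict)
    es_curves: dict[str, list[float]] = field(default_factory=dict)
    dark_gene_counts: dict[str, tuple[int, int]] = field(default_factory=dict)


def recall_precision(
    predicted: Iterable[str], gs: GeneSet
) -> tuple[float | None, float | None]:
    """Recall and precision of a prediction on a gene set's common genes.

    recall = |predicted ∩ common| / |common|;
    precision = |predicted ∩ common| / |predicted|.
    An empty common set gives recall None; an empty prediction gives
    precision None (undefined, not zero).
    """
    predicted = set(predicted)
    hits = len(predicted & gs.common)
    recall = hits / len(gs.common) if gs.common else None
    precision = hits / len(predicted) if predicted else None
    return recall, precision


def random_mfvs_ensemble(
    g: WeightedDigraph,
    w: WeightTable,
    count: int,
    seed: int,
) -> EnsembleResult:
    """Random MFVSs from weight-shuffled runs of the WMFVS pipeline.

    Each replicate permutes the multiset of weight values uniformly over the
    graph's vertices (defaulted zeros included — the shuffle is over all
    entries) and solves for the maximum-weight MFVS under the permuted
    weights.  Outputs are verified against the original graph and must have
    exactly the true MFVS size; replicates failing either check are
    discarded and only counted as attempts.  Same seed, same inputs ⇒
    identical ensemble.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    verts = g.sorted_vertices()
    values = np.array([w.get(v, 0.0) for v in verts], dtype=float)
    mfvs_size = full_pipeline(g, w, "MFVS").size

    solutions: list[FvsSolution] = []
    for _ in range(count):
        perm = rng.permutation(len(verts))
        shuffled = WeightTable(entries={v: float(values[j])
                                        for v, j in zip(verts, perm)})
        try:
            sol = full_pipeline(g, shuffled, "WMFVS")
        except SolverError:
            continue
        if sol.size == mfvs_size and verify_fvs(g, sol.members):
            solutions.append(sol)
    return EnsembleResult(solutions=solutions, attempted=count,
                          mfvs_size=mfvs_size)


def empirical_p(r_obs: float, r_random: Sequence[float]) -> float:
    """Permutation p-value: fraction of null statistics >= the observed one.

    Exact zeros are possible (and reported as such) when the observation
    exceeds every null replicate.
    """
    r_random = list(r_random)
    if not r_random:
        raise ValueError("r_random must be non-empty")
    return sum(1 for r in r_random if r >= r_obs) / len(r_random)


def rank_by_weight(w: WeightTable) -> list[str]:
    """All vertices sorted by weight descending, id ascending on ties."""
    return sorted(w.entries, key=lambda v: (-w.entries[v], v))


def enrichment_score(
    ranked: Sequence[str], gs: GeneSet
) -> tuple[list[float], float]:
    """Balanced running-sum enrichment of a gene set along a ranked list.

    Walking ``ranked`` from top to bottom, the sum gains 1/h at each of the
    h genes of ``gs.common`` present in the list and loses 1/(N - h)
    elsewhere, so it ends exactly at 0.  The returned ES is the curve value
    of maximum magnitude (positive: enrichment at the top; negative: at the
    bottom).  Degenerate sets — no common gene in the list, or all of it —
    have no excursion and raise ``ValueError``.
    """
    ranked = list(ranked)
    n = len(ranked)
    hits = gs.common & set(ranked)
    h = len(hits)
    if h == 0 or h == n:
        raise ValueError(
            f"gene set {gs.name!r} must be a non-empty strict subset of the "
            f"ranked list (got {h} hits of {n})"
        )
    up = 1.0 / h
    down = 1.0 / (n - h)
    curve: list[float] = []
    total = 0.0
    for v in ranked:
        total += up if v in hits else -down
        curve.append(total)
    es = max(curve, key=abs)
    return curve, float(es)


def dark_gene_split(
    predicted: Iterable[str], gs: GeneSet, deg: Iterable[str]
) -> tuple[int, int]:
    """Split predicted common genes into dark (non-DEG) and non-dark (DEG).

    A dark gene is a reference cancer gene with too little differential
    expression to be called a DEG; network-level selection can still find
    it.  Returns ``(dark, non_dark)`` counts over ``predicted ∩ gs.common``.
    """
    deg = set(deg)
    hits = set(predicted) & gs.common
    non_dark = len(hits & deg)
    return len(hits) - non_dark, non_dark


def frequency_gene_set(
    ensemble: Sequence[FvsSolution] | EnsembleResult, fraction: float
) -> set[str]:
    """Genes appearing in at least ``fraction`` of the ensemble's members."""
    if isinstance(ensemble, EnsembleResult):
        ensemble = ensemble.solutions
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not ensemble:
        raise ValueError("ensemble is empty")
    counts: dict[str, int] = {}
    for sol in ensemble:
        for v in sol.members:
            counts[v] = counts.get(v, 0) + 1
    threshold = fraction * len(ensemble)
    return {v for v, c in counts.items() if c >= threshold}


def top_k_by_weight(w: WeightTable, k: int) -> set[str]:
    """The k largest-weight vertices; boundary ties break lexicographically.

    This is the pure differential-expression baseline: rank by weight,
    take the top k.  A tie across the cut is resolved in id order and noted
    in the log.
    """
    if not 0 <= k <= len(w.entries):
        raise ValueError(f"k must be in [0, {len(w.entries)}]")
    order = rank_by_weight(w)
    if 0 < k < len(order) and w.entries[order[k - 1]] == w.entries[order[k]]:
        logging.getLogger(__name__).warning(
            "tie at the top-%d boundary (weight %g); broken lexicographically",
            k, w.entries[order[k]],
        )
    return set(order[:k])


def evaluate(
    predicted: Iterable[str],
    gene_sets: Sequence[GeneSet],
    *,
    ensemble: EnsembleResult | None = None,
    weight_table: WeightTable | None = None,
    deg: Iterable[str] | None = None,
) -> EvalReport:
    """Assemble a full report: recall/precision per set, and — when the
    corresponding inputs are given — permutation p-values (ensemble),
    enrichment curves (weight table) and dark-gene counts (DEG set)."""
    predicted = set(predicted)
    report = EvalReport(recall={}, precision={})
    ranked = rank_by_weight(weight_table) if weight_table is not None else None
    for gs in gene_sets:
        r, p = recall_precision(predicted, gs)
        report.recall[gs.name] = r
        report.precision[gs.name] = p
        if ensemble is not None and r is not None and ensemble.solutions:
            null = [recall_precision(sol.members, gs)[0]
                    for sol in ensemble.solutions]
            report.p_values[gs.name] = empirical_p(r, [x for x in null if x is not None])
        if ranked is not None:
            try:
                curve, es = enrichment_score(ranked, gs)
            except ValueError:
                pass
            else:
                report.es[gs.name] = es
                report.es_curves[gs.name] = curve
        if deg is not None:
            report.dark_gene_counts[gs.name] = dark_gene_split(predicted, gs, deg)
    return report
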