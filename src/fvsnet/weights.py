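"""Vertex weights from tumour/normal expression: absolute mean log2 fold change.

A gene's weight is |mean(log2 T) - mean(log2 N)| over tumour samples T and
normal samples N — the magnitude of the log2 fold change between the two
conditions.  High fold change marks a strong differential-expression signal,
so these weights steer the weighted feedback vertex set solvers toward genes
that are both topologically critical and transcriptionally perturbed.

Genes present in the network but absent from the expression data
("weight-loss" genes) receive a default weight of 0 rather than being
dropped: the network topology is never altered by missing data, and a gene
that is structurally forced into a solution can still surface despite having
no expression evidence.

Logs of zero are undefined and real count matrices contain zeros, so a
pseudocount (default 1) is added to every expression value before the log;
the fold-change formula is applied to value + pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .graph_core import WeightTable

__all__ = [
    "ExpressionMatrix",
    "fc_weight",
    "build_weight_table",
    "deg_call",
    "read_expression",
    "read_labels",
]

TUMOUR = "tumour"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a tumour/normal partition.

    ``values`` is a pandas DataFrame (rows = genes, columns = samples) of
    finite, non-negative expression values; ``labels`` maps every sample to
    ``"tumour"`` or ``"normal"``, and each group must be non-empty.
    """

    values: pd.DataFrame
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.labels]
        if missing:
            raise ValueError(f"samples without a label: {missing[:5]}")
        bad = {s: l for s, l in self.labels.items() if l not in (TUMOUR, NORMAL)}
        if bad:
            raise ValueError(f"labels must be '{TUMOUR}' or '{NORMAL}': {bad}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("expression values must be finite and >= 0")
        if not self.tumour_samples or not self.normal_samples:
            raise ValueError("need at least one tumour and one normal sample")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tumour_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == TUMOUR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == NORMAL]


def fc_weight(tumour, normal) -> float:
    """Absolute difference of mean log2 expression between the two groups.

        w = | mean(log2 tumour) - mean(log2 normal) |

    Both vectors must be non-empty and strictly positive (the log is
    undefined at 0 — add a pseudocount first; :func:`build_weight_table`
    does this for you).  The absolute value makes the weight symmetric in
    the two groups: up- and down-regulation score alike.
    """
    t = np.asarray(tumour, dtype=float)
    n = np.asarray(normal, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("tumour and normal vectors must be non-empty")
    if np.any(t <= 0) or np.any(n <= 0):
        raise ValueError(
            "expression values must be strictly positive for the log2 fold "
            "change; add a pseudocount to zero-containing data"
        )
    return float(abs(np.log2(t).mean() - np.log2(n).mean()))


def build_weight_table(
    x: ExpressionMatrix,
    network_vertices: Iterable[str],
    pseudocount: float = 1.0,
) -> WeightTable:
    """Fold-change weights for every network vertex; missing genes default to 0.

    Each network vertex found in the matrix gets
    ``fc_weight(values + pseudocount)``; vertices with no expression data get
    weight 0 and are recorded in ``defaulted``.  Genes in the matrix that are
    not network vertices are dropped.  Network topology is untouched — this
    function only produces a :class:`~fvsnet.graph_core.WeightTable`.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    network_vertices = set(network_vertices)
    tum = x.values[x.tumour_samples].to_numpy() + pseudocount
    nor = x.values[x.normal_samples].to_numpy() + pseudocount
    if np.any(tum <= 0) or np.any(nor <= 0):
        raise ValueError(
            "zero expression with zero pseudocount: set pseudocount > 0"
        )
    diff = np.abs(np.log2(tum).mean(axis=1) - np.log2(nor).mean(axis=1))
    computed = dict(zip(x.genes, diff))

    entries: dict[str, float] = {}
    defaulted: set[str] = set()
    for v in sorted(network_vertices):
        if v in computed:
            entries[v] = float(computed[v])
        else:
            entries[v] = 0.0
            defaulted.add(v)
    return WeightTable(entries=entries, defaulted=defaulted)


def deg_call(
    weight: float,
    fc_threshold: float = 1.0,
    adj_p: float | None = None,
    p_threshold: float = 0.05,
) -> bool:
    """Differentially-expressed-gene call: |log2 FC| >= 1 and adjusted p <= 0.05.

    The fold-change side uses the vertex weight (already an absolute log2
    fold change); the adjusted p-value is an externally computed, optional
    input — when absent, the call rests on fold change alone.  Both
    comparisons are inclusive.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if weight < fc_threshold:
        return False
    return adj_p is None or adj_p <= p_threshold


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_expression(expr_path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, remaining columns samples,
    header row with sample names) and a two-column sample-label TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, labels=read_labels(labels_path))


def read_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    first = True
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>label'")
            if first and tokens[1].lower() not in (TUMOUR, NORMAL):
                first = False
                continue  # header row
            first = False
            labels[tokens[0]] = tokens[1].lower()
    return labels
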