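"""Exact feedback vertex set solvers via integer linear programming.

All variants share one constraint system, the vertex-ordering (big-M)
acyclicity formulation: a binary indicator x_i per vertex (1 = in the FVS)
and an integer order variable k_i in [0, n-1], with

    k_i - k_j + n * x_i >= 1        for every arc (v_i, v_j)

Unselected vertices must admit a topological order of the residual graph,
so the selected set meets every cycle; a self-loop arc reduces the
constraint to n*x_i >= 1, forcing the vertex in.  On top of this system:

* **MFVS** — minimise sum(x): the minimum feedback vertex set size.
* **WMFVS** — fix sum(x) = s (the MFVS size) and maximise sum(w_i * x_i):
  the maximum-weight MFVS among all minimum ones.
* **WFVS, penalty form** — minimise sum(p_i * x_i) with reciprocal
  penalties p_i = 1/w_i (capped at l = 65536 when w_i < 1/l): a
  weight-driven FVS with no size constraint.  This is the default WFVS
  route.
* **WFVS, shift form** — maximise sum((w_i - w_max - eps) * x_i): shifting
  all weights below zero removes the trivial all-vertex optimum.

Problems are solved exactly with HiGHS through :func:`scipy.optimize.milp`
(zero MIP gap).  MILP solvers can mis-report on numerically awkward
instances, so every returned set is re-verified as a feedback vertex set by
direct acyclicity testing; on a verification failure the solve is retried
once with presolve disabled before raising.

:func:`full_pipeline` chains compression, solving on the compressed graph,
lift-back of the forced set ΔM, and verification against the original graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .compression import compress, lift_solution
from .graph_core import WeightedDigraph, WeightTable, apply_weights, is_acyclic

logger = logging.getLogger(__name__)

__all__ = [
    "FvsSolution",
    "PenaltyTable",
    "SolverError",
    "InfeasibleSizeError",
    "DEFAULT_PENALTY_CAP",
    "solve_mfvs_size",
    "solve_wmfvs",
    "penalty_transform",
    "solve_wfvs_penalty",
    "solve_wfvs_shift",
    "verify_fvs",
    "full_pipeline",
]

#: Large number l capping reciprocal penalties (and replacing them for
#: weights below 1/l, including zero and negative weights).
DEFAULT_PENALTY_CAP = 65536.0


class SolverError(RuntimeError):
    """The MILP backend failed or returned an unverifiable certificate."""


class InfeasibleSizeError(SolverError):
    """No FVS of the requested size exists (size below the true minimum)."""


@dataclass(frozen=True)
class FvsSolution:
    """A feedback vertex set together with how it was obtained.

    ``size`` and ``total_weight`` always refer to the member set itself;
    ``objective_value`` is the value of the ILP objective that produced it
    (e.g. the penalty sum for the penalty-form WFVS).  ``verified`` is True
    only if removing the members was checked to leave the graph acyclic.
    """

    members: frozenset[str]
    method: str
    size: int
    total_weight: float
    objective_value: float
    verified: bool
    forced: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.size != len(self.members):
            raise ValueError("size must equal |members|")


@dataclass
class PenaltyTable:
    """Positive per-vertex penalties p_i in (0, cap] for the penalty-form WFVS."""

    entries: dict[str, float]
    cap: float = DEFAULT_PENALTY_CAP

    def __post_init__(self) -> None:
        bad = {v: p for v, p in self.entries.items() if not (0 < p <= self.cap)}
        if bad:
            k = sorted(bad)[0]
            raise ValueError(
                f"penalties must lie in (0, {self.cap}]; entry {k!r} is {bad[k]}"
            )


# ---------------------------------------------------------------------------
# Core ordering-ILP solve
# ---------------------------------------------------------------------------

def _solve_ordering_ilp(
    g: WeightedDigraph,
    objective: dict[str, float],
    *,
    maximize: bool,
    fixed_size: int | None = None,
) -> frozenset[str]:
    """Solve one ordering ILP and return the selected vertex set.

    Raises :class:`InfeasibleSizeError` when a ``fixed_size`` constraint is
    infeasible and :class:`SolverError` on any other solver failure.
    """
    verts = g.sorted_vertices()
    n = len(verts)
    if n == 0:
        return frozenset()
    arcs = g.sorted_arcs()
    if not arcs and fixed_size in (None, 0):
        return frozenset()
    idx = {v: i for i, v in enumerate(verts)}

    # Variables: x_0..x_{n-1} (binary), k_0..k_{n-1} (integer in [0, n-1]).
    c = np.zeros(2 * n)
    for v, coef in objective.items():
        c[idx[v]] = -coef if maximize else coef

    rows, cols, vals = [], [], []
    for r, (u, v) in enumerate(arcs):
        i, j = idx[u], idx[v]
        if i == j:  # self-loop: n*x_i >= 1
            rows.append(r); cols.append(i); vals.append(float(n))
        else:
            rows.extend([r, r, r])
            cols.extend([n + i, n + j, i])
            vals.extend([1.0, -1.0, float(n)])
    n_rows = len(arcs)
    lb = np.ones(n_rows)
    ub = np.full(n_rows, np.inf)
    if fixed_size is not None:
        size_row = n_rows
        for i in range(n):
            rows.append(size_row); cols.append(i); vals.append(1.0)
        lb = np.append(lb, float(fixed_size))
        ub = np.append(ub, float(fixed_size))
        n_rows += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_rows, 2 * n))

    bounds = Bounds(
        lb=np.concatenate([np.zeros(n), np.zeros(n)]),
        ub=np.concatenate([np.ones(n), np.full(n, float(n - 1 if n > 1 else 0))]),
    )
    integrality = np.ones(2 * n)
    constraint = LinearConstraint(A, lb, ub)

    for attempt, options in enumerate(
        ({"mip_rel_gap": 0.0}, {"mip_rel_gap": 0.0, "presolve": False})
    ):
        res = milp(
            c=c,
            constraints=constraint,
            integrality=integrality,
            bounds=bounds,
            options=options,
        )
        if res.status == 2:  # infeasible
            raise InfeasibleSizeError(
                f"ordering ILP infeasible (fixed size {fixed_size})"
            )
        if res.success:
            x = res.x[:n]
            return frozenset(verts[i] for i in range(n) if x[i] > 0.5)
        logger.warning("MILP attempt %d failed: %s", attempt + 1, res.message)
    raise SolverError(f"MILP failed after retry: {res.message}")


def _checked_solve(
    g: WeightedDigraph,
    objective: dict[str, float],
    *,
    maximize: bool,
    fixed_size: int | None = None,
) -> frozenset[str]:
    """Solve and verify; retry once on a non-FVS certificate, then raise."""
    members = _solve_ordering_ilp(
        g, objective, maximize=maximize, fixed_size=fixed_size
    )
    if verify_fvs(g, members):
        return members
    logger.warning("solver returned a non-FVS certificate; retrying once")
    members = _solve_ordering_ilp(
        g, objective, maximize=maximize, fixed_size=fixed_size
    )
    if verify_fvs(g, members):
        return members
    raise SolverError("solver output failed FVS verification twice")


# ---------------------------------------------------------------------------
# Public solvers
# ---------------------------------------------------------------------------

def verify_fvs(g: WeightedDigraph, members) -> bool:
    """True iff removing ``members`` leaves ``g`` acyclic.

    This direct check is run on every solver output before it is trusted.
    """
    members = set(members)
    if not members <= set(g.vertices):
        raise ValueError("members must be a subset of the graph's vertices")
    return is_acyclic(g.without(members))


def _solution(g: WeightedDigraph, members: frozenset[str], method: str,
              objective_value: float, forced: frozenset[str] = frozenset()) -> FvsSolution:
    return FvsSolution(
        members=members,
        method=method,
        size=len(members),
        total_weight=sum(g.weight(v) for v in members),
        objective_value=objective_value,
        verified=verify_fvs(g, members),
        forced=forced,
    )


def solve_mfvs_size(g: WeightedDigraph) -> tuple[int, FvsSolution]:
    """Minimum feedback vertex set: the size optimum and one witness."""
    members = _checked_solve(g, {v: 1.0 for v in g.vertices}, maximize=False)
    return len(members), _solution(g, members, "MFVS", float(len(members)))


def solve_wmfvs(g: WeightedDigraph, s: int) -> FvsSolution:
    """Maximum-weight FVS among all FVSs of exactly size ``s``.

    ``s`` should be the MFVS size from :func:`solve_mfvs_size`; a smaller
    ``s`` is infeasible and raises :class:`InfeasibleSizeError`.
    """
    members = _checked_solve(g, g.weights, maximize=True, fixed_size=s)
    return _solution(
        g, members, "WMFVS", sum(g.weight(v) for v in members)
    )


def penalty_transform(
    w: WeightTable, l: float = DEFAULT_PENALTY_CAP
) -> PenaltyTable:
    """Reciprocal penalties: p_i = 1/w_i when w_i >= 1/l, else p_i = l.

    The cap ``l`` stands in for the infinite penalty of a zero weight and
    bounds the reciprocal of tiny weights; negative weights fall in the
    w_i < 1/l branch and also map to ``l`` (with a warning, since a
    negative weight is an unusual input for a penalty scheme).
    """
    if l <= 0:
        raise ValueError("penalty cap l must be positive")
    entries: dict[str, float] = {}
    negatives = 0
    for v, wv in w.entries.items():
        if wv >= 1.0 / l:
            entries[v] = 1.0 / wv
        else:
            if wv < 0:
                negatives += 1
            entries[v] = l
    if negatives:
        logger.warning(
            "%d negative weights mapped to the penalty cap %g", negatives, l
        )
    return PenaltyTable(entries=entries, cap=l)


def solve_wfvs_penalty(g: WeightedDigraph, p: PenaltyTable) -> FvsSolution:
    """Minimum-penalty FVS (no size constraint); penalty-form WFVS.

    Every graph vertex must have a penalty entry.  ``total_weight`` in the
    returned solution is computed from the graph's original weights;
    ``objective_value`` is the penalty sum actually minimised.
    """
    missing = sorted(set(g.vertices) - set(p.entries))
    if missing:
        raise KeyError(f"no penalty for vertices: {missing[:5]}")
    members = _checked_solve(
        g, {v: p.entries[v] for v in g.vertices}, maximize=False
    )
    return _solution(
        g, members, "WFVS-penalty", sum(p.entries[v] for v in members)
    )


def solve_wfvs_shift(
    g: WeightedDigraph,
    w: WeightTable | None = None,
    epsilon: float = 1e-3,
) -> FvsSolution:
    """Maximum-weight FVS via the negative-shift trick; shift-form WFVS.

    With non-negative weights the unconstrained maximum-weight "FVS" is the
    trivial all-vertex set, so each weight is shifted to w_i - w_max - eps,
    making all weights negative; when every weight is already negative the
    shift is unnecessary and the weights are used as-is.  ``total_weight``
    is reported on the original scale; ``objective_value`` is the shifted
    objective that was maximised.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    weights = dict(g.weights)
    if w is not None:
        weights.update({v: w.get(v, 0.0) for v in weights})
    w_max = max(weights.values(), default=0.0)
    if w_max >= 0:
        shifted = {v: wv - w_max - epsilon for v, wv in weights.items()}
    else:
        shifted = weights
    members = _checked_solve(g, shifted, maximize=True)
    gw = g.with_weights(weights)
    return FvsSolution(
        members=members,
        method="WFVS-shift",
        size=len(members),
        total_weight=sum(weights[v] for v in members),
        objective_value=sum(shifted[v] for v in members),
        verified=verify_fvs(gw, members),
    )


# ---------------------------------------------------------------------------
# Compress -> solve -> lift pipeline
# ---------------------------------------------------------------------------

def full_pipeline(
    g: WeightedDigraph,
    w: WeightTable | None = None,
    method: str = "MFVS",
    *,
    l: float = DEFAULT_PENALTY_CAP,
    epsilon: float = 1e-3,
    wfvs_form: str = "penalty",
) -> FvsSolution:
    """Compress, solve on the compressed graph, lift ΔM back, verify.

    Compression mode per method:

    * ``MFVS`` — plain bypass (preserves MFVS size);
    * ``WMFVS`` — weight-restricted bypass when all weights are strictly
      positive (preserves the maximum-weight MFVS); with zero or negative
      weights only the always-safe rules (C1, C2, SCC pruning) apply;
    * ``WFVS`` — always-safe rules only, since the bypass preserves minimum
      FVSs but not weight-optimal FVSs of arbitrary size.

    Self-loop vertices enter the forced set ΔM during compression and are
    part of the result for every method — a self-loop is a cycle only its
    own vertex can break, whatever its weight.  The lifted set is verified
    against the *original* graph; a verification failure raises
    :class:`SolverError`.
    """
    if method not in ("MFVS", "WMFVS", "WFVS"):
        raise ValueError(f"unknown method {method!r}")
    if w is not None:
        gw, _defaulted = apply_weights(g, w)
    else:
        gw = g

    if method == "MFVS":
        mode = "unweighted"
    elif method == "WMFVS":
        mode = "weighted" if all(x > 0 for x in gw.weights.values()) else "safe"
    else:
        mode = "safe"
    trace = compress(gw, mode)
    comp = trace.compressed
    if trace.delta_m:
        logger.info("%d forced vertices extracted during compression", len(trace.delta_m))

    if method == "MFVS":
        _size, sub = solve_mfvs_size(comp)
    elif method == "WMFVS":
        s, _ = solve_mfvs_size(comp)
        sub = solve_wmfvs(comp, s)
    elif wfvs_form == "penalty":
        ptab = penalty_transform(WeightTable(entries=dict(comp.weights)), l=l)
        sub = solve_wfvs_penalty(comp, ptab)
    elif wfvs_form == "shift":
        sub = solve_wfvs_shift(comp, epsilon=epsilon)
    else:
        raise ValueError(f"unknown WFVS form {wfvs_form!r}")

    members = frozenset(lift_solution(trace, set(sub.members)))
    if not verify_fvs(gw, members):
        raise SolverError("lifted solution failed verification on the original graph")

    total_weight = sum(gw.weight(v) for v in members)
    if method == "MFVS":
        objective = float(len(members))
        tag = "MFVS"
    elif method == "WMFVS":
        objective = total_weight
        tag = "WMFVS"
    elif wfvs_form == "penalty":
        full_pen = penalty_transform(WeightTable(entries=dict(gw.weights)), l=l)
        objective = sum(full_pen.entries[v] for v in members)
        tag = "WFVS-penalty"
    else:
        objective = sub.objective_value
        tag = "WFVS-shift"

    return FvsSolution(
        members=members,
        method=tag,
        size=len(members),
        total_weight=total_weight,
        objective_value=objective,
        verified=True,
        forced=frozenset(trace.delta_m),
    )
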