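# Methods

## Model

All computations act on a simple directed graph G = (V, A) with one real
weight per vertex. Self-loops are admitted (a self-loop is a one-vertex
cycle); parallel arcs are not — when a reduction would create a duplicate
arc it merges silently, which changes no cycle and therefore no feedback
vertex set. A feedback vertex set (FVS) is any S ⊆ V such that G − S is
acyclic. The three optimisation problems are:

* **MFVS** — minimise |S|;
* **WMFVS** — among all S with |S| = s* (the MFVS size), maximise Σ_{v∈S} v.w;
* **WFVS** — optimise weight with |S| free. Two forms are provided:
  *penalty* (default): minimise Σ p_v with p_v = 1/v.w for v.w ≥ 1/l and
  p_v = l otherwise (l = 65536, the cap standing in for the infinite
  penalty of a zero weight); *shift*: maximise Σ (v.w − w_max − ε),
  ε = 10⁻³, which makes all weights negative and removes the trivial
  all-vertex optimum. The two objectives are genuinely different — a
  minimum reciprocal-penalty set need not be a maximum-weight set — so the
  solution records which objective produced it. The penalty form is the
  default because the shifted objective differences large near-equal
  numbers and is the numerically flakier of the two on MILP backends.

Weights are dimensionless; in the intended application they are absolute
mean log2 fold changes between tumour and normal expression, so "heavy"
means "strongly differentially expressed".

## ILP formulation and solving

All variants share the vertex-ordering acyclicity system: binary x_v
(membership) and integer k_v ∈ [0, n−1], with k_u − k_v + n·x_u ≥ 1 for
every arc (u, v), where n is the vertex count of the graph actually handed
to the solver (post-compression — the tightest valid big-M). Unselected
vertices must admit a strictly decreasing order along residual arcs, i.e.
a topological order, so the selected set meets every cycle; a self-loop
reduces its constraint to n·x_v ≥ 1 and forces the vertex in.

Problems are solved with HiGHS via `scipy.optimize.milp` at zero MIP gap.
MILP backends can emit wrong certificates on awkward instances, so no
output is trusted: every returned set is re-checked by direct acyclicity
testing, with one automatic re-solve (presolve disabled) before an error
is raised. Among multiple optima the solver's incumbent is returned;
member sets are therefore best-effort reproducible, while optimal
*objective values* are the reproducible quantity.

## Compression

Four rules run to a fixed point, in the order C1, C2, C3, SCC-prune per
sweep (forced vertices leave earliest; the order affects the trace, not
the preserved optimum), candidates visited in lexicographic vertex order
for determinism:

* **C1** a self-loop vertex is in every FVS → move to the forced set ΔM;
* **C2** a vertex with no successors or no predecessors is on no cycle → drop;
* **C3** (`ignore`) a vertex v with |suc(v)| = 1 or |pre(v)| = 1 and no
  self-loop is bypassed (pre × suc arcs added, v removed): every cycle
  through v passes its sole neighbour, so some MFVS avoids v — size is
  preserved, though individual MFVSs can be lost;
* **C3w** (`ignore_w`) the weighted restriction: additionally v.w must be
  *strictly* below the sole neighbour's weight, all weights strictly
  positive. The exchange argument (replace v by its heavier neighbour)
  shows v is in no maximum-weight MFVS, so the weight optimum survives.
  Strictness follows the soundness proof; equal weights are deliberately
  not compressed even though a tie-preserving variant would keep *some*
  maximum — preserving all of them is the safer contract.
* **SCC-prune** arcs between distinct strongly connected components lie on
  no cycle → delete.

Modes: `unweighted` (C3), `weighted` (C3w; raises on any non-positive
weight, naming the vertex), and `safe` (no bypass at all). The WFVS
pipeline uses `safe`: the bypass arguments preserve *minimum* FVSs, not
weight-optimal FVSs of arbitrary size, so only the universally sound rules
apply there. The WMFVS pipeline uses `weighted` when every weight is
strictly positive and falls back to `safe` otherwise — real weight tables
contain defaulted zeros, which void the C3w hypothesis but never the safe
rules. ΔM ∪ (any solution of the compressed graph) is a solution of the
original graph; the pipeline performs this lift and re-verifies against
the original graph. Self-loop vertices are forced into the result for
every method, including WFVS with unfavourable weights: no other vertex
can break a self-loop.

## Expression weighting

`build_weight_table` computes |mean(log2 (T + c)) − mean(log2 (N + c))|
per gene with pseudocount c (default 1): logs of zero counts are undefined
and real count matrices contain zeros. At count scales of a few hundred
the pseudocount perturbs the weight by well under 0.01; the choice of c is
exposed for data on other scales. Network genes with no expression data
keep weight 0 and are tracked as "defaulted" — topology is never altered
by missing data, so a structurally forced gene can still be selected. The
DEG rule is |log2 FC| ≥ 1 (inclusive) plus, when supplied, an external
adjusted p-value ≤ 0.05; no differential-expression test is computed
in-package, because the weighting needs only the fold change and any test
choice belongs to the data-processing pipeline upstream.

## Evaluation statistics

Recall and precision are computed on *common genes* (reference ∩ network);
undefined ratios (empty common set, empty prediction) are reported as
undefined rather than zero. The permutation null shuffles the full
multiset of weights (defaulted zeros included) over vertices, re-runs the
WMFVS pipeline, and keeps only replicates that verify as true-size MFVSs
of the original graph, recording attempted vs approved counts. The
empirical p-value is the fraction of approved replicates whose recall is ≥
the observed recall — exact zeros are legitimate outputs. The enrichment
score walks the weight-descending ranking (ties broken by id) adding 1/h
on reference hits and subtracting 1/(N−h) on misses — the balanced scheme
that ends exactly at 0 — and reports the signed extreme of the excursion.
Dark genes are reference genes in the prediction that fail the DEG rule.

## Synthetic data

`random_digraph` plants k vertex-disjoint cycles (3-cycles when room
allows, else 2-cycles) on a seeded shuffle and overlays Erdős–Rényi arcs
with probability p over ordered pairs, never generating random self-loops;
weights come from a uniform, lognormal or constant law. This emulates the
property that matters to these algorithms — sparse digraphs with a
non-trivial, controllable cycle structure — and deliberately not the
degree distribution, motif content or scale of a real interactome, so
passing tests certify algorithmic correctness, not biological performance
at scale. `simulate_expression` draws per-gene log2 baselines around a
set level (default 8, counts near 256), adds the planted signed shift to
tumour samples and N(0, sd²) noise to all samples, and exponentiates; it
does not model library-size variation, overdispersion or batch effects,
which the fold-change weighting would anyway absorb upstream.

The differential-testing corpus is 200 graphs of 4–10 vertices, densities
0.08–0.20, 1–2 planted cycles, uniform weights on [0.2, 3.0] (strictly
positive so the weighted bypass is exercised) — small enough that the
exhaustive oracles (subset enumeration in increasing size, cap 15
vertices) are instant and exact on every instance.

## Numerical choices and edge cases

* Optima are compared to oracles at 10⁻⁶ absolute; enrichment curves must
  close at 0 within 10⁻⁹; weights are carried at full double precision and
  only rounded (1 d.p.) in CLI summaries.
* Empty graphs and DAGs yield the empty solution without invoking the
  solver; a fixed-size constraint below the true minimum reports
  infeasibility explicitly.
* Fold-change estimator bias: the absolute value folds the sampling
  distribution at zero, so at a true effect of 0 the estimator has
  positive bias ≈ sd·√(2/(π·m_eff)) — about 0.08 at 50 + 50 samples and
  sd 0.5. Averaged with the unbiased regimes at effects 1 and 2 the mean
  absolute bias stays below 0.05; this folding floor is inherent to any
  magnitude-of-effect weight, not an implementation artefact.
* The case study in `scripts/acceptance.py` uses a 60-vertex network,
  50 + 50 samples, 10 planted cancer genes (5 at |log2 FC| = 2, 5 dark at
  0.3) and a 40-replicate ensemble — sizes chosen so the full study runs
  in well under a minute while every component (compression, all three
  solvers, ensemble, statistics) is exercised at non-toy scale.

## Known limitations

* The ordering ILP carries O(|V|) integer order variables and one
  constraint per arc; it is exact but not tuned for graphs beyond a few
  thousand vertices post-compression. No lazy cycle-constraint generation
  is implemented.
* The exhaustive oracles are capped at 15 vertices by design.
* Weighted compression requires strictly positive weights; with zeros the
  pipeline falls back to the safe rules and the compressed instance handed
  to the ILP is larger.
* The published interactome benchmark can be re-run only when its
  distribution files are supplied (`fvsnet.replication`); nothing in this
  repository substitutes for them.
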