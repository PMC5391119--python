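# Methods

## Problem and model

The input is an H-description: m half-spaces Hᵢ = {x ∈ ℝⁿ : aᵢ·x ≤ bᵢ},
i ∈ I = {0, …, m−1}, whose intersection P is assumed bounded and of full
affine dimension (hence m > n). The output is the skeleton graph
G(P) = (V, E): V is the set of extreme points and {p, q} ∈ E when the
minimal face containing p and q is a segment. A feasible point p (slack
vector s(p) = b − Ap non-negative) is extreme iff its active rows
{aᵢ : i ∈ Z(p)} have rank n; its degeneracy is σ = |Z(p)| − n.

The method runs, per vertex, in three stages:

1. **Base cone.** A basis B ⊆ Z(p) (rank n) describes a regular cone
   containing the vertex cone; its n extreme rays are the negated
   biorthogonal companion of B, obtained by solving A_B R = −I and
   normalizing columns to primitive integer vectors.
2. **Incremental slicing.** The half-spaces B′ = Z(p) \ B are inserted one
   at a time. Inserting aₖ partitions the current rays by the sign of aₖ·ρ
   into inside / on-hyperplane / outside sets (X⁺, X⁰, X⁻); survivors are
   X⁺ ∪ X⁰, and each colaminar pair (ρ′, ρ) ∈ X⁻ × X⁺ contributes the ray
   φₖ = (aₖ·ρ′)ρ − (aₖ·ρ)ρ′ on the cutting hyperplane. The pair (J, X_J) of
   processed constraints and current rays is a double description of the
   partially sculpted cone throughout.
3. **Pivoting and traversal.** Each final ray is followed to its nearest
   blocking hyperplane (min-ratio step), yielding the neighbours; a FIFO
   breadth-first queue over vertices assembles (V, E), admitting a vertex
   only if it is neither scanned nor already queued.

## Colaminarity tests, record, rejection

Two equivalent 2-face tests are implemented and cross-checked:

- *algebraic*: rank{aᵢ : i ∈ J|ρ ∩ J|ρ′} = n − 2;
- *combinatorial*: no third current ray is tight on the whole joint set.

The improved slicer maintains a record L of unordered ray pairs known to be
colaminar. It is seeded with all pairs of the base cone (in a regular cone
every pair spans a 2-face), consulted before testing, and updated when a
cut destroys a recorded pair: the dying ray is replaced by the new ray it
spawned. Pairs whose joint active set has fewer than n − 2 elements are
rejected without any test (necessary condition). Entries naming a ray that
died in the current cut are dropped at the end of each insertion; this
keeps L sound — auditable against the current cone — at negligible cost.
A pair found in the record creates its new ray without re-testing and the
replacement entry covers the surviving 2-face; no additional entry is
needed on that path.

New rays' active subsets are recomputed by direct dot products over
J ∪ {k} rather than by set union of the parents' subsets, so coincidental
incidences in highly degenerate systems are captured; this matters because
later colaminarity decisions read those subsets.

`test="auto"` (the default of `skeleton_graph`) times both tests on the
first vertex's cone and keeps the faster for the rest of the run; which one
wins is input-dependent (dense connectivity tends to favour the
combinatorial test, sparse the algebraic one).

## Arithmetic

All quantities are exact rationals. This is a deliberate design decision,
not an optimization: the partition of rays, the activity of a constraint,
and every rank are zero-tests, and a floating tolerance would make the
combinatorics of degenerate inputs depend on ε. Consequences:

- Rays are canonicalized to primitive integer vectors (denominators
  cleared, content 1, orientation kept), which makes ray identity, record
  keys and deduplication exact. Vertices are keyed by their exact
  coordinate tuples.
- Rank uses integer-scaled rows and Gaussian elimination modulo the
  Mersenne prime 2⁶¹ − 1 whenever the product of the rows' squared
  Euclidean norms is below (2⁶¹ − 1)² — by Hadamard's inequality no minor
  can then be a nonzero multiple of the prime, so the modular rank equals
  the rational rank. Otherwise it falls back to exact rational
  elimination. The fast path covers all small-coefficient systems, where
  basis enumeration performs tens of thousands of rank computations.
- Duplicate new rays from distinct pairs cannot arise with exact tests; a
  counter asserts this (it is checked to be zero in the tests).

## Start vertex, basis, order

Conversion needs one extreme point to start. `skeleton_graph` accepts an
explicit point (tightened to a vertex if it is merely feasible), else tries
the origin, else tightens a supplied interior point. Tightening walks along
a null-space direction of the active rows (first basis vector of the
reduced null space, flipped if unblocked) to the nearest blocking
hyperplane; each step adds an independent row, so it terminates within n
moves and is deterministic.

The default basis of an active set takes the lowest indices that greedily
increase rank, and inserts the complement in ascending order. Both choices
only affect speed, never the result: the tests sweep all 720 insertion
orders at the worked example's origin cone, all bases × orders on a small
Birkhoff cone, and random basis/order overrides on whole conversions, and
always recover the identical ray sets and graphs. For hard degenerate
inputs the spread of CPU time across orders can exceed 2×; no dynamic
reordering is attempted (exploration costs more than it saves), but
`order_fn` / `basis_chooser` hooks allow callers to impose a schedule found
on a sample of vertices.

## Parameters that matter

| parameter | where | default | meaning |
|---|---|---|---|
| `test` | `skeleton_graph`, `slice_cone` | `auto` / `algebraic` | 2-face test selection |
| `use_record` | same | `True` | 2-face record + rejection pre-test |
| `cap` | `enumerate_bases` | 10⁶ | refuse C(|Z|, n) enumerations beyond this |
| `diameter_cap` | `compute_metrics` | 4000 | skip all-pairs BFS beyond this |V| |
| `precision` | `gen_random_regular` | 10⁶ | denominator of rationalized sphere points |
| `allow_unbounded` | `skeleton_graph`, `neighbors` | `False` | skip receding rays, mark graph partial |

## Generators and what they emulate

- `gen_ns_example()` is the exact 24 × 14 bipartite no-signaling system
  (binary inputs, 3 × 2 outcomes) used throughout the documentation; its
  origin is a σ = 6 vertex and its skeleton has 108 vertices and 1548
  edges with degrees 16 (×72) and 54 (×36).
- `gen_birkhoff(l)` builds the Birkhoff polytope of l × l doubly-stochastic
  matrices in the reduced coordinates left after eliminating the last row
  and column: n = (l−1)², m = l² non-negativity constraints on the
  completed matrix. Vertices are the l! permutation matrices; the skeleton
  diameter is 2 for l ≥ 4 (for l ≤ 3 the skeleton is complete, diameter 1).
- `gen_random_regular(n, m, seed)` draws m tangency points on the unit
  sphere and uses the tangent hyperplanes as constraints. Points are drawn
  over the *whole* sphere — sampling only the positive orthant leaves the
  intersection unbounded — and rationalized at denominator 10⁶ so the
  exact kernel applies; boundedness is verified by 2n linear programs and
  the draw repeated if needed. Such systems are regular (all σ = 0) except
  on a measure-zero set; the shipped seeds are asserted regular in the
  tests. Rationalization makes "probability 1" into "up to measure-zero
  accidents at 10⁻⁶ resolution", which the determinism of fixed seeds
  renders reproducible either way.
- `gen_classic` provides the cube, simplex and cross-polytope with known
  skeletons; the cross-polytope has σ = 2ⁿ⁻¹ − n at every vertex and
  exercises degeneracy independently of the no-signaling example.

Synthetic inputs emulate the *combinatorial* regimes (regular, moderately
degenerate, extremely degenerate) of real constraint-based models; they do
not emulate ill-conditioned or nearly-degenerate numerics, which exact
arithmetic sidesteps entirely, nor input sizes where |V| outgrows memory.
Passing tests therefore certify combinatorial correctness, not performance
on inputs orders of magnitude larger.

## Sizes used in the shipped checks

The test suite and the acceptance script run the full 24 × 14 worked
example (108 vertices, ~4 s), the Birkhoff polytopes up to l = 4
(24 vertices), random regular systems up to m = 10 in n = 3, and the
exhaustive C(20, 14) = 38 760 basis enumeration (~4 s). Exhaustive oracle
comparisons enumerate all C(m, n) square subsystems and are limited to
fixtures with m ≤ 12. Birkhoff l = 5 (120 vertices) runs in seconds but
adds no new regime, so it is not part of the default suite.

## Degenerate and edge inputs

- Unbounded feasible regions violate the model's compactness assumption; a
  ray with no blocking hyperplane raises `UnboundedError` naming the ray,
  or with `allow_unbounded=True` the ray is skipped and the graph marked
  partial.
- Equality (`linearity`) blocks in `.ine` files are rejected with a clear
  error: the polytope is assumed full-dimensional.
- Repeated or positively-scaled duplicate constraint rows are harmless:
  rank decisions see through them, and the greedy basis chooser skips
  dependent rows.
- Ties in the min-ratio step simply mean the neighbour is itself
  degenerate; only the value of λ is used, so no tie-breaking is needed.

## Known limitations

- Pure-Python exact arithmetic: conversion cost grows with coordinate bit
  length; random-regular systems with 10⁶-scale coefficients are noticeably
  slower per vertex than small-integer systems.
- The traversal keeps V, E and the per-vertex metadata in memory; there is
  no on-disk spilling, and no parallelism.
- V-representation input (`.ext`) and equality constraints are out of
  scope, as are simplex-tableau pivoting baselines and graph entropy or
  similarity measures of the output.
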