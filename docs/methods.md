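# Methods

## Tensor representation

A temporal network is a stream of timestamped undirected contact events
`(t, i, j)`.  Events are binned into consecutive half-open intervals
`[t0 + mΔ, t0 + (m+1)Δ)`; the number of slices is
`S = ceil((t_max − t0 + 1)/Δ)`.  Slice `m` is a binary adjacency matrix: a
link is present iff the pair had **at least one** contact in the interval
(a weighted variant counting contacts exists behind a flag but binary is
the default).  The node axis order is the lexicographically sorted node-id
registry, so identical inputs produce byte-identical tensors regardless of
file order.  Self-loops and exact duplicate events are dropped, with counts
kept on the parsed network.  Δ defaults to 780 s (~13 minutes), a scale at
which social-schedule structure (lessons, breaks) is visible while slices
stay dense enough to carry signal; it is a required knob for any serious
analysis.  All intervals between `t0` and `t_max` are kept, including empty
ones (e.g. overnight gaps): empty slices are informative zeros for the
activity timelines, not missing data.

## Factorization

The tensor is approximated by a rank-R non-negative CP model
`T ≈ Σ_r a_r ∘ b_r ∘ c_r`, fitted by minimizing the Frobenius residual.
Unfoldings follow the cyclic layout (mode 1: `I×(J·K)` with column index
`j + J·k`, modes 2 and 3 cyclically), under which
`T_(1) = A(C⊙B)ᵀ`, `T_(2) = B(A⊙C)ᵀ`, `T_(3) = C(B⊙A)ᵀ`.

One ANLS sweep updates A, then B, then C by solving each matricized
sub-problem *exactly* under non-negativity.  The row-wise NNLS solver is
block principal pivoting on the normal equations (passive-set exchange with
the standard safeguard: full exchange while the infeasibility count
decreases, then a bounded number of backup full exchanges, then
single-variable exchange at the lowest infeasible index, which is finite
and deterministic); if pivoting fails to settle, the row falls back to the
Lawson–Hanson active-set solver.  Exact block solves make the objective
monotone non-increasing, and the sweep raises if it ever increases by more
than 1e-10 relative — a deliberate solver-bug tripwire, not a tolerance to
tune.  Zero columns in a Khatri–Rao design fix the corresponding
coefficient at 0 with a warning.

Defaults: `n_runs = 20` random restarts, `max_iter = 500` sweeps,
convergence when the relative objective change drops below `tol = 1e-7`.
These are artifact choices (reasonable for networks of hundreds of nodes),
all configurable.  Initialization is i.i.d. uniform(0,1) entries scaled by
`mean(T)^(1/3)`, which matches the magnitude of the data while staying
non-negative and unstructured.  Restart `k` of master seed `s` draws from
`default_rng([s, k])`, so any run list is reproducible from `(seed, index)`.

Symmetry of A and B is **not** enforced for undirected input; it emerges at
convergence, and the solver records the asymmetry
`‖A_n − B_n‖_F/‖A_n‖_F` on unit-normalized columns as a convergence
sanity check.  A factor column that collapses to all-zero is re-seeded once
from uniform noise; a second collapse leaves it at zero and flags the
component index on the model.

## Model quality and selection

For fixed factors, the least-squares Tucker core is
`G = T ×₁ A⁺ ×₂ B⁺ ×₃ C⁺` (pseudoinverses with singular values below
`max(shape)·ε·σ_max` truncated; rank deficiency is flagged, not fatal).
Core consistency is `100·(1 − Σ(g_def − i_def)²/R)` against the unit
superdiagonal cube: 100 for a perfectly fitted CP model with
full-column-rank factors, decaying — possibly below zero, reported
unclamped — as components turn redundant.  Component relevance is
`r_k = ‖a_k‖·‖b_k‖·‖c_k‖` on the raw factors; it is invariant under the CP
scaling indeterminacy.  A decomposition is scored by the **sum** of its
relevances by default (a product mode is available; with components of
heterogeneous size the sum is the less brittle aggregate, as one
near-empty component zeroes a product).

Run selection is two-stage: sort restarts by core consistency, keep the top
`keep_cc = 10`, re-rank those by decomposition score, keep the top
`keep_score = 5`; ties break by run seed.  The model-order sweep tabulates
this per R and deliberately makes **no** automatic choice of R: the table
(both the CC-ranked and score-re-ranked views) is for locating the
crossover between the ~100 plateau and the redundancy drop, with CC ≈ 90
the conventional acceptability reference.

## Interpretation

Membership binarization is scalar 2-means per column of A (B-based and
averaged variants selectable): centers initialize at the column min and
max, Lloyd iterations run to a fixed point (≤ 100, scalar 2-means converges
in a handful), equidistant points join the lower cluster, and the
high-center cluster are the members.  This is deterministic, invariant
under positive rescaling of the column, and returns the empty set for
all-zero columns (max ≤ 1e-9).  Overlap is allowed and expected: a node may
belong to several components or none.

Activity strength combines the time factor with the community's overall
membership mass: `s_k(t) = c_tk · Σ_i a_ik`.  A normalized variant
(unit-norm columns with the absorbed weight `r_k`) is available when
comparing components across decompositions with different raw scalings.

## Validation

Components are matched to ground-truth classes through the vector of
Jaccard overlaps between the component's member set and each class,
restricted to students (teachers have no unambiguous class and are excluded
from matching and recall, though they do count in component sizes).  A
component matches iff **exactly one** class has non-zero overlap — strict
on purpose: any cross-class contamination, however small, voids the match.
"Non-zero" is exact set overlap, no epsilon.  Recall is
`covered / class_nodes` over the matched classes; if several components
match one class, coverage counts the union of their members.  Score
matrices `S = PᵀQ` project any binary node-community table (including one
produced by an external community detector) onto the classes; the reference
`PᵀP` is the diagonal matrix of class sizes.

Co-location series are element-wise products of the members' location
fingerprints per (receiver, interval) — non-zero iff *every* member
registered packets there and then.  Raw products are the default; binarized
(AND) and log-domain variants exist because the product over a large
component of O(λ) counts spans hundreds of orders of magnitude.

## The planted benchmark

The generator emulates the structure the method targets: disjoint groups
with per-interval Bernoulli activity schedules (interval-wise independent —
the simplest model of scheduled activity that imposes no temporal
continuity, matching the method's own agnosticism), within-group contact
probability `p_in` per active interval, uniform background noise `p_noise`
per pair-interval, and scheduled mixed-group events linking all pairs among
the participating groups' members with `p_event` at a named location.
Fingerprints place members of an active group at their home receiver and
event participants at the event receiver, with counts `1 + Poisson(λ−1)`,
λ = 5: a node whose presence was detected has by construction at least one
received packet, which also keeps planted co-location products strictly
positive where they should be.

The bundled school-day preset uses 10 groups of 6 nodes, 40 intervals,
`p_class_active = 0.7` outside a 4-interval lunch break, `p_in = 0.4`,
`p_noise = 0.001`, and one lunch gathering of the first 4 groups at
`p_event = 0.5` in the cafeteria — within-class contact odds high enough to
resemble a primary-school classroom at ~13-minute resolution, with the
gathering clearly present but noisier than class-time structure.  The
fixture seed (11) is part of the benchmark definition; solver seeds vary
freely.  These sizes keep the full pipeline (R = 11, 10 restarts) at a few
seconds on one CPU, which is the scale used throughout the test suite.

What the benchmark does *not* emulate: realistic heavy-tailed contact-
duration and inter-contact statistics, degree heterogeneity within groups,
gradual activity ramps, sensor dropout, or mobility between receivers
within an interval.  Passing the recovery tests therefore demonstrates the
correctness of the machinery (tensor building, solver, diagnostics,
matching) under clean planted conditions, not performance guarantees on
empirical sensor data, where membership-weight distributions need not
separate cleanly into two clusters.

## Numerical choices and degenerate inputs

- NNLS feasibility tolerance 1e-12; KKT residuals of returned solutions are
  ≤ 1e-8 (tested against exhaustive active-set enumeration).
- Pseudoinverse cutoff `max(shape)·ε·σ_max`, flagged when a factor is
  rank-deficient.
- Zero tensor: factors collapse to zero in one sweep; relative fit is
  undefined (error) for a zero tensor.
- All tabular writers print floats with `%.17g`, so write→read round trips
  are bit-exact for IEEE doubles.
- The tie in scalar 2-means (point equidistant from both centers) goes to
  the lower cluster; block-pivot cycling resolves at the lowest infeasible
  index — both chosen to pin down determinism, not for statistical reasons.

## Known limitations

Dense tensors only: memory is `O(N²S)`, comfortable for hundreds of nodes
and a few hundred intervals, not for `N ≫ 10³`.  Three-way tensors only; no
missing-data masking; no projected-gradient solver; no directed-network
in/out membership reporting.  The factorization is non-convex — multi-
restart selection mitigates but cannot guarantee global optimality, which
is precisely why core consistency and the selection protocol are part of
the package rather than an afterthought.
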