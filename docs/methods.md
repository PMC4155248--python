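# Methods

## Landscape model

A discrete energy landscape is the triple (X, E, M): a finite state set, an
energy function, and a symmetric move set. Two concrete instantiations are
provided.

**RNA landscapes.** States are the secondary structures of one sequence:
nested sets of canonical pairs (A-U, G-C, G-U), at most one pair per base,
hairpin loops of at least `min_loop` (default 3) unpaired bases. Moves add
or remove exactly one base pair; the normalization constant Δ equals the
number of admissible pairs of the sequence, which the open chain attains
and no structure exceeds. State enumeration is a breadth-first traversal of
the move graph from the open chain (every valid structure is reachable by
pair additions); an optional energy bound restricts it to bound-respecting
reachability, and a configurable state cap (default 5·10⁶) turns runaway
enumerations into explicit errors.

**Toy landscapes.** An explicit graph with per-state energies; Δ is the
maximum vertex degree. These are the hand-checkable oracle substrates; the
canonical fixtures are the 3-state path L1 (energies 0, 2, 1) and the
5-state path L2 (0, 3, 1, 2, 0.5), for which every downstream number can
be verified by hand.

**Degeneracy.** All comparisons of states use the strict total order
(energy, string encoding) with byte-wise comparison of the dot-bracket
(resp. state-id) string. This makes the steepest-descent neighbor — and
hence the gradient-basin map F — single-valued on energy plateaus, makes
local minimality well defined in degenerate landscapes, and fixes which
endpoint of an equal-energy boundary edge counts as the "higher" one.

## Energy backends

* `simple`: E(s) = Σ over pairs of −3 (G-C), −2 (A-U), −1 (G-U), arbitrary
  units, open chain exactly 0. Deterministic and dependency free. This is
  **not** the Turner nearest-neighbor model; landscapes built with it have
  qualitatively different statistics (e.g. the open chain is not a local
  minimum because every pair addition lowers the energy, and local minima
  are exactly the maximal structures).
* `nn`: full nearest-neighbor free energies in kcal/mol through the
  ViennaRNA bindings (default 37 °C); values are rounded to 0.01 kcal/mol
  (the native parameter resolution) and the binding version is recorded in
  every output. A missing binding raises a capability error; there is no
  silent fallback.

Default β is 1 for `simple` (arbitrary units) and 1/kT₃₇ ≈ 1.6225 mol/kcal
for `nn`.

## Decomposition algorithms

`brute_force_macromodel` enumerates X, assigns every state by an explicit
(memoized) gradient walk, accumulates Z_b, basin sizes and energy ranges,
and adds Δ⁻¹·w(higher endpoint) to Z{b,c} once per boundary micro-edge.

`barriers_flood` processes states in ascending total order; a state's basin
is a dictionary lookup of its steepest-descent neighbor's basin. States
whose lower neighborhood touches k ≥ 2 previously disconnected basin
components emit k−1 merge events at the state's energy (union-find over
basins, components represented by their order-lowest minimum; when several
states at one flood level could merge the same pair, the first in total
order records the saddle). The merge events define the barrier tree; the
pairwise saddle-energy matrix is materialized lazily from the merge replay.
With an energy bound, basins connected only above the bound remain separate
components (a forest).

`local_flood` floods one basin b from its minimum: a heap-ordered candidate
set T (stdlib heapq, push-guarded against duplicates) is popped in
ascending total order; a popped x is a member iff its steepest-descent
neighbor is already in the member set D. Members push their higher-ordered
neighbors and account boundary edges to lower non-members; non-members
account boundary edges down into D. F of non-members is an explicit
gradient walk with a bounded memo cache (default 10⁶ entries; a pure speed
device). The per-basin memory footprint is members + distinct non-member
contact states (candidates that fell outside b, plus boundary partners of
members), relative to |X|.

`discover_landscape` chains local floods: each flood's boundary names the
adjacent minima, which are queued until the component is exhausted.
Because Z{b,c} is computed independently from both sides, the two values
must agree within 1e-6 relative (a built-in consistency assertion; the
value from the order-earlier basin is stored). Floods are independent
tasks; with `workers > 1` a thread pool executes each batch, and the final
deterministic sort makes the output independent of worker count and
exploration order.

## Kinetics

All chains are discrete-time and row-stochastic with self-loops; the
diagonal completes each row and must stay non-negative (violations raise).

* exact: q(b→c) = Z{b,c}/Z_b (detailed balance w.r.t. Z_b by construction);
* barrier: a(b→c) = A·exp(−β(E(b,c) − E(b))) for **all** ordered pairs,
  E(b,c) the barrier-tree saddle; `A = "auto"` sets
  A = 0.99 / max row sum at A = 1, keeping diagonals positive. FPT ranks
  are provably invariant to A (scaling all off-diagonals by c scales all
  FPTs by 1/c), so the rank-based comparison is A-free;
* merged: barrier values masked to the exact adjacency, separating the
  Arrhenius model's loss of precision from its loss of topology.

First-passage times solve (I − Q_restricted)τ = 1 with the target removed;
starts that cannot reach the target get τ = ∞, and such targets are
excluded (with counts) from Spearman inputs. For model comparison from a
single start basin to all targets, solving one absorbing system per target
is O(|B|⁴); above 400 basins `compare_models` switches to a
fundamental-matrix route: for the reversible chains built here (stationary
weights Z_b for the exact chain, e^{−βE(b)} for barrier/merged), one
Cholesky factorization of the symmetrized I − P + 1πᵀ yields diag(Z) and
the start row, hence τ(start, t) = (Z_tt − Z_start,t)/π_t for every t at
O(|B|³) total. The two routes agree to ~1e-14 relative on test landscapes,
and the symmetrized solve is performed in place (the peak working set is
three |B|² matrices). Spearman correlations use average ranks for ties
(scipy) after dropping non-finite pairs; fewer than two usable pairs or
zero rank variance is an error, surfaced as `null` in CLI reports.

## Synthetic data

* `chain_landscape` — deterministic path graphs (the worked fixtures);
* `random_toy_landscape` — connected random graphs (random spanning tree
  plus extra edges to a target mean degree), energies uniform with ties
  nudged apart at 1e-9 so that oracle tests and tie-break tests exercise
  separate code paths; fully seeded;
* `random_rna_set` — i.i.d. uniform-composition sequences, `per_length`
  per length (default protocol: 10 per length, 25–35 nt). This reproduces
  the *distribution* of such panels, not any particular historical sample.

What the generators do not emulate: the Turner model's destabilizing terms
(so simple-backend landscapes have far more, and shallower, minima than
nearest-neighbor landscapes of the same length), sequence families with
designed structure, and lengths beyond exhaustive-enumeration reach.
Passing tests therefore certify the algorithms and their mutual
consistency, not thermodynamic accuracy for any biological RNA — for that,
run the `nn` backend.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
whole pipeline (three independent decomposition routes per landscape) stays
exact and cross-checkable: fixture sequences up to 20 nt (≤ ~2300 states),
50 random toy landscapes up to 2000 states, a fixed 10-sequence 25-nt panel
(simple backend, seed 1234; up to ~66 000 states / ~12 000 basins) for the
directional model comparison in the suite, and 22-nt/20-nt panels in the
acceptance script. Full nearest-neighbor landscapes of 30+ nt (tens of
millions of states) are supported by the same code paths via the CLI but
are multi-hour computations.

Tolerances: oracle equivalence 1e-9 relative (measured ~1e-15); two-sided
Z{b,c} agreement 1e-6 relative; chain row sums 1e-12; FPT recursion
residual 1e-8. Toy TSV and artifact floats are serialized with 12
significant digits, which round-trips the quantities the pipeline consumes.

## Known limitations

* Single add/remove move set only (no shift moves, no pseudoknots, no
  lonely-pair prohibition).
* Discrete-time chains; no continuous-time master-equation integration.
* The Arrhenius/merged comparison needs the barrier tree, i.e. a global
  flood; `--mode explore` alone supports the exact chain only.
* Memory accounting counts states, not bytes; `|T(b)|` is defined here as
  distinct non-member contact states (see docstrings), one of several
  defensible readings of a to-do-set footprint.
* Basins whose connections lie above an energy bound are reported
  unmerged; saddle queries across components raise.
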