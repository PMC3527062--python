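# Methods

## Distance model

The distance is defined on adjacency sets, not on genome structures. With
duplicate genes several structurally different genomes share one adjacency
set, so the value computed here is a lower bound on any structure-level
distance; `realize_genome` returns one (deterministic) structure per
multiset and makes the ambiguity explicit. Operations are unit-cost DCJ,
single-gene insertion and single-gene deletion; duplications are ordinary
insertions of an existing family. Multi-gene (block) indels and
length-dependent costs are out of scope.

Every optimal transformation uses exactly `|T1|` deletions and `|T2|`
insertions, where `T1`/`T2` are the ghost adjacencies built from the
per-family copy-number surpluses. Ghosts are paired head-with-tail within
their own family: the operations that consume them act on one gene at a
time, so cross-family pairing would produce unusable ghosts. When a family
has surplus above one, any within-family pairing is equivalent; the
implementation fixes the deterministic one (sorted order).

## Capping

Telomere `x` becomes the adjacency `x τ`; the side with fewer telomeres
(`2k_i` of them on side i) receives `|k2 - k1|` null adjacencies `τ τ`.
Capping preserves the distance and leaves a graph whose decompositions are
cycles only, which is what the packing step needs. Capping is applied
symmetrically (whichever side is poorer is padded). Capped elements carry
an origin tag `null-cap` distinct from `ghost`, so ghost counting never
sees τ-bearing elements.

Recovery removes every matched τ–τ slot pair, drops `τ τ` elements and
restores `x τ` to the telomere `x`. A cycle with `t` τ-edges splits into
one path per surviving arc. For an optimal decomposition this is
value-preserving; for an arbitrary completion it can only help: a cycle
with `t` τ-edges whose arcs contain `o_c` odd paths saves
`(t + o_c)/2 - 1 ≥ 0` operations. The reported `distance`, `n`, `c`, `o`
therefore always refer to the *recovered* decomposition, so
`distance = n - c - o/2` holds exactly and equals the scenario length; the
capped view is echoed as `n_capped`/`c_capped`.

## Packing

Candidates are all helpful cycles of length 4 **and** length 2 (identical
ghost-free left/right element pairs), deduplicated by covered element set.
Packing 2-cycles jointly is a deliberate design choice: with duplicates an
optimal decomposition may owe most of its value to 2-cycles, and a maximum
packing of 4-cycles alone can pay for them twice (a factor-2 outcome on
concrete instances). With both lengths in the pool, a maximum disjoint
selection `S` satisfies `|S| ≥ s + p` against an optimum with `s`
2-cycles, `p` 4-cycles and `q` longer helpful cycles, and since
`n ≥ s + 2p + 3q` the output `n - |S|` is within factor
`1 + q/(p + 2q) ≤ 1.5` of `n - s - p - q`.

Modes:

* `exact` — branch-and-bound maximum independent set on the candidate
  conflict graph (bitmask sets, greedy absorption of conflict-free
  candidates, cardinality bound). Refused above 512 candidates.
* `greedy_local` — seeded greedy (2-cycles first, then 4-cycles) improved
  by replace-one-with-two local swaps (`swap_radius ≥ 1`). No ratio
  guarantee, used for large inputs.
* `auto` (default) — exact for ≤ 24 candidates, greedy otherwise.

Completion first pairs remaining identical elements into 2-cycles
(non-ghost pairs preferred, which are helpful), then matches leftover slots
label by label in sorted order; balance of the capped graph guarantees this
always yields a valid decomposition. All helpful cycles of the *completed*
decomposition count toward the distance, never fewer than the packing
alone.

## Exact oracle

The oracle maximizes `c + o/2` by depth-first search over label-preserving
slot bijections. Components are scored as they close (union-find with
rollback tracking length, ghosts and telomeres per component). Two
prunings keep it practical: an admissible bound of one future helpful
cycle or odd path per left element that still has a free slot, and
skipping isomorphic choices among untouched identical right elements. The
search is seeded with the approximation algorithm's own decomposition. The
default size cap is 48 extremity slots per side — roughly 6 families at
copy number 3 with capping — and is configurable; above it the oracle
refuses rather than stall. The same search run on the *uncapped* graph
(telomeres kept, paths allowed) provides an independent route used to test
that capping preserves the distance.

## Scenarios

Each recovered component is sorted locally, in the order deletions →
insertions → DCJs:

* a ghost on the right side is consumed by one deletion merging its two
  left neighbours (telomere variants included);
* a ghost on the left side is consumed by one insertion that
  simultaneously completes one of its right neighbours, shrinking the
  component by two edges. Chains of ghosts are processed from an end
  adjacent to a real element; a cycle whose left side is entirely ghosts
  is bootstrapped by inserting a first gene from nothing, and a ghost
  chain spanning to a path end inserts the gene as a telomere pair. Both
  special moves are last resorts — used eagerly they would cost one
  operation above the budget;
* the ghost-free remainder is resolved by DCJs splitting off one finished
  2-cycle (or 1-path) each. With duplicates a cut-and-rejoin can reproduce
  an equal multiset (a legal DCJ that changes structure but not the
  adjacency set); rotations are scanned so such degenerate moves are
  emitted only when no alternative exists, keeping the count law intact.

The resulting scenario has exactly `|T1|` deletions, `|T2|` insertions and
`distance` operations in total; `verify_scenario` replays it step by step,
checks each operation against the rewrite schemas, and compares the final
multiset with `S2`.

## Simulator

`random_genome` draws per-family copy numbers from a truncated geometric
(`copy_rate` expected extra copies, default cap 2 extra so the oracle
stays feasible), shuffles the copies into a requested number of
chromosomes and assigns uniform signs and topologies
(`circular_fraction`). Histories are sampled at the adjacency-set level —
each step instantiates one rewrite schema on the current multiset — and
realized back into a genome, so the history length is an upper bound on
the true distance by construction. Deletions pick any present family;
insertions duplicate an existing family with probability 1/2, otherwise
invent a fresh label, exercising both ghost directions.

What the generator does not emulate: realistic rearrangement length
distributions, birth–death family dynamics, rate heterogeneity along the
genome, or orthology-assignment noise. Passing tests demonstrate
correctness of the combinatorics on uniform random instances, not
biological realism of the histories.

## Test-suite problem sizes

The acceptance suites use 200 instances with ≤ 6 families and copy number
≤ 3 (seeded 0–199, histories of 1–5 operations) for the ratio and
upper-bound checks, 1000 duplicate-free pairs (4–8 families) for the
classic-DCJ equivalence, and 150 low-circularity instances for the capping
invariance; these sizes keep every instance within the oracle cap while
covering all component shapes (ghost cycles on either side, τ paths of all
three recovery cases, double edges). The whole suite runs in seconds.

## Numerical and degenerate-input notes

Everything is exact integer combinatorics; there are no tolerances. Empty
genomes (no chromosomes), single-gene circular chromosomes (`{g_h g_t}`
adjacencies), palindromic adjacencies (`{x, x}` with equal labels) and
multi-chromosome mixes are all legal inputs with defined behaviour.
Determinism: element ordering is canonical (origin, slots, position), all
randomized steps (greedy shuffles, simulator) take explicit seeds, and
identical invocations produce byte-identical CLI output.
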