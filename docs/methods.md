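# Methods

## Model and problem

The input is a set `R = {R_1, …, R_m}` of aligned haplotype sequences
("recombinants") of equal length `n` over an alphabet encoded as
`[0, σ−1]`. A *founder set* is a set of length-`n` strings such that
every recombinant can be written as a concatenation of founder
substrings (a mosaic); a switch between founders is a *crossover*.
Restricting all crossovers to a common set of segment boundaries turns
founder reconstruction into the *minimum segmentation* problem: tile
`[1, n]` with segments of length ≥ `L` minimising the maximum per-segment
number of distinct substrings `|R[a, b]|`. The optimum `M(n)` equals the
founder count; `L` trades founder-set size against fragmentation (larger
`L` forbids rapid switching, hence needs more founders).

Unconstrained founder reconstruction (crossover positions free per row)
is NP-hard to approximate; the segmentation relaxation is what this
package solves exactly.

## The streaming solver

The quadratic reference recurrence is

```
M(k) = +∞                                        k < L
M(k) = |R[1, k]|                                 L ≤ k < 2L
M(k) = min_{0 ≤ j ≤ k−L} max(M(j), |R[j+1, k]|)  k ≥ 2L
```

with `M(0) = 0` (`dp_naive`; its distinct counts come from leftward
partition refinement, `O(m)` per window extension, fully independent of
the pBWT machinery).

The streaming solver (`solve`) exploits two facts about the positional
BWT divergence array `d_k`:

1. the window starts `j` where `|R[j, k]| ≠ |R[j+1, k]|` are exactly the
   values `d_k[i] − 1` falling in `[1, k−1]` — at most `m` of them; and
2. with `s_k` the sorted distinct values of `d_k` and `t_k` their
   multiplicities, suffix sums of `t_k` give `|R[s_k[j]−1, k]|` directly.

The inner minimisation therefore only needs, per run of constant
cardinality, the minimum of `M` over that run — maintained incrementally
in the array `u_k` (with the attaining positions `umin_pos` for
backtracking). Per column the update is: append boundary `k+1`; rebuild
the permutation by one stable counting-sort pass keyed on the new
column, recomputing `e_k` (the index of each row's divergence value in
`s_k`) via range maxima — valid because `e` is order-isomorphic to `d`;
recount `t`; drop vanished `s` entries, folding their `u` minima into the
following interval; finally fold in `M(k−L)`, which became a legal
predecessor this column. `M(k)` is then `min_j max(cards[j], u[j])` over
at most `m` entries.

Range maxima inside the counting-sort pass use the path-compressed
jump-pointer scan (`maxd`, amortised `O(m log σ)` per column; the default
and the production path) or a per-column sparse table (`pbwt_extend_rmq`;
`O(m log m)` build, kept as an independent second route). Both must agree
exactly with the definitional oracle `pbwt_naive`, and the test suite
enforces this at every column of randomised panels.

Only the last `L` values of `M` are retained (a `deque` of maxlen `L`);
together with the boundary arrays the working state is `O(m + L)`
integers beside the length-`n` backtracking array. The solver records
`peak_M_buffer` and `peak_state_ints` so the space contract is asserted,
not assumed.

## Numerical and tie-breaking choices

* Infinity is the integer sentinel `m + 1`; all finite values are ≤ `m`,
  so min/max arithmetic stays in integers.
* `dp_naive` breaks ties by the leftmost predecessor `j` (including the
  single-segment option `j = 0`). The streaming solver picks the leftmost
  winning `s`-interval and, inside it, the leftmost position attaining
  the interval minimum. These rules need not select the same optimal
  segmentation (the streaming recurrence never revisits `j = 0` for
  `k ≥ 2L`, which is safe for the value since `|R[j+1,k]| ≤ |R[j,k]|`):
  the package guarantees equality of the optimum and validity of the
  returned segmentation, which is what the tests assert.
* Fragments within a block are ordered by first occurrence (smallest row
  index); duplication visits fragments by decreasing occupancy (ties by
  smallest contained row); greedy matching breaks weight ties
  lexicographically. All pipelines are deterministic given a seed.
* Degenerate inputs: `m = 1` yields one founder; an all-monomorphic panel
  compacts to zero columns and short-circuits with a single founder;
  `L > n` (or `L < 1`) raises `InfeasibleError`.

## From segmentation to founders

Each segment's distinct substrings partition the rows by occupancy.
Blocks with `k < M(n)` fragments are padded: visiting fragments by
decreasing occupancy `|x|`, fragment `x` gains
`ceil(|x|/m · (M(n) − k))` extra copies, stopping (and clamping the last
increment) once the total reaches `M(n)`; copies share the original's
occupancy. Gluing fragments of adjacent segments is the Maximum
Intersection Between two Partitions problem with weights
`w(x, y) = |occ(x) ∩ occ(y)|`; a glued pair forces `m − w` crossovers.
Per boundary (independently, no lookahead) the package offers:

* `random` — a seeded uniform permutation (baseline);
* `greedy` — heaviest available pair first, built from the at-most-`m`
  nonzero weights found by row co-occurrence counting; at least half the
  optimal weight;
* `perfect` — exact maximum-weight perfect matching via
  `scipy.optimize.linear_sum_assignment`.

Per-boundary crossovers are `size·m − total_weight`; tests verify the
perfect route against permutation brute force (sizes ≤ 6) and the 1/2
bound for greedy.

## Parsing and reporting

`greedy_parse` scans a sequence left to right keeping the set of founders
matching the current stretch; when the set would empty it counts one
crossover and restarts there. Maximal-stretch extension is optimal
(minimum crossovers); the tests confirm this against a minimum-switch DP
over (position, founder) and full enumeration at tiny sizes. Note the
reported breakpoint is the first *mismatching* position, which can trail
the mosaic's nominal boundary when adjacent fragments coincide past it.

Statistics follow the usual founder-panel reporting: per-row crossover
counts (mean/median), average distance between recombinations
(`original_length / mean count`; the full length when nothing
recombines), and segment lengths mapped back to original coordinates.

## Coordinates and compaction

Monomorphic columns never create boundaries, so the pipeline drops them
before segmenting (`--no-compact` disables this); `L` is interpreted on
the coordinates of the matrix actually segmented. Mapping back, a
segment's end extends rightwards over removed columns up to the next
kept column (the last to `n`), and the first segment absorbs leading
removed columns, so mapped segments tile `[1, n]` exactly — the paperless
edge cases (how removed columns at boundaries are apportioned) are fixed
by this rule. BED output is 0-based half-open; everything else
user-facing is 1-based inclusive.

## Synthetic panels

`simulate_recombinants` plants `d` i.i.d. uniform founders over `σ`
symbols (default 4, the natural nucleotide-like choice) and builds each
of `m` rows by choosing a founder uniformly per segment of a shared
breakpoint grid with spacing ≥ `g`; optional point mutations replace a
cell with a uniformly chosen different symbol. Shared breakpoints match
the segmentation model's assumption that crossovers align across rows; a
`jitter` option deliberately breaks that assumption for stress tests.
With zero mutations and `L ≤ g` every grid segment induces at most `d`
distinct substrings, so the solver's optimum is ≤ `d` — the ground truth
behind the recovery tests. What the generator does *not* emulate:
realistic linkage structure, coalescent genealogies, allele-frequency
spectra, or indel processes; passing recovery tests demonstrates
correctness of the algorithmics, not biological calibration.

## Problem sizes

Randomised verification sweeps use panels up to `m = 8`, `n = 40`,
`σ ∈ {2, 4}`, `L ≤ 8` (300 instances for solver/oracle agreement, 100
for pBWT equivalence), 50 planted panels up to `m = 20`, `n = 200`, and
a single reference panel with `m = 30`, `n = 1000`, `d = 6` planted
founders and mutation rate 0.002 for the strategy comparison. These
sizes keep brute-force oracles exact while exercising every code path;
the solver itself is linear-time and handles much larger panels.

## Known limitations

* The RMQ construction route rebuilds its sparse table per column
  (`O(m log m)`), trading the theoretical `O(m)` bound for simplicity;
  the jump-pointer route is the default.
* Matching is locally optimal per boundary; global multi-boundary
  crossover minimisation is out of scope (and conjectured hard).
* Greedy matching uses the co-occurrence construction for candidate
  edges but a comparison sort over ≤ `m` pairs rather than radix passes;
  at panel scale this is never the bottleneck.
* The package assumes pre-aligned input; it computes no alignment and
  reads no VCF.
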