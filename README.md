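# founderseq

Founder sequence reconstruction from aligned haplotype panels via
linear-time minimum segmentation over a positional Burrows–Wheeler
transform.

## The problem

Pan-genomic analyses often start from a multiple sequence alignment of
thousands of haplotype sequences. A much smaller set of *founder*
sequences that preserves the local content of the panel makes downstream
indexing, read alignment and variant calling tractable. Formally: given
recombinants `R = {R_1, …, R_m}` of equal length `n` and a minimum
segment length `L`, find a partition of the columns `[1, n]` into
segments, each of length ≥ `L`, minimising

```
max over segments [a, b]  of  d(a, b) = |{ R_i[a, b] : 1 ≤ i ≤ m }|
```

the number of distinct substrings per segment. The optimum `M(n)` is the
number of founders needed when crossovers are confined to segment
boundaries. `founderseq` solves this exactly in `O(mn)` time and
`O(m + L)` working space with a streaming sweep over the panel,
maintaining a modified positional BWT (permutation `a_k`, run-length view
`s_k / e_k / t_k` of the divergence array `d_k`, and per-interval dynamic
programming minima `u_k`); a quadratic reference DP is included as an
oracle. Founder sequences are then assembled by gluing per-segment
fragments across boundaries with a random, greedy (1/2-approximate) or
exact maximum-weight perfect matching of the row partitions, and the
result is scored by optimal greedy parsing of each haplotype as a founder
mosaic.

## Worked example

The panel `{baaaa, baaab, babab}` with `L = 1`:

```sh
printf '>r1\nbaaaa\n>r2\nbaaab\n>r3\nbabab\n' > toy.fasta
founderseq founders toy.fasta --L 1 --matching perfect --seed 7 --out toyout
```

prints

```
{"founder_count": 2, "total_boundary_crossovers": 4}
```

Two founders suffice: no single column needs more than two symbols, and a
segmentation with per-segment distinct counts ≤ 2 exists. `toyout/`
contains the founders (`BAAAA`, `BABAB` — the panel parses as mosaics of
these two with at most one crossover per row), the segmentation as BED
and TSV (monomorphic columns are compacted away before segmentation and
mapped back afterwards, here giving segments `[1,4]` and `[5,5]`), the
per-segment fragment/occupancy table, and `summary.json` with crossover
statistics (`median_crossovers_per_row: 0.0`, mean 1/3: only `baaab`
needs a switch against this founder set).

The same machinery is available as a library:

```python
from founderseq import RecombinantMatrix, solve, build_founder_set, evaluate_all

mat = RecombinantMatrix.from_strings(["baaaa", "baaab", "babab"])
seg = solve(mat, L=1)                 # seg.founder_count == 2
fs = build_founder_set(mat, seg, strategy="perfect", seed=7)
stats = evaluate_all(mat, fs.sequences)
```

Other subcommands: `segment` (segmentation only, `--oracle` cross-checks
the quadratic DP), `evaluate` (parse a panel against an existing founder
FASTA), `simulate` (planted-founder panels with known ground truth) and
`pbwt-dump` (positional BWT arrays per column).

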