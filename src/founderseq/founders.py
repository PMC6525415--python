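"""From a segmentation to concrete founder sequences.

Each segment of an optimal segmentation induces at most ``M(n)`` distinct
substrings ("fragments"), each carried by a set of haplotype rows (its
*occupancy*).  Founder sequences are built by concatenating one fragment per
segment; the only freedom is the order in which fragments of consecutive
segments are glued together.  Gluing fragment ``X`` (occupancy ``A``) to
fragment ``Y`` (occupancy ``B``) forces ``m - |A ∩ B|`` of the rows to switch
founders at that boundary, so a good gluing maximises the summed intersection
between the two row partitions — the Maximum Intersection Between two
Partitions (MIBP) problem, a maximum-weight perfect matching on the bipartite
graph with edge weights ``w(X, Y) = |A ∩ B|``.

Segments with fewer than ``M(n)`` fragments are first padded by duplicating
fragments in proportion to their coverage (copies share the occupancy of the
original, which leaves the matching semantics intact).

Three gluing strategies are provided: ``random`` (baseline), ``greedy``
(heaviest available pair first; a 1/2-approximation of the optimum) and
``perfect`` (exact maximum-weight perfect matching via the assignment
problem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .msa_io import RecombinantMatrix
from .segmentation import SegmentationResult

__all__ = [
    "SegmentBlock",
    "PartitionMatching",
    "FounderSet",
    "extract_blocks",
    "duplicate_blocks",
    "mibp_weights",
    "match_perfect",
    "match_greedy",
    "match_random",
    "assemble",
    "boundary_crossovers",
    "build_founder_set",
    "is_founder_set",
]


@dataclass
class SegmentBlock:
    """Distinct substrings of one segment with their row-occupancy sets.

    ``occupancy[f]`` is the set of 0-based row indices whose substring over
    ``interval`` equals ``fragments[f]``; the sets partition the rows.
    ``copies[f]`` is the fragment's multiplicity after duplication (all 1
    until :func:`duplicate_blocks` runs).
    """

    interval: tuple[int, int]
    fragments: list[str]
    occupancy: list[frozenset[int]]
    copies: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.copies:
            self.copies = [1] * len(self.fragments)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def total_copies(self) -> int:
        return sum(self.copies)

    def expanded(self) -> list[int]:
        """Fragment indices repeated per copy, in fragment order."""
        out: list[int] = []
        for f, c in enumerate(self.copies):
            out.extend([f] * c)
        return out


@dataclass
class PartitionMatching:
    """A bijection between the duplicated fragment lists of two blocks.

    ``assignment[i]`` is the right-side expanded index glued to left expanded
    index ``i``; ``total_weight`` is the summed occupancy intersection over
    matched pairs.
    """

    assignment: np.ndarray
    total_weight: int
    size: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if sorted(self.assignment.tolist()) != list(range(self.size)):
            raise ValueError("assignment must be a permutation")


@dataclass
class FounderSet:
    """Assembled founder sequences plus the per-boundary matchings."""

    sequences: list[str]
    blocks: list[SegmentBlock]
    matchings: list[PartitionMatching]
    strategy: str

    @property
    def d(self) -> int:
        return len(self.sequences)

    def total_boundary_crossovers(self, m: int) -> int:
        return sum(boundary_crossovers(match, m) for match in self.matchings)


def extract_blocks(
    mat: RecombinantMatrix, segments: list[tuple[int, int]]
) -> list[SegmentBlock]:
    """Group rows by their substring in each segment (1-based intervals).

    Fragments are listed in order of first occurrence (smallest row index),
    which fixes all downstream tie-breaking deterministically.
    """
    blocks = []
    for a, b in segments:
        seen: dict[str, list[int]] = {}
        for i in range(mat.m):
            frag = mat.substring(i, a, b)
            seen.setdefault(frag, []).append(i)
        fragments = list(seen.keys())
        occupancy = [frozenset(seen[f]) for f in fragments]
        blocks.append(SegmentBlock(interval=(a, b), fragments=fragments, occupancy=occupancy))
    return blocks


def duplicate_blocks(blocks: list[SegmentBlock], d: int) -> list[SegmentBlock]:
    """Pad every block to exactly ``d`` fragment copies.

    A block with ``k < d`` fragments is visited by decreasing occupancy size
    (ties: smallest contained row index).  Fragment ``x`` receives
    ``ceil(|x| / m * (d - k))`` extra copies; the walk stops as soon as the
    copy total reaches ``d`` and the last increment is clamped so the total
    is exactly ``d``.
    """
    out = []
    for block in blocks:
        k = block.n_fragments
        if k > d:
            raise ValueError(
                f"segment {block.interval} has {k} fragments, more than d={d}"
            )
        m = sum(len(occ) for occ in block.occupancy)
        copies = [1] * k
        if k < d:
            order = sorted(
                range(k), key=lambda f: (-len(block.occupancy[f]), min(block.occupancy[f]))
            )
            total = k
            for f in order:
                if total >= d:
                    break
                extra = math.ceil(len(block.occupancy[f]) / m * (d - k))
                extra = min(extra, d - total)
                copies[f] += extra
                total += extra
            if total != d:
                raise AssertionError("duplication did not reach the founder count")
        out.append(
            SegmentBlock(
                interval=block.interval,
                fragments=list(block.fragments),
                occupancy=list(block.occupancy),
                copies=copies,
            )
        )
    return out


def _fragment_pair_weights(left: SegmentBlock, right: SegmentBlock) -> dict[tuple[int, int], int]:
    """Nonzero MIBP weights between original fragments via row co-occurrence.

    Builds the row-to-fragment arrays (each row lies in exactly one fragment
    per side) and counts pairs in one pass — at most ``m`` nonzero edges.
    """
    m = sum(len(occ) for occ in left.occupancy)
    g_left = [0] * m
    for f, occ in enumerate(left.occupancy):
        for i in occ:
            g_left[i] = f
    g_right = [0] * m
    for f, occ in enumerate(right.occupancy):
        for i in occ:
            g_right[i] = f
    weights: dict[tuple[int, int], int] = {}
    for i in range(m):
        key = (g_left[i], g_right[i])
        weights[key] = weights.get(key, 0) + 1
    return weights


def mibp_weights(left: SegmentBlock, right: SegmentBlock) -> np.ndarray:
    """Weight matrix ``w[x, y] = |occ(x) ∩ occ(y)|`` over expanded copies.

    Copies of a fragment share its occupancy, so rows/columns belonging to
    copies of the same fragment are identical.
    """
    if left.total_copies != right.total_copies:
        raise ValueError("blocks must carry equally many fragment copies")
    base = _fragment_pair_weights(left, right)
    el, er = left.expanded(), right.expanded()
    w = np.zeros((len(el), len(er)), dtype=np.int64)
    for i, f in enumerate(el):
        for j, g in enumerate(er):
            w[i, j] = base.get((f, g), 0)
    return w


def match_perfect(weights: np.ndarray) -> PartitionMatching:
    """Maximum-weight perfect matching, solved as an assignment problem."""
    w = np.asarray(weights)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    rows, cols = linear_sum_assignment(w, maximize=True)
    assignment = np.empty(w.shape[0], dtype=np.int64)
    assignment[rows] = cols
    total = int(w[rows, cols].sum())
    return PartitionMatching(assignment=assignment, total_weight=total, size=w.shape[0])


def match_greedy(left: SegmentBlock, right: SegmentBlock) -> PartitionMatching:
    """Greedy MIBP matching: heaviest pair whose endpoints are both free.

    Nonzero-weight pairs come from the row co-occurrence counts (at most
    ``m`` of them); ties break lexicographically on (left index, right
    index).  Unmatched copies are paired up in index order at the end.  The
    total weight is at least half the perfect-matching optimum.
    """
    if left.total_copies != right.total_copies:
        raise ValueError("blocks must carry equally many fragment copies")
    base = _fragment_pair_weights(left, right)
    el, er = left.expanded(), right.expanded()
    size = len(el)
    pairs = []
    for i, f in enumerate(el):
        for j, g in enumerate(er):
            w = base.get((f, g), 0)
            if w > 0:
                pairs.append((-w, i, j))
    pairs.sort()
    assignment = np.full(size, -1, dtype=np.int64)
    taken_right = [False] * size
    total = 0
    for neg_w, i, j in pairs:
        if assignment[i] < 0 and not taken_right[j]:
            assignment[i] = j
            taken_right[j] = True
            total += -neg_w
    free_right = [j for j in range(size) if not taken_right[j]]
    it = iter(free_right)
    for i in range(size):
        if assignment[i] < 0:
            j = next(it)
            assignment[i] = j
            total += base.get((el[i], er[j]), 0)
    return PartitionMatching(assignment=assignment, total_weight=total, size=size)


def match_random(
    left: SegmentBlock, right: SegmentBlock, rng: np.random.Generator
) -> PartitionMatching:
    """Uniformly random gluing order (the naive baseline)."""
    if left.total_copies != right.total_copies:
        raise ValueError("blocks must carry equally many fragment copies")
    size = left.total_copies
    assignment = rng.permutation(size)
    base = _fragment_pair_weights(left, right)
    el, er = left.expanded(), right.expanded()
    total = sum(base.get((el[i], er[int(assignment[i])]), 0) for i in range(size))
    return PartitionMatching(assignment=assignment, total_weight=int(total), size=size)


def boundary_crossovers(matching: PartitionMatching, m: int) -> int:
    """Crossovers forced at one boundary: ``size * m - total_weight``."""
    return matching.size * m - matching.total_weight


def assemble(blocks: list[SegmentBlock], matchings: list[PartitionMatching]) -> list[str]:
    """Concatenate fragments along the matching chains into founder strings.

    Founder ``j`` starts at expanded fragment ``j`` of the first block and
    follows the per-boundary bijections left to right.
    """
    if len(matchings) != len(blocks) - 1:
        raise ValueError("need one matching per adjacent block pair")
    d = blocks[0].total_copies
    founders = []
    for start in range(d):
        idx = start
        parts = []
        for b, block in enumerate(blocks):
            exp = block.expanded()
            parts.append(block.fragments[exp[idx]])
            if b < len(matchings):
                idx = int(matchings[b].assignment[idx])
        founders.append("".join(parts))
    return founders


def build_founder_set(
    mat: RecombinantMatrix,
    segmentation: SegmentationResult,
    strategy: str = "perfect",
    seed: int | None = None,
) -> FounderSet:
    """Full pipeline: blocks -> duplication -> per-boundary matching -> strings."""
    if strategy not in {"random", "greedy", "perfect"}:
        raise ValueError(f"unknown matching strategy {strategy!r}")
    blocks = extract_blocks(mat, segmentation.segments)
    blocks = duplicate_blocks(blocks, segmentation.founder_count)
    rng = np.random.default_rng(seed)
    matchings = []
    for left, right in zip(blocks[:-1], blocks[1:]):
        if strategy == "perfect":
            matchings.append(match_perfect(mibp_weights(left, right)))
        elif strategy == "greedy":
            matchings.append(match_greedy(left, right))
        else:
            matchings.append(match_random(left, right, rng))
    sequences = assemble(blocks, matchings)
    return FounderSet(
        sequences=sequences, blocks=blocks, matchings=matchings, strategy=strategy
    )


def is_founder_set(
    founders: list[str], mat: RecombinantMatrix, segments: list[tuple[int, int]]
) -> bool:
    """Check that every row's substring at every segment occurs in a founder."""
    for a, b in segments:
        window = {f[a - 1 : b] for f in founders}
        for i in range(mat.m):
            if mat.substring(i, a, b) not in window:
                return False
    return True
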