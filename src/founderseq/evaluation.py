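"""Parsing haplotypes against a founder set and summarising the result.

The quality measure for a founder set is how few crossovers are needed to
express each original haplotype as a mosaic of founder substrings.  The
greedy left-to-right parser below is optimal for this measure: it keeps the
set of founders matching the current stretch and extends maximally; when the
set would empty at a position it records one crossover and restarts there.
Maximal-stretch extension can never do worse than any other mosaic because a
parse switching earlier matches a subset of the positions available to the
greedy stretch.

Statistics mirror the usual reporting for founder panels: per-row crossover
counts (mean/median), the average distance between recombinations (sequence
length divided by the mean count), and segment lengths on the original,
pre-compaction coordinates.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .msa_io import CoordinateMap, RecombinantMatrix, map_segments

__all__ = ["ParseResult", "RecombinationStats", "greedy_parse", "evaluate_all"]


@dataclass
class ParseResult:
    """Minimum-crossover mosaic of one sequence over a founder set."""

    crossovers: int
    breakpoints: list[int]  # 1-based positions where a new stretch starts


@dataclass
class RecombinationStats:
    """Crossover and segment-length summary for a whole panel."""

    crossover_counts: list[int]
    breakpoints: list[list[int]]
    mean_crossovers: float
    median_crossovers: float
    original_length: int
    mean_distance_between_recombinations: float
    segment_lengths: list[int] = field(default_factory=list)
    mean_segment_length: float = 0.0
    median_segment_length: float = 0.0


def greedy_parse(seq: str, founders: list[str]) -> ParseResult:
    """Optimal (minimum-crossover) parse of ``seq`` as a founder mosaic.

    Scans left to right maintaining the active set of founders matching the
    current stretch.  When no active founder matches the next position, one
    crossover is counted and the stretch restarts at that position.  Raises
    :class:`ValueError` if some position is matched by no founder at all.
    """
    n = len(seq)
    for f in founders:
        if len(f) != n:
            raise ValueError("founders must have the same length as the sequence")
    active: set[int] | None = None
    crossovers = 0
    breakpoints: list[int] = []
    for p in range(n):
        c = seq[p]
        candidates = {f for f in (active if active is not None else range(len(founders)))
                      if founders[f][p] == c}
        if candidates:
            active = candidates
            continue
        fresh = {f for f in range(len(founders)) if founders[f][p] == c}
        if not fresh:
            raise ValueError(
                f"founder set does not cover input at position {p + 1}"
            )
        if active is None:
            active = fresh  # first position, no crossover
        else:
            crossovers += 1
            breakpoints.append(p + 1)
            active = fresh
    return ParseResult(crossovers=crossovers, breakpoints=breakpoints)


def evaluate_all(
    mat: RecombinantMatrix,
    founders: list[str],
    coordmap: CoordinateMap | None = None,
    segments: list[tuple[int, int]] | None = None,
) -> RecombinationStats:
    """Parse every row and aggregate crossover / segment-length statistics.

    When a :class:`CoordinateMap` is given the reported distances refer to
    the original (pre-compaction) coordinates; segment lengths are computed
    from ``segments`` mapped the same way.
    """
    counts: list[int] = []
    bps: list[list[int]] = []
    for i in range(mat.m):
        res = greedy_parse(mat.row_string(i), founders)
        counts.append(res.crossovers)
        bps.append(res.breakpoints)
    mean_c = sum(counts) / len(counts)
    median_c = float(statistics.median(counts))
    original_length = coordmap.original_length if coordmap is not None else mat.n_columns
    if mean_c > 0:
        distance = original_length / mean_c
    else:
        distance = float(original_length)
    seg_lengths: list[int] = []
    mean_len = median_len = 0.0
    if segments:
        mapped = map_segments(segments, coordmap) if coordmap is not None else list(segments)
        seg_lengths = [b - a + 1 for a, b in mapped]
        mean_len = sum(seg_lengths) / len(seg_lengths)
        median_len = float(statistics.median(seg_lengths))
    return RecombinationStats(
        crossover_counts=counts,
        breakpoints=bps,
        mean_crossovers=mean_c,
        median_crossovers=median_c,
        original_length=original_length,
        mean_distance_between_recombinations=distance,
        segment_lengths=seg_lengths,
        mean_segment_length=mean_len,
        median_segment_length=median_len,
    )
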