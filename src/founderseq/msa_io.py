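"""Reading, validating and writing aligned haplotype panels.

A panel is a multiple sequence alignment of ``m`` equal-length haplotype
sequences over an arbitrary character alphabet.  Gap characters (``-``) and
ambiguity codes (``N``) are treated as ordinary alphabet symbols: the
downstream segmentation machinery operates on plain strings and makes no
biological distinction between symbols.

Internally the panel is held as an integer matrix (:class:`RecombinantMatrix`)
with a dense symbol encoding: the observed characters are ranked and mapped to
codes ``0 .. sigma-1``.  Columns where every row carries the same symbol are
irrelevant to segmentation (they never create a recombination boundary) and
can be dropped with :func:`compact_columns`; the accompanying
:class:`CoordinateMap` converts intervals on the compacted matrix back to the
original coordinate system.

Coordinate conventions: the public interval API is 1-based inclusive; BED
output is 0-based half-open; array storage is 0-based.  Conversions happen
only at the edges of this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RecombinantMatrix",
    "CoordinateMap",
    "read_alignment",
    "compact_columns",
    "map_interval",
    "map_segments",
    "write_founders",
    "write_segmentation",
    "write_fragment_map",
]


@dataclass
class RecombinantMatrix:
    """An ``m x n`` integer-encoded alignment of haplotype rows.

    Attributes
    ----------
    codes
        ``(m, n)`` integer array; entry ``codes[i, k]`` is the dense code of
        the symbol of row ``i`` at column ``k`` (0-based).
    alphabet
        Code-to-character mapping: ``alphabet[c]`` is the original character
        for code ``c``.  Codes are the ranks of the sorted observed symbols.
    names
        Per-row identifiers, in file order.
    """

    codes: np.ndarray
    alphabet: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if self.m < 1:
            raise ValueError("a panel needs at least one row")
        if not self.names:
            self.names = [f"seq{i + 1}" for i in range(self.m)]
        if len(self.names) != self.m:
            raise ValueError("names must match the number of rows")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= len(self.alphabet)):
            raise ValueError("symbol codes must lie in [0, sigma)")

    @property
    def m(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    @property
    def sigma(self) -> int:
        return len(self.alphabet)

    @classmethod
    def from_strings(
        cls, sequences: Sequence[str], names: Sequence[str] | None = None
    ) -> "RecombinantMatrix":
        """Build a matrix from equal-length strings (uppercase-normalised)."""
        if not sequences:
            raise ValueError("empty input: no sequences")
        seqs = [s.upper() for s in sequences]
        n = len(seqs[0])
        labels = list(names) if names is not None else [f"seq{i + 1}" for i in range(len(seqs))]
        for label, s in zip(labels, seqs):
            if len(s) != n:
                raise ValueError(
                    f"record '{label}' has length {len(s)}, expected {n}: "
                    "all aligned sequences must have equal length"
                )
            if not s.isascii():
                raise ValueError(f"record '{label}' contains non-ASCII symbols")
        alphabet = sorted(set("".join(seqs))) if n > 0 else []
        index = {c: i for i, c in enumerate(alphabet)}
        codes = np.empty((len(seqs), n), dtype=np.int64)
        for i, s in enumerate(seqs):
            codes[i] = [index[c] for c in s]
        return cls(codes=codes, alphabet=alphabet, names=labels)

    def row_string(self, i: int) -> str:
        """Decode row ``i`` (0-based) back to its character string."""
        return "".join(self.alphabet[c] for c in self.codes[i])

    def row_strings(self) -> list[str]:
        return [self.row_string(i) for i in range(self.m)]

    def substring(self, i: int, a: int, b: int) -> str:
        """Characters of row ``i`` over the 1-based inclusive interval [a, b]."""
        return "".join(self.alphabet[c] for c in self.codes[i, a - 1 : b])

    def column(self, k: int) -> np.ndarray:
        """Symbol codes of 1-based column ``k``."""
        if not 1 <= k <= self.n_columns:
            raise ValueError(f"column {k} out of range [1, {self.n_columns}]")
        return self.codes[:, k - 1]


@dataclass(frozen=True)
class CoordinateMap:
    """Reversible record of which original columns a compacted matrix kept.

    ``kept_columns`` is the strictly increasing list of 1-based original
    column indices retained; ``original_length`` the pre-compaction width.
    """

    kept_columns: tuple[int, ...]
    original_length: int

    def __post_init__(self) -> None:
        cols = self.kept_columns
        if any(cols[i] >= cols[i + 1] for i in range(len(cols) - 1)):
            raise ValueError("kept_columns must be strictly increasing")
        if cols and not (1 <= cols[0] and cols[-1] <= self.original_length):
            raise ValueError("kept_columns out of range")

    @property
    def n_kept(self) -> int:
        return len(self.kept_columns)

    @classmethod
    def identity(cls, n: int) -> "CoordinateMap":
        return cls(kept_columns=tuple(range(1, n + 1)), original_length=n)


def read_alignment(path: str | Path) -> RecombinantMatrix:
    """Read an aligned FASTA file into a :class:`RecombinantMatrix`.

    All records must have equal length; gaps and ambiguity codes are kept as
    ordinary symbols.  Raises :class:`ValueError` naming the offending record
    on a length mismatch, and on empty input.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty alignment: no FASTA records in {path}")
    return RecombinantMatrix.from_strings(
        [str(r.seq) for r in records], [r.id for r in records]
    )


def compact_columns(mat: RecombinantMatrix) -> tuple[RecombinantMatrix, CoordinateMap]:
    """Drop monomorphic columns, returning the reduced matrix and its map.

    A column is kept iff at least two distinct codes occur in it.  Column
    order is preserved.  An all-identical panel compacts to zero columns (a
    warning is emitted since nothing remains to segment).
    """
    if mat.n_columns == 0:
        return mat, CoordinateMap(kept_columns=(), original_length=0)
    polymorphic = (mat.codes != mat.codes[0]).any(axis=0)
    kept = np.flatnonzero(polymorphic)
    if kept.size == 0:
        warnings.warn(
            "all columns are monomorphic; the compacted matrix is empty",
            stacklevel=2,
        )
    sub = RecombinantMatrix(
        codes=mat.codes[:, kept],
        alphabet=list(mat.alphabet),
        names=list(mat.names),
    )
    cmap = CoordinateMap(
        kept_columns=tuple(int(c) + 1 for c in kept),
        original_length=mat.n_columns,
    )
    return sub, cmap


def map_interval(
    interval: tuple[int, int], cmap: CoordinateMap, *, attach_leading: bool = False
) -> tuple[int, int]:
    """Map a compacted 1-based inclusive interval back to original coordinates.

    The start maps to its kept column; the end extends rightwards over the
    removed columns up to just before the next kept column (the last interval
    extends to ``original_length``).  Consecutive compacted intervals
    therefore tile ``[kept_columns[0], original_length]`` without gaps.  With
    ``attach_leading=True`` an interval starting at compacted column 1 also
    absorbs any original columns before the first kept one, so a full tiling
    starts at column 1.
    """
    a, b = interval
    if not 1 <= a <= b <= cmap.n_kept:
        raise ValueError(
            f"interval [{a}, {b}] out of range [1, {cmap.n_kept}] on the compacted axis"
        )
    start = cmap.kept_columns[a - 1]
    if attach_leading and a == 1:
        start = 1
    if b == cmap.n_kept:
        end = cmap.original_length
    else:
        end = cmap.kept_columns[b] - 1
    return start, end


def map_segments(
    segments: Iterable[tuple[int, int]], cmap: CoordinateMap
) -> list[tuple[int, int]]:
    """Map a whole segmentation back to original coordinates.

    The first segment absorbs leading monomorphic columns so the mapped
    segmentation tiles ``[1, original_length]``.
    """
    segs = list(segments)
    return [
        map_interval(seg, cmap, attach_leading=(i == 0)) for i, seg in enumerate(segs)
    ]


def original_position(pos: int, cmap: CoordinateMap) -> int:
    """Original 1-based column of a compacted 1-based position."""
    if not 1 <= pos <= cmap.n_kept:
        raise ValueError(f"position {pos} out of range on the compacted axis")
    return cmap.kept_columns[pos - 1]


def write_founders(
    founders: Sequence[str], path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write founder sequences as FASTA records ``founder1, founder2, ...``."""
    founders = list(founders)
    if not founders:
        raise ValueError("refusing to write an empty founder set")
    labels = list(names) if names is not None else [f"founder{i + 1}" for i in range(len(founders))]
    records = [
        SeqRecord(Seq(s), id=label, description="") for s, label in zip(founders, labels)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_segmentation(
    segments: Sequence[tuple[int, int]],
    counts: Sequence[int],
    bed_path: str | Path,
    tsv_path: str | Path,
    *,
    chrom: str = "msa",
) -> None:
    """Write a segmentation as BED (0-based half-open) and TSV (1-based).

    ``segments`` must already be in original coordinates.  TSV columns:
    segment_index, start, end, n_distinct.
    """
    with open(bed_path, "w") as bed:
        for (a, b), _c in zip(segments, counts):
            bed.write(f"{chrom}\t{a - 1}\t{b}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("segment_index\tstart\tend\tn_distinct\n")
        for idx, ((a, b), c) in enumerate(zip(segments, counts), start=1):
            tsv.write(f"{idx}\t{a}\t{b}\t{c}\n")


def write_fragment_map(blocks, path: str | Path, names: Sequence[str] | None = None) -> None:
    """Write per-segment distinct fragments and their haplotype occupancy.

    One TSV row per (segment, fragment) pair with columns segment_index,
    start, end, n_distinct, fragment, haplotype_ids.  ``blocks`` is a list of
    :class:`founderseq.founders.SegmentBlock`.
    """
    with open(path, "w") as tsv:
        tsv.write("segment_index\tstart\tend\tn_distinct\tfragment\thaplotype_ids\n")
        for idx, block in enumerate(blocks, start=1):
            a, b = block.interval
            for frag, occ in zip(block.fragments, block.occupancy):
                if names is not None:
                    ids = ",".join(names[i] for i in sorted(occ))
                else:
                    ids = ",".join(str(i + 1) for i in sorted(occ))
                tsv.write(f"{idx}\t{a}\t{b}\t{len(block.fragments)}\t{frag}\t{ids}\n")
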