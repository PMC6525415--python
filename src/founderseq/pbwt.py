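"""Positional Burrows-Wheeler transform over integer alphabets.

For a haplotype panel viewed as an ``m x n`` matrix, the pBWT at column ``k``
is the pair of arrays

* ``a`` — a permutation of the rows ordering the *reversed* prefixes
  ``R_i[1..k]`` lexicographically (i.e. colexicographic order of the
  prefixes), stable with respect to row order on ties;
* ``d`` — the divergence array: ``d[i]`` is the 1-based column where the
  longest common suffix of the prefixes of rows ``a[i]`` and ``a[i-1]``
  begins, with ``d[0] = k + 1`` (and ``k + 1`` whenever the common suffix is
  empty).

Row indices stored in ``a`` are 0-based; ``d`` values are 1-based column
positions in ``[1, k + 1]``, matching the usual presentation.

Three construction routes are provided and must agree exactly:

* :func:`pbwt_extend_rmq` — one counting-sort pass per column; divergence
  values come from range-maximum queries over the previous ``d`` array
  (a sparse table rebuilt per column).
* :func:`pbwt_extend_jump` — the same counting sort, but range maxima are
  computed by a path-compressed "jump pointer" scan (:func:`maxd`) that
  stores partial scan results in a scratch copy of the previous arrays;
  amortised cost is ``O(m log sigma)`` per column and it is the default
  production path.
* :func:`pbwt_naive` — the definition itself (sort reversed prefixes,
  measure common suffixes); quadratic, used as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PBWTColumn",
    "TouchCounter",
    "pbwt_init",
    "pbwt_extend_rmq",
    "pbwt_extend_jump",
    "pbwt_naive",
    "pbwt_columns",
    "maxd",
    "SparseTableMax",
]


@dataclass
class PBWTColumn:
    """pBWT state after processing columns ``1..k``.

    ``a`` holds 0-based row indices in colexicographic prefix order; ``d``
    holds 1-based divergence positions in ``[1, k + 1]``.
    """

    k: int
    a: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)

    @property
    def m(self) -> int:
        return len(self.a)


@dataclass
class TouchCounter:
    """Accumulates the number of jump-table nodes visited per column."""

    total: int = 0
    per_column: list[int] = field(default_factory=list)

    def start_column(self) -> None:
        self.per_column.append(0)

    def add(self, n: int) -> None:
        self.total += n
        if self.per_column:
            self.per_column[-1] += n


def pbwt_init(m: int) -> PBWTColumn:
    """Base pBWT state at ``k = 0``: identity order, all-empty suffixes."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return PBWTColumn(k=0, a=np.arange(m), d=np.ones(m, dtype=np.int64))


class SparseTableMax:
    """Static range-maximum structure with O(1) queries (inclusive bounds)."""

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=np.int64)
        n = len(arr)
        levels = max(1, int(np.floor(np.log2(n))) + 1) if n else 1
        self._table = [arr]
        for j in range(1, levels):
            prev = self._table[-1]
            half = 1 << (j - 1)
            if len(prev) <= half:
                break
            self._table.append(np.maximum(prev[:-half], prev[half:]))

    def query(self, lo: int, hi: int) -> int:
        """Maximum of the underlying array over 0-based inclusive [lo, hi]."""
        if lo > hi:
            raise ValueError("empty range")
        span = hi - lo + 1
        j = span.bit_length() - 1
        row = self._table[j]
        return int(max(row[lo], row[hi - (1 << j) + 1]))


def maxd(lo: int, hi: int, jump: list[int], vmax: list[int]) -> tuple[int, int]:
    """Path-compressed maximum of the original value array over [lo, hi].

    ``jump``/``vmax`` encode the scan work done so far: for every node ``v``,
    ``vmax[v]`` is the maximum of the original values over ``[v, jump[v])``,
    and chains of jump pointers starting at ``lo <= hi`` terminate exactly at
    ``hi + 1``.  The call returns ``(maximum over [lo, hi], nodes touched)``
    and redirects every visited pointer to ``hi + 1``, updating the stored
    maxima so later queries re-use this work.
    """
    if lo > hi:
        raise ValueError("maxd requires lo <= hi")
    visited = []
    best = -1
    v = lo
    while v <= hi:
        visited.append(v)
        if vmax[v] > best:
            best = vmax[v]
        v = jump[v]
    # Suffix maxima over the visited chain keep vmax[v] = max over [v, hi].
    run = -1
    for node in reversed(visited):
        if vmax[node] > run:
            run = vmax[node]
        vmax[node] = run
        jump[node] = hi + 1
    return best, len(visited)


def _counting_sort_pass(prev_a: np.ndarray, column: np.ndarray, sigma: int):
    """Stable counting sort of the previous permutation keyed on the column.

    Returns (bucket cursor array C, per-symbol last-seen array P, new order
    iterator state) split across the caller loop; here we only precompute the
    bucket offsets.
    """
    counts = np.bincount(column[prev_a], minlength=sigma)
    offsets = np.zeros(sigma, dtype=np.int64)
    offsets[1:] = np.cumsum(counts)[:-1]
    return offsets


def _validate_column(column, m: int, sigma: int | None) -> tuple[np.ndarray, int]:
    col = np.asarray(column, dtype=np.int64)
    if len(col) != m:
        raise ValueError("column length must equal the number of rows")
    if col.size and col.min() < 0:
        raise ValueError("negative symbol code")
    observed = int(col.max()) + 1 if col.size else 1
    if sigma is None:
        sigma = observed
    elif observed > sigma:
        raise ValueError(f"symbol code {observed - 1} out of range for sigma={sigma}")
    return col, sigma


def pbwt_extend_rmq(
    prev: PBWTColumn, column, sigma: int | None = None
) -> PBWTColumn:
    """Extend the pBWT by one column using an RMQ over the previous ``d``.

    One stable counting-sort pass reorders the permutation; each new
    divergence value is either ``k + 1`` (first occurrence of the symbol in
    sorted order) or the maximum of the previous ``d`` over the gap back to
    the last same-symbol predecessor.
    """
    m = prev.m
    col, sigma = _validate_column(column, m, sigma)
    k = prev.k + 1
    offsets = _counting_sort_pass(prev.a, col, sigma)
    table = SparseTableMax(prev.d)
    P = np.full(sigma, -1, dtype=np.int64)  # last-seen position per symbol
    a_new = np.empty(m, dtype=np.int64)
    d_new = np.empty(m, dtype=np.int64)
    for i in range(m):
        row = prev.a[i]
        b = col[row]
        slot = offsets[b]
        offsets[b] += 1
        a_new[slot] = row
        if P[b] < 0:
            d_new[slot] = k + 1
        else:
            d_new[slot] = table.query(int(P[b]) + 1, i)
        P[b] = i
    return PBWTColumn(k=k, a=a_new, d=d_new)


def pbwt_extend_jump(
    prev: PBWTColumn,
    column,
    sigma: int | None = None,
    counter: TouchCounter | None = None,
) -> PBWTColumn:
    """Extend the pBWT by one column with the amortised jump-pointer scan.

    Identical output to :func:`pbwt_extend_rmq`.  Internally, the previous
    ``d`` array is copied into a scratch pair (jump table + running maxima);
    range maxima are then served by :func:`maxd`, whose path compression keeps
    the amortised work at ``O(m log sigma)`` per column.  Pass a
    :class:`TouchCounter` to instrument the number of nodes visited.
    """
    m = prev.m
    col, sigma = _validate_column(column, m, sigma)
    k = prev.k + 1
    offsets = _counting_sort_pass(prev.a, col, sigma)
    # jump[v] = v + 1 with vmax = original d is the trivially valid start state.
    jump = list(range(1, m + 1))
    vmax = [int(x) for x in prev.d]
    P = [-1] * sigma
    a_new = np.empty(m, dtype=np.int64)
    d_new = np.empty(m, dtype=np.int64)
    if counter is not None:
        counter.start_column()
    for i in range(m):
        row = int(prev.a[i])
        b = int(col[row])
        slot = offsets[b]
        offsets[b] += 1
        a_new[slot] = row
        if P[b] < 0:
            d_new[slot] = k + 1
        else:
            val, touched = maxd(P[b] + 1, i, jump, vmax)
            d_new[slot] = val
            if counter is not None:
                counter.add(touched)
        P[b] = i
    return PBWTColumn(k=k, a=a_new, d=d_new)


def pbwt_naive(mat, k: int) -> PBWTColumn:
    """pBWT at column ``k`` straight from the definition (the oracle).

    Sorts the reversed prefixes with a stable sort (rows with equal reversed
    prefixes keep their input order, matching the counting-sort routes) and
    measures common suffixes directly.
    """
    if not 1 <= k <= mat.n_columns:
        raise ValueError(f"column {k} out of range [1, {mat.n_columns}]")
    rows = mat.codes
    m = mat.m
    reversed_prefixes = [tuple(rows[i, k - 1 :: -1]) for i in range(m)]
    order = sorted(range(m), key=lambda i: reversed_prefixes[i])
    d = np.empty(m, dtype=np.int64)
    d[0] = k + 1
    for pos in range(1, m):
        x, y = order[pos - 1], order[pos]
        lcs = 0
        while lcs < k and rows[x, k - 1 - lcs] == rows[y, k - 1 - lcs]:
            lcs += 1
        d[pos] = k + 1 - lcs
    return PBWTColumn(k=k, a=np.asarray(order), d=d)


def pbwt_columns(mat, method: str = "jump", counter: TouchCounter | None = None):
    """Yield the pBWT for columns ``1..n`` of a panel.

    ``method`` selects the per-column extension: ``"jump"`` (default),
    ``"rmq"`` or ``"naive"``.
    """
    state = pbwt_init(mat.m)
    for k in range(1, mat.n_columns + 1):
        if method == "jump":
            state = pbwt_extend_jump(state, mat.column(k), mat.sigma, counter)
        elif method == "rmq":
            state = pbwt_extend_rmq(state, mat.column(k), mat.sigma)
        elif method == "naive":
            state = pbwt_naive(mat, k)
        else:
            raise ValueError(f"unknown method {method!r}")
        yield state
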