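"""Minimum segmentation of a haplotype panel.

Given ``m`` aligned rows of length ``n`` and a minimum segment length ``L``,
partition the columns ``[1, n]`` into segments, each of length at least
``L``, minimising the maximum over segments of the number of distinct
substrings the panel induces on that segment.  That maximum is exactly the
number of founder sequences needed if crossovers are confined to segment
boundaries, so the optimum value ``M(n)`` is the founder count.

Two solvers are provided:

* :func:`dp_naive` — the classic quadratic dynamic programme

  ``M(k) = min over j in [0, k-L] of max(M(j), |R[j+1, k]|)``

  with ``M(0) = 0``; it recomputes distinct counts directly (partition
  refinement, no pBWT involved) and serves as the oracle.

* :func:`solve` — the streaming linear-time solver.  It sweeps the columns
  once, maintaining a modified positional Burrows-Wheeler transform: instead
  of the divergence array ``d_k`` it keeps its run-length view

  - ``s`` — the sorted distinct values of ``d_k`` (boundary positions + 1),
  - ``e`` — per sorted row, the index into ``s`` of its divergence value,
  - ``t`` — the multiplicity of each ``s`` entry in ``d_k``,
  - ``u`` — per ``s``-interval, the minimum dynamic-programming value over
    the predecessor positions that interval covers (with the positions
    attaining those minima, for backtracking).

  Suffix sums of ``t`` give the candidate segment cardinalities
  ``|R[s[j]-1, k]|`` in O(r) time; the recurrence then reduces to a minimum
  of at most ``m`` max-terms per column.  Only the last ``L`` values of ``M``
  are retained (circular buffer), so the working state is ``O(m + L)``
  integers beside the length-``n`` backtracking array.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .msa_io import RecombinantMatrix
from .pbwt import TouchCounter, maxd

__all__ = [
    "SegmentationResult",
    "BoundaryState",
    "distinct_count_naive",
    "distinct_counts_ending_at",
    "dp_naive",
    "solve",
    "backtrack",
    "segment_cardinalities",
]


class InfeasibleError(ValueError):
    """Raised when no segmentation satisfies the length constraint."""


@dataclass
class SegmentationResult:
    """Outcome of a minimum-segmentation run.

    ``segments`` are 1-based inclusive intervals tiling ``[1, n]``; the
    maximum of ``counts`` (per-segment distinct substrings) equals
    ``founder_count``.
    """

    founder_count: int
    segments: list[tuple[int, int]]
    counts: list[int]
    L: int
    backtrack: np.ndarray | None = None
    M: list[int] | None = None
    instrumentation: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass
class BoundaryState:
    """The streaming solver's per-column replacement for the ``d_k`` array.

    ``s`` is strictly increasing with ``s[-1] = k + 1``; ``sum(t) = m``;
    ``u[j]``/``upos[j]`` hold the minimum DP value (and its position) over
    predecessor positions ``[s[j-1] - 1, s[j] - 2]`` (with a sentinel
    ``s[0] = 1`` prepended conceptually), where values of ``M`` outside
    ``[1, k - L]`` count as infinity.
    """

    k: int
    a: np.ndarray
    e: list[int]
    s: list[int]
    t: list[int]
    u: list[int]
    upos: list[int]

    def reconstruct_d(self) -> np.ndarray:
        """The divergence array this state encodes (``d[i] = s[e[i]]``)."""
        return np.asarray([self.s[idx] for idx in self.e], dtype=np.int64)


def distinct_count_naive(mat: RecombinantMatrix, j: int, k: int) -> int:
    """Number of distinct row substrings over 1-based columns [j, k]."""
    if not 1 <= j <= k <= mat.n_columns:
        raise ValueError(f"invalid range [{j}, {k}] for n={mat.n_columns}")
    return len({tuple(row) for row in mat.codes[:, j - 1 : k]})


def distinct_counts_ending_at(mat: RecombinantMatrix, k: int) -> np.ndarray:
    """``counts[j] = |R[j, k]|`` for all ``j in [1, k]`` (1-based, counts[0] unused).

    Computed by leftward partition refinement: rows sharing the substring
    ``[j, k]`` share a group id; prepending column ``j - 1`` refines the
    grouping.  Direct grouping only — independent of the pBWT machinery.
    """
    m = mat.m
    counts = np.zeros(k + 1, dtype=np.int64)
    groups = [0] * m
    n_groups = 1  # empty suffix: all rows together before refinement at j = k
    for j in range(k, 0, -1):
        col = mat.codes[:, j - 1]
        seen: dict[tuple[int, int], int] = {}
        new_groups = [0] * m
        for i in range(m):
            key = (groups[i], int(col[i]))
            if key not in seen:
                seen[key] = len(seen)
            new_groups[i] = seen[key]
        groups = new_groups
        n_groups = len(seen)
        counts[j] = n_groups
    return counts


def dp_naive(mat: RecombinantMatrix, L: int, keep_M: bool = True) -> SegmentationResult:
    """Quadratic dynamic-programming solver (the oracle).

    Evaluates the recurrence exactly, scanning predecessors ``j`` from 0
    upward so ties pick the leftmost predecessor.  ``M(0) = 0`` makes the
    ``j = 0`` branch yield the single-segment value ``|R[1, k]|``.
    """
    n = mat.n_columns
    m = mat.m
    if not 1 <= L <= n:
        raise InfeasibleError(f"infeasible: L={L} must satisfy 1 <= L <= n={n}")
    INF = m + 1
    M = [0] + [INF] * n
    B = np.zeros(n + 1, dtype=np.int64)
    for k in range(1, n + 1):
        if k < L:
            continue
        counts = distinct_counts_ending_at(mat, k)
        best, best_j = INF, 0
        for j in range(0, k - L + 1):
            if M[j] >= INF:
                continue
            cand = max(M[j], int(counts[j + 1]))
            if cand < best:
                best, best_j = cand, j
        M[k], B[k] = best, best_j
    if M[n] >= INF:
        raise InfeasibleError("no segmentation satisfies the length bound")
    segments = backtrack(B, n, L)
    counts = [distinct_count_naive(mat, a, b) for a, b in segments]
    return SegmentationResult(
        founder_count=M[n],
        segments=segments,
        counts=counts,
        L=L,
        backtrack=B,
        M=M if keep_M else None,
    )


def backtrack(B: np.ndarray, n: int, L: int) -> list[tuple[int, int]]:
    """Recover the segmentation from the predecessor array.

    ``B[k] = 0`` closes the leftmost segment ``[1, k]``; otherwise ``B[k]``
    is the end of the previous segment.  Segments come out right-to-left and
    are reversed; a cycle (non-decreasing predecessor) is an internal error.
    """
    segments: list[tuple[int, int]] = []
    k = n
    while k > 0:
        j = int(B[k])
        if j >= k:
            raise AssertionError("backtracking cycle detected")
        segments.append((j + 1, k))
        if k - j < L:
            raise AssertionError("backtracked segment shorter than L")
        k = j
    segments.reverse()
    return segments


def segment_cardinalities(state: BoundaryState) -> list[int]:
    """``|R[s[j]-1, k]|`` for every ``s`` entry, via suffix sums of ``t``.

    The divergence value ``s[j]`` contributes one new distinct substring for
    each of its ``t[j]`` occurrences once the window start passes ``s[j]-1``,
    so the cardinality at ``s[j]-1`` is ``t[j] + t[j+1] + ... + t[r]``.
    """
    out = [0] * len(state.t)
    acc = 0
    for j in range(len(state.t) - 1, -1, -1):
        acc += state.t[j]
        out[j] = acc
    return out


def _merge_min(v1: int, p1: int, v2: int, p2: int) -> tuple[int, int]:
    # Minimum with leftmost-position tie-break.
    if v2 < v1 or (v2 == v1 and p2 < p1):
        return v2, p2
    return v1, p1


def _advance_boundary_state(
    state: BoundaryState,
    column: np.ndarray,
    sigma: int,
    INF: int,
    counter: TouchCounter | None = None,
) -> BoundaryState:
    """One column of the modified-pBWT update (counting sort on ``(a, e)``).

    Appends the new boundary ``k + 1``, recomputes ``a``/``e`` with the
    jump-pointer maximum scheme (valid because ``e`` is order-isomorphic to
    ``d``), recounts ``t``, and drops vanished ``s`` entries while merging
    their ``u`` minima into the following interval.
    """
    m = len(state.e)
    k = state.k + 1
    s = state.s + [k + 1]
    u = state.u + [INF]
    upos = state.upos + [k - 1]
    new_index = len(s) - 1  # index of the appended boundary k + 1

    counts = np.bincount(column, minlength=sigma)
    offsets = np.zeros(sigma, dtype=np.int64)
    offsets[1:] = np.cumsum(counts)[:-1]

    jump = list(range(1, m + 1))
    vmax = list(state.e)
    P = [-1] * sigma
    a_new = np.empty(m, dtype=np.int64)
    e_new = [0] * m
    if counter is not None:
        counter.start_column()
    a_prev = state.a
    for i in range(m):
        row = int(a_prev[i])
        b = int(column[row])
        slot = int(offsets[b])
        offsets[b] += 1
        a_new[slot] = row
        if P[b] < 0:
            e_new[slot] = new_index
        else:
            val, touched = maxd(P[b] + 1, i, jump, vmax)
            e_new[slot] = val
            if counter is not None:
                counter.add(touched)
        P[b] = i

    t = [0] * len(s)
    for idx in e_new:
        t[idx] += 1

    # Cleanup: drop s entries with t == 0, folding their u minima into the
    # next surviving interval; tmp re-indexes e afterwards.
    tmp = [0] * len(s)
    s2: list[int] = []
    t2: list[int] = []
    u2: list[int] = []
    upos2: list[int] = []
    pend_u, pend_pos = INF + 1, -1
    for i in range(len(s)):
        cu, cp = _merge_min(pend_u, pend_pos, u[i], upos[i])
        if t[i] > 0:
            tmp[i] = len(s2)
            s2.append(s[i])
            t2.append(t[i])
            u2.append(cu)
            upos2.append(cp)
            pend_u, pend_pos = INF + 1, -1
        else:
            pend_u, pend_pos = cu, cp
    if pend_u <= INF:  # the last entry always survives (t > 0)
        raise AssertionError("dangling minimum after cleanup")
    e_final = [tmp[idx] for idx in e_new]
    if sum(t2) != m:
        raise AssertionError("inconsistent boundary state: sum(t) != m")
    return BoundaryState(k=k, a=a_new, e=e_final, s=s2, t=t2, u=u2, upos=upos2)


def solve(
    mat: RecombinantMatrix,
    L: int,
    keep_M: bool = False,
    counter: TouchCounter | None = None,
) -> SegmentationResult:
    """Streaming minimum-segmentation solver (linear time in ``m * n``).

    Processes the columns left to right; after each column ``k`` the optimum
    ``M(k)`` for the prefix is available.  The retained state is the boundary
    arrays (``O(m)`` integers), the circular buffer of the last ``L`` values
    of ``M``, and the backtracking array.  The returned segmentation attains
    ``founder_count`` and all its segments have length at least ``L``.
    """
    n = mat.n_columns
    m = mat.m
    if not 1 <= L <= n:
        raise InfeasibleError(f"infeasible: L={L} must satisfy 1 <= L <= n={n}")
    INF = m + 1
    state = BoundaryState(
        k=0,
        a=np.arange(m),
        e=[0] * m,
        s=[1],
        t=[m],
        u=[INF],
        upos=[0],
    )
    recent_M: deque[int] = deque(maxlen=L)  # M(k-L) ... M(k-1), oldest first
    B = np.zeros(n + 1, dtype=np.int64)
    M_all: list[int] | None = [0] if keep_M else None
    peak_buffer = 0
    peak_state = 0

    for k in range(1, n + 1):
        column = mat.column(k)
        state = _advance_boundary_state(state, column, mat.sigma, INF, counter)

        if k >= 2 * L:
            # Position k - L just became a legal predecessor: fold its DP
            # value into the u entry of the interval containing it.
            ell = k - L
            jj = bisect_left(state.s, ell + 2)
            M_kL = recent_M[0]
            state.u[jj], state.upos[jj] = _merge_min(
                state.u[jj], state.upos[jj], M_kL, ell
            )

        if k < L:
            Mk, Bk = INF, 0
        elif k < 2 * L:
            # Single segment [1, k]: |R[1, k]| = m minus rows whose
            # divergence is 1 (they duplicate their sorted predecessor).
            Mk = m - (state.t[0] if state.s[0] == 1 else 0)
            Bk = 0
        else:
            cards = segment_cardinalities(state)
            best, best_pos = INF + 1, 0
            for j in range(len(state.u)):
                cand = max(cards[j], state.u[j])
                if cand < best:
                    best, best_pos = cand, state.upos[j]
            Mk, Bk = best, best_pos
        B[k] = Bk
        recent_M.append(Mk)
        if M_all is not None:
            M_all.append(Mk)
        peak_buffer = max(peak_buffer, len(recent_M))
        peak_state = max(
            peak_state,
            len(state.s) + len(state.t) + len(state.u) + len(state.upos) + len(state.e) + len(state.a),
        )

    M_n = recent_M[-1]
    if M_n >= INF:
        raise InfeasibleError("no segmentation satisfies the length bound")
    segments = backtrack(B, n, L)
    counts = [distinct_count_naive(mat, a, b) for a, b in segments]
    return SegmentationResult(
        founder_count=int(M_n),
        segments=segments,
        counts=counts,
        L=L,
        backtrack=B,
        M=M_all,
        instrumentation={
            "peak_M_buffer": peak_buffer,
            "peak_state_ints": peak_state,
            "m": m,
            "L": L,
        },
    )
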