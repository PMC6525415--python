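"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: segmentations
are enumerated exhaustively, range maxima come from linear scans, parses from
a minimum-switch dynamic programme over (position, founder) states, and
matchings from brute-force permutation search.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from founderseq import RecombinantMatrix, random_matrix


TOY_STRINGS = ["baaaa", "baaab", "babab"]


@pytest.fixture
def toy() -> RecombinantMatrix:
    """The three-recombinant instance {baaaa, baaab, babab}."""
    return RecombinantMatrix.from_strings(TOY_STRINGS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_instances(count, seed, m_range=(1, 8), n_range=(1, 40), sigmas=(2, 4),
                     L_range=None):
    """Yield (matrix, L) pairs with n >= L, reproducibly."""
    gen = np.random.default_rng(seed)
    for _ in range(count):
        m = int(gen.integers(m_range[0], m_range[1] + 1))
        sigma = int(gen.choice(sigmas))
        if L_range is not None:
            L = int(gen.integers(L_range[0], L_range[1] + 1))
            n = int(gen.integers(max(L, n_range[0]), n_range[1] + 1))
        else:
            L = 1
            n = int(gen.integers(n_range[0], n_range[1] + 1))
        mat = random_matrix(m, n, sigma, seed=int(gen.integers(2**31)))
        yield mat, L


# ---------------------------------------------------------------------------
# Oracles


def distinct_by_set(mat: RecombinantMatrix, a: int, b: int) -> int:
    """Distinct substrings over 1-based [a, b] by direct hashing."""
    return len({mat.substring(i, a, b) for i in range(mat.m)})


def enumerate_segmentations(n: int, L: int):
    """All tilings of [1, n] into intervals of length >= L (compositions)."""

    def rec(start):
        if start > n:
            yield []
            return
        for end in range(start + L - 1, n + 1):
            if n - end != 0 and n - end < L:
                continue
            for rest in rec(end + 1):
                yield [(start, end)] + rest

    yield from rec(1)


def best_segmentation_bruteforce(mat: RecombinantMatrix, L: int) -> int:
    """Exhaustive minimum over all valid segmentations of the max cardinality."""
    best = mat.m + 1
    for seg in enumerate_segmentations(mat.n_columns, L):
        value = max(distinct_by_set(mat, a, b) for a, b in seg)
        best = min(best, value)
    return best


def min_crossovers_dp(seq: str, founders: list[str]) -> int:
    """Minimum-switch DP over (position, founder) — the parse oracle."""
    INF = 10**9
    cost = [0 if f[0] == seq[0] else INF for f in founders]
    for p in range(1, len(seq)):
        cheapest = min(cost)
        new = []
        for fi, f in enumerate(founders):
            if f[p] != seq[p]:
                new.append(INF)
            else:
                new.append(min(cost[fi], cheapest + 1))
        cost = new
    best = min(cost)
    if best >= INF:
        raise ValueError("founder set does not cover input")
    return best


def min_crossovers_enumeration(seq: str, founders: list[str]) -> int:
    """Full enumeration over founder mosaics (tiny n only)."""
    n = len(seq)
    best = None
    for path in itertools.product(range(len(founders)), repeat=n):
        if any(founders[f][p] != seq[p] for p, f in enumerate(path)):
            continue
        switches = sum(1 for p in range(1, n) if path[p] != path[p - 1])
        if best is None or switches < best:
            best = switches
    if best is None:
        raise ValueError("founder set does not cover input")
    return best


def best_matching_bruteforce(weights: np.ndarray) -> int:
    """Maximum-weight perfect matching by trying every permutation."""
    size = weights.shape[0]
    return max(
        sum(int(weights[i, p[i]]) for i in range(size))
        for p in itertools.permutations(range(size))
    )
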