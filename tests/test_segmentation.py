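"""Minimum segmentation: naive DP oracle, streaming solver, boundary state."""

import numpy as np
import pytest

from founderseq import (
    InfeasibleError,
    RecombinantMatrix,
    distinct_count_naive,
    dp_naive,
    pbwt_naive,
    random_matrix,
    solve,
)
from founderseq.segmentation import (
    backtrack,
    distinct_counts_ending_at,
    segment_cardinalities,
    BoundaryState,
    _advance_boundary_state,
)

from conftest import (
    best_segmentation_bruteforce,
    distinct_by_set,
    random_instances,
)


def assert_valid(result, mat, L):
    assert all(b - a + 1 >= L for a, b in result.segments)
    flat = [c for a, b in result.segments for c in range(a, b + 1)]
    assert flat == list(range(1, mat.n_columns + 1))
    assert max(result.counts) == result.founder_count


class TestDistinctCounts:
    def test_toy_segments(self, toy):
        assert distinct_count_naive(toy, 1, 1) == 1
        assert distinct_count_naive(toy, 2, 3) == 2
        assert distinct_count_naive(toy, 4, 5) == 2

    def test_identical_rows(self):
        mat = RecombinantMatrix.from_strings(["AC", "AC", "AC"])
        assert distinct_count_naive(mat, 1, 2) == 1

    def test_count_nonincreasing_in_left_endpoint(self, rng):
        for _ in range(20):
            mat = random_matrix(int(rng.integers(2, 7)), int(rng.integers(2, 15)),
                                3, seed=int(rng.integers(2**31)))
            k = mat.n_columns
            counts = [distinct_count_naive(mat, j, k) for j in range(1, k + 1)]
            assert all(x >= y for x, y in zip(counts, counts[1:]))

    def test_refinement_matches_direct_hashing(self, rng):
        for _ in range(20):
            mat = random_matrix(int(rng.integers(1, 8)), int(rng.integers(1, 20)),
                                4, seed=int(rng.integers(2**31)))
            k = int(rng.integers(1, mat.n_columns + 1))
            counts = distinct_counts_ending_at(mat, k)
            for j in range(1, k + 1):
                assert counts[j] == distinct_by_set(mat, j, k)

    def test_invalid_range_rejected(self, toy):
        with pytest.raises(ValueError):
            distinct_count_naive(toy, 3, 2)


class TestNaiveDP:
    def test_toy_L1(self, toy):
        res = dp_naive(toy, 1)
        assert res.founder_count == 2
        assert res.M == [0, 1, 1, 2, 2, 2]
        assert res.segments == [(1, 3), (4, 5)]

    def test_toy_forced_single_segment(self, toy):
        res = dp_naive(toy, 5)
        assert res.founder_count == 3
        assert res.segments == [(1, 5)]

    def test_identical_rows_single_founder(self):
        mat = RecombinantMatrix.from_strings(["ACGT"] * 4)
        for L in (1, 2, 4):
            assert dp_naive(mat, L).founder_count == 1

    def test_matches_exhaustive_enumeration(self):
        for mat, _ in random_instances(40, seed=5, m_range=(1, 5),
                                       n_range=(1, 9), sigmas=(2, 3)):
            for L in range(1, mat.n_columns + 1):
                assert dp_naive(mat, L).founder_count == \
                    best_segmentation_bruteforce(mat, L)

    def test_infeasible_L(self, toy):
        with pytest.raises(InfeasibleError):
            dp_naive(toy, 6)
        with pytest.raises(InfeasibleError):
            dp_naive(toy, 0)


class TestBacktrack:
    def test_two_segments(self):
        B = np.array([0, 0, 0, 0, 0, 3])
        assert backtrack(B, 5, 1) == [(1, 3), (4, 5)]

    def test_single_segment(self):
        B = np.zeros(6, dtype=int)
        assert backtrack(B, 5, 5) == [(1, 5)]

    def test_n_equals_L_forced(self, toy):
        res = solve(toy, 5)
        assert res.segments == [(1, 5)]


class TestBoundaryState:
    @staticmethod
    def run_states(mat, L):
        """Advance the boundary state over all columns, yielding per-column."""
        m = mat.m
        INF = m + 1
        state = BoundaryState(k=0, a=np.arange(m), e=[0] * m, s=[1], t=[m],
                              u=[INF], upos=[0])
        for k in range(1, mat.n_columns + 1):
            state = _advance_boundary_state(state, mat.column(k), mat.sigma, INF)
            yield state

    def test_state_reconstructs_divergence_array(self):
        for mat, _ in random_instances(30, seed=17, m_range=(1, 8),
                                       n_range=(1, 24), sigmas=(2, 4)):
            for state in self.run_states(mat, L=1):
                oracle = pbwt_naive(mat, state.k)
                assert state.a.tolist() == oracle.a.tolist()
                assert state.reconstruct_d().tolist() == oracle.d.tolist()
                # t counts multiplicities of each s entry in d
                d = oracle.d.tolist()
                for s_val, t_val in zip(state.s, state.t):
                    assert d.count(s_val) == t_val
                assert sum(state.t) == mat.m
                assert state.s == sorted(set(d))
                assert state.s[-1] == state.k + 1

    def test_multiplicity_structure_with_four_distinct_values(self):
        # When d_k has 4 distinct values with multiplicities (2,1,1,2) in
        # increasing order, t mirrors them and sums to m = 6.
        found = False
        for mat, _ in random_instances(300, seed=23, m_range=(6, 6),
                                       n_range=(4, 16), sigmas=(3, 4)):
            for state in self.run_states(mat, L=1):
                if state.t == [2, 1, 1, 2]:
                    found = True
                    assert sum(state.t) == 6
                    d = pbwt_naive(mat, state.k).d.tolist()
                    assert state.s == sorted(set(d))
        assert found, "no instance realised the (2,1,1,2) multiplicity pattern"

    def test_cardinalities_are_suffix_sums(self):
        state = BoundaryState(k=7, a=np.arange(6), e=[0] * 6,
                              s=[3, 5, 7, 8], t=[2, 1, 1, 2],
                              u=[7, 7, 7, 7], upos=[0, 0, 0, 0])
        assert segment_cardinalities(state) == [6, 4, 3, 2]

    def test_cardinalities_single_block(self):
        state = BoundaryState(k=3, a=np.arange(4), e=[0] * 4, s=[4], t=[4],
                              u=[5], upos=[0])
        assert segment_cardinalities(state) == [4]

    def test_cardinalities_match_naive_counts(self):
        for mat, _ in random_instances(20, seed=31, m_range=(2, 8),
                                       n_range=(2, 20), sigmas=(2, 4)):
            for state in self.run_states(mat, L=1):
                cards = segment_cardinalities(state)
                for j, s_val in enumerate(state.s):
                    if s_val >= 2:  # s[j]-1 is a valid 1-based start
                        assert cards[j] == distinct_by_set(mat, s_val - 1, state.k)

    def test_boundary_positions_are_divergence_minus_one(self):
        # d_k[i]-1 marks exactly the window starts where the distinct count
        # changes.
        for mat, _ in random_instances(25, seed=41, m_range=(2, 7),
                                       n_range=(2, 16), sigmas=(2, 3)):
            n = mat.n_columns
            for k in range(1, n + 1):
                d = pbwt_naive(mat, k).d.tolist()
                from_d = {v - 1 for v in d if 1 <= v - 1 <= k - 1}
                changes = {
                    j for j in range(1, k)
                    if distinct_by_set(mat, j, k) != distinct_by_set(mat, j + 1, k)
                }
                assert from_d == changes


class TestStreamingSolver:
    def test_toy_L1(self, toy):
        res = solve(toy, 1, keep_M=True)
        assert res.founder_count == 2
        assert res.M == [0, 1, 1, 2, 2, 2]
        assert_valid(res, toy, 1)

    def test_matches_oracle_values_and_validity(self):
        for mat, L in random_instances(120, seed=3, m_range=(1, 8),
                                       n_range=(1, 40), sigmas=(2, 4),
                                       L_range=(1, 8)):
            oracle = dp_naive(mat, L)
            res = solve(mat, L, keep_M=True)
            assert res.founder_count == oracle.founder_count
            assert res.M == oracle.M
            assert_valid(res, mat, L)

    def test_L1_equals_max_column_distinct(self):
        for mat, _ in random_instances(40, seed=59, m_range=(1, 8),
                                       n_range=(1, 30), sigmas=(2, 4)):
            lower = max(distinct_by_set(mat, j, j)
                        for j in range(1, mat.n_columns + 1))
            assert solve(mat, 1).founder_count == lower

    def test_monotone_in_L(self):
        for mat, _ in random_instances(15, seed=67, m_range=(2, 6),
                                       n_range=(6, 24), sigmas=(2, 4)):
            values = [solve(mat, L).founder_count
                      for L in range(1, mat.n_columns + 1)]
            assert all(x <= y for x, y in zip(values, values[1:]))

    def test_bounds(self):
        for mat, L in random_instances(30, seed=83, m_range=(1, 8),
                                       n_range=(1, 24), sigmas=(2, 4),
                                       L_range=(1, 6)):
            res = solve(mat, L)
            lower = max(distinct_by_set(mat, j, j)
                        for j in range(1, mat.n_columns + 1))
            assert lower <= res.founder_count <= mat.m

    def test_single_row(self):
        mat = random_matrix(1, 12, 4, seed=7)
        for L in (1, 5, 12):
            assert solve(mat, L).founder_count == 1

    def test_streaming_space_instrumentation(self):
        mat = random_matrix(8, 120, 4, seed=11)
        L = 9
        res = solve(mat, L)
        inst = res.instrumentation
        # circular buffer holds exactly the last L values of M
        assert inst["peak_M_buffer"] == L
        # boundary-state arrays stay O(m): a + e are m each, s/t/u/upos <= m+1
        assert inst["peak_state_ints"] <= 6 * mat.m + 4

    def test_infeasible_inputs(self, toy):
        with pytest.raises(InfeasibleError):
            solve(toy, 6)
        with pytest.raises(InfeasibleError):
            solve(toy, 0)
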