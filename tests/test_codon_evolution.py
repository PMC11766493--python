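"""Genetic-code assignment: probabilities, gating, and the union rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from warmpond import (
    CodonAssignmentState,
    Vesicle,
    assignment_probability,
    attempt_assignment,
    combination_pool_size,
    union_assignments,
)
from warmpond.codons import EARLY_AAS, LATE_AAS, respects_early_before_late


def _vesicle(n_p, aas):
    return Vesicle(0, [5] * n_p, [15] * (3 * n_p), set(aas))


class TestPoolSize:
    @pytest.mark.parametrize("b, expected", [(4, 1280), (5, 2500), (6, 4320)])
    def test_pool_values(self, b, expected):
        assert combination_pool_size(b) == expected

    @pytest.mark.parametrize("b", [3, 7, 0, -1])
    def test_out_of_range_nucleotide_counts(self, b):
        with pytest.raises(ValueError, match="must be 4, 5 or 6"):
            combination_pool_size(b)


class TestAssignmentProbability:
    def test_fixed_mode_is_constant(self):
        assert all(assignment_probability(n) == 0.999 for n in range(20))

    @pytest.mark.parametrize(
        "n, expected",
        [(0, 1e-3), (10, 4e-3), (19, 0.4)],
    )
    def test_feedback_values(self, n, expected):
        assert assignment_probability(n, feedback_mode=True) == pytest.approx(expected)

    def test_feedback_strictly_increasing(self):
        probs = [assignment_probability(n, feedback_mode=True) for n in range(20)]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    @pytest.mark.parametrize("n", [-1, 20, 25])
    def test_invalid_count_rejected(self, n):
        with pytest.raises(ValueError, match="0..19"):
            assignment_probability(n)


class TestAttemptAssignment:
    def test_no_attempt_outside_pair_end_cycles(self, rng):
        v = _vesicle(45, range(1, 20))
        state = CodonAssignmentState(p_synchronize=1.0)
        attempt_assignment(v, state, cycle_index=3, rng=rng)
        assert v.n_assigned == 19
        attempt_assignment(v, state, cycle_index=4, rng=rng)
        assert v.n_assigned == 20

    def test_certain_assignment_completes_code(self, rng):
        v = _vesicle(45, range(1, 20))
        state = CodonAssignmentState(p_synchronize=1.0)
        attempt_assignment(v, state, cycle_index=2, rng=rng)
        assert v.assigned_aas == set(range(1, 21))

    def test_non_fuca_never_assigns_late(self, rng):
        v = _vesicle(15, range(1, 11))  # V3 with complete early block
        state = CodonAssignmentState(p_synchronize=1.0)
        for cycle in range(2, 40, 2):
            attempt_assignment(v, state, cycle, rng)
        assert v.n_assigned == 10

    def test_early_block_filled_before_late(self, rng):
        """With only 6 early AAs the next candidate is early, never late."""
        v = _vesicle(45, [1, 2, 3, 4, 5, 6])
        state = CodonAssignmentState(p_synchronize=1.0, candidate_mode="lowest")
        attempt_assignment(v, state, cycle_index=2, rng=rng)
        assert v.assigned_aas == {1, 2, 3, 4, 5, 6, 7}

    def test_stage_gate_blocks_late_assignment(self, rng):
        v = _vesicle(45, range(1, 11))
        state = CodonAssignmentState(p_synchronize=1.0, allow_late=False)
        for cycle in range(2, 20, 2):
            attempt_assignment(v, state, cycle, rng)
        assert v.n_assigned == 10

    def test_at_most_one_aa_per_wet_dry_pair(self, rng):
        v = _vesicle(45, [])
        state = CodonAssignmentState(p_synchronize=1.0)
        attempt_assignment(v, state, cycle_index=2, rng=rng)
        assert v.n_assigned == 1

    def test_fixed_mode_completion_rate_matches_closed_form(self):
        """A lone FUCA at NA=14 completes in 6 wet-dry pairs w.p. 0.999**6.

        2000 independent lineages; the empirical completion fraction must
        sit within 4 sigma of the closed form (~0.994).
        """
        rng = np.random.default_rng(7)
        state = CodonAssignmentState(p_synchronize=0.999)
        n_reps, hits = 2000, 0
        for _ in range(n_reps):
            v = _vesicle(45, range(1, 15))
            for cycle in range(2, 14, 2):  # six pair-ends
                attempt_assignment(v, state, cycle, rng)
            hits += v.n_assigned == 20
        expected = 0.999**6
        sigma = (expected * (1 - expected) / n_reps) ** 0.5
        assert abs(hits / n_reps - expected) < 4 * sigma + 1e-9


valid_sets = st.one_of(
    # early-only subsets
    st.sets(st.integers(1, 10), max_size=10),
    # complete early block plus any late subset
    st.sets(st.integers(11, 20), max_size=10).map(lambda late: set(range(1, 11)) | late),
)


class TestUnion:
    def test_worked_example(self):
        assert union_assignments({1, 2, 3, 4, 5}, {1, 2, 3, 4, 6}) == {1, 2, 3, 4, 5, 6}

    def test_idempotent(self):
        s = {1, 2, 3, 9}
        assert union_assignments(s, s) == s

    def test_late_union(self):
        a = set(range(1, 11)) | {11}
        b = set(range(1, 11)) | {12}
        assert union_assignments(a, b) == set(range(1, 13))

    @given(valid_sets, valid_sets)
    @settings(derandomize=True, max_examples=200)
    def test_union_preserves_early_before_late(self, a, b):
        assert respects_early_before_late(union_assignments(a, b))

    @given(st.lists(valid_sets, min_size=2, max_size=6), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=100)
    def test_invariant_under_random_interleavings(self, sets, seed):
        """Any mix of assignment attempts and unions keeps the invariant
        and never decreases NA."""
        rng = np.random.default_rng(seed)
        state = CodonAssignmentState(p_synchronize=1.0, candidate_mode="random")
        vesicles = [_vesicle(45, s) for s in sets]
        for cycle in range(2, 14, 2):
            for v in vesicles:
                before = v.n_assigned
                if rng.random() < 0.5:
                    attempt_assignment(v, state, cycle, rng)
                else:
                    other = vesicles[int(rng.integers(len(vesicles)))]
                    v.assigned_aas = union_assignments(v.assigned_aas, other.assigned_aas)
                assert respects_early_before_late(v.assigned_aas)
                assert v.n_assigned >= before
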