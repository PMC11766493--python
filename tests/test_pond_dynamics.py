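"""Cycle engine: volume, contacts, encounters, joining, absorption, survival."""

import numpy as np
import pytest

from warmpond import (
    JoinRuleTable,
    MergeMatrix,
    PondState,
    SimulationConfig,
    Vesicle,
    absorb_monomers,
    apply_breakage,
    contact_probability,
    join_biopolymers,
    merge_vesicles,
    resolve_encounter,
    sample_contacts,
    survival_lottery,
    update_volume,
)
from warmpond.pond import _resolve_all


def _vesicle(vid, n_p, n_r=None, n_a=5, pep_len=5):
    n_r = 3 * n_p if n_r is None else n_r
    return Vesicle(vid, [pep_len] * n_p, [15] * n_r, set(range(1, n_a + 1)))


def _state(vesicles, seed=0, contact_base=1e-5):
    return PondState(rng=np.random.default_rng(seed), vesicles=vesicles, contact_base=contact_base)


class TestVolumeAndContact:
    def test_volume_bands(self, rng):
        for _ in range(200):
            assert 50 <= update_volume("dry", rng) <= 80
            assert 80 <= update_volume("wet", rng) <= 100

    def test_unknown_phase_rejected(self, rng):
        with pytest.raises(ValueError, match="wet.*dry"):
            update_volume("damp", rng)

    @pytest.mark.parametrize(
        "base, volume, expected",
        [(1e-5, 100, 1e-5), (1e-5, 50, 4e-5), (1e-6, 80, 1.5625e-6)],
    )
    def test_contact_probability_scales_inverse_square(self, base, volume, expected):
        assert contact_probability(base, volume) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            contact_probability(1e-5, 0)


class TestSampleContacts:
    def test_zero_probability_yields_no_contacts(self):
        state = _state([_vesicle(i, 3) for i in range(10)])
        assert sample_contacts(state, 0.0) == []

    def test_single_pair_certain_contact(self):
        state = _state([_vesicle(0, 3), _vesicle(1, 3)])
        pairs = sample_contacts(state, 1.0)
        assert len(pairs) == 1
        assert set(pairs[0]) == {0, 1}

    def test_pairs_are_disjoint(self):
        state = _state([_vesicle(i, 3) for i in range(21)])
        pairs = sample_contacts(state, 1.0)
        flat = [i for pair in pairs for i in pair]
        assert len(flat) == len(set(flat))
        assert len(pairs) == 10  # at most one encounter per vesicle

    def test_matches_per_pair_bernoulli_oracle(self):
        """Binomial event-count sampling agrees with a brute-force
        per-pair Bernoulli sweep (with the one-encounter-per-vesicle
        rule) at small N over 1e5 repetitions."""
        n, pc, reps = 6, 1e-3, 100_000
        state = _state([_vesicle(i, 3) for i in range(n)], seed=11)
        sampler_total = sum(len(sample_contacts(state, pc)) for _ in range(reps))

        # independent oracle: sweep all 15 pairs in random order, each
        # fires with pc unless a member is already engaged
        rng = np.random.default_rng(99)
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        fired = rng.random((reps, len(all_pairs))) < pc
        oracle_total = 0
        for row in np.flatnonzero(fired.any(axis=1)):
            order = rng.permutation(len(all_pairs))
            used: set[int] = set()
            for idx in order:
                if fired[row, idx]:
                    i, j = all_pairs[idx]
                    if i not in used and j not in used:
                        used.update((i, j))
                        oracle_total += 1
        mean_events = len(all_pairs) * pc
        sigma = (mean_events / reps) ** 0.5  # Poisson-scale MC error
        assert abs(sampler_total - oracle_total) / reps < 5 * sigma


class TestEncounters:
    def test_merge_conserves_counts_and_unions_codons(self):
        a = Vesicle(0, [5, 8], [15, 15, 15, 15, 15], {1, 2, 3, 4, 5})
        b = Vesicle(1, [4, 4, 4], [12] * 8, {1, 2, 3, 4, 6})
        merged = merge_vesicles(a, b)
        assert merged.n_peptides == 5
        assert merged.n_rnas == 13
        assert merged.assigned_aas == {1, 2, 3, 4, 5, 6}

    def test_v2_always_absorbs_v1(self, rng):
        """Exact 0/1 matrix entries stay exact under jitter."""
        matrix = MergeMatrix()
        for _ in range(200):
            v1, v2 = _vesicle(0, 3), _vesicle(1, 7)
            winner, absorbed = resolve_encounter(v1, v2, matrix, rng)
            assert winner is v2 and absorbed is v1

    def test_equal_types_absorb_evenly(self, rng):
        matrix = MergeMatrix()
        wins = 0
        n_reps = 4000
        for _ in range(n_reps):
            a, b = _vesicle(0, 15), _vesicle(1, 15)
            winner, _ = resolve_encounter(a, b, matrix, rng)
            wins += winner is a
        assert abs(wins / n_reps - 0.5) < 0.04

    def test_jitter_stays_within_five_to_ten_percent(self, rng):
        matrix = MergeMatrix()
        for _ in range(500):
            p = matrix.absorb_probability(5, 1, rng)  # V6 vs V2, nominal 0.9
            rel = abs(p / 0.9 - 1.0)
            assert 0.05 <= rel <= 0.10

    def test_disabled_merging_is_a_no_op(self, rng):
        a, b = _vesicle(0, 3), _vesicle(1, 7)
        assert resolve_encounter(a, b, MergeMatrix(), rng, merge_enabled=False) is None
        assert a.n_peptides == 3 and b.n_peptides == 7

    def test_population_totals_conserved_by_encounter_pass(self):
        state = _state([_vesicle(i, 3 + i) for i in range(20)], seed=3)
        total_p = sum(v.n_peptides for v in state.vesicles)
        total_r = sum(v.n_rnas for v in state.vesicles)
        pairs = sample_contacts(state, 1.0)
        _resolve_all(state, pairs, MergeMatrix(), merge_enabled=True)
        assert sum(v.n_peptides for v in state.vesicles) == total_p
        assert sum(v.n_rnas for v in state.vesicles) == total_r
        assert state.cumulative_dead == len(pairs)


class TestJoining:
    def _certain_rules(self):
        ones = np.ones((4, 4))
        return JoinRuleTable(peptide_probs=ones.copy(), rna_probs=ones.copy())

    def test_certain_join_merges_one_pair(self, rng):
        v = Vesicle(0, [5, 8], [], set())
        join_biopolymers(v, self._certain_rules(), rng)
        assert v.peptides == [13]

    def test_molecule_joins_at_most_once_per_cycle(self, rng):
        v = Vesicle(0, [5, 5, 5], [], set())
        join_biopolymers(v, self._certain_rules(), rng)
        assert sorted(v.peptides) == [5, 10]
        assert sum(v.peptides) == 15

    def test_single_molecule_cannot_join(self, rng):
        v = Vesicle(0, [9], [21], set())
        join_biopolymers(v, JoinRuleTable(), rng)
        assert v.peptides == [9] and v.rnas == [21]

    def test_length_classes_pick_the_table_cell(self):
        rules = JoinRuleTable()
        assert rules.peptide_probs[rules.peptide_class(5), rules.peptide_class(8)] == pytest.approx(1e-5)
        assert rules.peptide_probs[rules.peptide_class(60), rules.peptide_class(60)] == pytest.approx(0.01e-5)
        assert rules.rna_probs[rules.rna_class(20), rules.rna_class(45)] == pytest.approx(0.6e-5)

    def test_join_probabilities_symmetric(self):
        rules = JoinRuleTable()
        assert np.allclose(rules.peptide_probs, rules.peptide_probs.T)
        assert np.allclose(rules.rna_probs, rules.rna_probs.T)


class TestAbsorption:
    def test_zero_probability_changes_nothing(self, rng):
        v = _vesicle(0, 3)
        absorb_monomers(v, 0.0, rng)
        assert v.n_peptides == 3 and v.n_rnas == 9

    def test_add_mode_appends_one_of_each(self, rng):
        v = _vesicle(0, 3)
        absorb_monomers(v, 1.0, rng, mode="add")
        assert v.n_peptides == 4 and v.n_rnas == 10
        assert 3 <= v.peptides[-1] <= 10
        assert v.rnas[-1] % 3 == 0

    def test_elongate_mode_keeps_counts(self, rng):
        v = _vesicle(0, 3)
        before_p, before_r = sum(v.peptides), sum(v.rnas)
        absorb_monomers(v, 1.0, rng, mode="elongate")
        assert v.n_peptides == 3 and v.n_rnas == 9
        assert sum(v.peptides) > before_p and sum(v.rnas) > before_r


class TestBreakageAndSurvival:
    def test_breakage_extremes(self):
        state = _state([_vesicle(i, 3) for i in range(50)])
        apply_breakage(state, state.rng, 0.0)
        assert state.n_alive == 50
        apply_breakage(state, state.rng, 1.0)
        assert state.n_alive == 0
        assert state.cumulative_dead == 50

    def test_merged_vesicles_are_exempt_this_cycle(self):
        doomed = Vesicle(0, [5], [15], set())  # FS = 0 -> certain death
        saved = Vesicle(1, [5], [15], set(), merged_this_cycle=True)
        state = _state([doomed, saved])
        survival_lottery(state)
        assert state.vesicles == [saved]
        assert state.cumulative_dead == 1
        assert saved.merged_this_cycle is False  # flag reset after lottery

    def test_high_fitness_guarantees_survival(self):
        immortal = Vesicle(0, [5] * 2000, [15] * 6000, set(range(1, 21)))  # FS >> e^10
        state = _state([immortal])
        for _ in range(50):
            survival_lottery(state)
        assert state.n_alive == 1
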