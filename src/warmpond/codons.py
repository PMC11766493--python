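"""Genetic-code (SGC) assignment dynamics.

The standard genetic code is modelled as the set of amino acids that have
been assigned a codon set; the code is complete at 20. Two rules shape its
evolution here:

* **Early before late.** A protocell must assign all ten early amino acids
  (indices 1..10) before it may assign any of the ten late ones (11..20),
  and only FUCAs (type-V6 vesicles) may perform late assignments.
* **One per wet-and-dry cycle.** A vesicle can add at most one amino acid
  per whole wet-and-dry cycle, i.e. per two simulator cycles; attempts run
  at the end of each wet phase.

The per-attempt success probability is either fixed (``pSynchronize``,
default 0.999) or follows a positive-feedback law
``P(n) = base * (20 / (20 - n))**2`` where ``n`` is the number of AAs
already assigned: each assignment shrinks the remaining codon pool and so
accelerates the next one. With base 1e-3 this rises from 1e-3 at n = 0 to
0.4 at n = 19.

The codon-combination pool — 20 * b**3 combinations for b in {4, 5, 6}
available nucleotides, i.e. 1280..4320 — is drawn once per run and recorded
for provenance; it does not modulate the assignment probability.

On merger the absorbing vesicle obtains the union of both assignment sets
("horizontal biomolecule transfer"); the union of two sets that each
respect early-before-late respects it too, because late AAs only ever occur
in sets already containing all ten early AAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vesicles import N_AMINO_ACIDS, N_EARLY_AAS, Vesicle, is_fuca

__all__ = [
    "EARLY_AAS",
    "LATE_AAS",
    "CodonAssignmentState",
    "combination_pool_size",
    "assignment_probability",
    "attempt_assignment",
    "union_assignments",
    "respects_early_before_late",
    "lowest_unassigned",
]

EARLY_AAS = frozenset(range(1, N_EARLY_AAS + 1))
LATE_AAS = frozenset(range(N_EARLY_AAS + 1, N_AMINO_ACIDS + 1))


@dataclass
class CodonAssignmentState:
    """Run-level configuration of the assignment machinery.

    Parameters
    ----------
    pool_size
        Codon-combination pool, 20 * b**3 for b in {4, 5, 6}; recorded in
        run summaries, not used by the dynamics.
    p_synchronize
        Fixed per-wet-dry-cycle success probability (default 0.999).
    feedback_mode
        Use the positive-feedback probability law instead of the fixed one.
    base_p
        Base probability of the feedback law (default 1e-3).
    allow_early, allow_late
        Stage gates: stage-1 runs disable late assignment entirely; in all
        stages late assignment additionally requires type V6.
    candidate_mode
        ``"lowest"`` (default, deterministic) picks the lowest-index
        unassigned AA; ``"random"`` picks a uniform unassigned one. AA
        identities are interchangeable in this model, so the choice only
        affects bookkeeping.
    """

    pool_size: int = 2500
    p_synchronize: float = 0.999
    feedback_mode: bool = False
    base_p: float = 1e-3
    allow_early: bool = True
    allow_late: bool = True
    candidate_mode: str = "lowest"


def combination_pool_size(b: int) -> int:
    """Number of AA/codon combinations with ``b`` available nucleotides.

    20 amino acids times b**3 triplet codons: 1280, 2500, 4320 for
    b = 4, 5, 6.
    """
    if b not in (4, 5, 6):
        raise ValueError(f"nucleotide count b must be 4, 5 or 6, got {b}")
    return N_AMINO_ACIDS * b**3


def assignment_probability(
    n_assigned: int,
    feedback_mode: bool = False,
    base_p: float = 1e-3,
    p_synchronize: float = 0.999,
) -> float:
    """Per-wet-dry-cycle probability of assigning the next amino acid."""
    if not 0 <= n_assigned <= N_AMINO_ACIDS - 1:
        raise ValueError(f"n_assigned must be in 0..19, got {n_assigned}")
    if feedback_mode:
        return base_p * (N_AMINO_ACIDS / (N_AMINO_ACIDS - n_assigned)) ** 2
    return p_synchronize


def respects_early_before_late(aas: set[int] | frozenset[int]) -> bool:
    """True iff any late AA in the set implies all early AAs are present."""
    return not (aas & LATE_AAS) or EARLY_AAS <= aas


def lowest_unassigned(aas: set[int], late: bool) -> int | None:
    """Lowest unassigned AA index in the early (or late) block, if any."""
    block = LATE_AAS if late else EARLY_AAS
    remaining = block - aas
    return min(remaining) if remaining else None


def _pick_candidate(
    v: Vesicle,
    state: CodonAssignmentState,
    rng: np.random.Generator | None = None,
) -> int | None:
    """Next admissible AA for ``v``, or None when nothing may be assigned.

    Early AAs (in order) until all ten are present; late AAs only for
    FUCAs (V6) and only where the stage gate allows.
    """
    n_early = len(v.assigned_aas & EARLY_AAS)
    if n_early < N_EARLY_AAS:
        if not state.allow_early:
            return None
        remaining = EARLY_AAS - v.assigned_aas
    else:
        if not state.allow_late or not is_fuca(v):
            return None
        remaining = LATE_AAS - v.assigned_aas
        if not remaining:
            return None
    if state.candidate_mode == "lowest" or rng is None:
        return min(remaining)
    return int(rng.choice(sorted(remaining)))


def attempt_assignment(
    v: Vesicle,
    state: CodonAssignmentState,
    cycle_index: int,
    rng: np.random.Generator,
) -> Vesicle:
    """One codon-assignment attempt for one vesicle.

    Attempts only fire at the end of a whole wet-and-dry pair, i.e. on even
    1-based cycle indices; on other cycles the vesicle is returned
    unchanged. At most one AA is added per attempt.
    """
    if cycle_index <= 0 or cycle_index % 2 != 0:
        return v
    candidate = _pick_candidate(v, state, rng)
    if candidate is None:
        return v
    # a candidate exists, so the vesicle has at most 19 AAs assigned
    p = assignment_probability(
        len(v.assigned_aas),
        feedback_mode=state.feedback_mode,
        base_p=state.base_p,
        p_synchronize=state.p_synchronize,
    )
    if rng.random() < p:
        v.assigned_aas.add(candidate)
    return v


def union_assignments(a_set: set[int], b_set: set[int]) -> set[int]:
    """Union of two codon-assignment sets (merger rule)."""
    return set(a_set) | set(b_set)
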