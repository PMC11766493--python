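"""The warm-little-pond cycle engine.

One simulator cycle is one pond phase — dry or wet, strictly alternating,
starting dry from an initiation volume of 100 units. The dry phase shrinks
the pond to 50-80 volume units (raising vesicle contact rates
quadratically) and breaks a small fraction of vesicles; the wet phase
swells it back to 80-100 units and brings a larger influx of fresh V1/V2
vesicles.

Per cycle, in fixed order:

1. phase flip and volume redraw;
2. influx of new V1/V2 vesicles;
3. contact sampling over all unordered pairs (binomial event count, then
   uniform disjoint pairs);
4. encounter resolution: one vesicle absorbs the other with the
   type-vs-type probabilities of :class:`MergeMatrix` (jittered +/-5-10%),
   and gains all peptides, RNAs and codon assignments;
5. within-vesicle biopolymer joining (two peptides -> one longer peptide,
   likewise RNAs) with the length-class probabilities of
   :class:`JoinRuleTable`;
6. monomer absorption from the pond (unlimited supply);
7. codon-assignment attempts (end of each wet-dry pair only);
8. dry-phase breakage;
9. the survival lottery: non-merged vesicles survive with
   PS = ln(FS)/10;
10. census.

The engine is event-count-first throughout: contacts, joins, and
absorption draw how many events occur (one vectorised binomial per cycle)
and then realise only those events, which keeps ~1000-cycle runs with
~5000 agents at desk scale. This is statistically equivalent to per-pair
Bernoulli sweeps (checked against a brute-force oracle at small N in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .codons import CodonAssignmentState, EARLY_AAS, LATE_AAS, assignment_probability
from .vesicles import (
    BELOW_THRESHOLD,
    N_AMINO_ACIDS,
    N_EARLY_AAS,
    TYPE_LABELS,
    Vesicle,
    _NP_LOWER,
    is_luca,
    make_vesicles_batch,
    type_index,
)

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

__all__ = [
    "PondState",
    "MergeMatrix",
    "JoinRuleTable",
    "update_volume",
    "contact_probability",
    "sample_contacts",
    "resolve_encounter",
    "merge_vesicles",
    "join_biopolymers",
    "absorb_monomers",
    "influx",
    "apply_breakage",
    "survival_lottery",
    "step",
]

#: Pond volume bands (units) per phase; initiation is 100.
VOLUME_BANDS = {"dry": (50.0, 80.0), "wet": (80.0, 100.0)}
INITIAL_VOLUME = 100.0

# Row-absorbs-column probabilities, types V1..V6. Each pair (i,j)/(j,i)
# sums to one and the diagonal is an even draw.
_MERGE_PROBS = np.array(
    [
        [0.5, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1.0, 0.5, 0.4, 0.3, 0.2, 0.1],
        [1.0, 0.6, 0.5, 0.4, 0.3, 0.2],
        [1.0, 0.7, 0.6, 0.5, 0.4, 0.3],
        [1.0, 0.8, 0.7, 0.6, 0.5, 0.4],
        [1.0, 0.9, 0.8, 0.7, 0.6, 0.5],
    ]
)

# Joining probabilities by length class, symmetric; identical grid for
# peptides (classes <=10, 11-25, 26-50, >=51 AAs) and RNAs (<=30, 31-60,
# 61-120, >120 nucleotide bases).
_JOIN_PROBS = 1e-5 * np.array(
    [
        [1.0, 0.6, 0.3, 0.1],
        [0.6, 0.3, 0.1, 0.05],
        [0.3, 0.1, 0.05, 0.02],
        [0.1, 0.05, 0.02, 0.01],
    ]
)


@dataclass
class MergeMatrix:
    """Encounter-resolution probabilities between the six vesicle types.

    ``probs[i, j]`` is the probability that a type-``i`` vesicle absorbs a
    type-``j`` one. Each realised encounter perturbs the entry by a
    multiplicative jitter of +/-5-10% (sign and magnitude drawn
    uniformly); exact 0 and 1 entries stay exact — a jittered
    impossibility remains impossible.
    """

    probs: np.ndarray = field(default_factory=lambda: _MERGE_PROBS.copy())
    jitter_range: tuple[float, float] = (0.05, 0.10)

    def absorb_probability(self, i: int, j: int, rng: np.random.Generator) -> float:
        """Jittered probability that the type-``i`` side absorbs type ``j``."""
        p = float(self.probs[i, j])
        if 0.0 < p < 1.0:
            mag = rng.uniform(*self.jitter_range)
            if rng.random() < 0.5:
                mag = -mag
            p = min(1.0, max(0.0, p * (1.0 + mag)))
        return p


@dataclass
class JoinRuleTable:
    """Length-class probabilities for joining two molecules into one."""

    peptide_probs: np.ndarray = field(default_factory=lambda: _JOIN_PROBS.copy())
    rna_probs: np.ndarray = field(default_factory=lambda: _JOIN_PROBS.copy())
    peptide_class_edges: tuple[int, ...] = (10, 25, 50)
    rna_class_edges: tuple[int, ...] = (30, 60, 120)

    @property
    def p_max(self) -> float:
        """Upper envelope used by the thinned event sampler."""
        return float(max(self.peptide_probs.max(), self.rna_probs.max()))

    def peptide_class(self, length: int) -> int:
        return int(np.searchsorted(self.peptide_class_edges, length))

    def rna_class(self, length: int) -> int:
        return int(np.searchsorted(self.rna_class_edges, length))


@dataclass
class PondState:
    """The whole system at one point in time."""

    rng: np.random.Generator
    vesicles: list[Vesicle] = field(default_factory=list)
    cycle_index: int = 0
    phase: str = "init"
    volume: float = INITIAL_VOLUME
    contact_base: float = 1e-5
    cumulative_dead: int = 0
    fucas_produced: int = 0
    first_fuca_cycle: int | None = None
    lucas: list[dict] = field(default_factory=list)
    first_luca_cycle: int | None = None
    next_id: int = 0
    volume_total: float = 0.0
    census_rows: list[dict] = field(default_factory=list)
    _luca_ids: set[int] = field(default_factory=set)

    @property
    def n_alive(self) -> int:
        return len(self.vesicles)


def update_volume(phase: str, rng: np.random.Generator) -> float:
    """Redraw the pond volume uniformly within the phase band."""
    try:
        lo, hi = VOLUME_BANDS[phase]
    except KeyError:
        raise ValueError(f"phase must be 'wet' or 'dry', got {phase!r}") from None
    return float(rng.uniform(lo, hi))


def contact_probability(base: float, volume: float) -> float:
    """Per-pair contact probability PC = base * (100 / volume)**2."""
    if volume <= 0:
        raise ValueError(f"pond volume must be positive, got {volume}")
    return base * (100.0 / volume) ** 2


def sample_contacts(state: PondState, pc: float) -> list[tuple[int, int]]:
    """Sample this cycle's contact events as disjoint index pairs.

    The event count is binomial over all N(N-1)/2 unordered pairs with
    probability ``pc``; the events are then realised as uniformly chosen
    disjoint pairs, so each vesicle takes part in at most one encounter
    per cycle.
    """
    n = len(state.vesicles)
    if n < 2 or pc <= 0.0:
        return []
    n_pairs = n * (n - 1) // 2
    k = int(state.rng.binomial(n_pairs, min(pc, 1.0)))
    k = min(k, n // 2)
    if k == 0:
        return []
    chosen = state.rng.choice(n, size=2 * k, replace=False)
    return [(int(chosen[2 * m]), int(chosen[2 * m + 1])) for m in range(k)]


def merge_vesicles(winner: Vesicle, absorbed: Vesicle) -> Vesicle:
    """The winner gains every peptide, RNA and codon assignment.

    Counts are conserved: NP and NR of the merged vesicle are the sums of
    the two ancestors'.
    """
    winner.peptides.extend(absorbed.peptides)
    winner.rnas.extend(absorbed.rnas)
    winner.assigned_aas |= absorbed.assigned_aas
    return winner


def resolve_encounter(
    a: Vesicle,
    b: Vesicle,
    matrix: MergeMatrix,
    rng: np.random.Generator,
    merge_enabled: bool = True,
) -> tuple[Vesicle, Vesicle] | None:
    """Resolve one contact: returns (winner, absorbed) or None.

    Below-threshold fragments (NP < 2) cannot take part in mergers. With
    merging disabled (control experiments) every contact is a no-op.
    """
    if not merge_enabled:
        return None
    ti, tj = type_index(a), type_index(b)
    if ti < 0 or tj < 0:
        return None
    p_a = matrix.absorb_probability(ti, tj, rng)
    winner, absorbed = (a, b) if rng.random() < p_a else (b, a)
    merge_vesicles(winner, absorbed)
    winner.merged_this_cycle = True
    absorbed.merged_this_cycle = True
    return winner, absorbed


def _sample_joins(
    lengths: list[int],
    k_events: int,
    probs: np.ndarray,
    edges: tuple[int, ...],
    p_max: float,
    rng: np.random.Generator,
) -> None:
    """Realise up to ``k_events`` candidate joins on one molecule list.

    Each candidate picks an unordered pair uniformly and accepts it with
    p(class_i, class_j) / p_max (thinning); a molecule joins at most once
    per cycle. Joined pairs are replaced in place by one molecule of the
    summed length.
    """
    n = len(lengths)
    used: set[int] = set()
    joins: list[tuple[int, int]] = []
    for _ in range(k_events):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1  # uniform over distinct (i, j)
        if i in used or j in used:
            continue
        ci = int(np.searchsorted(edges, lengths[i]))
        cj = int(np.searchsorted(edges, lengths[j]))
        if rng.random() < probs[ci, cj] / p_max:
            used.update((i, j))
            joins.append((i, j))
    for i, j in sorted(joins, key=lambda ij: max(ij), reverse=True):
        hi, lo = (i, j) if i > j else (j, i)
        merged = lengths[hi] + lengths[lo]
        del lengths[hi]
        lengths[lo] = merged


def join_biopolymers(v: Vesicle, rules: JoinRuleTable, rng: np.random.Generator) -> Vesicle:
    """One cycle of within-vesicle joining for a single vesicle.

    The number of candidate events is binomial over the molecule pairs at
    the table's maximum probability, then thinned to the exact per-pair
    probability for the pair's length classes.
    """
    p_max = rules.p_max
    for lengths, probs, edges in (
        (v.peptides, rules.peptide_probs, rules.peptide_class_edges),
        (v.rnas, rules.rna_probs, rules.rna_class_edges),
    ):
        n = len(lengths)
        n_pairs = n * (n - 1) // 2
        if n_pairs == 0:
            continue
        k = int(rng.binomial(n_pairs, p_max))
        if k:
            _sample_joins(lengths, k, probs, edges, p_max, rng)
    return v


def _join_all(vesicles: list[Vesicle], rules: JoinRuleTable, rng: np.random.Generator) -> None:
    """Vectorised joining pass over the whole population.

    Joins are rare (p <= 1e-5 per pair), so the per-vesicle event counts
    are drawn in a single binomial call and only vesicles with events are
    touched.
    """
    n = len(vesicles)
    if n == 0:
        return
    p_max = rules.p_max
    for attr, probs, edges in (
        ("peptides", rules.peptide_probs, rules.peptide_class_edges),
        ("rnas", rules.rna_probs, rules.rna_class_edges),
    ):
        counts = np.fromiter((len(getattr(v, attr)) for v in vesicles), np.int64, count=n)
        n_pairs = counts * (counts - 1) // 2
        k = rng.binomial(n_pairs, p_max)
        for i in np.flatnonzero(k):
            _sample_joins(getattr(vesicles[i], attr), int(k[i]), probs, edges, p_max, rng)


def absorb_monomers(
    v: Vesicle,
    p_abs: float,
    rng: np.random.Generator,
    peptide_len_range: tuple[int, int] = (3, 10),
    mode: str = "add",
) -> Vesicle:
    """Absorption of monomers from the pond's unlimited supply.

    With probability ``p_abs`` the vesicle packages absorbed amino acids
    into one new short peptide, and with an independent ``p_abs`` draw it
    packages nucleotides into one new RNA of 3x a sampled AA count
    (``mode="add"``, the default, the only route besides merger by which
    NP and NR grow). With ``mode="elongate"`` the absorbed monomers extend
    one existing molecule instead, leaving the counts unchanged.
    """
    lo, hi = peptide_len_range
    if rng.random() < p_abs:
        length = int(rng.integers(lo, hi + 1))
        if mode == "add" or not v.peptides:
            v.peptides.append(length)
        else:
            v.peptides[int(rng.integers(len(v.peptides)))] += length
    if rng.random() < p_abs:
        length = 3 * int(rng.integers(lo, hi + 1))
        if mode == "add" or not v.rnas:
            v.rnas.append(length)
        else:
            v.rnas[int(rng.integers(len(v.rnas)))] += length
    return v


def _absorb_all(state: PondState, config: "SimulationConfig") -> None:
    n = len(state.vesicles)
    if n == 0 or config.p_abs <= 0:
        return
    rng = state.rng
    lo, hi = config.peptide_init_len
    add = config.absorb_mode == "add"
    pep_hits = np.flatnonzero(rng.random(n) < config.p_abs)
    rna_hits = np.flatnonzero(rng.random(n) < config.p_abs)
    for i in pep_hits:
        v = state.vesicles[i]
        length = int(rng.integers(lo, hi + 1))
        if add or not v.peptides:
            v.peptides.append(length)
        else:
            v.peptides[int(rng.integers(len(v.peptides)))] += length
    for i in rna_hits:
        v = state.vesicles[i]
        length = 3 * int(rng.integers(lo, hi + 1))
        if add or not v.rnas:
            v.rnas.append(length)
        else:
            v.rnas[int(rng.integers(len(v.rnas)))] += length


def influx(state: PondState, phase: str, rng: np.random.Generator, config: "SimulationConfig") -> PondState:
    """Add the phase's external supply of fresh V1/V2 vesicles.

    The count is uniform within the phase's configured range; each new
    vesicle is independently V1 or V2 with equal probability.
    """
    if not config.influx_enabled:
        return state
    lo, hi = config.influx_dry if phase == "dry" else config.influx_wet
    if hi <= 0:
        return state
    k = int(rng.integers(lo, hi + 1))
    if k == 0:
        return state
    types = rng.integers(0, 2, size=k)
    new = make_vesicles_batch(
        types,
        rng,
        start_id=state.next_id,
        peptide_len_range=config.peptide_init_len,
        aa_mode=config.assignment_candidate,
    )
    state.next_id += k
    state.vesicles.extend(new)
    return state


def apply_breakage(state: PondState, rng: np.random.Generator, p_break: float) -> PondState:
    """Dry-phase breakage: each vesicle is destroyed with ``p_break``.

    Broken vesicles' contents are discarded (the pond's monomer supply is
    unlimited, so recycling them would be invisible to the dynamics).
    """
    n = len(state.vesicles)
    if n == 0 or p_break <= 0:
        return state
    keep = rng.random(n) >= p_break
    if keep.all():
        return state
    survivors = [v for v, kf in zip(state.vesicles, keep.tolist()) if kf]
    state.cumulative_dead += n - len(survivors)
    state.vesicles = survivors
    return state


def survival_lottery(state: PondState, rng: np.random.Generator | None = None) -> PondState:
    """Fitness-based survival for vesicles that did not merge this cycle.

    Each non-merged vesicle survives with PS = ln(NA x NP)/10 (clamped);
    vesicles that merged or acquired this cycle are exempt. Merge flags
    are reset afterwards.
    """
    rng = rng or state.rng
    n = len(state.vesicles)
    if n == 0:
        return state
    na = np.fromiter((len(v.assigned_aas) for v in state.vesicles), np.int64, count=n)
    np_counts = np.fromiter((len(v.peptides) for v in state.vesicles), np.int64, count=n)
    fs = na * np_counts
    ps = np.zeros(n)
    pos = fs > 1
    ps[pos] = np.minimum(1.0, np.log(fs[pos]) / 10.0)
    merged = np.fromiter((v.merged_this_cycle for v in state.vesicles), bool, count=n)
    survive = merged | (rng.random(n) < ps)
    survivors = [v for v, kf in zip(state.vesicles, survive.tolist()) if kf]
    state.cumulative_dead += n - len(survivors)
    state.vesicles = survivors
    for v in survivors:
        v.merged_this_cycle = False
    return state


def _resolve_all(state: PondState, pairs: list[tuple[int, int]], matrix: MergeMatrix, merge_enabled: bool) -> None:
    if not pairs or not merge_enabled:
        return
    absorbed_idx: list[int] = []
    ves = state.vesicles
    rng = state.rng
    for i, j in pairs:
        res = resolve_encounter(ves[i], ves[j], matrix, rng, merge_enabled=True)
        if res is None:
            continue
        _, absorbed = res
        absorbed_idx.append(i if ves[i] is absorbed else j)
    if absorbed_idx:
        drop = set(absorbed_idx)
        state.vesicles = [v for m, v in enumerate(ves) if m not in drop]
        state.cumulative_dead += len(drop)


def _assign_all(state: PondState, codon_state: CodonAssignmentState) -> None:
    """Vectorised codon-assignment attempts at the end of a wet-dry pair."""
    n = len(state.vesicles)
    if n == 0:
        return
    rng = state.rng
    na = np.fromiter((len(v.assigned_aas) for v in state.vesicles), np.int64, count=n)
    np_counts = np.fromiter((len(v.peptides) for v in state.vesicles), np.int64, count=n)
    early_ok = codon_state.allow_early & (na < N_EARLY_AAS)
    late_ok = (
        codon_state.allow_late
        & (na >= N_EARLY_AAS)
        & (na < N_AMINO_ACIDS)
        & (np_counts >= _NP_LOWER[-1])
    )
    eligible = early_ok | late_ok
    if not eligible.any():
        return
    if codon_state.feedback_mode:
        p = np.zeros(n)
        p[eligible] = codon_state.base_p * (N_AMINO_ACIDS / (N_AMINO_ACIDS - na[eligible])) ** 2
    else:
        p = np.full(n, codon_state.p_synchronize)
    hits = np.flatnonzero(eligible & (rng.random(n) < p))
    random_mode = codon_state.candidate_mode == "random"
    # one batched draw instead of per-vesicle rng calls (hits are many)
    picks = rng.random(hits.size) if random_mode else None
    for m, i in enumerate(hits):
        v = state.vesicles[i]
        if len(v.assigned_aas & EARLY_AAS) < N_EARLY_AAS:
            remaining = EARLY_AAS - v.assigned_aas
        else:
            remaining = LATE_AAS - v.assigned_aas
        if remaining:
            if random_mode:
                ordered = sorted(remaining)
                v.assigned_aas.add(ordered[int(picks[m] * len(ordered))])
            else:
                v.assigned_aas.add(min(remaining))


def _detect_fucas(state: PondState) -> None:
    """Count first-time entries into type V6 (cumulative FUCA production)."""
    threshold = _NP_LOWER[-1]
    for v in state.vesicles:
        if not v.was_v6 and len(v.peptides) >= threshold:
            v.was_v6 = True
            state.fucas_produced += 1
            if state.first_fuca_cycle is None:
                state.first_fuca_cycle = state.cycle_index


def _luca_snapshot(v: Vesicle, config: "SimulationConfig", cycle: int) -> dict:
    n_p, n_r = len(v.peptides), len(v.rnas)
    long_p = sum(1 for length in v.peptides if length > config.long_peptide_aa)
    long_r = sum(1 for length in v.rnas if length > config.long_rna_nb)
    return {
        "cycle": cycle,
        "vesicle_id": v.id,
        "n_peptides": n_p,
        "n_rnas": n_r,
        "n_assigned": len(v.assigned_aas),
        "pct_peptides_gt_threshold": 100.0 * long_p / n_p if n_p else 0.0,
        "pct_rnas_gt_threshold": 100.0 * long_r / n_r if n_r else 0.0,
    }


def _detect_lucas(state: PondState, config: "SimulationConfig") -> None:
    n = len(state.vesicles)
    if n == 0:
        return
    na = np.fromiter((len(v.assigned_aas) for v in state.vesicles), np.int64, count=n)
    for i in np.flatnonzero(na >= config.luca_num_aas):
        v = state.vesicles[i]
        if v.id in state._luca_ids:
            continue
        if is_luca(v, config.luca_min_peptides, config.luca_min_rnas, config.luca_num_aas):
            state._luca_ids.add(v.id)
            state.lucas.append(_luca_snapshot(v, config, state.cycle_index))
            if state.first_luca_cycle is None:
                state.first_luca_cycle = state.cycle_index


def _census(state: PondState) -> None:
    n = len(state.vesicles)
    if n:
        np_counts = np.fromiter((len(v.peptides) for v in state.vesicles), np.int64, count=n)
        na = np.fromiter((len(v.assigned_aas) for v in state.vesicles), np.int64, count=n)
        bins = np.searchsorted(_NP_LOWER, np_counts, side="right")  # 0 = below threshold
        counts = np.bincount(bins, minlength=7)
        mean_fs = float((na * np_counts).mean())
        max_na = int(na.max())
    else:
        counts = np.zeros(7, dtype=np.int64)
        mean_fs = 0.0
        max_na = 0
    row = {
        "cycle": state.cycle_index,
        "phase": state.phase,
        "volume": round(state.volume, 3),
    }
    for t, label in enumerate(TYPE_LABELS):
        row[f"n_{label}"] = int(counts[t + 1])
    row.update(
        n_total=n,
        n_dead_cum=state.cumulative_dead,
        n_fuca_cum=state.fucas_produced,
        n_luca=len(state.lucas),
        mean_FS=round(mean_fs, 3),
        max_NA=max_na,
    )
    state.census_rows.append(row)


def step(
    state: PondState,
    config: "SimulationConfig",
    matrix: MergeMatrix,
    rules: JoinRuleTable,
    codon_state: CodonAssignmentState,
) -> PondState:
    """Advance the pond by one cycle (one phase) in the documented order."""
    state.cycle_index += 1
    state.phase = "dry" if state.cycle_index % 2 == 1 else "wet"
    state.volume = update_volume(state.phase, state.rng)
    state.volume_total += state.volume

    influx(state, state.phase, state.rng, config)

    pc = contact_probability(state.contact_base, state.volume)
    pairs = sample_contacts(state, pc)
    _resolve_all(state, pairs, matrix, config.merge_enabled)

    _join_all(state.vesicles, rules, state.rng)
    _absorb_all(state, config)

    pair_end = state.cycle_index % 2 == 0
    if pair_end and (codon_state.allow_early or codon_state.allow_late):
        _assign_all(state, codon_state)

    _detect_fucas(state)
    _detect_lucas(state, config)

    if state.phase == "dry":
        apply_breakage(state, state.rng, config.p_break)
    if config.survival_every_cycle or pair_end:
        survival_lottery(state)

    if config.record_census:
        _census(state)
    return state
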