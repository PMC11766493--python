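"""Protocell (vesicle) agents: inventories, typing, fitness, and survival.

The model reduces a protocell to three inventories:

* ``peptides`` — a list of peptide lengths, each counted in amino acids (AAs);
* ``rnas`` — a list of RNA lengths, each counted in nucleotide bases;
* ``assigned_aas`` — the set of amino-acid indices (1..20) that already have
  a codon set assigned, i.e. the growing standard genetic code (SGC).

Molecular chemistry is deliberately out of scope: molecules carry lengths,
not sequences, and amino-acid identities matter only through the early/late
split of the genetic code (indices 1..10 are the ten early AAs Gly..Thr,
11..20 the ten late AAs Phe..Met).

Vesicles are binned into six types V1..V6 by peptide count. V6 is a FUCA
(First Universal Cellular Ancestor): a protocell large enough to host the
late phase of genetic-code evolution but still lacking a complete code. A
FUCA that completes all 20 codon assignments while holding at least 100
peptides and 300 RNAs is a LUCA, and a simulation run ends.

Classification keys on the peptide count only, with V6 open-ended (NP >= 41):
the per-type RNA and assigned-AA ranges overlap once mergers union arbitrary
inventories, whereas peptide count is the one monotone, non-overlapping axis.
This keeps classification a total function after any sequence of mergers.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Vesicle",
    "VesicleTypeSpec",
    "TYPE_SPECS",
    "SPEC_BY_LABEL",
    "TYPE_LABELS",
    "BELOW_THRESHOLD",
    "PEPTIDE_RNA_RATIO",
    "EARLY_AA_NAMES",
    "LATE_AA_NAMES",
    "N_AMINO_ACIDS",
    "N_EARLY_AAS",
    "classify_np",
    "classify_vesicle",
    "type_index",
    "fitness_score",
    "survival_probability",
    "is_fuca",
    "is_luca",
    "make_vesicle",
    "make_vesicles_batch",
]

N_AMINO_ACIDS = 20
N_EARLY_AAS = 10

#: The ten amino acids assumed to enter the genetic code first, in index
#: order 1..10, and the ten late ones, indices 11..20. Identity never
#: affects the dynamics; only the early/late split does.
EARLY_AA_NAMES = ("Gly", "Ala", "Ser", "Asp", "Glu", "Val", "Leu", "Ile", "Pro", "Thr")
LATE_AA_NAMES = ("Phe", "Tyr", "Arg", "His", "Trp", "Asn", "Gln", "Lys", "Cys", "Met")

#: Admissible peptide:RNA count ratio at vesicle creation.
PEPTIDE_RNA_RATIO = (2.5, 3.5)

BELOW_THRESHOLD = "below_threshold"
TYPE_LABELS = ("V1", "V2", "V3", "V4", "V5", "V6")

# Lower peptide-count edge of each type; V6 is open-ended.
_NP_LOWER = (2, 5, 11, 21, 31, 41)


@dataclass(frozen=True)
class VesicleTypeSpec:
    """One row of the vesicle typing table.

    ``fitness_range`` is informational only (it is implied by
    ``aa_assigned_range`` x ``peptide_range`` through FS = NA x NP and is
    never used by the dynamics).
    """

    type_label: str
    peptide_range: tuple[int, int]
    rna_range: tuple[int, int]
    aa_assigned_range: tuple[int, int]
    fitness_range: tuple[int, int]


#: The six vesicle types. V6 vesicles are FUCAs.
TYPE_SPECS: tuple[VesicleTypeSpec, ...] = (
    VesicleTypeSpec("V1", (2, 4), (5, 10), (5, 6), (10, 24)),
    VesicleTypeSpec("V2", (5, 10), (10, 30), (6, 8), (30, 80)),
    VesicleTypeSpec("V3", (11, 20), (25, 70), (8, 10), (88, 200)),
    VesicleTypeSpec("V4", (21, 30), (50, 100), (10, 12), (210, 360)),
    VesicleTypeSpec("V5", (31, 40), (75, 140), (12, 14), (272, 560)),
    VesicleTypeSpec("V6", (41, 50), (120, 160), (14, 16), (576, 800)),
)

SPEC_BY_LABEL = {spec.type_label: spec for spec in TYPE_SPECS}


class Vesicle:
    """A single protocell agent.

    Uses ``__slots__`` and plain Python lists: runs hold a few thousand
    living vesicles and create millions over their lifetime, so agents are
    kept as lean as possible.
    """

    __slots__ = ("id", "peptides", "rnas", "assigned_aas", "merged_this_cycle", "was_v6")

    def __init__(
        self,
        id: int,
        peptides: list[int],
        rnas: list[int],
        assigned_aas: set[int],
        merged_this_cycle: bool = False,
        was_v6: bool = False,
    ):
        self.id = id
        self.peptides = peptides
        self.rnas = rnas
        self.assigned_aas = assigned_aas
        self.merged_this_cycle = merged_this_cycle
        #: whether this vesicle has ever classified as V6 (used to count
        #: each distinct entry into the FUCA class exactly once).
        self.was_v6 = was_v6

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_rnas(self) -> int:
        return len(self.rnas)

    @property
    def n_assigned(self) -> int:
        return len(self.assigned_aas)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Vesicle(id={self.id}, NP={self.n_peptides}, NR={self.n_rnas}, "
            f"NA={self.n_assigned}, type={classify_vesicle(self)})"
        )


def classify_np(np_count: int) -> str:
    """Classify a peptide count into ``below_threshold`` or V1..V6.

    Total function: every non-negative count maps to exactly one label.
    A vesicle needs at least 2 peptides to qualify as a vesicle at all
    (V1 is the minimum threshold); NP >= 41 is V6 with no upper bound.
    """
    if np_count < _NP_LOWER[0]:
        return BELOW_THRESHOLD
    return TYPE_LABELS[bisect_right(_NP_LOWER, np_count) - 1]


def classify_vesicle(v: Vesicle) -> str:
    """Type label of a vesicle; see :func:`classify_np`."""
    return classify_np(len(v.peptides))


def type_index(v: Vesicle) -> int:
    """0-based index into :data:`TYPE_SPECS`, or -1 for below-threshold."""
    np_count = len(v.peptides)
    if np_count < _NP_LOWER[0]:
        return -1
    return bisect_right(_NP_LOWER, np_count) - 1


def fitness_score(v: Vesicle) -> int:
    """FS = NA x NP: assigned-AA count times peptide count."""
    return len(v.assigned_aas) * len(v.peptides)


def survival_probability(fs: float) -> float:
    """Per-cycle survival probability PS = ln(FS)/10, clamped to [0, 1].

    ln(FS)/10 is negative for FS < 1 and exceeds one for FS > e^10; both
    tails are clamped, and FS <= 1 maps to zero.
    """
    if fs <= 1:
        return 0.0
    return min(1.0, math.log(fs) / 10.0)


def is_fuca(v: Vesicle) -> bool:
    """A FUCA is exactly a type-V6 vesicle (NP >= 41)."""
    return len(v.peptides) >= _NP_LOWER[-1]


def is_luca(
    v: Vesicle,
    min_peptides: int = 100,
    min_rnas: int = 300,
    num_aas: int = N_AMINO_ACIDS,
) -> bool:
    """A LUCA is a FUCA with a complete code and a full inventory.

    All 20 AAs assigned, at least 100 peptides and 300 RNAs (defaults).
    ``is_luca`` implies ``is_fuca`` since 100 >= 41.
    """
    return (
        len(v.assigned_aas) >= num_aas
        and len(v.peptides) >= min_peptides
        and len(v.rnas) >= min_rnas
    )


def _ratio_bounds(np_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Integer-exact ceil(2.5*NP) and floor(3.5*NP).
    return (5 * np_counts + 1) // 2, (7 * np_counts) // 2


def _assigned_sets(
    na_counts: np.ndarray,
    is_v6: np.ndarray,
    rng: np.random.Generator,
    aa_mode: str,
) -> list[set[int]]:
    """Initial codon-assignment sets for a batch of vesicles.

    Early-before-late always holds: non-V6 vesicles receive only early
    AAs (capped at ten), V6 vesicles receive all ten early plus late ones
    up to their count. ``aa_mode="random"`` draws uniform subsets within
    each block so different lineages carry different AAs; ``"lowest"``
    yields the deterministic prefix sets.
    """
    k = na_counts.size
    n_early = np.minimum(na_counts, N_EARLY_AAS)
    n_late = np.where(is_v6, na_counts - n_early, 0)
    if aa_mode == "lowest":
        return [
            set(range(1, int(n_early[i]) + 1))
            | set(range(N_EARLY_AAS + 1, N_EARLY_AAS + 1 + int(n_late[i])))
            for i in range(k)
        ]
    if aa_mode != "random":
        raise ValueError(f"aa_mode must be 'lowest' or 'random', got {aa_mode!r}")
    early_order = np.argsort(rng.random((k, N_EARLY_AAS)), axis=1) + 1
    late_order = np.argsort(rng.random((k, N_AMINO_ACIDS - N_EARLY_AAS)), axis=1) + N_EARLY_AAS + 1
    return [
        set(early_order[i, : int(n_early[i])].tolist())
        | set(late_order[i, : int(n_late[i])].tolist())
        for i in range(k)
    ]


def make_vesicles_batch(
    type_indices: Sequence[int] | np.ndarray,
    rng: np.random.Generator,
    start_id: int = 0,
    peptide_len_range: tuple[int, int] = (3, 10),
    aa_mode: str = "random",
) -> list[Vesicle]:
    """Create many vesicles at once (vectorised draws, one object pass).

    For each vesicle of type ``t``:

    * NP is uniform over the type's peptide range;
    * NR is uniform over the intersection of [2.5 NP, 3.5 NP] with the
      type's RNA range; if that intersection is empty the ratio band takes
      precedence;
    * per-peptide lengths are uniform over ``peptide_len_range`` (AAs);
    * per-RNA lengths are 3x an independently sampled AA count from the
      same range (one codon per amino acid);
    * k AAs are assigned, with k uniform over the type's assigned-AA
      range; V1..V5 stay within the ten early AAs (capped at ten), V6
      starts with all ten early plus late ones up to its 14-16 count.
      See :func:`_assigned_sets` for ``aa_mode``.
    """
    idx = np.asarray(type_indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= len(TYPE_SPECS)):
        raise ValueError("type index out of range 0..5")
    k = idx.size
    if k == 0:
        return []

    p_lo = np.array([s.peptide_range[0] for s in TYPE_SPECS])[idx]
    p_hi = np.array([s.peptide_range[1] for s in TYPE_SPECS])[idx]
    r_lo = np.array([s.rna_range[0] for s in TYPE_SPECS])[idx]
    r_hi = np.array([s.rna_range[1] for s in TYPE_SPECS])[idx]
    a_lo = np.array([s.aa_assigned_range[0] for s in TYPE_SPECS])[idx]
    a_hi = np.array([s.aa_assigned_range[1] for s in TYPE_SPECS])[idx]

    np_counts = rng.integers(p_lo, p_hi + 1)
    band_lo, band_hi = _ratio_bounds(np_counts)
    nr_lo = np.maximum(band_lo, r_lo)
    nr_hi = np.minimum(band_hi, r_hi)
    empty = nr_lo > nr_hi  # ratio band takes precedence over the type range
    nr_lo = np.where(empty, band_lo, nr_lo)
    nr_hi = np.where(empty, band_hi, nr_hi)
    nr_counts = rng.integers(nr_lo, nr_hi + 1)
    na_counts = rng.integers(a_lo, a_hi + 1)
    assigned = _assigned_sets(na_counts, idx == len(TYPE_SPECS) - 1, rng, aa_mode)

    len_lo, len_hi = peptide_len_range
    pep_lens = rng.integers(len_lo, len_hi + 1, size=int(np_counts.sum())).tolist()
    rna_lens = (3 * rng.integers(len_lo, len_hi + 1, size=int(nr_counts.sum()))).tolist()

    p_off = np.concatenate(([0], np.cumsum(np_counts))).tolist()
    r_off = np.concatenate(([0], np.cumsum(nr_counts))).tolist()

    return [
        Vesicle(
            start_id + i,
            pep_lens[p_off[i] : p_off[i + 1]],
            rna_lens[r_off[i] : r_off[i + 1]],
            assigned[i],
        )
        for i in range(k)
    ]


def make_vesicle(
    type_label: str,
    rng: np.random.Generator,
    peptide_len_range: tuple[int, int] = (3, 10),
    aa_mode: str = "random",
) -> Vesicle:
    """Sample a single fresh vesicle of the given type (V1..V6)."""
    if type_label not in SPEC_BY_LABEL:
        raise ValueError(f"unknown vesicle type {type_label!r}; expected one of {TYPE_LABELS}")
    idx = TYPE_LABELS.index(type_label)
    return make_vesicles_batch([idx], rng, peptide_len_range=peptide_len_range, aa_mode=aa_mode)[0]
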