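"""Experiment designs and replicate batches.

Four designs are supported:

* ``stage1`` — origin of FUCAs: start from simple V1/V2 vesicles, merging
  enabled, early-AA assignment only; run a fixed number of cycles and
  count cumulative V6 (FUCA) emergences.
* ``stage2`` — FUCAs to LUCA: start from a batch of V6 vesicles with
  14-16 AAs already assigned, late assignment enabled; halt when the
  first LUCA appears.
* ``combined`` — both stages together from a V1/V2 start; halt at the
  first LUCA.
* ``control`` — the combined design with vesicle merging disabled and
  everything else identical; the expected outcome is that no FUCA and no
  LUCA ever emerges.

Each run returns a :class:`RunSummary`; :func:`simulate` additionally
exposes the per-cycle census table. Replicate batches derive their seeds
from one master seed through ``numpy.random.SeedSequence`` so a whole
batch is reproducible from a single integer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence
import warnings

import numpy as np
import pandas as pd

from .codons import CodonAssignmentState, combination_pool_size
from .config import SimulationConfig
from .pond import INITIAL_VOLUME, JoinRuleTable, MergeMatrix, PondState, _census, step
from .vesicles import (
    TYPE_LABELS,
    Vesicle,
    _assigned_sets,
    classify_vesicle,
    make_vesicles_batch,
)

__all__ = [
    "RunSummary",
    "SimulationResult",
    "simulate",
    "run_stage1",
    "run_stage2",
    "run_combined",
    "run_control",
    "run_replicates",
    "derive_seeds",
]


@dataclass
class RunSummary:
    """Emergence times and final censuses of one run.

    ``first_fuca_cycle`` / ``first_luca_cycle`` are None when the event
    never occurred within the horizon.
    """

    experiment: str
    seed: int
    config_hash: str
    cycles_run: int
    halted_on_luca: bool
    mean_volume: float
    contact_base: float
    pool_size: int
    census: dict[str, int]
    n_alive: int
    total_dead: int
    first_fuca_cycle: int | None
    fucas_produced: int
    first_luca_cycle: int | None
    n_lucas: int
    lucas: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_flat_row(self) -> dict[str, Any]:
        """Single flat mapping suitable for one TSV row."""
        row: dict[str, Any] = {
            "experiment": self.experiment,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "cycles_run": self.cycles_run,
            "halted_on_luca": self.halted_on_luca,
            "mean_volume": round(self.mean_volume, 2),
            "contact_base": self.contact_base,
            "pool_size": self.pool_size,
        }
        for label in TYPE_LABELS:
            row[f"n_{label}_alive"] = self.census.get(label, 0)
        row.update(
            n_alive=self.n_alive,
            total_dead=self.total_dead,
            cycles_to_first_fuca=self.first_fuca_cycle,
            fucas_produced=self.fucas_produced,
            cycles_to_first_luca=self.first_luca_cycle,
            n_lucas=self.n_lucas,
        )
        first = self.lucas[0] if self.lucas else {}
        row.update(
            luca_n_peptides=first.get("n_peptides"),
            luca_n_rnas=first.get("n_rnas"),
            luca_n_assigned=first.get("n_assigned"),
            luca_pct_peptides_long=first.get("pct_peptides_gt_threshold"),
            luca_pct_rnas_long=first.get("pct_rnas_gt_threshold"),
        )
        return row


@dataclass
class SimulationResult:
    summary: RunSummary
    census: pd.DataFrame
    config: SimulationConfig


def _initial_population(config: SimulationConfig, rng: np.random.Generator) -> list[Vesicle]:
    if config.experiment == "stage2":
        return _initial_fucas(config, rng)
    types = np.concatenate(
        [np.zeros(config.v1_init, dtype=np.int64), np.ones(config.v2_init, dtype=np.int64)]
    )
    return make_vesicles_batch(
        types, rng, peptide_len_range=config.peptide_init_len, aa_mode=config.assignment_candidate
    )


def _initial_fucas(config: SimulationConfig, rng: np.random.Generator) -> list[Vesicle]:
    """Stage-2 seed population: V6 vesicles with a partial late code.

    Peptide counts are uniform in ``stage2_np_range``, RNA counts follow
    the 2.5-3.5 peptide:RNA ratio, and 14-16 AAs (all ten early plus some
    late) are already assigned.
    """
    k = config.stage2_fuca_count
    if k == 0:
        return []
    lo, hi = config.stage2_np_range
    np_counts = rng.integers(lo, hi + 1, size=k)
    ratios = rng.uniform(2.5, 3.5, size=k)
    nr_counts = np.rint(ratios * np_counts).astype(np.int64)
    na_lo, na_hi = config.stage2_na_range
    na_counts = rng.integers(na_lo, na_hi + 1, size=k)
    assigned = _assigned_sets(
        na_counts, np.ones(k, dtype=bool), rng, config.assignment_candidate
    )
    len_lo, len_hi = config.peptide_init_len
    pep_lens = rng.integers(len_lo, len_hi + 1, size=int(np_counts.sum())).tolist()
    rna_lens = (3 * rng.integers(len_lo, len_hi + 1, size=int(nr_counts.sum()))).tolist()
    p_off = np.concatenate(([0], np.cumsum(np_counts))).tolist()
    r_off = np.concatenate(([0], np.cumsum(nr_counts))).tolist()
    out = []
    for i in range(k):
        v = Vesicle(
            i,
            pep_lens[p_off[i] : p_off[i + 1]],
            rna_lens[r_off[i] : r_off[i + 1]],
            assigned[i],
            was_v6=True,  # initialised as FUCAs, not counted as emergences
        )
        out.append(v)
    return out


def _codon_state(config: SimulationConfig, pool_size: int) -> CodonAssignmentState:
    return CodonAssignmentState(
        pool_size=pool_size,
        p_synchronize=config.p_synchronize,
        feedback_mode=config.feedback_mode,
        base_p=config.feedback_base,
        allow_early=True,
        allow_late=config.experiment != "stage1",
        candidate_mode=config.assignment_candidate,
    )


def simulate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulationResult:
    """Run one experiment end to end.

    The seed argument overrides ``config.seed``; all randomness flows from
    the one generator it seeds, in a fixed draw order (contact base, codon
    pool, initial population, then the cycle loop), so identical
    (config, seed) pairs reproduce bitwise-identical results.
    """
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)

    contact_base = (
        config.contact_base
        if config.contact_base is not None
        else float(rng.uniform(*config.contact_base_range))
    )
    pool_size = combination_pool_size(int(rng.integers(4, 7)))

    state = PondState(rng=rng, contact_base=contact_base)
    state.vesicles = _initial_population(config, rng)
    state.next_id = len(state.vesicles)

    matrix = MergeMatrix(jitter_range=config.jitter_range)
    rules = JoinRuleTable()
    codon_state = _codon_state(config, pool_size)

    halt_on_luca = config.experiment in ("stage2", "combined", "control")

    if config.record_census:
        state.phase = "init"
        state.volume = INITIAL_VOLUME
        _census(state)

    for _ in range(config.max_cycles):
        step(state, config, matrix, rules, codon_state)
        if halt_on_luca and state.lucas:
            break

    summary = _summarize(state, config, seed, pool_size)
    census = pd.DataFrame(state.census_rows)
    return SimulationResult(summary=summary, census=census, config=config)


def _summarize(state: PondState, config: SimulationConfig, seed: int, pool_size: int) -> RunSummary:
    census: dict[str, int] = {label: 0 for label in TYPE_LABELS}
    below = 0
    for v in state.vesicles:
        label = classify_vesicle(v)
        if label in census:
            census[label] += 1
        else:
            below += 1
    census["below_threshold"] = below
    mean_volume = state.volume_total / state.cycle_index if state.cycle_index else INITIAL_VOLUME
    return RunSummary(
        experiment=config.experiment,
        seed=seed,
        config_hash=config.config_hash(),
        cycles_run=state.cycle_index,
        halted_on_luca=bool(state.lucas),
        mean_volume=mean_volume,
        contact_base=state.contact_base,
        pool_size=pool_size,
        census=census,
        n_alive=state.n_alive,
        total_dead=state.cumulative_dead,
        first_fuca_cycle=state.first_fuca_cycle,
        fucas_produced=state.fucas_produced,
        first_luca_cycle=state.first_luca_cycle,
        n_lucas=len(state.lucas),
        lucas=list(state.lucas),
    )


def _run(experiment: str, config: SimulationConfig | None, seed: int | None) -> RunSummary:
    config = config or SimulationConfig(experiment=experiment)
    if config.experiment != experiment:
        # relabel but keep the caller's (already resolved) horizon
        config = config.replace(experiment=experiment)
    return simulate(config, seed=seed).summary


def run_stage1(config: SimulationConfig | None = None, seed: int | None = None) -> RunSummary:
    """Stage 1: origin of FUCAs from simple V1/V2 vesicles."""
    return _run("stage1", config, seed)


def run_stage2(config: SimulationConfig | None = None, seed: int | None = None) -> RunSummary:
    """Stage 2: from an initial batch of FUCAs to the first LUCA."""
    return _run("stage2", config, seed)


def run_combined(config: SimulationConfig | None = None, seed: int | None = None) -> RunSummary:
    """Both stages together, halting at the first LUCA."""
    return _run("combined", config, seed)


def run_control(config: SimulationConfig | None = None, seed: int | None = None) -> RunSummary:
    """The combined design with merging disabled (negative control)."""
    return _run("control", config, seed)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Replicate seeds from one master seed.

    Uses ``SeedSequence(master).generate_state(n)`` masked to 31 bits: a
    documented, platform-stable splitting rule.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def run_replicates(
    config: SimulationConfig | None = None,
    n_reps: int = 1,
    seed_list: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Run independent replicates and tabulate one row per run.

    Seeds come from ``seed_list`` when given (duplicates draw a warning
    but the batch continues), otherwise they are derived from the
    config's master seed via :func:`derive_seeds`. The returned table
    carries one row per replicate plus min/median/max summary rows over
    the numeric columns.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    config = config or SimulationConfig()
    if seed_list is None:
        master = config.seed if config.seed is not None else 0
        seed_list = derive_seeds(master, n_reps)
    else:
        seed_list = list(seed_list)
        if len(seed_list) != n_reps:
            raise ValueError(f"seed_list has {len(seed_list)} entries for n_reps={n_reps}")
        if len(set(seed_list)) != len(seed_list):
            warnings.warn("duplicate seeds in seed_list; replicates will not be independent")

    rows = []
    for i, s in enumerate(seed_list, start=1):
        summary = simulate(config, seed=s).summary
        row = {"replicate": str(i)}
        row.update(summary.to_flat_row())
        rows.append(row)
    table = pd.DataFrame(rows)

    numeric = table.select_dtypes(include=[np.number]).columns
    summary_rows = []
    for name, fn in (("min", np.nanmin), ("median", np.nanmedian), ("max", np.nanmax)):
        row = {"replicate": name}
        for col in numeric:
            values = table[col].to_numpy(dtype=float)
            row[col] = fn(values) if not np.isnan(values).all() else np.nan
        summary_rows.append(row)
    return pd.concat([table, pd.DataFrame(summary_rows)], ignore_index=True)
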