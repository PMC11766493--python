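# Methods

## Model

The simulator is a discrete-time, well-mixed agent-based model of one
"warm little pond". Time advances in cycles; one cycle is one pond
phase, dry and wet strictly alternating (cycle 1 is dry; a "wet-and-dry
cycle" therefore spans two simulator cycles and completes on even cycle
indices). The pond starts at 100 volume units; each dry phase redraws
the volume uniformly from 50–80 units, each wet phase from 80–100.

Agents are vesicles reduced to three inventories: a list of peptide
lengths (amino acids), a list of RNA lengths (nucleotide bases, 3× an
amino-acid count at creation), and the set of amino-acid indices 1..20
whose codon sets are already assigned. No sequences, chemistry,
metabolism, replication, membrane physics, or spatial structure are
modelled; those are deliberate exclusions, not simplifying bugs — the
object of study is whether merger-driven pooling of biomolecules alone
can assemble a LUCA-sized protocell with a complete code.

Vesicles are typed V1–V6 by peptide count alone (2–4, 5–10, 11–20,
21–30, 31–40, ≥ 41). Peptide count is the one monotone, non-overlapping
axis of the type table, so classification stays total after arbitrary
mergers; the per-type RNA and assigned-AA ranges are enforced only at
creation. V6 vesicles are FUCAs. A FUCA with all 20 AAs assigned,
≥ 100 peptides and ≥ 300 RNAs is a LUCA; runs that select for LUCA halt
at the end of the cycle in which the first one appears, reporting all
LUCAs that co-emerged in that cycle.

### Per-cycle order of operations

1. phase flip; volume redraw;
2. influx of fresh V1/V2 vesicles (count uniform in 2000–3000 dry /
   4000–5000 wet; V1 or V2 with equal probability);
3. contact sampling: event count ~ Binomial(N(N−1)/2, PC) with
   PC = p_base (100/X)², realised as uniformly chosen disjoint pairs
   (each vesicle in at most one encounter per cycle);
4. encounter resolution: the type-vs-type acquisition probability
   (diagonal 0.5; larger types favoured up to 0.9 vs 0.1; V1 never
   absorbs a larger type) is jittered multiplicatively by ±5–10%
   (exact 0/1 entries stay exact), the absorber gains all peptides,
   RNAs, and codon assignments (set union), and the absorbed vesicle is
   removed and counted dead;
5. within-vesicle joining: for each molecule class, candidate events
   ~ Binomial(pairs, 10⁻⁵) thinned to the symmetric length-class
   probability table (1×10⁻⁵ down to 0.01×10⁻⁵); each molecule joins at
   most once per cycle;
6. monomer absorption: with probability 5×10⁻³ each for peptide and RNA
   material; by default absorbed monomers elongate one existing
   molecule (counts unchanged), the alternative `absorb_mode="add"`
   packages them into one new short molecule instead;
7. codon assignment (end of each wet–dry pair only): each eligible
   vesicle adds at most one AA — a uniformly drawn unassigned early AA
   while any of the ten early AAs is missing; a late AA only for FUCAs —
   with fixed probability 0.999 or, in feedback mode,
   10⁻³ (20/(20−n))²;
8. dry-phase breakage with probability 0.01 per vesicle (contents
   discarded — recycling would be invisible given the unlimited monomer
   supply);
9. survival lottery: every vesicle that did not merge this cycle
   survives with PS = ln(NA·NP)/10, clamped to [0, 1] with FS ≤ 1
   mapped to 0; merge flags then reset;
10. census.

All randomness flows from one seeded generator per run in a fixed draw
order (contact base, codon pool size, initial population, cycle loop),
so a (config, seed) pair reproduces results bitwise. Replicate batches
derive per-run seeds from a master seed via `SeedSequence` masked to 31
bits.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `contact_base_range` | [10⁻⁶, 10⁻⁵] | per-pair contact base probability, drawn once per run (set `contact_base` to pin it) |
| `influx_dry` / `influx_wet` | 2000–3000 / 4000–5000 | external V1/V2 supply per cycle |
| `v1_init` / `v2_init` | 3000 / 2000 | initial census |
| `p_synchronize` | 0.999 | codon-assignment probability per wet–dry pair |
| `feedback_mode` / `feedback_base` | off / 10⁻³ | positive-feedback assignment law |
| `p_abs` | 5×10⁻³ | monomer absorption per cycle |
| `p_break` | 0.01 | dry-phase breakage (no published value; chosen small so breakage perturbs but does not dominate mortality, and exposed as a config knob) |
| `stage2_fuca_count` / `stage2_np_range` / `stage2_na_range` | 300 / 100–416 / 14–16 | stage-2 seed FUCAs |
| `luca_min_peptides` / `luca_min_rnas` / `luca_num_aas` | 100 / 300 / 20 | LUCA criteria |
| `max_cycles` | 200 / 200 / 1500 / 1500 | horizon per experiment (stage1/stage2/combined/control) |

## Design choices where the design was open

* **Event-count-first sampling.** Contacts, joins, and absorption draw
  an event count from one (vectorised) binomial and realise only those
  events, instead of sweeping all O(N²) pairs; this is statistically
  equivalent (verified against a brute-force per-pair Bernoulli oracle
  at small N in the test suite) and is what makes ~1500-cycle runs with
  ~5000 living agents run in tens of seconds on one core.
* **Random assignment candidates.** The unassigned AA to try next is
  drawn uniformly within the admissible block (early before late), so
  different lineages carry different partial codes and mergers can pool
  them — the union-gain mechanism at the heart of the model. The
  deterministic lowest-index-first alternative
  (`assignment_candidate="lowest"`) makes every set a prefix, in which
  case unions never gain an AA; it is kept for analysis because it
  isolates the pure single-lineage assignment process.
* **Absorption elongates by default.** Absorbed monomers extend an
  existing molecule, leaving NP/NR unchanged; merging is then the only
  route to larger peptide counts, which is precisely the contrast the
  control experiment (merging disabled) is meant to isolate. With
  `absorb_mode="add"`, borderline V2 vesicles can drift into V3 in
  control runs through absorption alone, blurring that contrast.
* **Survival every cycle.** The lottery runs each phase rather than
  each wet–dry pair (`survival_every_cycle=False` switches to the
  latter). Mortality is therefore high: a fresh V1 (FS ≈ 10–24)
  survives a phase with probability ~0.25–0.3, and population size
  equilibrates near 2000–2500 with the default influx.
* **One encounter per vesicle per cycle** (disjoint contact pairs)
  avoids within-cycle order dependence; **jitter** applies to the
  row-absorbs probability with the complement renormalised.
* **Classification by NP only**, V6 open-ended — see above.
* **Codon pool size** is drawn as 20·b³ with b uniform in {4, 5, 6}
  (1280, 2500, or 4320 combinations), recorded in every run summary for
  provenance; it does not modulate the assignment probability, which is
  parameterised directly.

## What the generator emulates — and what passing tests do not show

The synthetic populations are the study conditions themselves (the
model has no external data): initial censuses, influx ranges, contact
and acquisition probabilities, joining tables, and the stage-2 FUCA
seeds all follow the defaults above. Real prebiotic ponds obviously
differ — monomer supply is not unlimited, vesicles are not well-mixed
point agents, fitness is not NA·NP, and amino acids are not
interchangeable tokens — so passing tests demonstrate the internal
logic and reproducibility of the merger-driven scenario, not its
chemical realism.

Two empirical regimes are robust across seeds and are what the
end-to-end tests assert:

* **Merging off ⇒ nothing happens.** With acquisition disabled and
  elongation-only absorption, peptide counts can only fall (joins merge
  two molecules into one), so no vesicle ever crosses the V3 threshold,
  let alone FUCA/LUCA — the control null result.
* **Merging on ⇒ FUCAs emerge, and seeded FUCAs complete the code
  quickly.** Stage-1 runs produce their first FUCA within tens to ~150
  cycles depending on the drawn contact base; stage-2 runs from 300
  FUCAs reach a LUCA within ~10 cycles (well inside the published
  ≤ 56-cycle envelope), because at 0.999 per pair an NA = 16 seed needs
  only four wet–dry pairs and hundreds of seeds race in parallel.

Two published magnitudes are *not* reproduced under these mechanics,
and the corresponding end-to-end expectations are asserted at the
published envelope and left failing rather than tuned:

* **Cumulative stage-1 FUCA counts.** The published tables report
  36–284 FUCAs within 100–200 cycles alongside ~900 living V3 vesicles;
  under the stated contact law (PC ≤ 10⁻⁵·(100/X)², i.e. ≲ 250 merge
  events per cycle among ~5000 agents) and a per-phase survival lottery
  that removes most small vesicles each cycle, the sustainable V3
  population is an order of magnitude smaller and the median cumulative
  FUCA count over 8 seeds is ~1–5. Reaching the published counts
  requires an effective contact/merger rate several-fold above the
  printed formula's ceiling.
* **Combined-run LUCA.** Completing the ten late assignments takes at
  least 20 cycles as a V6, plus growth to ≥ 100 peptides; with the
  per-phase lottery a V6 lineage survives that long with probability
  ≪ 10⁻³, so no LUCA emerges within 1500 cycles from a cold V1/V2
  start, whereas the published runs report one LUCA by cycle 800–1120.
  (Stage 2's seeded FUCAs escape this because they start with
  NP ≥ 100 and NA ≥ 14.)

Both gaps trace to the same under-specification — the published
source's effective contact rate and survival cadence are not derivable
from its stated parameters — and are insensitive to the choices this
package does expose (assignment candidate mode, absorption mode,
per-run vs per-cycle contact base).

## Numerical notes and degenerate inputs

* `survival_probability` maps FS ≤ 1 to 0 and clamps at 1 (FS > e¹⁰);
  it is monotone non-decreasing.
* Length classes are closed on the printed boundaries (peptides ≤ 10,
  11–25, 26–50, ≥ 51; RNAs ≤ 30, 31–60, 61–120, > 120).
* Joining can drop a V1 to a single-peptide "below-threshold" fragment
  (~10⁻⁵ per pair); fragments remain tracked, cannot merge, and die
  quickly under the lottery (they are reported in the census total but
  not as a type).
* Contact sampling caps realised events at ⌊N/2⌋ (disjointness);
  with default probabilities the cap is never approached.
* An empty pond, zero-cycle horizons, `p_break` ∈ {0, 1}, and
  `pABS` ∈ {0, 1} are all exercised in the test suite.

## Problem sizes

Default horizons (200 cycles for the staged designs, 1330–1500 for
control/combined) with ~2000–2500 living agents run at roughly 20–30 ms
per cycle on one core; the full end-to-end battery (one control run,
8 stage-1, 25 stage-2, and 2 combined runs) completes in a few minutes.

## Known limitations

* Counts-and-lengths abstraction: no sequence information, so "genetic
  code" means a 20-element set, and stop codons are not modelled.
* The published per-run pond volumes, exact table cell values, and
  LUCA composition percentages (e.g. 80% of peptides > 50 AAs) are
  single stochastic realizations of an under-specified model and are
  not reproduced cell-for-cell; with default joining probabilities
  (≤ 10⁻⁵) molecules longer than 50 AAs remain rare, so the reported
  long-molecule percentages stay near zero.
* Vesicle division/fission, virus evolution, and spatially structured
  ponds are out of scope.
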