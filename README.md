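# warmpond

An agent-based simulator of protocell evolution in a Darwinian "warm
little pond": simple vesicles merge with and acquire each other under
alternating wet-and-dry cycles, pooling peptides, RNAs, and codon
assignments until large protocells (FUCAs — First Universal Cellular
Ancestors) and finally a LUCA (Last Universal Common/Cellular Ancestor)
with a complete standard genetic code emerge. The package is aimed at
origin-of-life researchers who want a reproducible, scriptable
re-implementation of this merger-driven ("horizontal biomolecule
transfer") scenario, including its negative control in which merging is
disabled and no larger protocell ever evolves.

## The model in brief

A vesicle is a bag of biopolymer lengths: `NP` peptides, `NR` RNAs
(`NR/NP` in 2.5–3.5 at creation), and a set of `NA ≤ 20` amino acids
already assigned to codon sets. Vesicles are typed V1–V6 by peptide
count (V1: 2–4 … V6: ≥ 41); V6 vesicles are FUCAs. Per cycle (one wet
*or* dry phase):

* the pond volume `X` is redrawn (dry 50–80, wet 80–100 units), and each
  unordered pair of vesicles makes contact with probability
  `PC = p_base · (100/X)²`, `p_base ∈ [10⁻⁶, 10⁻⁵]`;
* every contact resolves into an acquisition: one vesicle absorbs the
  other with type-dependent probabilities (jittered ±5–10%) and gains
  all its peptides, RNAs, and codon assignments (set union);
* molecules within a vesicle may join pairwise into longer ones
  (`p ≤ 10⁻⁵`), monomers are absorbed from an unlimited pond supply
  (`pABS = 5·10⁻³`), and fresh V1/V2 vesicles flow in (2000–3000 per dry
  phase, 4000–5000 per wet phase);
* once per wet–dry pair a vesicle may assign one more amino acid —
  the ten early AAs (Gly…Thr) first, the ten late AAs (Phe…Met) only in
  FUCAs — with probability 0.999, or optionally the positive-feedback
  law `P(n) = 10⁻³ (20/(20−n))²`;
* non-merged vesicles then survive with `PS = ln(FS)/10` where
  `FS = NA · NP`, and the dry phase breaks a small fraction of vesicles.

A FUCA becomes a LUCA — and the run halts — when `NA = 20`,
`NP ≥ 100`, and `NR ≥ 300`.

## Worked example

```python
from warmpond import SimulationConfig, simulate

cfg = SimulationConfig(experiment="stage1")   # 200 cycles, V1/V2 start
result = simulate(cfg, seed=1)
s = result.summary
print(f"first FUCA at cycle {s.first_fuca_cycle}, "
      f"{s.fucas_produced} FUCAs produced, {s.n_alive} vesicles alive")
```

prints (seed 1):

```
first FUCA at cycle 160, 1 FUCAs produced, 2456 vesicles alive
```

i.e. in this replicate the first vesicle crossed the 41-peptide FUCA
threshold after 160 phases, one vesicle reached that size
within 200 cycles, and about 2.5k vesicles (almost all V1/V2, plus a
tail of V3–V5) were alive at the horizon. `result.census` holds the
per-cycle census table (counts per type, deaths, mean fitness, maximum
`NA`), which `warmpond.plot_census` can draw.

The same runs are available from the shell:

```bash
warmpond stage1  --seed 1 --out out/stage1
warmpond control --seed 1 --max-cycles 1330 --out out/control
warmpond stage2  --reps 25 --seed 1 --out out/stage2
```

Each run writes `census.tsv`, `summary.tsv`, `summary.json`,
`config_echo.yaml`, `type_specs.tsv`, and `log.txt`; replicate batches
write `replicates.tsv` with min/median/max rows. A control run reports
`fucas=0 lucas=0` and a final census containing only V1/V2 vesicles —
without mergers nothing larger ever evolves.

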