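"""Simulation configuration: defaults, validation, loading, hashing.

Every tunable of the model lives in :class:`SimulationConfig`. The
defaults are the study conditions of the four experiment designs; an
empty configuration document is therefore runnable as-is. Documents are
flat YAML key-value mappings mirroring the dataclass fields; unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationConfig", "load_config", "dump_config", "EXPERIMENTS"]

EXPERIMENTS = ("stage1", "stage2", "combined", "control")

#: Default cycle horizons per experiment design.
DEFAULT_MAX_CYCLES = {"stage1": 200, "stage2": 200, "combined": 1500, "control": 1500}


@dataclass
class SimulationConfig:
    """All parameters of a simulation run.

    Probabilities are per cycle unless noted; ``p_synchronize`` is per
    wet-and-dry pair (two cycles). Ranges are inclusive.
    """

    experiment: str = "combined"
    seed: int | None = None
    #: run horizon in cycles; None picks the experiment's default
    max_cycles: int | None = None

    # --- initial population and influx -----------------------------------
    v1_init: int = 3000
    v2_init: int = 2000
    influx_enabled: bool = True
    influx_dry: tuple[int, int] = (2000, 3000)
    influx_wet: tuple[int, int] = (4000, 5000)

    # --- contact and merger ----------------------------------------------
    #: fixed per-pair contact base probability; None draws one value per
    #: run uniformly from ``contact_base_range``
    contact_base: float | None = None
    contact_base_range: tuple[float, float] = (1e-6, 1e-5)
    merge_enabled: bool = True
    jitter_range: tuple[float, float] = (0.05, 0.10)

    # --- per-cycle vesicle processes -------------------------------------
    p_break: float = 0.01
    p_abs: float = 5e-3
    #: "elongate" integrates absorbed monomers into existing molecules
    #: (counts unchanged); "add" packages them into one new short molecule
    absorb_mode: str = "elongate"
    survival_every_cycle: bool = True
    peptide_init_len: tuple[int, int] = (3, 10)

    # --- genetic-code assignment -----------------------------------------
    p_synchronize: float = 0.999
    feedback_mode: bool = False
    feedback_base: float = 1e-3
    #: "random" draws a uniform unassigned AA within the admissible block,
    #: so different lineages assign different AAs and mergers can pool
    #: them; "lowest" is the deterministic alternative (unions of two
    #: lowest-first sets never gain an AA)
    assignment_candidate: str = "random"

    # --- FUCA / LUCA criteria and stage-2 initialisation ------------------
    luca_min_peptides: int = 100
    luca_min_rnas: int = 300
    luca_num_aas: int = 20
    stage2_fuca_count: int = 300
    stage2_np_range: tuple[int, int] = (100, 416)
    stage2_na_range: tuple[int, int] = (14, 16)

    # --- reporting --------------------------------------------------------
    long_peptide_aa: int = 50
    long_rna_nb: int = 150
    record_census: bool = True

    def __post_init__(self) -> None:
        if self.max_cycles is None and self.experiment in DEFAULT_MAX_CYCLES:
            self.max_cycles = DEFAULT_MAX_CYCLES[self.experiment]
        if self.experiment == "control":
            # the control design is the combined run with merging off
            self.merge_enabled = False
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {value}")

        def _range(name: str, rng: tuple, lo_ok=None) -> None:
            if len(rng) != 2 or rng[0] > rng[1]:
                raise ValueError(f"{name} must be an ordered (lo, hi) pair, got {rng}")
            if lo_ok is not None and rng[0] < lo_ok:
                raise ValueError(f"{name} lower bound must be >= {lo_ok}, got {rng}")

        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}")
        if self.max_cycles is None or self.max_cycles < 0:
            raise ValueError(f"max_cycles must be >= 0, got {self.max_cycles}")
        for name in ("p_break", "p_abs", "p_synchronize", "feedback_base"):
            _prob(name, getattr(self, name))
        _prob("p_synchronize (must also be positive)", self.p_synchronize)
        if self.p_synchronize <= 0:
            raise ValueError("p_synchronize must be in (0, 1]")
        for name, lo_ok in (
            ("influx_dry", 0),
            ("influx_wet", 0),
            ("contact_base_range", 0.0),
            ("jitter_range", 0.0),
            ("peptide_init_len", 1),
            ("stage2_np_range", 1),
            ("stage2_na_range", 0),
        ):
            _range(name, getattr(self, name), lo_ok)
        if self.contact_base is not None and not 0.0 <= self.contact_base <= 1.0:
            raise ValueError(f"contact_base must be in [0, 1], got {self.contact_base}")
        if self.stage2_na_range[1] > 20:
            raise ValueError("stage2_na_range upper bound cannot exceed 20")
        if self.absorb_mode not in ("add", "elongate"):
            raise ValueError(f"absorb_mode must be 'add' or 'elongate', got {self.absorb_mode!r}")
        if self.assignment_candidate not in ("lowest", "random"):
            raise ValueError(
                f"assignment_candidate must be 'lowest' or 'random', got {self.assignment_candidate!r}"
            )
        for name in ("v1_init", "v2_init", "stage2_fuca_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = list(value)
            out[f.name] = value
        return out

    @classmethod
    def from_dict(cls, document: dict[str, Any] | None) -> "SimulationConfig":
        document = dict(document or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(document) - known
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {sorted(unknown)}; known keys: {sorted(known)}"
            )
        for key, value in document.items():
            if isinstance(value, list):
                document[key] = tuple(value)
        return cls(**document)

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def config_hash(self) -> str:
        """Stable short hash of every parameter except the seed."""
        payload = {k: v for k, v in self.to_dict().items() if k != "seed"}
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(source: str | Path | dict | None = None) -> SimulationConfig:
    """Load and validate a configuration from a YAML path or a mapping.

    An empty or missing document yields the full defaults. Validation
    errors name the offending key and the admissible range.
    """
    if source is None or isinstance(source, dict):
        return SimulationConfig.from_dict(source)
    text = Path(source).read_text()
    document = yaml.safe_load(text) or {}
    if not isinstance(document, dict):
        raise ValueError(f"configuration document must be a mapping, got {type(document).__name__}")
    return SimulationConfig.from_dict(document)


def dump_config(config: SimulationConfig, path: str | Path | None = None) -> str:
    """Serialise a configuration to YAML (round-trips losslessly)."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text
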