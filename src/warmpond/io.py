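"""Result writers: per-cycle census TSV, run summaries, config echo, log.

All tabular outputs are TSV (tab-separated, header row, UTF-8, LF line
endings) so that runs diff cleanly. Files are deterministic given
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .config import SimulationConfig, dump_config
from .experiments import RunSummary, SimulationResult
from .vesicles import TYPE_SPECS

__all__ = ["write_run_outputs", "write_type_specs", "preflight_out_dir", "plot_census"]


def preflight_out_dir(out_dir: str | Path) -> Path:
    """Create the output directory and verify it is writable."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    return out


def write_type_specs(out_dir: str | Path) -> Path:
    """Dump the six vesicle type specifications as a provenance TSV."""
    rows = []
    for spec in TYPE_SPECS:
        d = dataclasses.asdict(spec)
        rows.append(
            {
                "type": d["type_label"],
                "peptides_min": d["peptide_range"][0],
                "peptides_max": d["peptide_range"][1],
                "rnas_min": d["rna_range"][0],
                "rnas_max": d["rna_range"][1],
                "aas_assigned_min": d["aa_assigned_range"][0],
                "aas_assigned_max": d["aa_assigned_range"][1],
                "fitness_min": d["fitness_range"][0],
                "fitness_max": d["fitness_range"][1],
            }
        )
    path = Path(out_dir) / "type_specs.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def _log_lines(summary: RunSummary, census: pd.DataFrame, verbose: bool) -> list[str]:
    lines = [
        f"experiment={summary.experiment} seed={summary.seed} config_hash={summary.config_hash}",
        f"contact_base={summary.contact_base:.6g} pool_size={summary.pool_size}",
    ]
    if verbose and not census.empty:
        for row in census.itertuples(index=False):
            lines.append(
                f"cycle={row.cycle} phase={row.phase} volume={row.volume} "
                f"n_total={row.n_total} fuca_cum={row.n_fuca_cum} n_luca={row.n_luca}"
            )
    lines.append(
        f"done cycles_run={summary.cycles_run} alive={summary.n_alive} dead={summary.total_dead} "
        f"fucas={summary.fucas_produced} lucas={summary.n_lucas}"
    )
    return lines


def write_run_outputs(
    result: SimulationResult,
    out_dir: str | Path,
    verbose: bool = False,
) -> dict[str, Path]:
    """Write the full file set for one run.

    ``census.tsv`` (per-cycle), ``summary.tsv`` and ``summary.json``,
    ``config_echo.yaml``, ``type_specs.tsv``, and ``log.txt``.
    """
    out = preflight_out_dir(out_dir)
    files: dict[str, Path] = {}

    files["census"] = out / "census.tsv"
    result.census.to_csv(files["census"], sep="\t", index=False, lineterminator="\n")

    files["summary_tsv"] = out / "summary.tsv"
    pd.DataFrame([result.summary.to_flat_row()]).to_csv(
        files["summary_tsv"], sep="\t", index=False, lineterminator="\n"
    )

    files["summary_json"] = out / "summary.json"
    payload = {"summary": result.summary.to_dict(), "config": result.config.to_dict()}
    files["summary_json"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    files["config_echo"] = out / "config_echo.yaml"
    dump_config(result.config, files["config_echo"])

    files["type_specs"] = write_type_specs(out)

    files["log"] = out / "log.txt"
    files["log"].write_text("\n".join(_log_lines(result.summary, result.census, verbose)) + "\n")
    return files


def plot_census(census: pd.DataFrame, path: str | Path) -> Path:
    """Minimal census-over-time figure (counts per vesicle type)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for label in ("n_V1", "n_V2", "n_V3", "n_V4", "n_V5", "n_V6"):
        if label in census:
            ax.plot(census["cycle"], census[label], label=label[2:])
    ax.set_xlabel("cycle")
    ax.set_ylabel("vesicles alive")
    ax.set_yscale("symlog")
    ax.legend(ncol=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
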