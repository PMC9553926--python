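"""End-to-end orchestration: config, stage wiring, reports, and run logs.

The MALDI pipeline composes the experimental workflow — oligo protection →
RNase A digestion → cyanoethylation/¹⁸O chemistry → theoretical species →
peak matching → editing-state inference — and writes an assignment TSV, a
call JSON, and a run log.  Re-running with an identical config and seed
yields byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chemistry import Species, candidate_species
from .digestion import RNASE_A, RNASE_T1, digest, protect_window
from .maldi import (
    EditingCall,
    ION_MODES,
    assignment_table,
    infer_editing_state,
    load_peaklist,
    match_peaks,
)
from .mrm import quantify, read_signal_table
from .sequence import parse_modified_sequence, read_fasta, read_profile


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated, serializable description of one pipeline run."""

    fasta: str | None = None
    mods: str | None = None
    peaks: str | None = None
    signals: str | None = None
    window: tuple[int, int] = (10, 46)
    enzyme: str = RNASE_A
    edit_position: int = 32
    ion: str = "[M-H]-"
    tolerance_da: float = 0.3
    ce_treated: bool = True
    include_o18: bool = True
    normalizer: str = "m5U"
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.window = (int(self.window[0]), int(self.window[1]))
        if self.window[0] > self.window[1]:
            raise ConfigError(f"inverted window {self.window}")
        if self.enzyme not in (RNASE_A, RNASE_T1):
            raise ConfigError(f"unknown enzyme {self.enzyme!r}")
        if self.ion not in ION_MODES:
            raise ConfigError(f"unknown ion mode {self.ion!r}")
        if self.tolerance_da <= 0:
            raise ConfigError(f"tolerance must be positive, got {self.tolerance_da}")
        if self.edit_position < 1:
            raise ConfigError(f"edit position must be >= 1, got {self.edit_position}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        config = cls(**kwargs)
        config.extras.update(extras)
        return config

    def to_dict(self) -> dict:
        data = asdict(self)
        data["window"] = list(self.window)
        return data

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config field {name!r} is required for this stage")
            if not Path(value).exists():
                raise ConfigError(f"input file for {name!r} not found: {value}")


def _write_log(outdir: Path, lines: list[str], config: PipelineConfig) -> None:
    header = [
        f"pseudomap {__version__}",
        f"config: {json.dumps(config.to_dict(), sort_keys=True)}",
    ]
    (outdir / "run.log").write_text("\n".join(header + lines) + "\n")


def run_maldi_pipeline(config: PipelineConfig) -> EditingCall:
    """Protect → digest → chemistry → match → infer; write reports."""
    config.require("fasta", "mods", "peaks")
    seq = parse_modified_sequence(read_fasta(config.fasta), read_profile(config.mods))
    log = [f"stage=parse id={seq.id} length={len(seq)}"]

    window = protect_window(seq, *config.window)
    log.append(f"stage=protect window={config.window[0]}..{config.window[1]} residues={len(window)}")

    fragments = digest(window, config.enzyme)
    log.append(f"stage=digest enzyme={config.enzyme} fragments={len(fragments)}")

    species: list[Species] = []
    n_diag = 0
    for fragment in fragments:
        if fragment.covers(config.edit_position):
            diag = candidate_species(
                fragment,
                config.edit_position,
                ce_treated=config.ce_treated,
                include_o18=config.include_o18,
            )
            species.extend(diag)
            n_diag += len(diag)
        else:
            species.append(Species(fragment, 1.0))
    log.append(f"stage=chemistry species={len(species)} diagnostic={n_diag}")

    peaks = load_peaklist(config.peaks)
    assignments = match_peaks(
        species, peaks, tolerance_da=config.tolerance_da, ion=config.ion
    )
    unmatched = len(peaks) - len(assignments)
    log.append(
        f"stage=match peaks={len(peaks)} assigned={len(assignments)} unmatched={unmatched}"
    )

    call = infer_editing_state(assignments, config.edit_position)
    log.append(
        f"stage=infer position={call.position} state={call.state} "
        f"fraction={call.edited_fraction}"
    )

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        assignment_table(assignments).to_csv(
            outdir / "assignments.tsv", sep="\t", index=False
        )
        payload = {
            "position": call.position,
            "state": call.state,
            "edited_fraction": call.edited_fraction,
            "n_diagnostic": len(call.assignments),
            "seed": config.seed,
        }
        (outdir / "call.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        _write_log(outdir, log, config)
    return call


def call_from_simulation(sim) -> EditingCall:
    """Closed loop in memory: simulate a peak list, then analyze it.

    Runs the same protect → digest → candidates → match → infer chain as
    :func:`run_maldi_pipeline` on a peak list produced by
    :func:`pseudomap.simulate.simulate_maldi` under the given conditions.
    """
    from .simulate import make_trna_like, simulate_maldi

    seq = make_trna_like(sim)
    window = protect_window(seq, *sim.window)
    species: list[Species] = []
    for fragment in digest(window, RNASE_A):
        if fragment.covers(sim.edit_position):
            species.extend(candidate_species(fragment, sim.edit_position))
        else:
            species.append(Species(fragment, 1.0))
    peaks = simulate_maldi(sim)
    assignments = match_peaks(species, peaks)
    return infer_editing_state(assignments, sim.edit_position)


def run_mrm_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Load a signal table, normalize against m⁵U, write the quant report."""
    config.require("signals")
    signals = read_signal_table(config.signals)
    table = quantify(signals, normalizer=config.normalizer)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "quant.tsv", sep="\t", index=False)
        _write_log(
            outdir,
            [
                f"stage=quantify samples={table['sample'].nunique()} rows={len(table)} "
                f"normalizer={config.normalizer}"
            ],
            config,
        )
    return table
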