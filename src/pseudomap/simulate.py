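"""Seeded generators for every input the analysis consumes.

The substrate is an ~85-nt tRNA-Tyr-like molecule: D16 in the D-loop, the
editable C at position 32, queuosine at wobble position 34, ms²io⁶A at 37,
and m⁵U at 54, arranged so the RNase A products of the protected window
include the two diagnostic tetramers — G-A-G-D (positions 13–16) and
A-G-A-C (positions 29–32, ending at the edit site).  The window layout is
fixed so no other digest product is near-isobaric with the diagnostic
species; the acceptor stem and the 3′ half outside the window are drawn
from the seeded stream.

A single root seed fans out to independent per-generator streams, so
adding a generator never perturbs existing outputs, and noiseless settings
reproduce theoretical values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from zlib import crc32

import numpy as np
import pandas as pd

from .chemistry import Species, enumerate_species
from .digestion import RNASE_A, digest, protect_window
from .maldi import as_peaklist, mz
from .modifications import default_table
from .mrm import CHANNEL_M, CHANNEL_M2, nucleoside_inventory
from .sequence import ModRNASeq, parse_modified_sequence

DEFAULT_PROFILE = ((16, "D"), (32, "C"), (34, "Q"), (37, "ms2io6A"), (54, "m5U"))

# Fixed 5' layout through position 55 (1-based).  Positions 1-7 (acceptor
# stem) are seeded; the window 10-46 is laid out so RNase A yields GAGD at
# 13-16 and AGAC at 29-32, with all other products of length != 4 except a
# heavy ms2io6A-containing tetramer far from the diagnostic mass range.
_FIXED_8_55 = "UA" "CAUGAGUAACGGUAGCAAUAGACUGUAAACGGAGGUC" "AGGCGAG" "UU"

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SimulationError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the in vitro editing experiments: an 85-nt substrate,
    50% ¹⁸O-labeled water, essentially complete cyanoethylation, ~0.1 Da
    MALDI mass error and 5% intensity noise.
    """

    seed: int = 0
    length: int = 85
    profile: tuple = DEFAULT_PROFILE
    window: tuple = (10, 46)
    edit_position: int = 32
    edit_state: str = "Y"
    edit_fraction: float = 0.0
    ce_efficiency: float = 1.0
    o18_fraction: float = 0.5
    mass_error_sd: float = 0.1
    intensity_cv: float = 0.05
    n_replicates: int = 2
    decoy_rate: float = 0.0
    peak_scale: float = 100.0
    mrm_scale: float = 1000.0

    def __post_init__(self):
        for name in ("edit_fraction", "ce_efficiency", "o18_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {value}")
        for name in ("mass_error_sd", "intensity_cv", "decoy_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.length < 65:
            raise SimulationError("length must be >= 65 to hold the tRNA-like layout")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.edit_state not in ("U", "Y"):
            raise SimulationError(f"edit_state must be U or Y, got {self.edit_state!r}")
        for position, _ in self.profile:
            if not 1 <= int(position) <= self.length:
                raise SimulationError(
                    f"profile position {position} outside 1..{self.length}"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one named stream of this seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), crc32(stream.encode())])
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def make_trna_like(config: SimConfig) -> ModRNASeq:
    """Reproducible tRNA-Tyr-like substrate for a given seed."""
    rng = config.rng("sequence")
    stem = "".join(rng.choice(list("AGCU"), size=7))
    n_filler = config.length - 55 - 10  # between position 55 and stem'+CCA
    filler = "".join(rng.choice(list("AGCU"), size=n_filler))
    stem_rc = "".join(_COMPLEMENT[b] for b in reversed(stem))
    bases = stem + _FIXED_8_55 + filler + stem_rc + "CCA"
    assert len(bases) == config.length
    return parse_modified_sequence(
        (f"tRNA-Tyr-like-seed{config.seed}", bases), config.profile
    )


def simulate_maldi(config: SimConfig) -> pd.DataFrame:
    """Forward model of a MALDI peak list for the protected window.

    Every RNase A product of the window emits one peak; the fragment
    covering the edit site is expanded into its species ensemble under the
    configured (f, c, w) condition.  Peaks get Gaussian mass error and
    multiplicative intensity noise, floored at zero; optional uniform
    decoy peaks model matrix junk.
    """
    seq = make_trna_like(config)
    window = protect_window(seq, *config.window)
    fragments = digest(window, RNASE_A)
    species: list[Species] = []
    for fragment in fragments:
        if fragment.covers(config.edit_position):
            ensemble = enumerate_species(
                fragment,
                config.edit_position,
                edit_fraction=config.edit_fraction,
                ce_efficiency=config.ce_efficiency,
                o18_fraction=config.o18_fraction,
                edit_state=config.edit_state,
            )
            species.extend(ensemble)
        else:
            species.append(Species(fragment, 1.0))
    rng = config.rng("maldi")
    rows = []
    for s in species:
        theo = mz(s.fragment)
        observed = theo + rng.normal(0.0, config.mass_error_sd) if config.mass_error_sd else theo
        intensity = config.peak_scale * s.weight
        if config.intensity_cv:
            intensity *= 1.0 + rng.normal(0.0, config.intensity_cv)
        rows.append({"mz": observed, "intensity": max(intensity, 0.0)})
    if config.decoy_rate:
        lo = min(r["mz"] for r in rows) - 50.0
        hi = max(r["mz"] for r in rows) + 50.0
        for _ in range(rng.poisson(config.decoy_rate)):
            rows.append(
                {
                    "mz": rng.uniform(lo, hi),
                    "intensity": rng.uniform(0.0, config.peak_scale / 2),
                }
            )
    return as_peaklist(pd.DataFrame(rows))


def simulate_mrm(config: SimConfig) -> pd.DataFrame:
    """Forward model of an MRM signal table over replicate samples.

    Channel intensities are proportional to nucleoside stoichiometry per
    molecule: the edit moves ``f`` of the site's cytidine into the edited
    code, of which a fraction ``w`` carries the water-derived ¹⁸O and
    reports in the M+2 channel.  m⁵U is one per molecule, giving the fixed
    normalization channel.  Noise is multiplicative per row.
    """
    seq = make_trna_like(config)
    counts = nucleoside_inventory(seq)
    f, w = config.edit_fraction, config.o18_fraction
    state = config.edit_state
    site_code = seq.code_at(config.edit_position)
    table = default_table()
    rng = config.rng("mrm")
    rows = []
    for rep in range(1, config.n_replicates + 1):
        sample = f"sample{rep}"
        stoich: dict[tuple[str, str], float] = {}
        for code, n in sorted(counts.items()):
            stoich[(code, CHANNEL_M)] = float(n)
        stoich[(site_code, CHANNEL_M)] -= f
        stoich[(state, CHANNEL_M)] = stoich.get((state, CHANNEL_M), 0.0) + f * (1 - w)
        stoich[(state, CHANNEL_M2)] = f * w
        # report an (empty) M+2 channel for every deamination-eligible code
        for code in sorted(counts):
            if table[code].o18_eligible:
                stoich.setdefault((code, CHANNEL_M2), 0.0)
        for (code, channel), amount in sorted(stoich.items()):
            intensity = config.mrm_scale * amount
            if config.intensity_cv:
                intensity *= 1.0 + rng.normal(0.0, config.intensity_cv)
            rows.append(
                {
                    "sample": sample,
                    "code": code,
                    "channel": channel,
                    "intensity": max(intensity, 0.0),
                }
            )
    return pd.DataFrame(rows)


def simulate_trace(config: SimConfig) -> pd.DataFrame:
    """Sanger trace peak heights at the edit site (U and Ψ both read as T)."""
    rng = config.rng("trace")
    scale = 1000.0
    f = config.edit_fraction
    t = scale * f
    c = scale * (1 - f)
    if config.intensity_cv:
        t *= 1.0 + rng.normal(0.0, config.intensity_cv)
        c *= 1.0 + rng.normal(0.0, config.intensity_cv)
    return pd.DataFrame(
        [
            {
                "position": config.edit_position,
                "A": 0.0,
                "C": max(c, 0.0),
                "G": 0.0,
                "T": max(t, 0.0),
            }
        ]
    )


def simulate_reporter(
    config: SimConfig,
    effects: dict[str, float] | None = None,
    codon: str = "UAC",
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Dual-luciferase measurements for strains with known decoding effects.

    ``effects`` maps strain → multiplier on the in-frame F/R ratio relative
    to WT (frameshift signal unchanged), so the expected relative Rt/Rs of
    a strain equals its effect.  Signals carry lognormal replicate noise.
    """
    effects = dict(effects or {"WT": 1.0, "mutant": 0.5})
    if "WT" not in effects:
        raise SimulationError("effects must include the WT reference strain")
    n = n_replicates or config.n_replicates
    rng = config.rng("reporter")
    base_renilla, base_f0, base_f1 = 1.0e4, 2.0, 0.1
    cv = config.intensity_cv
    rows = []
    for strain, effect in effects.items():
        for frame, ratio in (("0", base_f0 * effect), ("+1", base_f1)):
            for _ in range(n):
                renilla = base_renilla * np.exp(rng.normal(0.0, cv)) if cv else base_renilla
                firefly = renilla * ratio * (np.exp(rng.normal(0.0, cv)) if cv else 1.0)
                rows.append(
                    {
                        "strain": strain,
                        "codon": codon,
                        "frame": frame,
                        "firefly": firefly,
                        "renilla": renilla,
                    }
                )
    return pd.DataFrame(rows)
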