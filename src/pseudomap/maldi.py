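"""MALDI-TOF m/z computation, peak matching, and editing-state inference.

Fragments fly as singly (de)protonated ions; the default convention is
[M−H]⁻ on the monoisotopic scale, the one consistent with the printed m/z
of the diagnostic tetramers (AGACp 1325.1, GAGDp 1344, AGAΨp+CE 1379.1).
Observed peak lists are matched greedily to theoretical species within a
mass tolerance, and the editing state at a target position is called from
which diagnostic species are observed:

* the CE-shifted species (+0.984 +53.027) → Ψ,
* the +0.984 species without a CE shift, after CE treatment → U,
* only the unedited species → C.

The edited fraction is estimated from relative intensities of the
diagnostic species, assuming equal desorption/ionization efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chemistry import Species, SpeciesLabel
from .digestion import Fragment, neutral_mass
from .elements import MONOISOTOPIC, PROTON_MASS
from .modifications import ModificationTable, default_table

ION_MODES = {
    "[M-H]-": -PROTON_MASS,
    "[M+H]+": +PROTON_MASS,
}


class MatchingError(ValueError):
    """Invalid peak list, ion mode, or inference input."""


def mz(
    fragment: Fragment,
    ion: str = "[M-H]-",
    scale: str = MONOISOTOPIC,
    table: ModificationTable | None = None,
) -> float:
    """m/z of a singly charged fragment ion."""
    try:
        adjust = ION_MODES[ion]
    except KeyError:
        raise MatchingError(f"unknown ion type {ion!r}; expected one of {sorted(ION_MODES)}") from None
    return neutral_mass(fragment, scale=scale, table=table) + adjust


def load_peaklist(path) -> pd.DataFrame:
    """Read a TSV/CSV peak list (``mz``, ``intensity``; header optional)."""
    path = Path(path)
    if not path.exists():
        raise MatchingError(f"peak list not found: {path}")
    frame = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    first = frame.iloc[0]
    if any(isinstance(v, str) for v in first):
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.shape[1] < 2:
        raise MatchingError(f"peak list {path} needs two columns (mz, intensity)")
    frame = frame.iloc[:, :2].astype(float)
    frame.columns = ["mz", "intensity"]
    return as_peaklist(frame)


def as_peaklist(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort an (mz, intensity) table ascending by m/z."""
    if not {"mz", "intensity"} <= set(frame.columns):
        raise MatchingError("peak list needs 'mz' and 'intensity' columns")
    if (frame["mz"] <= 0).any():
        raise MatchingError("peak m/z values must be positive")
    if (frame["intensity"] < 0).any():
        raise MatchingError("peak intensities must be non-negative")
    return frame.sort_values("mz", kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class Assignment:
    """One observed peak matched to one theoretical species."""

    peak_index: int
    mz_observed: float
    intensity: float
    species: Species
    mz_theoretical: float
    error: float  # observed − theoretical (Da)

    @property
    def fragment(self) -> Fragment:
        return self.species.fragment

    @property
    def label(self) -> SpeciesLabel | None:
        return self.species.label


@dataclass(frozen=True)
class EditingCall:
    """Inferred state of the edit site with an edited-fraction estimate."""

    position: int
    state: str  # "C" | "U" | "Y"
    edited_fraction: float | None
    assignments: tuple[Assignment, ...]


def match_peaks(
    species: Sequence[Species],
    peaks: pd.DataFrame,
    tolerance_da: float = 0.3,
    ion: str = "[M-H]-",
    scale: str = MONOISOTOPIC,
    table: ModificationTable | None = None,
) -> list[Assignment]:
    """Greedy nearest-mass matching of peaks to theoretical species.

    Each peak is assigned to at most one species and each species to at
    most one peak; candidate pairs within tolerance are taken smallest
    |error| first, ties broken by higher peak intensity.
    """
    if tolerance_da <= 0:
        raise MatchingError(f"tolerance must be positive, got {tolerance_da}")
    table = table or default_table()
    peaks = as_peaklist(peaks)
    theoretical = [mz(s.fragment, ion=ion, scale=scale, table=table) for s in species]
    candidates = []
    for pi, (observed, intensity) in enumerate(
        zip(peaks["mz"].to_numpy(), peaks["intensity"].to_numpy())
    ):
        for si, theo in enumerate(theoretical):
            error = observed - theo
            if abs(error) <= tolerance_da:
                candidates.append((abs(error), -intensity, pi, si))
    candidates.sort()
    assignments: list[Assignment] = []
    used_peaks: set[int] = set()
    used_species: set[int] = set()
    for abs_err, neg_int, pi, si in candidates:
        if pi in used_peaks or si in used_species:
            continue
        used_peaks.add(pi)
        used_species.add(si)
        observed = float(peaks["mz"].iloc[pi])
        assignments.append(
            Assignment(
                peak_index=pi,
                mz_observed=observed,
                intensity=float(peaks["intensity"].iloc[pi]),
                species=species[si],
                mz_theoretical=theoretical[si],
                error=observed - theoretical[si],
            )
        )
    assignments.sort(key=lambda a: a.peak_index)
    return assignments


def diagnostic_assignments(
    assignments: Iterable[Assignment], position: int
) -> list[Assignment]:
    """Assignments of labeled species whose fragment covers the position."""
    return [
        a
        for a in assignments
        if a.label is not None and a.fragment.covers(position)
    ]


def estimate_edit_fraction(assignments: Sequence[Assignment]) -> float:
    """Edited fraction from relative intensities of diagnostic species.

    fraction = Σ intensity(edited species) / Σ intensity(all diagnostic
    species); assumes equal ionization efficiency across species, hence is
    invariant to a common intensity scale.
    """
    labeled = [a for a in assignments if a.label is not None]
    if not labeled:
        raise MatchingError("no diagnostic species observed; fraction undefined")
    total = sum(a.intensity for a in labeled)
    if total <= 0:
        raise MatchingError("total diagnostic intensity is zero; fraction undefined")
    edited = sum(a.intensity for a in labeled if a.label.edited)
    return edited / total


def infer_editing_state(
    assignments: Iterable[Assignment],
    position: int,
) -> EditingCall:
    """Call the editing state at ``position`` from matched assignments."""
    diag = diagnostic_assignments(assignments, position)
    if not diag:
        raise MatchingError(
            f"no diagnostic fragment covering position {position} was observed"
        )
    observed = [a for a in diag if a.intensity > 0]
    basis = observed or diag
    if any(a.label.state == "Y" and a.label.ce > 0 for a in basis):
        state = "Y"
    elif any(a.label.state == "U" for a in basis):
        state = "U"
    else:
        state = "C"
    fraction = estimate_edit_fraction(diag) if any(a.intensity > 0 for a in diag) else None
    return EditingCall(
        position=position,
        state=state,
        edited_fraction=fraction,
        assignments=tuple(diag),
    )


def assignment_table(assignments: Iterable[Assignment]) -> pd.DataFrame:
    """Tabular assignment report (TSV-ready)."""
    rows = [
        {
            "peak_mz": a.mz_observed,
            "intensity": a.intensity,
            "fragment": a.fragment.sequence,
            "start": a.fragment.start,
            "end": a.fragment.end,
            "species": a.label.text() if a.label else "",
            "theoretical_mz": a.mz_theoretical,
            "error_da": a.error,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows)
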