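"""Editing-state substitution, cyanoethylation, and ¹⁸O labeling.

The edit site can be in one of three states — C (unedited), U (deaminated
only), or Ψ (deaminated and isomerized).  Deamination installs a base
oxygen drawn from water, so in heavy-water reactions the U/Ψ product may
carry ¹⁸O (+2.00425 Da); acrylonitrile attaches a cyanoethyl group
(+53.0266 Da) specifically to Ψ.  An experimental condition — edit
fraction ``f``, cyanoethylation efficiency ``c``, ¹⁸O water fraction ``w``
— therefore induces a small, weighted ensemble of molecular species, which
this module enumerates under independence of the three channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb, isclose
from typing import Iterable, Mapping

from .digestion import Fragment
from .modifications import ModificationTable, default_table
from .sequence import ModRNASeq, SequenceError

EDIT_STATES = ("C", "U", "Y")

_STATE_DISPLAY = {"C": "C", "U": "U", "Y": "Ψ"}


class ChemistryError(ValueError):
    """Invalid editing state, site, or condition parameter."""


@dataclass(frozen=True)
class SpeciesLabel:
    """Diagnostic identity of one molecular species at the edit site."""

    state: str  # "C" | "U" | "Y"
    ce: int = 0  # cyanoethyl adducts carried
    o18: bool = False  # deamination oxygen is ¹⁸O

    def __post_init__(self):
        if self.state not in EDIT_STATES:
            raise ChemistryError(f"unknown edit state {self.state!r}; expected C/U/Y")

    @property
    def edited(self) -> bool:
        return self.state != "C"

    def text(self) -> str:
        label = _STATE_DISPLAY[self.state]
        if self.ce:
            label += "+CE" if self.ce == 1 else f"+{self.ce}CE"
        if self.o18:
            label += "+18O"
        return label


@dataclass(frozen=True)
class Species:
    """A concrete molecular variant with an abundance weight."""

    fragment: Fragment
    weight: float = 1.0
    label: SpeciesLabel | None = None  # None → not diagnostic for the edit site

    def __post_init__(self):
        if self.weight < 0:
            raise ChemistryError(f"negative species weight {self.weight}")


@dataclass(frozen=True)
class SpeciesEnsemble:
    """Weighted set of species induced by one experimental condition."""

    species: tuple[Species, ...]
    params: Mapping | None = None

    def __post_init__(self):
        total = sum(s.weight for s in self.species)
        if self.species and not isclose(total, 1.0, abs_tol=1e-9):
            raise ChemistryError(f"ensemble weights sum to {total}, not 1")

    def __iter__(self):
        return iter(self.species)

    def __len__(self) -> int:
        return len(self.species)


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ChemistryError(f"{name} must be in [0, 1], got {value}")
    return value


def apply_editing(
    seq: ModRNASeq,
    position: int,
    state: str,
    o18_labeled: bool = False,
) -> ModRNASeq:
    """Set the editing state of a C/U/Ψ site on a full sequence.

    With ``o18_labeled`` and a deaminated state (U or Ψ), the installed
    base oxygen is ¹⁸O and the position is recorded as labeled.
    """
    if state not in EDIT_STATES:
        raise ChemistryError(f"unknown edit state {state!r}; expected C/U/Y")
    current = seq.code_at(position)
    if current not in EDIT_STATES:
        raise ChemistryError(
            f"position {position} holds {current!r}, not an editable C/U/Ψ site"
        )
    labeled = bool(o18_labeled) and state in ("U", "Y")
    return seq.replace_code(position, state, o18=labeled)


def seq_to_fragment(
    seq: ModRNASeq,
    five_prime: str = "OH",
    three_prime: str = "OH",
) -> Fragment:
    """View a whole (sub)sequence as one fragment with native termini."""
    return Fragment(
        parent_id=seq.id,
        start=seq.start,
        end=seq.end,
        codes=seq.codes,
        five_prime=five_prime,
        three_prime=three_prime,
        o18_count=len(seq.o18_positions),
    )


def cyanoethylate(
    fragment: Fragment,
    efficiency: float = 1.0,
    table: ModificationTable | None = None,
) -> SpeciesEnsemble:
    """Acrylonitrile treatment of one fragment.

    Each CE-reactive site (Ψ, by default the only reactive code) gains a
    cyanoethyl group independently with probability ``efficiency``; the
    result is the binomial ensemble over adduct counts.  A fragment with no
    reactive sites returns the identity ensemble.
    """
    efficiency = _check_unit("efficiency", efficiency)
    table = table or default_table()
    n_sites = sum(1 for code in fragment.codes if table[code].ce_reactive)
    if n_sites == 0 or efficiency == 0.0:
        return SpeciesEnsemble(
            (Species(fragment, 1.0),), params={"efficiency": efficiency}
        )
    species = []
    for k in range(n_sites + 1):
        weight = comb(n_sites, k) * efficiency**k * (1 - efficiency) ** (n_sites - k)
        if weight == 0.0:
            continue
        species.append(Species(replace(fragment, ce_count=fragment.ce_count + k), weight))
    return SpeciesEnsemble(tuple(species), params={"efficiency": efficiency})


def _edit_variant(
    fragment: Fragment,
    position: int,
    label: SpeciesLabel,
) -> Fragment:
    """Fragment variant realizing one species label at the edit site."""
    variant = fragment.replace_code(position, label.state)
    return replace(
        variant,
        ce_count=fragment.ce_count + label.ce,
        o18_count=fragment.o18_count + (1 if label.o18 else 0),
    )


def enumerate_species(
    fragment: Fragment,
    position: int,
    edit_fraction: float,
    ce_efficiency: float = 1.0,
    o18_fraction: float = 0.0,
    edit_state: str = "Y",
    table: ModificationTable | None = None,
) -> SpeciesEnsemble:
    """Species ensemble of the fragment covering the edit site.

    Weights follow independence of the three channels: the site is edited
    with probability ``f``; an edited site carries the water-derived ¹⁸O
    with probability ``w``; an edited Ψ site is cyanoethylated with
    probability ``c`` (CE does not touch C or U).  Setting any parameter to
    0 or 1 collapses the corresponding branch, so e.g. ``f=1, c=1, w=0``
    yields the single Ψ+CE species.
    """
    f = _check_unit("edit_fraction", edit_fraction)
    c = _check_unit("ce_efficiency", ce_efficiency)
    w = _check_unit("o18_fraction", o18_fraction)
    if edit_state not in ("U", "Y"):
        raise ChemistryError(f"edit_state must be U or Y, got {edit_state!r}")
    if not fragment.covers(position):
        raise ChemistryError(
            f"edit position {position} outside fragment {fragment.start}..{fragment.end}"
        )
    if fragment.code_at(position) not in EDIT_STATES:
        raise ChemistryError(
            f"position {position} holds {fragment.code_at(position)!r}, not an editable site"
        )
    table = table or default_table()
    ce_applies = edit_state == "Y" and table[edit_state].ce_reactive

    weighted: list[tuple[SpeciesLabel, float]] = [(SpeciesLabel("C"), 1 - f)]
    ce_branches = ((1, c), (0, 1 - c)) if ce_applies else ((0, 1.0),)
    for ce, p_ce in ce_branches:
        for o18, p_o18 in ((True, w), (False, 1 - w)):
            weighted.append((SpeciesLabel(edit_state, ce=ce, o18=o18), f * p_ce * p_o18))

    species = tuple(
        Species(_edit_variant(fragment, position, label), weight, label)
        for label, weight in weighted
        if weight > 0.0
    )
    params = {
        "edit_fraction": f,
        "ce_efficiency": c,
        "o18_fraction": w,
        "edit_position": position,
        "edit_state": edit_state,
    }
    return SpeciesEnsemble(species, params=params)


def candidate_species(
    fragment: Fragment,
    position: int,
    ce_treated: bool = True,
    include_o18: bool = True,
    table: ModificationTable | None = None,
) -> list[Species]:
    """All diagnostic species to search for at match time (weights unknown).

    After cyanoethylation the observable states are: unedited C; U without
    a CE shift (the pseudouridylase-dead outcome); and Ψ carrying the CE
    adduct — each with an optional ¹⁸O channel for the deaminated states.
    Without CE treatment U and Ψ are isobaric, so only the U label is
    emitted for the +0.984 species.
    """
    if not fragment.covers(position):
        raise ChemistryError(
            f"edit position {position} outside fragment {fragment.start}..{fragment.end}"
        )
    table = table or default_table()
    labels = [SpeciesLabel("C")]
    o18_options = (False, True) if include_o18 else (False,)
    for o18 in o18_options:
        labels.append(SpeciesLabel("U", o18=o18))
        if ce_treated:
            labels.append(SpeciesLabel("Y", ce=1, o18=o18))
    return [
        Species(_edit_variant(fragment, position, label), 1.0, label) for label in labels
    ]
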