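"""Oligo-protection windowing and in-silico RNase A / T1 digestion.

RNase A cleaves 3′ of pyrimidine-derived residues, RNase T1 3′ of
guanosine-derived residues, both leaving 5′-OH products and a 3′ phosphate
(linear after hydrolysis of the 2′,3′-cyclic intermediate, which is also
available as an option).  2′-O-methylated residues block cleavage at their
position; queuosine is treated as T1-resistant by default.  Digestion is
modeled as complete — partial digestion is expressed only through missed
cleavages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .elements import (
    CYANOETHYL,
    HPO3,
    MONOISOTOPIC,
    WATER,
    Formula,
    mass_of,
)
from .modifications import ModificationTable, default_table
from .sequence import ModRNASeq, SequenceError

RNASE_A = "RNaseA"
RNASE_T1 = "RNaseT1"

# Terminal chemistry codes
FIVE_OH = "OH"
FIVE_P = "p"
THREE_P = "p"  # linear 3'-phosphate (default, hydrolyzed product)
THREE_CYCLIC = "cp"  # 2',3'-cyclic phosphate
THREE_OH = "OH"


class DigestionError(ValueError):
    """Unknown enzyme or invalid digestion parameters."""


@dataclass(frozen=True)
class Fragment:
    """A contiguous digest product with terminal chemistry and labels."""

    parent_id: str
    start: int  # 1-based inclusive, parent coordinates
    end: int
    codes: tuple[str, ...]
    five_prime: str = FIVE_OH
    three_prime: str = THREE_P
    ce_count: int = 0
    o18_count: int = 0
    missed_cleavages: int = 0

    def __post_init__(self):
        if self.end < self.start:
            raise DigestionError(f"fragment end {self.end} < start {self.start}")
        if len(self.codes) != self.end - self.start + 1:
            raise DigestionError("fragment codes do not match its span")
        if self.ce_count < 0 or self.o18_count < 0:
            raise DigestionError("label counts must be non-negative")

    def __len__(self) -> int:
        return len(self.codes)

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end

    def code_at(self, position: int) -> str:
        if not self.covers(position):
            raise DigestionError(f"position {position} outside fragment {self.start}..{self.end}")
        return self.codes[position - self.start]

    def replace_code(self, position: int, code: str) -> "Fragment":
        i = position - self.start
        return replace(self, codes=self.codes[:i] + (code,) + self.codes[i + 1 :])

    @property
    def sequence(self) -> str:
        return "-".join(self.codes)


def protect_window(seq: ModRNASeq, start: int = 10, end: int = 46) -> ModRNASeq:
    """Retain the oligo-protected window, keeping original position labels.

    The default window (10, 46) is the region protected by the two
    complementary DNA oligos in the fragment-analysis workflow.
    """
    if start > end:
        raise SequenceError(f"inverted protection window {start}..{end}")
    return seq.subsequence(start, end)


def cleaves_after(
    code: str,
    enzyme: str,
    table: ModificationTable,
    t1_resistant: frozenset = frozenset({"Q"}),
) -> bool:
    """Whether the enzyme cleaves the phosphodiester bond 3′ of ``code``."""
    moddef = table[code]
    if moddef.blocks_cleavage:
        return False
    if enzyme == RNASE_A:
        return moddef.pyrimidine_derived
    if enzyme == RNASE_T1:
        return moddef.guanosine_derived and code not in t1_resistant
    raise DigestionError(f"unknown enzyme {enzyme!r}; expected {RNASE_A} or {RNASE_T1}")


def digest(
    seq: ModRNASeq,
    enzyme: str,
    missed_cleavages: int = 0,
    phosphate_form: str = THREE_P,
    table: ModificationTable | None = None,
    t1_resistant: Iterable[str] = ("Q",),
    parent_three_prime: str = THREE_OH,
) -> list[Fragment]:
    """Complete limit digest of ``seq``, in sequence order.

    Products carry 5′-OH and the requested 3′ phosphate form; the final
    fragment keeps the parent's native 3′ end.  With ``missed_cleavages``
    > 0, all variants skipping up to that many internal sites are included.
    """
    if missed_cleavages < 0:
        raise DigestionError("missed_cleavages must be >= 0")
    if phosphate_form not in (THREE_P, THREE_CYCLIC):
        raise DigestionError(f"unknown phosphate form {phosphate_form!r}")
    table = table or default_table()
    t1_resistant = frozenset(t1_resistant)
    n = len(seq)
    if n == 0:
        return []
    # 0-based indices of residues after which a cut occurs (internal only)
    cuts = [
        i
        for i, code in enumerate(seq.codes[:-1])
        if cleaves_after(code, enzyme, table, t1_resistant)
    ]
    bounds = [-1] + cuts + [n - 1]
    fragments = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + missed_cleavages + 2, len(bounds))):
            lo, hi = bounds[i] + 1, bounds[j]  # 0-based inclusive slice
            start, end = seq.start + lo, seq.start + hi
            is_terminal = hi == n - 1
            fragments.append(
                Fragment(
                    parent_id=seq.id,
                    start=start,
                    end=end,
                    codes=seq.codes[lo : hi + 1],
                    five_prime=FIVE_OH,
                    three_prime=parent_three_prime if is_terminal else phosphate_form,
                    o18_count=sum(1 for p in seq.o18_positions if start <= p <= end),
                    missed_cleavages=j - i - 1,
                )
            )
    fragments.sort(key=lambda f: (f.start, f.end))
    return fragments


# ---------------------------------------------------------------------------
# Fragment composition and mass
# ---------------------------------------------------------------------------

def fragment_formula(fragment: Fragment, table: ModificationTable | None = None) -> Formula:
    """Neutral elemental composition of a fragment, labels included.

    Chain of n internal residues (each carrying one phosphate) + H₂O gives
    the 5′-OH / 3′-linear-phosphate molecule; terminal variants adjust by
    ±H₂O / ±HPO₃.
    """
    table = table or default_table()
    formula = WATER
    for code in fragment.codes:
        formula = formula + table.residue_formula(code)
    if fragment.five_prime == FIVE_P:
        formula = formula + HPO3
    elif fragment.five_prime != FIVE_OH:
        raise DigestionError(f"unknown 5' terminus {fragment.five_prime!r}")
    if fragment.three_prime == THREE_CYCLIC:
        formula = formula - WATER
    elif fragment.three_prime == THREE_OH:
        formula = formula - HPO3
    elif fragment.three_prime != THREE_P:
        raise DigestionError(f"unknown 3' terminus {fragment.three_prime!r}")
    formula = formula + CYANOETHYL * fragment.ce_count
    return formula.substitute("O", "O[18]", fragment.o18_count)


def neutral_mass(
    fragment: Fragment,
    scale: str = MONOISOTOPIC,
    table: ModificationTable | None = None,
) -> float:
    return mass_of(fragment_formula(fragment, table), scale=scale)


def fragment_table(
    fragments: Iterable[Fragment],
    table: ModificationTable | None = None,
) -> pd.DataFrame:
    """Tabular digest report (TSV-ready)."""
    table = table or default_table()
    rows = [
        {
            "start": f.start,
            "end": f.end,
            "sequence": f.sequence,
            "five_prime": f.five_prime,
            "three_prime": f.three_prime,
            "ce_count": f.ce_count,
            "o18_count": f.o18_count,
            "missed_cleavages": f.missed_cleavages,
            "neutral_mass": neutral_mass(f, table=table),
        }
        for f in fragments
    ]
    return pd.DataFrame(rows)
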