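"""Modified-nucleotide vocabulary.

Each residue code maps to a :class:`ModDef` holding the internal-chain
residue formula (nucleoside-5′-monophosphate minus water — i.e. the unit
added per chain position, one phosphate included) plus the chemistry flags
the digestion and labeling stages consult:

``pyrimidine_derived``
    residue is an RNase A cleavage substrate (C, U, Ψ, D, m⁵U, …);
``guanosine_derived``
    residue is an RNase T1 cleavage substrate (G, Q, …);
``ce_reactive``
    acrylonitrile attaches a cyanoethyl group (Ψ only, by default);
``blocks_cleavage``
    2′-O-methylation removes the 2′-OH required for RNase cleavage;
``o18_eligible``
    deamination can install a water-derived base oxygen (U/Ψ), so an
    M+2 isotopologue channel is meaningful.

The shipped table (``data/modifications.tsv``) uses short local codes with
a MODOMICS short-name column for cross-reference.  Unknown codes are always
errors, never silently skipped.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .elements import HPO3, WATER, Formula


class UnknownModificationError(KeyError):
    """Residue code absent from the modification table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class ModDef:
    code: str
    name: str
    modomics_short: str
    parents: str  # canonical bases this code may sit on, e.g. "U" or "CU"
    formula: Formula  # internal chain residue (includes one phosphate)
    pyrimidine_derived: bool
    guanosine_derived: bool
    ce_reactive: bool
    blocks_cleavage: bool
    o18_eligible: bool
    mrm_product_rule: str | None  # e.g. "loss:H4O2"; None → default ribose loss

    @property
    def nucleoside_formula(self) -> Formula:
        """Free nucleoside (residue − HPO₃ + H₂O), as released by P1/PDE/CIP."""
        return self.formula - HPO3 + WATER


class ModificationTable(Mapping):
    """Lookup of residue codes → :class:`ModDef`."""

    def __init__(self, defs: Mapping[str, ModDef]) -> None:
        self._defs = dict(defs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ModificationTable":
        defs = {}
        for row in frame.itertuples(index=False):
            rule = getattr(row, "mrm_product_rule", None)
            if rule is not None and (pd.isna(rule) or rule == ""):
                rule = None
            defs[row.code] = ModDef(
                code=row.code,
                name=row.name,
                modomics_short=row.modomics_short,
                parents=row.parents,
                formula=Formula.parse(row.formula),
                pyrimidine_derived=bool(int(row.pyrimidine_derived)),
                guanosine_derived=bool(int(row.guanosine_derived)),
                ce_reactive=bool(int(row.ce_reactive)),
                blocks_cleavage=bool(int(row.blocks_cleavage)),
                o18_eligible=bool(int(row.o18_eligible)),
                mrm_product_rule=rule,
            )
        return cls(defs)

    @classmethod
    def from_tsv(cls, path) -> "ModificationTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def __getitem__(self, code: str) -> ModDef:
        try:
            return self._defs[code]
        except KeyError:
            raise UnknownModificationError(
                f"unknown residue code {code!r}; known codes: {sorted(self._defs)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def residue_formula(self, code: str) -> Formula:
        return self[code].formula


@lru_cache(maxsize=1)
def default_table() -> ModificationTable:
    """Modification table shipped with the package."""
    ref = resources.files("pseudomap").joinpath("data/modifications.tsv")
    with resources.as_file(ref) as path:
        return ModificationTable.from_tsv(path)
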