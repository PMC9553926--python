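"""Elemental composition and mass bookkeeping for modified-RNA species.

Atomic masses come from the NIST table shipped with :mod:`pyteomics`.
Stable-isotope labels are first-class element symbols written in bracket
notation (``O[18]``), so ¹⁸O-labeled and unlabeled species coexist in one
formula without any mass hacks: substituting ``O[18]`` for ``O`` shifts a
monoisotopic mass by +2.00425 Da, exactly the shift tracked in heavy-water
deamination experiments.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from pyteomics.mass import nist_mass

MONOISOTOPIC = "monoisotopic"
AVERAGE = "average"

#: Mass of a proton (Da); used for [M−H]⁻ / [M+H]⁺ ion adjustments.
PROTON_MASS = 1.00727646688

_TOKEN = re.compile(r"([A-Z][a-z]?)(?:\[(\d+)\])?(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or invalid element arithmetic."""


class Formula(Mapping):
    """Immutable multiset of element symbols with non-negative counts.

    Supports ``+``, ``-`` (raising if any count would go negative — a
    finalized molecule can never owe atoms), integer ``*``, and isotope
    substitution via :meth:`substitute`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        clean: dict[str, int] = {}
        for symbol, n in dict(counts or {}).items():
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {symbol}: {n}")
            if n:
                clean[symbol] = n
        object.__setattr__(self, "_counts", clean)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("Formula is immutable")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse e.g. ``"C9H12N3O7P"`` or ``"C9H11N2O7O[18]P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at {pos}")
            symbol = m.group(1)
            if m.group(2):
                symbol = f"{symbol}[{m.group(2)}]"
            counts[symbol] = counts.get(symbol, 0) + int(m.group(3) or 1)
            pos = m.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at {pos}")
        return cls(counts)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, symbol: str, default: int = 0) -> int:
        return self._counts.get(symbol, default)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for symbol, n in other.items():
            counts[symbol] = counts.get(symbol, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for symbol, n in other.items():
            new = counts.get(symbol, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction leaves negative {symbol} count ({new})"
                )
            counts[symbol] = new
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative int, got {k!r}")
        return Formula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def substitute(self, old: str, new: str, n: int = 1) -> "Formula":
        """Replace ``n`` atoms of ``old`` by ``new`` (isotope labeling)."""
        if n == 0:
            return self
        counts = dict(self._counts)
        have = counts.get(old, 0)
        if have < n:
            raise FormulaError(f"cannot substitute {n}×{old}: only {have} present")
        counts[old] = have - n
        counts[new] = counts.get(new, 0) + n
        return Formula(counts)

    # -- misc -------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def to_string(self) -> str:
        def key(symbol: str):
            order = {"C": 0, "H": 1}
            return (order.get(symbol.split("[")[0], 2), symbol)

        parts = []
        for symbol in sorted(self._counts, key=key):
            n = self._counts[symbol]
            parts.append(symbol if n == 1 else f"{symbol}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"Formula({self.to_string()!r})"


class ElementMassTable:
    """Monoisotopic and average masses for element symbols.

    Plain symbols (``O``) resolve to the natural element; bracketed symbols
    (``O[18]``) to a specific isotope, whose average mass equals its exact
    mass by definition.
    """

    def __init__(self, data: Mapping | None = None) -> None:
        self._data = data if data is not None else nist_mass

    @staticmethod
    def _split(symbol: str) -> tuple[str, int | None]:
        if "[" in symbol:
            element, _, rest = symbol.partition("[")
            return element, int(rest.rstrip("]"))
        return symbol, None

    def monoisotopic(self, symbol: str) -> float:
        element, isotope = self._split(symbol)
        try:
            table = self._data[element]
            mass = table[isotope][0] if isotope is not None else table[0][0]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None
        return mass

    def average(self, symbol: str) -> float:
        element, isotope = self._split(symbol)
        try:
            table = self._data[element]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None
        if isotope is not None:
            return table[isotope][0]
        total = num = 0.0
        for iso, (mass, abundance) in table.items():
            if iso == 0 or not abundance:
                continue
            num += mass * abundance
            total += abundance
        return num / total if total else table[0][0]

    def mass(self, symbol: str, scale: str = MONOISOTOPIC) -> float:
        if scale == MONOISOTOPIC:
            return self.monoisotopic(symbol)
        if scale == AVERAGE:
            return self.average(symbol)
        raise ValueError(f"unknown mass scale {scale!r}")


DEFAULT_MASS_TABLE = ElementMassTable()


def mass_of(
    formula: Formula,
    scale: str = MONOISOTOPIC,
    table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Σ count × element mass on the requested scale (Da)."""
    return sum(n * table.mass(symbol, scale) for symbol, n in formula.items())


WATER = Formula.parse("H2O")
#: Cyanoethyl adduct installed on Ψ by acrylonitrile (+53.0266 Da).
CYANOETHYL = Formula.parse("C3H3N")
#: Phosphate unit gained/lost when changing terminal chemistry.
HPO3 = Formula.parse("HPO3")

#: Monoisotopic shift of an ¹⁸O-for-¹⁶O substitution (≈ +2.00425 Da).
O18_MASS_SHIFT = DEFAULT_MASS_TABLE.monoisotopic("O[18]") - DEFAULT_MASS_TABLE.monoisotopic("O")

#: Net deamination delta C→U on a residue: −NH, +O (≈ +0.98402 Da).
DEAMINATION_MASS_SHIFT = (
    DEFAULT_MASS_TABLE.monoisotopic("O")
    - DEFAULT_MASS_TABLE.monoisotopic("N")
    - DEFAULT_MASS_TABLE.monoisotopic("H")
)
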