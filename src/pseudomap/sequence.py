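"""Modified-RNA sequence model and its FASTA + profile readers.

A :class:`ModRNASeq` is an ordered list of residue codes with 1-based,
inclusive, linear positions.  Sub-sequences (e.g. an oligo-protected
window) retain the parent's position labels, so "position 32" always means
the same residue regardless of windowing.  ¹⁸O labels live on the sequence
as a set of labeled positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .modifications import ModificationTable, default_table

CANONICAL_BASES = ("A", "C", "G", "U")


class SequenceError(ValueError):
    """Invalid sequence, position, or modification-profile input."""


@dataclass(frozen=True)
class ModRNASeq:
    """Ordered residues with modification codes and 1-based positions."""

    id: str
    codes: tuple[str, ...]
    start: int = 1  # position label of the first residue
    o18_positions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        bad = self.o18_positions - set(self.positions())
        if bad:
            raise SequenceError(f"¹⁸O labels at positions outside sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def end(self) -> int:
        return self.start + len(self.codes) - 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def index(self, position: int) -> int:
        if not self.start <= position <= self.end:
            raise SequenceError(
                f"position {position} outside {self.start}..{self.end} of {self.id!r}"
            )
        return position - self.start

    def code_at(self, position: int) -> str:
        return self.codes[self.index(position)]

    def replace_code(self, position: int, code: str, o18: bool | None = None) -> "ModRNASeq":
        i = self.index(position)
        codes = self.codes[:i] + (code,) + self.codes[i + 1 :]
        labels = set(self.o18_positions)
        if o18 is True:
            labels.add(position)
        elif o18 is False:
            labels.discard(position)
        return replace(self, codes=codes, o18_positions=frozenset(labels))

    def subsequence(self, start: int, end: int) -> "ModRNASeq":
        if start > end:
            raise SequenceError(f"inverted window {start}..{end}")
        i, j = self.index(start), self.index(end)
        return replace(
            self,
            codes=self.codes[i : j + 1],
            start=start,
            o18_positions=frozenset(p for p in self.o18_positions if start <= p <= end),
        )


def parse_modified_sequence(
    record,
    profile_rows: Iterable[tuple[int, str]] = (),
    table: ModificationTable | None = None,
    id: str | None = None,
) -> ModRNASeq:
    """Build a :class:`ModRNASeq` from a base sequence plus a profile.

    ``record`` may be a Bio.SeqRecord, a ``(id, sequence)`` pair, or a plain
    string.  ``profile_rows`` are ``(position, code)`` pairs substituting
    modification codes at the stated 1-based positions; every code must
    resolve in the table and sit on a compatible parent base.
    """
    table = table or default_table()
    if isinstance(record, SeqRecord):
        seq_id, bases = record.id, str(record.seq)
    elif isinstance(record, str):
        seq_id, bases = id or "seq", record
    else:
        seq_id, bases = record
    bases = bases.upper().replace("T", "U")
    for i, base in enumerate(bases, start=1):
        if base not in CANONICAL_BASES:
            raise SequenceError(f"non-AGCU base {base!r} at position {i} of {seq_id!r}")
    codes = list(bases)
    n = len(codes)
    for position, code in profile_rows:
        position = int(position)
        if not 1 <= position <= n:
            raise SequenceError(
                f"profile position {position} out of range 1..{n} for {seq_id!r}"
            )
        moddef = table[code]  # raises UnknownModificationError
        parent = bases[position - 1]
        if moddef.parents and parent not in moddef.parents:
            raise SequenceError(
                f"modification {code!r} at position {position} sits on base {parent!r}; "
                f"expected one of {tuple(moddef.parents)}"
            )
        codes[position - 1] = code
    return ModRNASeq(id=seq_id, codes=tuple(codes))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> SeqRecord:
    """First record of a FASTA file."""
    path = Path(path)
    try:
        return next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise SequenceError(f"no FASTA records in {path}") from None


def write_fasta(seq: ModRNASeq, path, bases: str | None = None) -> None:
    """Write the canonical-base FASTA underlying ``seq``.

    Modification codes are collapsed onto their (first) parent base; the
    profile TSV carries the modification layer.
    """
    table = default_table()
    if bases is None:
        bases = "".join(
            code if code in CANONICAL_BASES else table[code].parents[0]
            for code in seq.codes
        )
    record = SeqRecord(Seq(bases), id=seq.id, description="")
    SeqIO.write([record], str(path), "fasta")


def read_profile(path) -> list[tuple[int, str]]:
    """Modification profile TSV with header ``position<TAB>code``."""
    frame = pd.read_csv(path, sep="\t", dtype={"position": int, "code": str})
    missing = {"position", "code"} - set(frame.columns)
    if missing:
        raise SequenceError(f"profile {path} lacks columns: {sorted(missing)}")
    return list(frame[["position", "code"]].itertuples(index=False, name=None))


def write_profile(rows: Sequence[tuple[int, str]], path) -> None:
    pd.DataFrame(rows, columns=["position", "code"]).to_csv(path, sep="\t", index=False)


def profile_of(seq: ModRNASeq) -> list[tuple[int, str]]:
    """The (position, code) rows of all non-canonical residues."""
    return [
        (pos, code)
        for pos, code in zip(seq.positions(), seq.codes)
        if code not in CANONICAL_BASES
    ]
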