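"""Nucleoside-level inventory, dynamic-MRM transitions, and quantification.

Complete digestion (nuclease P1 + phosphodiesterase + phosphatase) turns a
tRNA into free nucleosides, measured by LC-MS/MS in multiple reaction
monitoring mode.  Precursors are protonated nucleosides; the default
product ion is the protonated base after neutral loss of the ribose
(−132.0423 Da), with per-modification overrides for species that deviate —
Ψ is a C-glycoside, so its glycosidic bond survives and water losses are
monitored instead.  ¹⁸O isotopologue (M+2) channels are generated for
deamination products (U/Ψ), whose extra base oxygen is retained in the
product ion, shifting precursor and product by the same +2.00425 Da.
Signals are normalized per sample against m⁵U, a stoichiometric one-per-
molecule modification unaffected by the editing reaction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .elements import MONOISOTOPIC, PROTON_MASS, Formula, mass_of
from .modifications import ModificationTable, default_table
from .sequence import ModRNASeq

CHANNEL_M = "M"
CHANNEL_M2 = "M+2"

#: Default product-ion rule: neutral loss of the ribose moiety (C5H8O4).
RIBOSE_LOSS = Formula.parse("C5H8O4")


class QuantError(ValueError):
    """Invalid transition request or quantification input."""


@dataclass(frozen=True)
class MRMTransition:
    code: str
    channel: str  # "M" | "M+2"
    precursor_mz: float
    product_mz: float
    rt_window: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.precursor_mz > self.product_mz > 0:
            raise QuantError(
                f"transition {self.code}/{self.channel}: need precursor > product > 0, "
                f"got {self.precursor_mz} -> {self.product_mz}"
            )


def nucleoside_inventory(seq: ModRNASeq) -> Counter:
    """Multiset of residue codes released by complete digestion."""
    return Counter(seq.codes)


def _product_loss(rule: str | None) -> Formula:
    if rule is None:
        return RIBOSE_LOSS
    if rule.startswith("loss:"):
        return Formula.parse(rule.removeprefix("loss:"))
    raise QuantError(f"unknown MRM product rule {rule!r}")


def mrm_transitions(
    codes: Iterable[str],
    channels: Sequence[str] = (CHANNEL_M, CHANNEL_M2),
    table: ModificationTable | None = None,
) -> list[MRMTransition]:
    """Transition list for the requested codes.

    The M channel is emitted for every code; the M+2 (¹⁸O) channel only
    for codes whose base oxygen can derive from water during deamination
    (U and Ψ), matching how the label is introduced.
    """
    table = table or default_table()
    bad = set(channels) - {CHANNEL_M, CHANNEL_M2}
    if bad:
        raise QuantError(f"unknown channels {sorted(bad)}; expected M / M+2")
    transitions = []
    for code in codes:
        moddef = table[code]
        nucleoside = moddef.nucleoside_formula
        loss = _product_loss(moddef.mrm_product_rule)
        for channel in channels:
            if channel == CHANNEL_M2 and not moddef.o18_eligible:
                continue
            formula = (
                nucleoside.substitute("O", "O[18]")
                if channel == CHANNEL_M2
                else nucleoside
            )
            precursor = mass_of(formula, MONOISOTOPIC) + PROTON_MASS
            # label sits on the base, so the ribose/water loss is unlabeled
            product = mass_of(formula - loss, MONOISOTOPIC) + PROTON_MASS
            transitions.append(MRMTransition(code, channel, precursor, product))
    return transitions


def transitions_table(transitions: Iterable[MRMTransition]) -> pd.DataFrame:
    """Dynamic-MRM method export (TSV-ready)."""
    rows = [
        {
            "code": t.code,
            "channel": t.channel,
            "precursor_mz": t.precursor_mz,
            "product_mz": t.product_mz,
            "rt_start": t.rt_window[0] if t.rt_window else "",
            "rt_end": t.rt_window[1] if t.rt_window else "",
        }
        for t in transitions
    ]
    return pd.DataFrame(rows)


def read_signal_table(path) -> pd.DataFrame:
    """Signal table TSV with columns sample, code, channel, intensity."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"sample", "code", "channel", "intensity"} - set(frame.columns)
    if missing:
        raise QuantError(f"signal table {path} lacks columns: {sorted(missing)}")
    return frame


def quantify(
    signals: pd.DataFrame,
    normalizer: str = "m5U",
    normalizer_channel: str = CHANNEL_M,
) -> pd.DataFrame:
    """Normalize each channel's intensity against the normalizer, per sample.

    Adds a ``normalized`` column; the normalizer's own normalized value is
    1 by construction, and the result is invariant to a common intensity
    scale factor within a sample.
    """
    missing = {"sample", "code", "channel", "intensity"} - set(signals.columns)
    if missing:
        raise QuantError(f"signal table lacks columns: {sorted(missing)}")
    if (signals["intensity"] < 0).any():
        raise QuantError("intensities must be non-negative")
    out = []
    for sample, group in signals.groupby("sample", sort=False):
        ref = group[
            (group["code"] == normalizer) & (group["channel"] == normalizer_channel)
        ]["intensity"]
        if ref.empty:
            raise QuantError(
                f"sample {sample!r} lacks normalizer {normalizer}/{normalizer_channel}"
            )
        ref_value = float(ref.sum())
        if ref_value <= 0:
            raise QuantError(f"sample {sample!r} has zero normalizer intensity")
        g = group.copy()
        g["normalized"] = g["intensity"] / ref_value
        out.append(g)
    return pd.concat(out, ignore_index=True)
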