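"""Non-MS quantitative readouts: Sanger trace ratios and the Rt/Rs statistic.

Sanger sequencing reads both U and Ψ as T, so the edited fraction at the
target position is simply T/(T+C) of the trace peak heights — invariant to
any common height scaling.

The dual-luciferase decoding statistic compares firefly/renilla (F/R)
ratios between an in-frame (frame 0) reporter and a +1-frameshift
reporter carrying the test codon: Rt is the mean F/R of frame-0
replicates, Rs the mean F/R of frame-+1 replicates, and the reported
score is (Rt/Rs) normalized to the wild-type strain's value for the same
codon, making the WT score 1 by construction.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

TRACE_BASES = ("A", "C", "G", "T")


class ReporterError(ValueError):
    """Invalid trace heights or reporter measurements."""


def editing_fraction_from_trace(heights: Mapping[str, float] | pd.Series) -> float:
    """Edited fraction T/(T+C) from per-base peak heights at one position."""
    t = float(heights.get("T", 0.0))
    c = float(heights.get("C", 0.0))
    if t < 0 or c < 0:
        raise ReporterError("trace peak heights must be non-negative")
    if t + c == 0:
        raise ReporterError("C and T heights are both zero; fraction undefined")
    return t / (t + c)


def trace_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-position edited fractions from a trace peak-height table.

    Expects columns ``position`` plus per-base heights A, C, G, T.
    """
    missing = {"position", *TRACE_BASES} - set(table.columns)
    if missing:
        raise ReporterError(f"trace table lacks columns: {sorted(missing)}")
    rows = [
        {
            "position": int(row["position"]),
            "edited_fraction": editing_fraction_from_trace(row),
        }
        for _, row in table.iterrows()
    ]
    return pd.DataFrame(rows)


def _normalize_frame(value) -> str:
    text = str(value).strip()
    if text in ("0", "0.0"):
        return "0"
    if text in ("+1", "1", "1.0"):
        return "+1"
    raise ReporterError(f"unknown reporter frame {value!r}; expected 0 or +1")


def rt_rs(
    measurements: pd.DataFrame,
    wt_strain: str = "WT",
) -> pd.DataFrame:
    """Relative decoding scores per strain and codon.

    ``measurements`` columns: strain, codon, frame (0 or +1), firefly,
    renilla.  Returns one row per (strain, codon) with Rt, Rs, their
    ratio, and the ratio normalized to the WT strain of the same codon.
    """
    required = {"strain", "codon", "frame", "firefly", "renilla"}
    missing = required - set(measurements.columns)
    if missing:
        raise ReporterError(f"reporter table lacks columns: {sorted(missing)}")
    frame = measurements.copy()
    if (frame["renilla"] <= 0).any():
        raise ReporterError("renilla signals must be positive")
    frame["frame"] = frame["frame"].map(_normalize_frame)
    frame["f_over_r"] = frame["firefly"] / frame["renilla"]

    rows = []
    for (strain, codon), group in frame.groupby(["strain", "codon"], sort=False):
        by_frame = group.groupby("frame")["f_over_r"]
        means = by_frame.mean()
        counts = by_frame.size()
        if "0" not in means.index or "+1" not in means.index:
            raise ReporterError(
                f"strain {strain!r} codon {codon!r}: both frame 0 and +1 "
                "measurements are required"
            )
        rt, rs = float(means["0"]), float(means["+1"])
        if rs == 0:
            raise ReporterError(f"strain {strain!r} codon {codon!r}: Rs is zero")
        rows.append(
            {
                "strain": strain,
                "codon": codon,
                "n_frame0": int(counts["0"]),
                "n_frame1": int(counts["+1"]),
                "Rt": rt,
                "Rs": rs,
                "rt_rs": rt / rs,
            }
        )
    scores = pd.DataFrame(rows)
    out = []
    for codon, group in scores.groupby("codon", sort=False):
        wt = group[group["strain"] == wt_strain]
        if wt.empty:
            raise ReporterError(
                f"codon {codon!r}: reference strain {wt_strain!r} missing"
            )
        g = group.copy()
        g["relative_rt_rs"] = g["rt_rs"] / float(wt["rt_rs"].iloc[0])
        out.append(g)
    return pd.concat(out, ignore_index=True)


def per_replicate_scores(
    measurements: pd.DataFrame,
    wt_strain: str = "WT",
) -> pd.DataFrame:
    """Per-replicate relative scores for downstream group comparisons.

    Each frame-0 replicate's F/R is divided by its strain/codon Rs and by
    the WT Rt/Rs, so per-strain means equal the summary relative score and
    the WT mean is 1 by construction.  No inference is performed here.
    """
    summary = rt_rs(measurements, wt_strain=wt_strain).set_index(["strain", "codon"])
    frame = measurements.copy()
    frame["frame"] = frame["frame"].map(_normalize_frame)
    frame = frame[frame["frame"] == "0"].copy()
    frame["f_over_r"] = frame["firefly"] / frame["renilla"]
    rows = []
    for (strain, codon), group in frame.groupby(["strain", "codon"], sort=False):
        info = summary.loc[(strain, codon)]
        wt_ratio = float(info["rt_rs"] / info["relative_rt_rs"])
        for _, row in group.iterrows():
            rows.append(
                {
                    "strain": strain,
                    "codon": codon,
                    "relative_score": row["f_over_r"] / float(info["Rs"]) / wt_ratio,
                }
            )
    return pd.DataFrame(rows)
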