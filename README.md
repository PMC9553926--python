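# pseudomap

Mass-spectrometry readout chain for detecting and quantifying **C-to-Ψ
tRNA editing** — the two-step conversion of cytidine to pseudouridine
(deamination C→U, then isomerization U→Ψ) found at position 32 of the
*Vibrio cholerae* tRNA-Tyr anticodon loop.

Ψ is an isobaric isomer of U, so neither Sanger sequencing (both read as
T) nor plain mass measurement can distinguish them. The workflow this
package implements resolves the three states chemically:

1. **Oligo protection** trims the tRNA to a window (positions 10–46)
   around the edit site.
2. **Cyanoethylation** (acrylonitrile) attaches a cyanoethyl group
   (C₃H₃N, +53.0266 Da) specifically to Ψ.
3. **RNase A digestion** releases short 5′-OH/3′-phosphate fragments,
   including the diagnostic tetramer A-G-A-C ending at the edit site.
4. **MALDI-TOF** of the digest distinguishes the species by mass:
   C (m/z 1325.2), U (+0.984), Ψ+CE (+0.984+53.027).
5. **¹⁸O tracing**: deamination draws its new base oxygen from water, so
   reactions run in H₂¹⁸O tag the edited base with a +2.00425 Da label,
   trackable both in fragments and in nucleoside-level MRM (U+2/Ψ+2
   channels, normalized against the stoichiometric m⁵U signal).

The package provides every computational stage as a tested library —
modified-RNA mass bookkeeping, in-silico digestion, species-ensemble
chemistry, greedy peak assignment with editing-state inference, MRM
transition generation and normalization, plus the Sanger-trace T/(T+C)
ratio and the dual-luciferase Rt/Rs decoding statistic — together with
seeded synthetic-data generators that emulate the tRNA-Tyr-like substrate
(D16, C32, Q34, ms²io⁶A37, m⁵U54) for closed-loop validation.

## Worked example

Simulate a partially edited substrate (true edited fraction 0.6, 50%
¹⁸O water, 0.1 Da mass error, 5% intensity noise), then analyze the
simulated peak list:

```bash
$ pseudomap simulate --seed 7 --out demo --edit-fraction 0.6
wrote simulated inputs to demo
$ pseudomap maldi --seq demo/seq.fasta --mods demo/mods.tsv \
      --peaks demo/peaks.tsv --position 32 --out demo/report
position 32: state Ψ, edited fraction 0.605
```

The call means: the cyanoethyl-shifted species was observed, so the site
is pseudouridylated, and the relative intensities of the diagnostic
species (C at m/z 1325.2, Ψ+CE at 1379.2, Ψ+CE+¹⁸O at 1381.2) put the
edited fraction at 0.605 — recovering the simulated truth of 0.6.
`demo/report/assignments.tsv` lists every matched peak, e.g.

```
peak_mz    intensity  fragment  start  end  species  theoretical_mz  error_da
1325.373   38.937     A-G-A-C   29     32   C        1325.197         0.176
1344.063   99.426     G-A-G-D   13     16            1344.192        -0.128
```

and `call.json` records the machine-readable call. The same library is
importable directly:

```python
from pseudomap import SimConfig, mz
from pseudomap.pipeline import call_from_simulation

call = call_from_simulation(SimConfig(seed=7, edit_fraction=0.6))
print(call.state, round(call.edited_fraction, 3))   # Y 0.605
```

## Layout

| module | role |
|---|---|
| `pseudomap.elements` | formulas, element/isotope masses, chemistry deltas |
| `pseudomap.modifications` | residue vocabulary + shipped modification table |
| `pseudomap.sequence` | modified-RNA sequences, FASTA/profile I/O |
| `pseudomap.digestion` | protection window, RNase A/T1 digestion, fragment masses |
| `pseudomap.chemistry` | editing states, cyanoethylation, ¹⁸O, species ensembles |
| `pseudomap.maldi` | m/z, peak matching, state inference, fraction estimation |
| `pseudomap.mrm` | nucleoside inventory, MRM transitions, m⁵U normalization |
| `pseudomap.reporter` | Sanger trace ratio, dual-luciferase Rt/Rs statistic |
| `pseudomap.simulate` | seeded generators for every pipeline input |
| `pseudomap.pipeline` / `pseudomap.cli` | orchestration, reports, `pseudomap` CLI |

See `docs/methods.md` for the underlying model, parameter choices, and
limitations.
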