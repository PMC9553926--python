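# Methods

## The measurement model

The package models the readout chain for distinguishing C, U, and Ψ at a
single tRNA position. Its chemistry rests on three exact mass facts:

* deamination (C→U) changes a residue by −NH+O = **+0.98402 Da**;
* isomerization (U→Ψ) is mass-silent — Ψ and U share the formula
  C₉H₁₁N₂O₈P as chain residues — so Ψ is only visible after
  acrylonitrile adds a cyanoethyl group (C₃H₃N, **+53.0266 Da**) to it;
* deamination draws the new base oxygen from water, so heavy water
  labels the edited base with ¹⁸O (**+2.00425 Da**), retained through
  both fragment-level and nucleoside-level measurement.

All masses are computed from elemental compositions. ¹⁸O is a distinct
element symbol (`O[18]`) in formulas rather than a numeric offset, so
labeled and unlabeled species coexist and compose correctly with every
other operation. Atomic masses come from the NIST table shipped with
pyteomics.

Positions are 1-based, inclusive, linear coordinates throughout;
sub-sequences keep their parent's position labels, so "position 32"
survives windowing. Cloverleaf-style structural numbering is not
implemented — every positional statement the pipeline needs is linear.

## Digestion

RNase A cleaves 3′ of pyrimidine-derived residues (C, U, Ψ, D, m⁵U),
RNase T1 3′ of guanosine-derived residues (G, I; queuosine is treated as
resistant by default but is configurable). 2′-O-methylated residues
block cleavage. Products carry 5′-OH and, by default, a **linear
3′-phosphate**: that choice makes an n-mer product carry exactly n
phosphates, and it is the convention under which the diagnostic tetramer
masses match their reported values; the 2′,3′-cyclic form (−18.011 Da)
is available as an option. Digestion is modeled as complete — a limit
digest — with partiality expressed only through missed-cleavage
variants, which only ever add fragments. The last fragment keeps the
parent's native 3′ end.

The digest engine is checked against an independently written
brute-force cleavage-site scan on 1,000 random modified sequences
(length ≤ 60) plus a tiling invariant (zero-missed-cleavage fragments
partition the input exactly, in order).

## MALDI assignment and state inference

Fragment ions are singly deprotonated, monoisotopic ([M−H]⁻, −1.00728),
the only convention consistent with the reported tetramer values;
positive mode is a flag. Matching is greedy nearest-mass within a
tolerance (default **0.3 Da**, a MALDI-TOF linear-mode figure; observed
errors in practice sit around 0.1–0.2 Da): candidate (peak, species)
pairs are taken smallest |error| first, ties broken by higher peak
intensity, each peak and each species used at most once.

State logic at the target position, after CE treatment:

* CE-shifted species observed → **Ψ**;
* +0.984 species without a CE shift → **U** (the
  pseudouridylase-dead outcome);
* only the unedited species → **C**.

The edited fraction is Σ intensity(edited species) / Σ intensity(all
diagnostic species). This assumes equal desorption/ionization
efficiency across the diagnostic species — they are four isomer-grade
variants of the same tetramer, which makes the assumption reasonable,
but it is an assumption, stated here rather than hidden. The estimator
is invariant to a common intensity scale.

## Nucleoside MRM

Complete digestion (P1 nuclease + phosphodiesterase + phosphatase)
releases free nucleosides; precursors are [M+H]⁺ of the nucleoside and
the default product ion is the protonated base after neutral loss of
the ribose (−132.0423 Da). Per-modification overrides live in the
modification table because some species deviate: Ψ is a C-glycoside
whose glycosidic bond survives fragmentation, so its rule monitors the
double-water loss (245.08 → 209.06) instead; 2′-O-methyl species lose
the methylated ribose (−146.0579). These defaults are first-principles
transition rules, not transcriptions of any instrument method file.
M+2 (¹⁸O) channels are generated only for deamination products (U, Ψ),
and because the label sits on the base, precursor and product shift by
the same +2.00425 Da — an invariant the tests assert.

Quantification divides every channel by the m⁵U signal of the same
sample. m⁵U is stoichiometric (one per tRNA) and untouched by the
editing reaction, which makes it the natural internal normalizer; the
normalized m⁵U value is 1 by construction and all normalized values are
invariant to per-sample scale.

## Trace and reporter statistics

Sanger sequencing reads U and Ψ as T, so the edited fraction from a
trace is T/(T+C) of the peak heights at the site — scale-invariant,
undefined when both heights are zero. Raw chromatogram (AB1) parsing is
out of scope; input is a pre-extracted height table.

The decoding statistic compares dual-luciferase reporters: Rt is the
mean firefly/renilla ratio of in-frame (frame 0) replicates, Rs the
mean of +1-frameshift replicates, and the score is (Rt/Rs) normalized
to the wild-type strain's value for the same codon — so the WT score is
1 by construction. The frame-0/frame-+1 assignment of Rt and Rs is
implemented literally as the assay defines it. Since frame-0 and
frame-+1 measurements come from different cultures, per-replicate
scores are derived by dividing each frame-0 replicate's F/R by the
group Rs; their per-strain mean equals the summary score. Group
inference (ANOVA and post-hoc corrections) is deliberately not
reimplemented — the module emits per-replicate scores for any external
test.

## The synthetic-data generator

The generator emulates an 85-nt tRNA-Tyr-like substrate — the actual
primary sequence is not public, so the substrate is designed, not
transcribed. It fixes what the analysis depends on: D16, the editable
C32, Q34, ms²io⁶A37, m⁵U54, and a protected-window layout in which
RNase A releases G-A-G-D from 13–16 and A-G-A-C from 29–32 (the
tetramer ending at the edit site). The window layout is additionally
chosen so that no other digest product is near-isobaric with the
diagnostic species (other products are 1–3-mers, a heavy
ms²io⁶A-containing tetramer ~60 Da away, and a 6-mer), so closed-loop
estimator tests measure estimator behavior, not accidental mass
collisions. Only the acceptor stem and the 3′ half outside the window
vary with the seed; a single root seed fans out to named per-generator
streams, so adding a generator never perturbs existing outputs.

Default conditions mirror the emulated experiments: CE efficiency 1.0
(the labeling reaction is specific and, in practice, essentially
complete), ¹⁸O water fraction 0.5, MALDI mass error sd 0.1 Da,
intensity CV 5%, decoy-peak rate 0 (raisable for robustness tests).
The MALDI forward model emits one peak per species — theoretical m/z
plus Gaussian mass error, intensity proportional to ensemble weight
with multiplicative noise floored at zero. The MRM forward model is
stoichiometric: channel intensity ∝ per-molecule count, with the edited
site contributing f·(1−w) to the light and f·w to the heavy channel of
the edited code. Noiseless settings reproduce theoretical values
exactly, which the tests use as oracles.

What the generator does **not** emulate: isotopic envelopes beyond the
explicit ¹⁸O channel, adducts, matrix effects, detector saturation,
chromatographic behavior, ionization bias between species, or ¹⁸O
back-exchange. Passing closed-loop tests therefore demonstrates the
correctness of the computational chain under the stated noise model,
not robustness to every artifact of real spectra.

## Problem sizes and numerical choices

* Digestion oracle: 1,000 random sequences up to length 60, both
  enzymes, plus property tests (~150 cases) under hypothesis with
  derandomized seeds.
* Estimator recovery: edited fractions 0.1–0.9 in steps of 0.1, 200
  simulated spectra each at the default noise model; mean absolute
  error of the recovered fraction is required to stay below 0.05.
* Matching tolerance 0.3 Da; species within ~1 Da (C vs U, ±0.984) are
  resolved by nearest-mass assignment, which at 0.1 Da mass error
  misassigns with negligible probability (≈5σ separation).
* Ensemble weights must sum to 1 within 1e-9; zero-weight branches are
  pruned so boundary conditions (f, c, w ∈ {0,1}) collapse exactly.
* Ties in matching are broken deterministically (smaller |error|, then
  higher intensity, then input order), making reports byte-stable
  across reruns of the same config and seed.

## Known limitations

* Linear coordinates only; no structural (Sprinzl-style) numbering or
  secondary-structure modeling.
* The protection step is pure windowing — no hybridization
  thermodynamics for the protecting oligos.
* Peak lists are taken as given: no centroiding, baseline handling, or
  deconvolution.
* Equal-ionization assumption in the fraction estimator (above).
* MRM transition defaults are computed, not instrument-validated;
  retention-time windows are passthrough fields.
* The reporter module computes scores only; experimental designs where
  frame-0 and frame-+1 replicates are paired would support stronger
  per-replicate statistics than the unpaired construction used here.
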