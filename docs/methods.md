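# Methods

## Problem and model

`surfann` annotates cyclic lipopeptides of the surfactin type from
centroided LC-ESI-MS/MS peak lists. A surfactin is a heptapeptide
(Glu¹-Leu/Ile²-Leu³-Val⁴-Asp⁵-Leu⁶-Leu/Ile⁷) closed into a lactone with a
β-hydroxy fatty acid of variable carbon count *n*; homologs differ by CH₂
units (14.01565 Da) in the acyl chain. The observable structure the package
exploits:

* **MS1**: protonated molecular ions [M+H]⁺ spaced by CH₂ (a homolog
  series), sodiated partners [M+Na]⁺ offset by Na−H = 21.98194 Da, and
  dehydration ions [M−H₂O]⁺ (−18.01056 Da).
* **MS2 (CID)**: a b-type prefix ladder whose lowest rung carries the acyl
  moiety, a y-type suffix ladder, and the ring-closing terminal residue read
  as precursor − (top b rung).

The total mass model is

    [M+H]⁺ = proton + L(n) + Σᵢ residue(i),    L(n) = 14.01565·n + 29.97418

where `L(n)` treats the acyl moiety as CₙH₂ₙ₋₂O₂ — the β-hydroxy fatty acid
as it exists inside the closed ring, both condensations having spent their
water. The acyl moiety's elemental composition is not directly observable
in unit-resolution data; this calibration is a reconstruction, chosen
because it reproduces the four observed precursors (994/1008/1022/1036 for
n = 12…15) within 0.7 Da. Residue masses are monoisotopic (19 distinct
values; Leu = Ile = 113.08406 reported as the merged label "Leu/Ile";
Gln/Lys, 0.036 Da apart, are always co-reported when either matches).

Absolute y-type values in the targeted data behave as **plain suffix
residue sums**, not proton/water-bearing fragments: the observed y rungs
sit within 0.7 Da of suffix sums but ~1 Da from the proton+water
convention, and b + y then reconstructs the precursor (the observed
complement reads 994 − 553.99 = 440.01 vs the direct b rung 441.05, a
1.04 Da closure error). This is the only absolute model consistent with
the unit-resolution arithmetic the package targets; assignments therefore
rest primarily on consecutive differences, with absolute models used only
for anchoring under wide tolerances.

## Annotation algorithm

1. **Spectrum graph.** Peaks are nodes; a directed edge u→v exists when
   v − u matches a residue mass within the step tolerance. Peaks within
   2.0 Da of the precursor or of precursor − H₂O are excluded (molecular
   and dehydration ions are not sequence rungs; the C13 worked example's
   molecular-ion reading sits exactly one Leu/Ile above the top b rung and
   would otherwise extend every ladder).
2. **Candidate b ladders.** All maximal paths and their suffixes (leading
   rungs may belong to the y series). For each candidate and each complete
   family template: the terminal residue is precursor − top rung; the
   *lipid anchor* is first rung − proton − Σ(assumed template prefix),
   matched to `L(n)`; an anchor whose *n* falls outside the template's acyl
   range counts as no anchor (y-rung suffix sums are themselves near the
   CH₂-quantized lipid grid, so out-of-range pseudo-anchors are common).
3. **Joint scoring.** Each interpretation scores

       score = coverage_b − w·Σ|errors_b|  +  y-bonus

   where coverage counts positions read off the spectrum (ladder steps plus
   a matched terminal; template-assumed prefix positions earn nothing) and
   errors are the best-candidate step errors, the terminal error and
   |anchor error| in Da, with weight w = 1.5. The y-bonus applies the same
   coverage-minus-error form to the ladder extracted from the unconsumed
   peaks, but only when that chain's absolute rungs track the template's
   suffix-sum sequence within the anchor tolerance — the structural
   asymmetry that distinguishes the true b reading (which leaves a clean
   complementary y ladder) from longer chains drifting through y peaks.
   The weight 1.5 makes one extra claimed position (+1) unable to pay for
   a near-tolerance (~1 Da) supporting error; for surfactin the spurious
   readings carry a characteristic ≈1.03 Da anchor misfit
   (L(13)+Glu+proton vs the Asp-Leu-Leu suffix sum), so genuine and
   spurious anchors separate cleanly at this weight. Interpretations with
   a valid anchor always outrank anchorless ones; remaining ties resolve
   toward more rungs, greater total intensity, lower starting m/z, then
   lexicographically — fully deterministic.
4. **Reporting.** Complement pairs (|b + y − precursor| ≤ 1.2 Da) are a
   confidence feature and never veto. Water-loss searches run against both
   the precursor and the top b rung (the worked examples show both kinds).
   Classification tests every constrained template position against the
   candidate sets (membership, with ambiguity flagged) plus the acyl range;
   among matching templates the most exact-best matches win; otherwise
   "unassigned", with the failing constraint reported.

`extract_ladder` itself is the pure deterministic longest-path operation
(checked against exhaustive path enumeration); the joint selection above
lives in `annotate_spectrum`.

## Tolerances (Da), defaults and rationale

| knob | default | nominal mode | why |
|---|---|---|---|
| MS1 spacing tol | 0.1 | 0.6 | high-precision vs integer-printed precursors |
| residue step tol | 0.8 | 1.6 | unit-resolution fragment scatter; printed step deltas deviate up to ~1.5 Da from monoisotopic theory in the worked examples |
| lipid anchor tol | 1.2 | 1.2 | worst observed anchor arithmetic ≈1.2 Da; half the CH₂ spacing (7.0) bounds it safely |
| complement tol | 1.2 | 1.2 | worst observed closure error 1.04 Da |
| water-loss tol | 0.75 | 0.75 | observed dehydration deviations ≤0.55 Da |
| adduct tol | 0.5 | 0.5 | Na−H pairing on centroided MS1 |
| precursor window | 2.0 | 2.0 | excludes molecular/dehydration ions from the graph |
| score weight w | 1.5 | 1.5 | see above |

"Nominal mode" (`PipelineConfig.nominal()`, CLI `--nominal`) is for peak
lists printed as rounded/unit-resolution values. Everything is overridable
per config file or flags; mass tables and templates ship as plain-text
files (`surfann/data/*.tsv`, `*.yaml`) users can replace. Acyl carbon
range defaults to 8–20; the surfactin template constrains 10–17.

Numbering follows the lipopeptide convention: the acyl chain is the ring's
"position 1", residues are reported 1…7, and the ring-closing residue 7
corresponds to b₈ in conventional proteomics numbering (bₖ here spans the
acyl plus the first k residues; y-type values are bare suffix sums, see
above).

## Synthetic data

The generator emits what the pipeline assumes and nothing more: noiseless
rungs from the mass model (b for prefix lengths 2–6, y for suffix lengths
3–5, water loss, molecular ion), Gaussian m/z jitter (default sd 0.2 Da for
fragments — about the scatter seen in unit-resolution readings — and
0.02 Da for MS1 centroids, which average over the chromatographic peak),
log-normal intensities, and uniform decoys rejection-sampled to stay
2.0 Da away from every peak, every peak ± a residue mass, and water
offsets, so decoys cannot enter the spectrum graph (an adversarial switch
instead plants decoys exactly one residue mass from true rungs). Retention
times increase linearly with *n* anchored at 6.5 min for C12. Defaults:
chain lengths {12,13,14,15}, Na adducts and water loss on, 20 decoys.

Not emulated: intensity physics, isotope envelopes, charge states > 1,
chromatographic peak shapes, correlated mass errors. Recovery results on
synthetic data therefore demonstrate the combinatorial correctness of
ladder reconstruction under peak-position noise, not robustness to real
instrument artefacts.

The bioassay generator draws inhibition-zone diameters
`DAC = dac_control·rate(cond,t)/100 + N(0, σ)` truncated at 0, default
control 30 mm, σ = 0.5 mm, 3 replicates; the default true curve keeps
40–70 °C at ≥90 % residual rate over 10 days with 80 °C decaying to 85 %.

## Bioassay statistics

* Residual rate (%) = 100 · DAC(treated) / DAC(time-matched control mean);
  may exceed 100. Stability summaries are tidy (condition, time, mean, sd,
  n) with replicate sd (0 for a single replicate); missing time-matched
  controls are an alignment error listing the orphan rows.
* MIC = the lowest concentration at or above which every well of the
  two-fold dilution series shows no growth; "not reached" when the highest
  concentration grows. A growth reading below a no-growth reading (skipped
  well) does not change the call but sets a non-monotonicity flag. The
  positive control must grow and the negative must not, else the failed
  control is named in a quality error.
* Inhibition-zone grades −/+/++/+++ use left-closed bins at 10/20/30 mm by
  default (configurable); the top bin is anchored to the "more than 3 cm"
  reading of a strongly inhibited plate.

## Degenerate inputs and numerical choices

Empty spectra, edgeless graphs and all-decoy spectra yield valid
"unassigned" annotations, never errors. Duplicate m/z values are merged
(intensity-summed) at construction so the graph ordering is strict. An
empty residue-match set and a lipid no-match are valid results; a negative
anchor residual (prefix hypothesis heavier than the rung) is an
inconsistency error. All randomness flows from a single integer seed via
`numpy.random.default_rng`; equal seeds give byte-identical outputs. Ties
everywhere resolve by documented deterministic keys.

## Problem sizes used in the shipped checks

Desk-scale checks run on the worked-example peak lists (8–10 true peaks,
plus 20 seeded decoys where stated). Property suites use ≥100 random
instances (≤50 peaks for series detection, ≤12 for ladder extraction
against exhaustive enumeration), 100 seeded jittered replicates for the
recovery rate, and 200–300 random dilution series for the MIC oracle.

## Known limitations

* Only the surfactin template ships complete; iturin/fengycin entries are
  stubs users can fill in (the classifier skips incomplete templates).
* Leu/Ile (and effectively Gln/Lys) cannot be distinguished; positions are
  reported with candidate sets, not forced calls.
* Single-charge, monoisotopic reading only; no deisotoping, no average-mass
  mode, no mzML ingestion (convert to MGF or tables externally).
* The acyl mass law is a calibration (see above); chain lengths are
  reported relative to it.
* The b/y identity resolution depends on the template registry; a spectrum
  from an unknown family with surfactin-like suffix sums could be
  mis-anchored.
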