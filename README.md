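# bundlequant

Quantitative analysis of sensory hair-cell imaging and physiology, built
around the question of how membrane cholesterol is distributed in hair
cells: confocal z-stack segmentation and fluorescence quantification,
enlarged-lysosome detection, hair-bundle morphometry, auditory
evoked-potential (AEP) threshold estimation, and physicochemical-alphabet
sequence-pattern / CRAC–CARC cholesterol-recognition motif scanning.
Every stage ships with a synthetic-data generator producing stacks,
recordings and alignments with known ground truth, so the whole pipeline
is testable without any microscope or amplifier.

It is intended for hearing-research and cell-biology groups who quantify
probe distributions (e.g. a cholesterol biosensor such as the
perfringolysin-O D4H domain against a uniform plasma-membrane marker) in
zebrafish or mouse hair cells, and for anyone who needs a reproducible,
scriptable replacement for ad-hoc quantification macros.

## The quantities at the core

**Compartment enrichment (ratio of ratios).** For each channel *c*, with
stereocilium mask *S* and basolateral mask *B*,

&nbsp;&nbsp;&nbsp;&nbsp;r_c = 100% · mean_S(I_c) / mean_B(I_c)

and the fold enrichment of a probe over the membrane reference is
F = r_probe / r_ref. Because both channels are measured over the same
voxels, F cancels geometry and segmentation bias: a probe that merely
follows the (folded, denser) stereocilium membrane has F ≈ 1, while a
probe enriched on stereocilium membrane has F ≈ its true enrichment.
With the published compartment means r_probe = 567.7% and
r_ref = 73.7%, F = 7.7.

**Enlarged-lysosome rule.** Connected components of a lysosome-marker
mask (6-connected, 3-D) are vesicle calls; the equivalent diameter is
that of the equal-volume sphere, d = (6V/π)^(1/3), and a call is
*enlarged* iff d > 2 µm (strict). Cells are flagged by centroid
containment of an enlarged call, and group-wise flag counts form a 2×2
table tested with a two-sided Fisher exact test computed from exact
integer hypergeometric weights.

**AEP threshold.** Blackman-windowed tone pips are presented in
descending level; epochs are averaged per (frequency, level), a response
is detected when the averaged peak-to-peak reaches k× the single-sweep
baseline RMS (default k = 2), and the threshold is the lowest level
detected contiguously from the top. Undetected top level ⇒ "not
reached".

**Degenerate patterns and CRAC/CARC.** Conserved patterns are derived
column-wise from alignments over normalized physicochemical symbols
(Ω aromatic, Ψ aliphatic, π small, ζ hydrophilic, Φ hydrophobic, +, −),
e.g. `[pi]-[ST]-[Omega]-[ST]-[Psi]-[zeta]-[zeta]-[Omega]`, and scanned
with exhaustive overlap-reporting semantics. The cholesterol-recognition
consensus CRAC = (L/V)-x(1,5)-Y-x(1,5)-(K/R) and its mirrored analogue
CARC = (K/R)-x(1,5)-(Y/F/W)-x(1,5)-(L/V) are built-in special cases.

## Worked example

```python
import bundlequant as bq

# a two-cell synthetic stack: PM reference plus an 8x-enriched D4H probe,
# rendered with PSF blur, shot noise and read noise
spec = bq.PhantomSpec(n_cells=2, seed=1)
stack, truth = bq.simulate_stack(spec)

# segment the reference channel adaptively, split at the apex plane,
# and measure the cross-channel fold enrichment
apex_z = spec.margin_um + spec.stereocilium_length_um
result = bq.estimate_fold_enrichment(stack, apex_z, probe="D4H", reference="PM")
print(f"PM   stereocilium/basolateral ratio: {result.ratio_pct['PM']:.1f}%")
print(f"D4H  stereocilium/basolateral ratio: {result.ratio_pct['D4H']:.1f}%")
print(f"fold enrichment (D4H over PM): {result.ratio_of_ratios:.1f}")

test = bq.fisher_exact_2x2([[39, 145], [134, 102]])
print(f"Fisher exact two-sided p = {test.p_value:.2e}")

rec, truth_db = bq.simulate_aep(bq.AepSimSpec(seed=1))
est = bq.AepThresholdEstimator().fit(rec)
print(f"AEP threshold at 200 Hz: {est.thresholds_[200.0]:.0f} dB (true {truth_db[200.0]:.0f} dB)")

matches = bq.scan_crac_carc("VAAAYAAAK")
print(f"CRAC motifs in VAAAYAAAK: {[(m.kind, m.start, m.end) for m in matches]}")
```

prints

```
PM   stereocilium/basolateral ratio: 37.0%
D4H  stereocilium/basolateral ratio: 263.2%
fold enrichment (D4H over PM): 7.1
Fisher exact two-sided p = 8.84e-14
AEP threshold at 200 Hz: 140 dB (true 140 dB)
CRAC motifs in VAAAYAAAK: [('CRAC', 1, 9)]
```

Note what the numbers mean: under blur and noise the *within*-channel
ratios are strongly distorted (the thin stereocilia lose intensity to
their surroundings, so even the uniform PM probe reads 37%, not 100%),
but the *ratio of ratios* still recovers the generative 8× enrichment to
within ~11% — the same reason the measure is robust on real stacks. The
Fisher test reproduces the expected extreme significance of 39/184
versus 134/236 flagged cells, and the threshold estimator lands on the
true simulated 140 dB.

The transform/fit-shaped steps are scikit-learn estimators
(`AdaptiveSegmenter`, `VesicleDetector`, `AepThresholdEstimator`,
`ConservedPatternMiner`, `PatternScanner`, `CracCarcScanner`) with
`get_params`/`set_params` and fitted `*_` attributes, so they compose
with sklearn tooling; the module-level functions are thin wrappers.

A `bundlequant` console script exposes the same operations
(`simulate-phantom`, `quantify`, `enrich`, `vesicles`, `bundles`,
`count`, `aep`, `motif derive|scan|crac`, `run --config cfg.yaml`).

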