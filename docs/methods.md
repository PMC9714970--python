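# Methods

This note records the models, conventions and numerical choices behind
bundlequant, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic validations do
and do not demonstrate.

## Imaging phantom

The generator renders an idealised hair-cell scene on the voxel grid by
centre-of-voxel inclusion (a voxel belongs to a shape iff its centre
lies inside). Each cell is an ellipsoidal body (default semi-axes
4.0 × 2.5 × 2.5 µm in z, y, x) carrying a membrane shell (0.4 µm thick,
the "basolateral" compartment — the whole body shell is treated as
basolateral in the two-compartment scheme), a grid of apical
stereocilium cylinders (default 9 cylinders, radius 0.25 µm, length
3 µm, with per-cell jitter), an optional longer kinocilium, and
intracellular lysosome spheres (default 3 per cell, diameters
N(0.8, 0.15²) µm clipped to [0.2, 1.9]) placed inside the body with an
80% apical bias. A configurable fraction of cells additionally receives
one 2.5 µm vesicle, which drives the enlarged-lysosome statistics.

Fluorescence: each probe (channel) assigns emission densities —
basolateral membrane 1.0, stereocilium membrane 1.0 × E where E is the
probe's stereocilia enrichment factor, cytoplasm 0.05, lysosome voxels
an optional extra density for a lysosome marker. Stereocilia are thin
enough that the whole cylinder is treated as membrane. Optics and
detection: Gaussian PSF blur (σ = 0.15 µm, converted per axis for
anisotropic voxels, applied to the density field *before* noise, since
optics precede detection), then Poisson shot noise at a photon gain of
100 counts per density unit, then additive Gaussian read noise
(σ = 2 counts), clipped at zero. Default voxels are 0.3 × 0.15 × 0.15 µm.

All geometry and noise parameters are artifact choices for validation:
they are loosely confocal-realistic but reconstruct no real specimen,
and none were fitted to data. Randomness is organised as one
`SeedSequence` per scene with one spawned child stream per cell, so cell
geometry is stable when `n_cells` changes. Geometry that would leave the
stack raises an error rather than being clipped.

What the phantom does *not* model: spherical aberration, depth-dependent
attenuation, bleaching, scanner artifacts, spectral bleed-through, or
real stereocilia ultrastructure (membrane folding is emulated only
implicitly, by giving the full stereocilium cylinder membrane density).
Passing the recovery tests therefore shows the *measurement chain* is
unbiased under the stated noise model, not that any biological value is
correct.

## Segmentation and quantification

Adaptive thresholding selects voxels with intensity strictly above the
local mean over a window of physical size `window_um` (default 5 µm)
times `1 + offset_frac` (default 0.10). Windows are 2-D within each
optical section by default (confocal stacks are quantified per slice),
switchable to 3-D. Both parameters are recorded in the mask's
provenance. Two caveats follow from the local-mean construction: a
constant image segments to empty (nothing exceeds its own mean plus a
positive offset), and the interior of a uniform object larger than the
window is *not* selected — so re-thresholding an already-binarised field
reproduces the foreground only for objects smaller than the window. The
defaults suit membrane shells, puncta and thin protrusions, which is
what the pipeline measures.

ROI boxes are specified in µm and converted to voxels rounding outward
(floor the origin, ceil the far edge), 0-based half-open internally; all
reports are in µm. ROIs may be auto-centred on the intensity centroid of
a designated channel, clipped to stay inside the stack. Empty
selections report sum 0 with an explicitly flagged undefined mean
(NaN + flag), never a silent zero.

The total/recruited decomposition used for sterol staining reports the
whole-field sum of the signal channel ("total") and the mean of the
signal channel inside the marker-positive mask ("recruited"); the marker
mask may be supplied or derived by adaptive thresholding of the marker
channel.

Compartment enrichment reports per-compartment volumes, per-channel
compartment means, within-channel stereocilium/basolateral ratios as
percentages, and the cross-channel ratio of ratios (probe ÷ reference).
The ratio of ratios is exactly scale-invariant per channel and inverts
under channel exchange. On noise-free phantoms the full pipeline
(adaptive segmentation of the reference channel, apex-plane split,
enrichment) recovers E ∈ {1, 2, 4, 8} essentially exactly; under the
default noise model the worst error is ≈ 11%, dominated by PSF dilution
of the thin stereocilia, which affects both channels almost equally and
therefore largely cancels in the ratio of ratios.

## Morphometry

Vesicles: 6-connected (face-adjacent) 3-D components — the conservative
choice that splits touching vesicles most readily; connectivity is
config-exposed. Volume = voxel count × voxel volume; equivalent diameter
= (6V/π)^(1/3); *enlarged* is strict (> 2 µm). At 0.1 µm voxels the
equivalent-diameter error for spheres near the threshold is ≈ 0.02 µm,
well under one voxel, and shrinks with voxel size. Cells are flagged via
centroid containment of an enlarged call (a deterministic surrogate for
by-eye assignment); vesicles whose centroid lies in no cell are recorded
as unassigned and excluded from counts.

Bundles: length is the extent of the 2-D mask's pixel centres projected
on its second-moment principal axis plus one projected pixel footprint;
width is measured in a one-footprint slab at mid-length (a declared
convention — the mid-length extent, not the mean width) as the slab's
perpendicular centre extent plus the mean perpendicular spacing of
projected centre rows (pixel area ÷ footprint). The correction makes
axis-aligned rectangles exact and keeps rotated rectangles within 5%;
measures are exactly translation-invariant. If the width estimate
exceeds the length (near-degenerate masks) the two are swapped.

Cell counting uses centroid-in-region with a half-open 50 × 50 µm box
(centred on the image unless specified): a cell overlapping the box but
with its centroid outside is excluded.

## Evoked potentials

Stimuli are Blackman-windowed sinusoids (default 10 ms). The simulated
response to a pip at level L is a one-cycle Blackman-windowed template
(matching the stimulus bandwidth) scaled by
A(L) = A_max · logistic((L − θ)/s), inserted at a 5 ms latency into
Gaussian noise; s = 0 degenerates to a hard step. Defaults: 200 Hz,
levels 160→120 dB in 5 dB steps, 30 epochs per level, A_max = 1,
s = 1 dB, noise σ = 0.1, 8 kHz sampling.

Detection compares the peak-to-peak of the post-stimulus window
(0–30 ms) of the *averaged* trace against k × the baseline RMS measured
on the *raw* trace in the pre-stimulus windows (−10–0 ms), default
k = 2, ties detected. The single-sweep baseline is deliberate: the
peak-to-peak of pure noise over an m-sample window concentrates near
2·σ_avg·√(2·ln m), so a criterion of 2× the *averaged*-trace RMS would
fire on noise alone; against the single-sweep RMS, averaging N epochs
suppresses the noise peak-to-peak to ≈ 2√(2 ln m)/√N · σ (≈ 1.2 σ at
N = 30), leaving a clean margin below 2σ while genuine responses of
order A_max pass easily. With baseline RMS exactly zero (noiseless
simulations) the rule degenerates to "any strictly positive amplitude",
so a flat average is still undetected.

The threshold at a frequency is the lowest level detected contiguously
from the top of the descending sequence (audiometric convention);
detections below an undetected level are ignored with a warning, and an
undetected top level yields "not reached". Raising k can only raise the
estimated threshold. The criterion is a declared convention: published
threshold values from real recordings depend on an unreported detection
rule and epoch counts and are not desk-reproducible, so validation is by
simulation — across 100 seeded logistic runs the estimate lands within
one 5 dB step of the true θ in ≥ 95 (observed: 100).

## Sequence patterns and motifs

The default residue-class table is Ω = {F,W,Y,H}, Ψ = {I,L,V,M},
π = {A,G,P,S}, + = {K,R,H}, − = {D,E}, ζ = {D,E,H,K,N,Q,R,S,T},
Φ = {A,C,F,I,L,M,V,W,Y}; every standard residue belongs to at least one
class, and the table is overridable because normalized-symbol
conventions differ slightly between sources. In the text syntax a
bracketed lowercase/ASCII name (`[pi]`, `[Omega]`…) is a class and
bracketed capitals (`[PI]`, `[ST]`) are explicit residue sets; a bare
`-` is always a separator, so the acidic class is written `[minus]`.

Pattern derivation is column-wise: literal if the top residue's
frequency ≥ 0.9, else explicit set if ≤ 2 distinct residues, else the
smallest covering class (ties broken by table order), else wildcard;
columns with > 50% gaps are wildcards and other columns ignore gap
characters. Maximal non-wildcard windows of length ≥ 4 become patterns,
which also guarantees no leading/trailing wildcards. Derivation is
order-invariant over sequences.

Scanning enumerates all gap lengths in [m, n] explicitly (no greedy/lazy
ambiguity), reports every overlapping match with 1-based inclusive
coordinates, and deduplicates identical (sequence, span, kind) hits that
arise from different internal gap splits. The scanner is checked
exhaustively against a direct set-membership oracle.

CRAC is restricted to a tyrosine centre per the strict consensus; CARC
tolerates Y/F/W; both centres and the spacing bounds (default 1–5) are
configurable, since published motif counts depend on these choices.
The bundled 190-residue test sequence with three planted CRAC/CARC
sites is a synthetic stand-in constructed for the scanner tests, not a
real protein sequence. Database hit counts are out of scope (they are
database-version dependent).

## Statistics

The two-sided Fisher exact p sums hypergeometric probabilities of all
tables, margins fixed, no more probable than the observed one — the
standard exact convention (the doubling convention differs and is not
used). Weights C(r1,k)·C(r2,c1−k) share the denominator C(n,c1), so the
"no more probable" comparison runs on exact integers and the only
floating-point step is the final division; agreement with independent
float enumeration over all 132,470 tables with n ≤ 40 is ≤ 6e-16. Other
group comparisons (t tests, Mann–Whitney, ANOVA families) are delegated
to standard statistical libraries by design; only the exact test is
first-principles because it anchors the package's headline contingency
result. Percent-of-control reports 100 × value / mean(control) with
mean ± sem summaries, sem = sd(n−1)/√n; a non-positive control mean is
an error.

## Determinism and problem sizes

All generators are pure functions of (spec, seed); the pipeline runner
validates the whole config before executing any stage, propagates one
seed, and writes provenance (config, seed, versions) beside its outputs;
identical config + seed reproduces bit-identical tables. The bundled
validations use deliberately small scenes — two-cell stacks of roughly
190k voxels, 100-run threshold simulations, a 1,000-sequence random
library — chosen so the full suite runs in minutes on a single core
while still exercising every code path at meaningful signal-to-noise.

## Known limitations

- The adaptive threshold is one published-style convention (local mean ×
  multiplicative offset); the original quantification scripts this
  emulates are not public, so parameter defaults are declared, not
  reconstructed.
- Whether "recruited" quantification should threshold the marker channel
  or use a fixed mask is ambiguous in the source material; both are
  supported, thresholding is the default.
- The enlarged-lysosome rule is applied per connected component;
  aggregates that touch merge into one call.
- Bundle width at mid-length is sensitive to mask jaggedness at the
  ±5% level for rotated elongated shapes.
- AEP analysis has no artifact rejection by default (an optional
  amplitude-clipping rejection, `reject_above`, drops epochs exceeding
  an absolute limit before averaging), and models no electrode or
  amplifier physics.
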