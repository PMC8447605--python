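# Methods

## Pre-processing: à trous band-pass filter

Each channel is decomposed with the undecimated ("à trous") wavelet
transform using the separable B3-spline kernel `[1, 4, 6, 4, 1]/16`. At
scale *k* the kernel is dilated by inserting `2^(k-1) − 1` zeros between
taps; plane `w_k = c_{k-1} − c_k`, where `c_k` is the smoothing of
`c_{k-1}` and `c_0` is the input. Boundaries are mirror-reflected
(reflection about the edge sample), which keeps reconstruction exact —
`Σ w_k + c_J` equals the input to float round-off — and avoids edge
darkening. These are the canonical choices for this transform; the
transform itself fixes neither.

The band-pass keeps `w_2 … w_J` by default (`J = 4`): the finest plane
carries single-pixel speckle, the residual carries diffuse background,
and endosomal puncta (σ ≈ 1–3 px) live in the intermediate planes. Both
drop counts are configurable. After summing the retained planes,
negative pixels are clamped to zero (strictly-positive pixel counting is
ill-defined on signed data) and values are capped at 1.

**Output re-quantization.** By default the filtered image is rounded
back to the source bit-depth grid (1/255 for 8-bit). This mirrors an
integer-image workflow and is load-bearing for the downstream counting
statistics: a linear filter turns a removed speckle delta into a faint
positive halo (the retained planes of a delta have a ~5×5 footprint),
and on float data every halo pixel would count as "strictly positive",
inflating expression fractions *more* than the unfiltered speckle does.
Re-quantization sends sub-half-gray-level residues to zero, so the
filter actually removes what it attenuates. Set
`quantize_output=False` for float-valued analysis.

## Co-localization statistics

All statistics are restricted to a binary ROI of `N` pixels, including
the Costes regression and threshold scan (the analysis region is the
unit of measurement; pixels outside it never enter any sum).

* Expression fraction: `F_X = N_X / N`, where `N_X` counts ROI pixels
  with intensity `> ε`, `ε = 1e-12` (a float-dust guard above exact
  zero; after the default quantization it is equivalent to "at least one
  gray level").
* Overlap image: elementwise product of normalized channels; overlap
  fraction is the expression fraction of the product. Multiplication
  makes the combined image strictly positive exactly where every factor
  is, so `OF_RFG ≤ min(OF_RG, OF_RF, OF_FG)` holds by construction.
* Manders `M1 = Σ(I_R | I_G > T_G) / Σ I_R` and symmetrically `M2`;
  zero-sum channels return 0 with a flag rather than NaN.
* Costes thresholds: orthogonal (total-least-squares) regression
  `I_G ≈ a·I_R + b` fitted on ROI pixels via the closed-form major-axis
  slope; candidate `T_R` descends from `max(I_R)` in steps of 1/255 (the
  8-bit quantum; configurable, e.g. 1/65535 for 16-bit) with paired
  `T_G = a·T_R + b`, stopping at the first candidate where the Pearson
  correlation of the pixels below both thresholds is ≤ 0. If the
  correlation never crosses zero the scan stops at the grid floor (one
  step) and reports `at_floor`; sub-threshold sets with fewer than two
  pixels or zero variance leave the correlation undefined and the scan
  continues. A negative regression slope (anti-correlated channels)
  makes descent along the line meaningless; the search ceiling is
  returned with `anti_correlated` set. Thresholds are clipped to [0, 1].
* Three-marker statistic: `I_FR = I_F × I_R` is scored against `G`
  with the same Costes + Manders machinery (`T_FR`, `T_G`). Saturated or
  otherwise constant channels make the regression degenerate; the triple
  path then forces zero thresholds (every positive pixel co-localizes),
  which is the correct limit for identical markers.

Metrics are computed on band-pass-filtered channels by default; a raw
mode (`wavelet.enabled = false`) exists for filter-free analysis. The
orchestrator reports both `M1` and `M2` (and both triple coefficients);
which one a study reports is a user choice, so aggregation is left to
the caller.

## Assay quantifiers

**Recycling.** The original assay scores, per chase time and
compartment (total / cell surface / internalized), the percentage of
receptor-positive cells over DAPI-counted nuclei, referred to the
time-zero value. Counting is automated here: global Otsu threshold on
the nuclear channel, connected components with a minimum-area filter
(default 40 px), watershed split of touching nuclei on the smoothed
distance transform, dilation of each nucleus by a fixed radius (default
8 px) to approximate the cell, and a cell is positive when its mean
marker intensity exceeds a threshold (default 0.05 — chosen for
robustness on dim recycled signal; an area-fraction criterion was the
alternative). Every parameter is exposed, and manually scored count
tables bypass segmentation entirely. Counts at the same condition ×
compartment × time are pooled before percentages are formed; a zero
time-zero percentage makes the series undefined and raises.

**Invasion.** Given per-insert serial sections (constant 20 µm spacing
enforced), the invading fraction is the summed fluorescence of sections
strictly deeper than the threshold (default 40 µm; "beyond" is
implemented as `>`) over the total.

## Condition statistics

Summaries are median ± SD (n−1 denominator; SD absent for n = 1),
matching how such imaging panels are typically reported. The default
test is the pooled-variance two-tailed Student t test, with Welch as an
option; p-values come from the t distribution. Zero pooled variance
with equal means gives t = 0, p = 1; with unequal means the comparison
is flagged degenerate. No multiple-testing correction is applied by
default (per-comparison stars, one star below p = 0.005 by default);
Benjamini–Hochberg adjustment is available as an explicit call.

## Synthetic scenes and what they do (not) show

The generator renders what the metrics consume: anti-aliased nuclear
discs (radius 15 px), optional membrane rings, and isotropic Gaussian
puncta (σ = 2 px, amplitude 0.9, 25 per marker channel on a 256×256
frame) with a planted shared fraction *f* — shared puncta sit at
identical centers across channels, non-shared puncta keep ≥ 16 px
(≈ 8σ) from every spot of the other channels so their quantized
supports cannot touch. Scenes are 8-bit quantized, mirroring 8-bit
acquisition. Noise is Gaussian read noise plus single-pixel speckle;
speckle amplitude defaults to 3/255 — a few gray levels, the
shot/dark-noise regime that corrupts strictly-positive pixel counting
and that the band-pass filter targets. All randomness flows from one
explicit seed; no global state is touched, and equal seeds give
bit-identical scenes.

On these scenes the planted fraction is recovered two ways: `M1`
approximates *f* directly (intensity-weighted fraction of R in
G-positive compartments), and the ratio `OF_RG / mean(F_R, F_G)`
(jointly-positive area over mean marker-positive area) is a
threshold-free estimate used for monotonicity and filter-benefit
checks.

The recycling simulator draws each cell's per-compartment positivity as
an independent Bernoulli variable from the scheduled fraction and
renders jittered-grid fields (ring = surface signal, cytoplasmic puncta
= internalized); the schedule used in validation (surface 100% → 30% →
80% over 0/40/120 min, 200 cells, 20 repeats) emulates an
internalize-then-recycle experiment.

Passing on synthetic scenes shows the estimators are correct and
calibrated under the generative model; it does not certify performance
on real micrographs, where puncta are not isotropic Gaussians, noise is
not purely single-pixel, background is structured, and cells overlap.
In particular the automated "receptor-positive" criterion stands in for
what was originally visual scoring and should be tuned per dataset.

## Numerical choices and limitations

* Validation problem sizes (200 reconstruction images at 128², 50
  oracle instances at 32², 1000 bound scenes at 24², 20 seeds per
  planted-fraction level, 10⁴ null t-test simulations) were chosen so
  the full property suite runs in well under a minute per stage while
  keeping Monte-Carlo error far below the asserted tolerances.
* Costes thresholds from the vectorized scan agree with an exhaustive
  naive scan to within one grid step by construction; ties terminate at
  the first (largest) qualifying candidate.
* The pipeline is byte-deterministic: identical config, inputs and seed
  reproduce identical CSVs (run logs contain a config digest, no
  timestamps).
* 2D only (single confocal planes); no z-stacks, no PSF-accurate
  optics, no photobleaching, no object-based (spot-matching)
  co-localization, and no Costes randomization significance test —
  Costes is used for thresholds only.
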