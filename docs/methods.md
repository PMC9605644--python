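# Methods

This note documents the models, parameter choices and numerical
conventions behind `gema`, and what the synthetic study conditions do and
do not establish about real data.

## The segmentation model

The adaptive engine assumes cells are distinguished from the chamber
background by fine-grained texture rather than by absolute intensity —
the operating regime of label-free brightfield imaging of adherent cells.
The pipeline per frame is: grayscale → CLAHE → Gaussian smoothing → Gabor
bank response → CV-scheduled adaptive binarization → binary closing.

### Preprocessing

* Grayscale is the plain channel average `(R+G+B)/3`, rounded half-up —
  not the luminance weighting, so the three channels of a color camera
  contribute equally.
* CLAHE is implemented in-package with OpenCV-style semantics: per-tile
  256-bin histograms clipped at `clip_limit` times the uniform bin height
  (default 2.0, tile grid 8×8), excess redistributed uniformly, and
  per-pixel bilinear interpolation of the tile mappings. With a 1×1 grid
  and a large clip limit it reduces exactly to global histogram
  equalization, which is what the test oracle checks. Note that only each
  pixel location's effective lookup table is monotone; the ordering of two
  pixels at different locations may invert under interpolation.
* Gaussian smoothing uses σ = 0.6 px by default. This is deliberately
  light: the Gabor carrier wavelength is ≈3.3 px, and σ = 1.0 would
  attenuate that band to ~16% amplitude, destroying most of the texture
  signal the method runs on. σ = 0.6 keeps ~50% of the band while
  suppressing single-pixel noise. Reflective borders everywhere, so
  frame edges contribute no spurious gradients and the image mean is
  preserved to within quantization.

### Gabor bank

The four kernels are the real (even-cosine) part of the standard Gabor
function sampled on a 21×21 grid whose axes span [−1, 1]; `f = 3` thus
means three carrier cycles per kernel half-width (λ ≈ 3.3 px for the
default size). γ = 10 makes the envelope essentially flat along the
stripe; η = 0.5 confines it to ~1.2 px across. Each kernel is
mean-subtracted so constant regions produce exactly zero response.

Orientation fusion is the pixel-wise maximum of absolute responses
(configurable to sum). The fused response is normalized to [0, 255] by the
per-frame peak, **with a gain cap**: the divisor is
`max(peak, min_texture_amplitude × matched_grating_response)`. Pure
per-frame peak normalization is scale-invariant, so a frame containing
only sensor noise would be amplified to full range and segment to tens of
percent spurious foreground; the cap fixes the maximum gain the way a
camera AGC does. The default floor of 25 intensity units (of equivalent
matched-grating contrast) sits between the noise-only response of an
empty chip (≈5–8 units equivalent) and genuine cell texture (≈20–60
units). An empty-chamber frame (background 120, noise sd 2) segments to
0.2% foreground.

### Threshold scheduling

`CV = σ/μ` (population σ over all pixels) is computed on the preprocessed
grayscale by default (`cv_source` can switch to raw). CV is scale-free,
so lamp brightness drift does not move it, and it is minimal both for an
empty chamber and a uniformly covered one — which is why the controller
needs the experiment mode as an input:

* growth: low CV means confluence → offset C → 5; high CV → 11;
* apoptosis: low CV → 11; high CV → 5.

The CV series is modeled by ordinary least squares `CV = m·x + b`. The
model refits when its mean absolute relative error over the most recent
`min_refit_window` (5) points exceeds `refit_tolerance` (5%); the refit
window is all points since the previous refit, extended to at least 5
points. Evaluating the error on recent points only means a regime change
registers within one or two frames regardless of how long the preceding
stable segment was; the result is the piecewise-linear tracking a slowly
drifting culture requires. The predicted CV is clamped to the observed
[cv_min, cv_max] range and mapped linearly onto the integers {5..11},
rounded half-up. Until the observed CV range spans at least 10% of its
maximum (`min_calibration_span`), interpolation is refused and the
mode's cold-start endpoint is used (growth starts sparse → 11; apoptosis
starts confluent → 5); with a degenerate span, float noise would
otherwise throw the threshold to an arbitrary endpoint.

### Binarization and morphology

A pixel is foreground iff `response − local_mean > C`, with the local
mean Gaussian-weighted (sd = block/6, support clipped at the block;
`adaptive_method="mean"` switches to a uniform window). Strict
inequality, so ties go to background and a constant response yields an
empty mask. The block size default is 101 px — it must exceed a cell
diameter (up to ~60 px in the study conditions), otherwise the local mean
tracks the cell itself and hollows it out.

Closing uses a 7×7 square: the |real-Gabor| response of granular texture
oscillates with ridge spacing of roughly half the grain wavelength, and
the closing element must bridge those gaps. Border convention: dilation
pads with background, erosion with foreground, so closing is extensive
and idempotent. A final dilation is available (`dilation_se`) but
disabled by default: the 21-px kernel support already smears the response
~3–4 px beyond the textured core, which performs the boundary enlargement
a dilation would, and stacking both systematically overshoots the
annotated cell extent.

The gradient baseline shares the preprocessing (disable with
`preprocess.enabled = false`), computes local max − local min under a 5×5
square, and thresholds at a fixed 25 (strict).

## Synthetic study conditions

The generator emulates the optical regime of brightfield MCF7 cultures in
a PDMS chamber at the point where texture-based segmentation is the right
tool, with exact ground truth. Defaults (256×256, 20 frames, coverage
0.1 → 0.9 on a logistic ramp):

* **Cells** are ellipses (radii 12–30 px) carrying granular band-pass
  noise texture (difference-of-Gaussians around a grain scale of
  3–4.5 px, inside the bank's passband), rendered ~0.7·contrast brighter
  than background with ±0.35·contrast modulation (contrast 70). Granular
  rather than sinusoidal texture matters: a pure grating at 22.5° from
  the nearest bank orientation is invisible to a 4-orientation real-Gabor
  set.
* **Faint margins**: the outer 5 px of every cell renders at background
  (ramping up over the next 4 px), while the gold mask includes it —
  annotators circumscribe the full cell, but thin spread margins are
  nearly invisible in brightfield.
* **Confluence flattening**: per-cell contrast falls linearly with the
  covered fraction (80% loss at full coverage), emulating
  contact-inhibited flattening. This is what makes the frame CV fall
  again as the culture approaches confluence, reproducing the
  low-CV-at-confluence behavior the controller relies on.
* **Background**: level 120, Gaussian noise sd 3, plus ~40 static
  out-of-focus debris blobs (±20 intensity, radii 4–10 px) that persist
  across frames and count as background in the gold standard.
* Cell placements persist across the sequence (growth adds, apoptosis
  removes in reverse order), per-frame coverage targets are hit within
  ±2 percentage points, and everything is a pure function of the seed.

Under these conditions the adaptive engine reaches mean Dice ≈ 0.85–0.87
with every mid-coverage frame ≥ 0.82, the gradient baseline ≈ 0.79–0.81,
and the percent-cells trace correlates with true coverage at r ≥ 0.99
(stable across seeds).

**What this does and does not show.** The fixtures exercise the full
pipeline — texture detection, gain control, CV scheduling, morphology,
evaluation — under controlled, known-truth conditions that include the
main nuisances of real chips (noise, debris, faint margins, contrast
drift with density). They do not include uneven illumination, defocus
drift, halo artifacts, cell shape diversity or annotation error, so
passing them does not certify accuracy on any particular real dataset;
it certifies the machinery and its claimed relative behavior (adaptive
engine ≥ fixed-threshold gradient in this regime).

## Numerical conventions

* Coordinates: x = column, y = row, 0-based, origin top-left (VIA's
  convention). Rasterization is center-inside with the boundary counted
  as foreground.
* Shoelace area takes the absolute value, so vertex orientation is
  irrelevant; Dice of two empty masks is defined as 1.0 (logged).
* 16-bit images are rescaled by the dtype maximum, not the per-image
  maximum, so CV is comparable across frames.
* Strict `>` at every threshold; half-up rounding wherever a float meets
  an 8-bit grid. Two runs with the same config and seed are
  byte-identical.
* The trace's threshold column reports whatever the engine used (the
  scheduled 5–11 offset, or the gradient baseline's fixed 25).

## Problem sizes

Default tests and the acceptance script run 20-frame 256×256 sequences
(~10 s each end to end) and 100-replicate regression experiments; oracle
equivalence checks use ≥100 random images up to 32×32 against pure-Python
brute-force implementations.

## Known limitations

* The mask resolution is bounded by the 21-px kernel support: boundaries
  are recovered to ~±4 px, and structures thinner than the carrier
  wavelength are missed. The method measures area fraction, not cell
  counts or shapes.
* The growth/apoptosis mode flag is user input; CV alone cannot
  distinguish an emptying chamber from a filling one.
* The refit heuristic assumes CV evolves piecewise-linearly; oscillating
  CV (e.g. periodic media exchange) would cause frequent refits.
* Online mode uses polling with a file-size stability check — adequate at
  minutes-per-frame acquisition, not for sub-second streams.
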