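# Methods

## The measurement problem

Intravital fluorescence of a systemically injected metabolic probe is an
indirect measurement: the camera records dark offset + tissue
autofluorescence + probe signal, all multiplied by the illumination
profile and a day-specific system gain. Comparing animals imaged on
different days — the whole point of a longitudinal or multi-group design —
requires removing each of these instrument signatures per session.
`ivmquant` implements that correction chain, the kinetic and texture
endpoints computed on corrected frames, and the statistics used to compare
groups of animals.

## Calibration chain

For each raw frame `F`:

1. **Dark**: subtract the laser-off signal. Default is the *scalar mean*
   of the dark frame (the dark level is an electronic offset, spatially
   flat up to read noise); a per-pixel mode exists for cameras with fixed
   pattern noise.
2. **Background**: subtract the pre-injection autofluorescence, itself
   dark-subtracted. Default is *pixelwise* (the per-pixel mean of all
   pre-injection frames), because tissue autofluorescence is spatially
   structured; a scalar mode exists.
3. **Flat-field**: divide by the dark-subtracted uniform-phantom image
   normalized to unit mean, removing vignetting while preserving the
   intensity scale. The phantom is Gaussian-smoothed first (default
   σ = 2 px) so phantom shot noise is not imprinted onto every frame;
   σ = 0 disables smoothing and is the correct setting for a noiseless
   (synthetic) phantom — with smoothing on, a smooth analytic vignette
   would be slightly distorted and exact inversion impossible.
4. **Standard**: multiply by `standard_reference / mean(standard frame)`.
   The reference defaults to 1, so calibrated values are in
   "standard-equivalent" units; only cross-session comparability matters,
   not absolute radiometry.

Subtractions precede the phantom division even though the background is
itself vignetted; this matches the stated processing order of the source
protocol, and because the background is subtracted *as imaged* (also
vignetted), probe-free regions still null exactly. A
`background_after_flatfield` mode is available but off by default.

Negative pixels after subtraction are **retained** for all means and
statistics — clipping at zero before averaging would bias low-signal
comparisons upward — and clipped only when building display-style pixel
PDFs.

The chain is exactly invertible on the simulator's noiseless forward
model: `calibrated = (reference/standard_level) · U · (1 − e^{−t/τ})` to
machine precision, and is invariant to a global gain change applied to
data, phantom, and standard alike (the gain cancels algebraically).

## Kinetics

The kinetic curve is the mean calibrated intensity over the field of view
(or a mask) per time point. Normalization divides by the curve maximum —
uptake *kinetics* are then comparable across animals whose uptake
*levels* differ. The plateau check computes CV (sample sd / mean) of the
curve inside a window, default 30–80 min with threshold 0.10; for
`τ = 10 min` saturating kinetics the analytic CV over that window is
≈ 0.016, comfortably stable, and the 30-min value is 1 − e^{−3} ≈ 0.950
of the asymptote (≈ 0.964 of the plateau-window mean level).

The summary parameter is the curve value (or full frame) at the frame
*nearest* 60 min, ties to the earlier frame; interpolation is refused
because the summary image must be an acquired frame, not a synthetic one.
An error is raised if the nearest frame is farther than half the median
inter-frame interval.

Caliper tumor volume uses `L·W²/2` with `W` the smallest axis; swapped
inputs are corrected with a warning.

## Local-range heterogeneity

"Neighborhood holding ~1% of the image's pixels" is realized as the odd
square window side `s` minimizing `|s² − 0.01·N|` (ties to the smaller
side), computed per image; a disk footprint of the same nominal diameter
is available. The map is max − min over that window, computed with
separable running max/min filters (±∞ padding in constant mode, which is
exactly window truncation at borders). Truncation, not mirroring or
zero-padding, because padding fabricates intensities and corrupts the
range statistic at edges. The fast path is contract-tested to equal a
brute-force per-pixel scan exactly. Local range is invariant to additive
offsets and equivariant to positive scaling, so calibration residual
offsets cannot create spurious texture.

## Statistics

* Pooled-pixel PDFs: all pixels of all animals in a group, histogram
  normalized to unit integral. Default 100 equal-width bins spanning the
  pooled 0.1–99.9 percentile range (clipping resists hot pixels); when
  groups are compared, shared edges must be passed, and the pipeline does.
  Pooling weights each pixel equally, so animals contribute in proportion
  to analyzed pixels.
* KS tests run on pooled **raw** pixels, never on binned densities.
  P-values are asymptotic (pixel pools are large). Outputs carry raw pixel
  counts: pixels are spatially correlated, so the effective sample size is
  far below the pixel count and pooled-pixel p-values overstate
  significance; the package reports the caveat rather than inventing a
  correction.
* Wilcoxon signed-rank (paired, zeros dropped, exact null for n ≤ 25) and
  Wilcoxon rank-sum (all pairwise, Bonferroni `min(1, m·p)`, exact null
  for n ≤ 8 without ties). At n = 4 pairs the exact two-sided floor is
  p = 0.125 — a uniform decrease in four animals cannot beat 0.05, which
  is reported as-is.
* Two-way ANOVA treats `group` and `time` as crossed fixed factors with
  animal curves as independent replicates (no repeated-measures term);
  implemented as OLS + type-II ANOVA and cross-checked against textbook
  sums of squares on balanced designs.

## Simulator

Forward model per pixel and frame:
`raw(t) = dark_offset + gain · V · (autofluorescence + U · (1 − e^{−t/τ})) + noise`,
with `V` a Gaussian-beam vignette and `U` a Gaussian random field
(mean = per-animal amplitude, sd = `texture_sd`, correlation length
`texture_corr_len_px`, clipped at 0). Defaults, chosen once as the study
conditions the pipeline targets: frames at 0, 5, …, 80 min plus two
pre-injection baselines; τ = 10 min (≥95% saturated by 30 min, stable
through 80); amplitude 100 with 15% between-animal CV; texture sd 20 at
5 px correlation length; autofluorescence 20; dark offset 100;
vignette σ = 0.6 of the frame diagonal; Gaussian shot noise with variance
equal to the expected signal (exact Poisson by flag); read noise sd 1 on
the dark frame; 4 animals per group. The default frame is 160 × 210 px —
the 2.1 × 1.6 mm window field of view at 10 µm pitch, a deliberately
desk-scale raster (tests and the acceptance script use 48 × 63 to
80 × 105 frames; every statistic involved is resolution-independent at
these scales because window sizes are computed per image).

Kinetics are single-exponential saturation with no washout: the data the
pipeline targets show a stable plateau to 80 min, and modeling beyond
that horizon is out of scope. Seeding uses
`SeedSequence(seed, spawn_key=(animal_index,))`: adding animals or groups
never perturbs existing ones, and identical (config, seed) is
bit-identical. Paired designs re-simulate the same animal with its
amplitude rescaled while sharing the field substream, so day-0/day-4
geometry is correlated as in a real longitudinal session.

What the simulator does **not** emulate: tissue optics (scattering,
depth-dependent attenuation), vascular delivery and washout pharmacology,
motion/breathing artifacts, fixed-pattern noise, and tumor geometry
(uptake fields are stationary random fields, not lesions). Passing tests
therefore demonstrate that the *pipeline* is correct and unbiased under
its stated noise model — not that the biology of any particular tumor
model is reproduced.

## Numerical and statistical choices

* All pixel math in float64 regardless of on-disk dtype; maps written as
  float32 TIFF (bit-exact round-trip).
* Phantom pixels must be strictly positive after smoothing; otherwise the
  session is rejected rather than silently producing infinities.
* Residual-unbiasedness checks compare residual means across *replicate
  sessions* rather than against a naive pooled per-pixel SE: the
  background estimate, smoothed phantom, and scalar standard factor are
  common to every frame of a session, so within-session residuals are
  strongly correlated and the pooled SE understates the sampling error of
  the mean by roughly an order of magnitude.
* Fold-change recovery is assessed with matched per-animal substreams
  across groups (`matched_amplitudes=True`), making the ground-truth group
  amplitude ratio exact by construction; with independent draws the
  design's own between-animal sampling noise (≈10% sd on a ratio of two
  n = 4 means at 15% CV) would swamp the pipeline error being measured.
* Uptake-field clipping at zero slightly raises the realized mean of
  low-amplitude groups (≈1% at amplitude 25, texture sd 20), visible as
  recovered ratios a few percent below nominal at ratio 4.

## Known limitations

* No photobleaching or probe-washout correction.
* No conversion to absolute probe concentration.
* Pooled-pixel tests ignore spatial autocorrelation (reported, not
  corrected).
* The two-way ANOVA ignores within-curve repeated measures; a mixed-model
  variant would be the principled extension.
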