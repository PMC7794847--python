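# ivmquant

Quantitative analysis of intravital fluorescence time-lapse imaging of
metabolic probe uptake — the kind of data produced by imaging a
fluorescently labeled fatty acid (Bodipy FL c16) or a mitochondrial
membrane-potential dye (TMRE) through a mammary window chamber for
~80 minutes after tail-vein injection.

It is written for imaging labs that need to turn raw camera frames into
numbers comparable across animals, days, and instruments:

* **Calibration** — each session's frames are corrected by (1) subtracting
  the laser-off dark level, (2) subtracting the pre-injection
  autofluorescence background, (3) dividing by a unit-mean image of a
  uniform fluorescent phantom to remove the Gaussian beam profile, and
  (4) scaling by a factor derived from a Rhodamine B standard imaged every
  session, which removes day-to-day system gain.
* **Kinetics** — per-animal uptake curves `I(t)` (mean calibrated intensity
  per time point), max-normalization, a plateau check (CV of the curve over
  30–80 min), and the summary parameter: the calibrated fluorescence at
  60 min post-injection (the plateau mid-point), per animal.
* **Heterogeneity** — per-pixel *local range* maps: max − min over a window
  holding ≈1% of the image's pixels, a texture statistic that separates
  patchy from uniform uptake even at equal mean intensity.
* **Statistics** — pooled-pixel probability density functions and
  two-sample Kolmogorov–Smirnov tests, Wilcoxon signed-rank for paired
  (longitudinal) designs, Wilcoxon rank-sum with Bonferroni correction for
  multi-group designs, and two-way (group × time) ANOVA on kinetic curves.
* **Simulator** — a forward model
  `raw(t) = dark + gain · vignette · (autofluorescence + U · (1 − e^{−t/τ})) + noise`
  with a Gaussian-random-field uptake map `U`, which generates complete
  synthetic sessions (frames + calibration frames + ground truth) so the
  whole pipeline is testable without animal data.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/02_uptake_kinetics.py` simulates a session, calibrates
it, and prints the kinetic analysis (output abbreviated):

```
time_min  mean_intensity  normalized
       0          0.0001      0.0001
       5          0.3353      0.3941
      30          0.8094      0.9514
      60          0.8502      0.9993
      80          0.8508      1.0000

plateau 30-80 min: cv = 0.0158 (11 points) -> stable = True
summary value at 60 min: 0.8502 (true plateau x scale: 0.8505)
```

The curve saturates by ~30 min (τ = 10 min, so 1 − e^{−3} ≈ 95% of the
asymptote) and is flat through 80 min (CV 1.6% ≪ the 10% stability
threshold); the 60-min value recovers the simulator's known plateau level
to 0.04%. `examples/04_group_comparison.py` runs a complete two-group
experiment (3-fold uptake difference, n = 4/group) and prints the
rank-sum, ANOVA, and pooled-pixel KS results:

```
rank-sum ['high', 'low']: p = 0.0286 (Bonferroni-adjusted 0.0286), left-shifted
two-way ANOVA group effect: F = 439.3, p = 9.39e-39
pooled-pixel KS ['high', 'low']: D = 0.817, p = 0.00e+00, left-shifted
```

## Command line

The same stages are exposed as a thin CLI:

```bash
ivmquant simulate --preset two-group --seed 1 --out sim/
ivmquant run --input-dir sim/ --out results/ --seed 1
ivmquant kinetics sim/high_00_day0 --out kin/
ivmquant heterogeneity kin/summary.tif --out het/
```

`run` writes per-session summary images and local-range maps (float32
TIFF), curve and summary-value tables (CSV), pooled-pixel PDFs, a
`report.json` with all test results, and a provenance sidecar per
artifact.

## Session layout on disk

One directory per session: `stack.tif` (multi-page float TIFF, or a
directory of single-page TIFFs in lexical time order) plus a
`session.yaml` sidecar carrying `times_min` (negative = pre-injection
baseline frames), probe, exposure, animal/group labels, and a
`calibration:` section pointing at `dark.tif`, `phantom.tif`,
`standard.tif` and the standard's reference value. `ivmquant simulate`
writes this layout, `manifest.csv`, and per-session `ground_truth/`.

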