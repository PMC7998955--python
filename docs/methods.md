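# Methods

This note records the models implemented in `icedrop`, the assumptions behind
them, the synthetic-data generator's design, and the numerical choices that a
maintainer would otherwise have to reverse-engineer from the code.

## Ice-nucleation statistics

The package works in the deterministic (singular) description of heterogeneous
ice nucleation: each nucleation site has a characteristic temperature at or
below which it is active, and time/cooling-rate dependence is neglected. This
is a good approximation for efficient biological nucleants active above
−10 °C; it is *not* adequate near the homogeneous limit, and nothing here
models stochastic nucleation rates J(T).

- Frozen fraction: `f = Nf / N`, with a Wilson score 95 % interval on the
  binomial proportion. Wilson is used because points near f = 0 and f = 1 are
  routine in freezing curves and the normal approximation degenerates there.
- Active-site density: `nm(T) = −ln(1 − f) / (V · Cm)` in sites per mg, with
  `V` the droplet volume in mL and `Cm` the nucleant concentration in mg/mL.
  `f = 1` points are **censored** (excluded from nm spectra and flagged),
  never clipped or reported as infinity: the formula diverges and any finite
  surrogate would be an invention. Interval bounds on nm are obtained by
  transforming the Wilson bounds on f, which is exact because nm(f) is
  monotone.
- Droplet volume convention: spheres, `V = (π/6) d³`. The droplets (70–85 µm)
  are smaller than the channel cross-section (200 × 150 µm), so they are
  unconfined. The default nominal diameter is 75 µm
  (V ≈ 2.209 × 10⁻⁷ mL).

## The class-resolved INP population model

A sample is a sum of INP classes, each with a site density (sites/mg) and an
activation-temperature distribution; `nm(T) = Σ density_c · Pr(T_act,c ≥ T)`.
Class presets follow the standard Snomax® subpopulation windows: A active
above −4.5 °C, B in [−6.5, −4.5] °C, C below −7.5 °C. Two distribution
families are provided: truncated normal (default) and uniform.

Default population (illustrative, not fitted to any dataset):

| class | density (mg⁻¹) | activation distribution |
|---|---|---|
| A | 5 × 10⁵ | truncnorm(mean −4.2, sd 0.3) on (−4.5, 0] |
| B | 2 × 10⁶ | truncnorm(mean −5.5, sd 0.5) on [−6.5, −4.5] |
| C | 6 × 10⁷ | truncnorm(mean −8.5, sd 0.6) on (−∞, −7.5] |

These densities were chosen once so that, for a 75 µm droplet at 1 mg/mL, the
expected frozen-fraction curve rises from f ≈ 0.03 at −4 °C to f ≈ 0.95 at
−8 °C with a steep warm flank (class A), an intermediate plateau at f ≈ 0.42
(class B scarce relative to A and C), and a steep cold flank (class C) — the
characteristic shape of efficient bacterial nucleants.

Treatments are transforms on the population: a temperature shift applied to
all activation distributions plus per-class multiplicative density depletion.
Presets: `heat55` (shift −1.3 °C, no depletion — mild heat damage translates
the curve), and `heat95` (class A destroyed, remainder shifted −7 °C, B/C
thinned to 0.3/0.8 — severe degradation lowers the onset by >7 °C and
flattens the curve). A shift is an exact translation of nm(T), which the
tests exploit as a machine-precision identity.

Counts are simulated as `Nf ~ Binomial(N, 1 − exp(−nm(T)·V·Cm))` — the
deterministic model plus sampling noise, nothing more.

## Synthetic video generator

The generator emulates the recording geometry of a flow-through assay:
128 × 256 px frames at 1.953 µm/px (250 µm channel height over 128 px),
droplet diameters uniform in 70–85 µm (~36–44 px), constant velocity
12 mm/s along the channel axis, arrival at a fixed pitch (default 100 px)
plus uniform jitter, never overlapping. Desk-scale defaults use a
150 fps-equivalent sampling (≈41 px/frame displacement, so each droplet is
fully visible in ≥5 frames) and hundreds of droplets per video; full-scale
parameters (3000 fps, thousands of droplets) are reachable through the same
arguments.

The default pitch deliberately keeps the droplet duty cycle per pixel below
one half, which makes the per-pixel temporal median an exact background
estimator; a two-pass masked estimator is provided for denser trains.

Appearance model (8-bit intensities):

- *Bright field.* Background ≈120 with a mild horizontal gradient and a
  brighter off-center stripe emulating the trace of an under-channel sensor.
  Liquid droplets: smooth bright interior (≈150–185) with a dark rim (≈45).
  Frozen droplets (all subtypes): speckled interior (sd 25–35, an order of
  magnitude above the sensor noise) with an irregular rim whose radius is
  modulated by a smooth random angular function.
- *Polarized.* Background level depends on the analyzer angle: ≈4 at full
  extinction (90°), ≈20 once the analyzer is backed off to ≤85°. Liquid
  droplets show lensing contrast proportional to a visibility factor that is
  0 at 90° and 1 at ≤85° — at 90° liquid droplets are indistinguishable from
  background (within 1 % of dynamic range), which is the documented failure
  mode of fully crossed polarizers. Frozen subtypes: `frozen_bright` adds a
  per-droplet birefringence gain drawn uniform in [110, 210] (optionally
  redrawn along the track to emulate droplet rotation); `frozen_dark` sits at
  0.4× background (visible as a dark disk at 60–85°, invisible at 90°);
  `recalescent` renders as a liquid droplet plus faint speckle — by
  construction almost indistinguishable from liquid between polarizers while
  plainly textured in bright field. The default frozen-subtype mixture is
  70 % bright / 15 % dark / 15 % recalescent (a free simulation parameter;
  real proportions are sample-dependent and unknown).

A `class_contrast` parameter blends frozen renderings toward the liquid
appearance; it exists solely to stress-test classifiers and is 1 (nominal)
everywhere else.

What the generator does **not** emulate: physically accurate birefringence
(no ray tracing, no polarization optics), droplet deformation, freezing-front
propagation within a droplet, droplet coalescence or overlap, illumination
drift, and camera artifacts beyond additive Gaussian noise. Consequently,
passing tests demonstrate correctness of the counting/classification
machinery under the stated morphological contrasts — not performance on any
particular real instrument, where contrast and noise structure differ.

Ground truth (per droplet: state, binary label, diameter, trajectory) is
carried alongside every stack and round-trips through JSONL.

## Detection and tracking

The detector's goal is bookkeeping: count every droplet exactly once.

- Background: per-pixel median over ≤200 evenly sampled frames (exact when
  droplets cover a pixel <50 % of the time; see above).
- Segmentation: `|frame − background|` thresholded at 8 intensity levels
  (≈3 σ of the default sensor noise), binary closing (radius 3; frames are
  edge-padded first because scipy's closing otherwise erodes objects away
  from the image border and edge-straddling droplets would lose their
  `partial` flag), hole filling, connected components. Components touching
  the upstream/downstream edges are flagged partial and exempted from the
  size/circularity filters (a clipped droplet fails both by construction);
  full components must have equivalent diameter in [25, 55] px and
  circularity `4πA/P² ≥ 0.6`.
- Tracking: greedy nearest-neighbour assignment inside a gate of half a
  nominal diameter around the position predicted by a constant-velocity
  prior; gaps up to 2 frames are bridged; partial regions never join tracks;
  tracks shorter than 3 observations are discarded. Droplets are counted as
  completed tracks, so a droplet is counted once even though it is detected
  in ~5 frames, and partial appearances at the ROI edges are never counted.
- Crops: one per track, taken at the observation nearest the ROI centre,
  side 2.5× the droplet diameter (rim context included), padded with the
  background median where necessary, normalized to [0, 1] on the dtype scale
  (not min–max, which would amplify noise in low-contrast polarized crops),
  and resampled to 64 × 64.

At a 90° analyzer angle, liquid droplets produce no background contrast and
are not detected; total counts from fully crossed polarizers are therefore
unusable, which is why the polarized workflow assumes 60–85°.

## Classifiers

*Dual-threshold (polarized).* The statistic is the mean intensity over the
droplet disk at the crop centre (the disk mask makes it independent of crop
background; a max-over-disk variant is available). Calibration places the
high threshold at the midpoint between the 99th percentile of liquid
references and the 1st percentile of bright-frozen references, and the low
threshold symmetrically against dark-frozen references (disabled when none
are given). Overlapping reference distributions or a <95 % self-check raise
an error — the method refuses to calibrate rather than silently degrade.
Ties at a threshold are scored liquid (frozen requires strict exceedance).
Recalescent droplets fall between the thresholds and are scored liquid; this
single mechanism reproduces the undercount of polarized thresholding against
ground truth.

*Trainable classifier (bright field).* Eleven fixed features per crop: disk
mean/std, interior mean/std, annulus mean, interior-annulus and
disk-background contrasts, the 10–90 percentile spread, and the mean/std of
the high-frequency residual inside the disk plus its background reference.
Training crops come from videos whose temperature implies their label
(expected f of 0 or 1); augmentation (flips along the flow axis, ±2 px
shifts, ±8 % scale jitter, intensity jitter) at least doubles each class.
The default backend is a regularized logistic regression on standardized
features: with a few hundred perfectly separable training crops,
gradient-boosted trees (available via config) tend to split on whichever
single feature happens to separate the training set — in testing this was
the disk-std, which drifts with droplet-radius estimation error and produced
~1 % confident false negatives; the linear model weighs all cues and showed
0–1 errors per 2000 droplets. A stratified 20 % held-out accuracy is stored
in the model metadata, and models serialize to a joblib bundle with a JSON
sidecar. Training is per experiment, by design: background level and
alignment differ between experiments, and retraining on the experiment's own
extreme-temperature videos absorbs that.

## Curve analysis

Temperature points pool replicates at identical temperatures by summing
counts. Curves are reported raw (warm → cold); expected curves are monotone,
and observed violations beyond 3 combined binomial standard errors are
flagged, never corrected (isotonic smoothing exists behind an explicit call).

Onset temperature is the warmest temperature where the interpolated f(T)
reaches a threshold, default f_on = 0.05 ("onset" has no universal
operational definition; the threshold is explicit and configurable, and curve
comparisons always use the same definition on both curves). Crossings are
located with a monotone PCHIP interpolant through the bracketing
neighbourhood (plain linear for two-point curves). Treatment shifts are
temperature differences at a matched fraction (default f = 0.5), positive
when the second curve is colder.

Sampling-design note: the default population's class-C truncation at −7.5 °C
puts a corner in f(T) close to the f = 0.5 crossing. Curves sampled on a
coarse temperature grid alias that corner differently depending on grid
phase, biasing any interpolated crossing by up to ~0.03 °C; the end-to-end
treatment-shift check therefore samples at 0.1 °C, which resolves the corner.

## FTIR amide-I deconvolution

The 1600–1700 cm⁻¹ window is fit as a sum of 1–8 Gaussians plus a linear
baseline, by bounded nonlinear least squares. Initial peak centers come from
second-derivative minima of a Savitzky–Golay-smoothed spectrum (≈8 cm⁻¹
window) — overlapping bands keep distinct curvature minima long after their
sum merges — with an even-spread fallback. Convergence to a local optimum is
detected by comparing the residual RMS against 2× a high-frequency noise
estimate of the data; the fit then restarts from an even-spread and from
deterministically jittered starts (up to 5). An identifiability flag is
raised when any parameter's standard error exceeds 10× its magnitude
(heavily overlapping or superfluous peaks). Peak area is
`amplitude · sigma · √(2π)`; structure fractions are area ratios within
assignment windows, which default to common amide-I literature ranges
(β-sheet 1612–1643, helix 1643–1662, turns/antiparallel 1662–1696 cm⁻¹) and
are explicitly *not* calibrated values — set them for the solvent and
instrument at hand. The synthetic generator samples at 0.5 cm⁻¹, the typical
stored data spacing of a 4 cm⁻¹-resolution instrument after zero-filling.

## Reproducibility and problem sizes

Every stochastic step takes a seed; the experiment pipeline derives all
per-stage seeds from one master seed, and reruns are byte-identical (the
manifest records a curve-CSV hash). The simulator draws its layout/truth,
rendering, and noise streams independently, so the same seed produces the
same droplets and labels in bright-field and polarized mode — matched-mode
comparisons depend on this.

The test suite runs desk-scale experiments: classifier benchmarking uses
300-droplet training and 500-droplet evaluation videos; full-pipeline
population recovery uses 12 temperatures at 2000 droplets each; the polarized
undercount check uses 10 videos of 250 droplets; count-level checks use
replicate simulations at 2000 droplets per point. These sizes were chosen as
the smallest at which binomial intervals are tight enough for the respective
checks to be informative.

## Known limitations

- The deterministic framework ignores cooling-rate and residence-time
  effects; comparisons across instruments with different cooling rates need
  care that this package does not provide.
- The detector assumes non-overlapping, roughly circular droplets in steady
  flow; it does not resolve overlaps or deformation.
- The renderer's polarized model is phenomenological (visibility ramp,
  additive gain), not optical simulation; analyzer angles between 85° and 90°
  interpolate a behaviour that a real system would show only qualitatively.
- Temperature is taken from stack metadata; there is no thermometry model or
  temperature-uncertainty propagation.
- FTIR fitting assumes Gaussian sub-bands on a linear baseline within the
  window; ATR correction and solvent-band subtraction are out of scope.
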