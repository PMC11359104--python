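# Methods

This note records the models implemented in `hivesense`, the parameters
that matter, the synthetic data the package is exercised on, and the design
choices made where the underlying procedure left room for interpretation.

## 1. Audio front end

A hive recording (nominally 8-bit unsigned PCM, 22,050 Hz, 30–90 s) is
reduced to a single 224×224 feature matrix in five steps:

1. **Low-pass filter.** Zero-phase Butterworth of order 10 at 2,500 Hz
   (`scipy.signal.sosfiltfilt`). Colony sound of interest lives below
   2.5 kHz; the zero-phase application avoids phase distortion of band
   energies and squares the magnitude response, giving ≫40 dB stopband
   attenuation at 5 kHz. Order and cutoff are configurable.
2. **Windowing.** Consecutive non-overlapping 10 s windows; the first is
   discarded (microphone start-up transients), trailing partial windows are
   dropped. A 60 s recording yields 5 windows; the minimum accepted
   recording (20 s) yields 1.
3. **STFT.** 1024-point transform, periodic Hann window, hop 256, frames
   centred by half-window zero padding. A 220,500-sample window therefore
   yields exactly 862 frames × 513 frequency rows (0–11,025 Hz in steps of
   22,050/1024 ≈ 21.53 Hz). This is the unique standard parameterisation
   consistent with the target 513×862 shape; the transform is an ordinary
   dense STFT — any sparse-FFT speedup would be an implementation detail
   with the same output.
4. **Crop and average.** Each magnitude matrix is cropped to its first 224
   rows (0–4,800 Hz) and 224 frames, and the crops are averaged
   elementwise into the mean response matrix `A`.
5. **Image mapping.** `A` is min-max normalised to [0, 1] and quantised to
   8 bits with half-up rounding (`floor(255·x + 0.5)`), making pixel values
   bit-exact across platforms. A constant matrix maps to an all-zero image.
   Min-max is used because the contract is a [0, 1] range; a mean-centred
   scaling cannot deliver that range.

The Mel display image is purely a visualisation: 128 triangular Mel bands
(HTK scale) over a 20 s excerpt starting at 0.2× the recording duration
(clamped to fit), dB amplitude floored at −80 dB relative to peak. The band
count and floor are display defaults, not analysis parameters.

## 2. Beegram and condition measures

The beegram is a 16-element vector of mean magnitudes over fixed
low-frequency bands of the *unit-normalised* `A` (the measure limits below
are calibrated on that scale). Only three band ranges are pinned by
calibration — band 0: 107–128 Hz, band 1: 129–149 Hz, band 15: 602–687 Hz —
so the 13 intermediate bands default to a contiguous near-uniform partition
of the rows between them (rows 7–27), overridable in configuration. Row
assignment follows row centre frequency (`row × 21.53 Hz`) and is capped at
row 30, the last of the 31 rows the beegram reads; by that rule the
107–128 Hz band is row 5.

Measures and critical limits (flags raised outside the stated band):

| measure | formula | critical |
|---|---|---|
| hunger `Bh` | (|b₀|+|b₁|)/2 | ≤ 0.3 or > 1.8 |
| growth `Bg` | mean of |b₂..b₇| | ≤ 0.1 |
| queen tone `Qt` | max(|b₁₁|,|b₁₂|) + |b₁₅| | ≤ 0.3 or > 0.8 |
| thermal `Th` | |b₇| | > 0.5 |
| swarming `Sw` | ¾·max|b₈..b₁₀| + ¼·max|b₁₁..b₁₄| | > 0.7 |

All five are positively homogeneous of degree 1 in the beegram, which the
property tests exploit.

## 3. Fuzzy annotation of sensor days

Temperature sets use a bounded sigmoid reconstructed as

    bs(x) = 1 / (1 + 9·exp(−4·ln3·(x − x_low)/(x_high − x_low)))

which is pinned to 0.1 at `x_low`, 0.5 at the midpoint and 0.9 at `x_high`
— the unique two-parameter logistic consistent with "close to 0 and 1 at
the bounds" (the printed formula is typographically corrupted). The
triangular form is the rising sigmoid up to `x_center` and the falling
complement beyond, peaking at ≈0.9. Parameters: cold = 1−bs(·; 0, 10),
disease = ts(·; 10, 15, 28), normal = ts(·; 15, 32, 38), hot = bs(·; 38, 42);
humidity dry = 1−bs(·; 0, 30), normal = exp(−0.004·(H−40)²),
wet = bs(·; 70, 85).

The 12-rule table is evaluated Mamdani-style: rule activation =
min(temperature membership, humidity membership) × influence modifier
(1.25 "plus", 1.0, 0.75 "minus"); per-class activation is the max over the
class's rules; the label is the argmax. The min/max choice is the standard
Mamdani t-norm/aggregation (the source procedure names neither); the
reported confidence is clipped to [0, 1]. One surprising mapping —
(disease-range temperature, dry) → class 2 — is preserved as specified.

Readings outside physical sensor plausibility (−20…60 °C, 0…100 %RH) are
gated to class 4 (outlier) *before* fuzzy inference; a daily batch with any
single out-of-range raw value is likewise class 4. Daily classification
uses arithmetic means per signal, with the fuzzified temperature taken as
the equal-weight blend of mean probe temperature and mean lid temperature
(the aggregation was not specified; the blend reproduces all reference
class examples).

## 4. Synthetic data

**Sensor days.** Each class has a day-level uniform envelope derived from
its verbal definition (probe base temperature, lid temperature or
lid-offset, humidity), plus hourly Gaussian jitter of σ = 0.5 °C / 2 %RH —
the DHT22 accuracy figures. Outlier days are normal-looking days with 1–3
readings corrupted to impossible values. Every generated day is
re-annotated by the fuzzy engine and redrawn on mismatch (rejection
sampling, capped at 1,000 rounds so envelope/rule inconsistencies surface
as errors rather than loops); generated labels therefore agree with the
annotation by construction. The default dataset size is 16,000 days per
class, matching the scale at which the sensor classifier was originally
balanced.

What this generator does *not* emulate: diurnal temperature cycles,
weather-driven humidity drift, probe placement effects, or correlated
sensor failures. Accuracy numbers on this data show that the training
pipeline recovers cleanly separable, envelope-structured classes — not
field performance.

**Audio.** Each acoustic class (queen-loss, weak, normal, early-swarm,
late-swarm) is a sum of harmonic stacks (fundamental + 2 harmonics at 0.3
and 0.15 relative amplitude, random phases) whose fundamentals sit on STFT
row centres inside the class's characteristic bands — e.g. the late-swarm
class fills 400–500 Hz, the weak class the 107–149 Hz hunger bands, the
normal class adds a 602–646 Hz queen-tone component — over a white-noise
floor of 0.01 full scale, peak-normalised to 0.8 and 8-bit quantised.
Placing tones on row centres makes band energy land deterministically in
the intended beegram bands. The generator reproduces band-level energy
structure only; real bee timbre, amplitude modulation and background noise
are out of scope, so image-classifier accuracies on this data demonstrate
the harness, not acoustic detection performance.

## 5. Stranded sensor classifier

One dense network per input size 72/96/120/144/168/192 (= 24·(probes+2)).
Default topology `input → h1 → 32 → 5` with ReLU hidden activations and a
softmax output, where h1 = input size for inputs ≤ 120 and 256 for larger
strands. These widths were chosen to reproduce the published trainable
parameter counts exactly: 12,581 (96-strand, ≈0.013 M) and 45,509
(144-strand, ≈0.046 M). Topology is overridable per strand.

Training recipe: Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−8), categorical
cross-entropy, batch 64, 100 epochs, no dropout, L1 (lasso) penalty
λ = 0.005 on each dense layer's weight matrix. The dataset splits 80/20
into train/held-out; 10 % of the training part provides per-epoch
validation metrics. Labels are the hard argmax of the fuzzy annotation.
One addition of this implementation: inputs are standardised by
training-set mean/std (stored with the model) — raw °C/%RH magnitudes with
lr 0.001 converge poorly. Training is deterministic for a fixed seed up to
floating-point reduction order.

The networks are implemented directly on numpy (float32): dense and small
convolutional layers with explicit backward passes and an Adam optimizer.
At these model sizes (≤ 50k parameters) a deep-learning framework adds no
capability the package needs.

## 6. Image classifier harness

The harness fixes data handling (80/20 split, batch training, per-epoch
validation, label smoothing where configured) and treats architectures as
pluggable builders. The built-in `compact` architecture — 8×8 average-pool
stem (224→28), one 3×3 convolution with 8 filters, ReLU, 2×2 max-pool,
dense 32, softmax 5 — is sized to train in seconds on a few hundred images
while still reading the band-position structure that distinguishes the
synthetic classes. Standard large architectures (resnet18/50,
inception_v3, wide_resnet40) have their documented hyperparameter knobs
validated (stride, dropout 0.2 — the printed "0.2 %" is read as
probability 0.2 —, label smoothing 0.1, depth 40/widen 4) but require a
registered builder; no full-scale CNN benchmark is in scope because the
original audio corpus is not deposited. Inference on the mean image of a
recording (mean-then-classify), not per-window voting.

## 7. Metrics

* Cross-entropy: L = −(1/N)·ΣᵢΣⱼ yᵢⱼ·log(ŷᵢⱼ) with predictions clipped at
  1e−12 before the log.
* Accuracy: diagonal sum of the confusion matrix over the total count (the
  printed lower-triangle index on the numerator contradicts the
  accompanying text; the diagonal reading is implemented).
* Convergence speed over epochs k…n: Σ(Accᵢ₊₁−Accᵢ)/(n−k+1), which
  telescopes to (Acc_n−Acc_k)/(n−k+1). The denominator is kept as printed,
  (n−k+1), rather than the natural (n−k). Reported at epoch breakpoints
  20/50/100, each rate taken from the previous breakpoint (or the first
  recorded epoch). Bands: >1 fast (possible overfit), (0,1] improving,
  ≈0 plateau, [−1,0) declining, <−1 underachieving.

## 8. Problem sizes and numerical choices

* The full-scale training check uses the default dataset (16,000
  days/class, 80,000 days total) on the 144-strand for 100 epochs — about
  three minutes per run on one CPU core — repeated over three seeds in the
  test suite. Unit tests use 200 days/class and ~10 epochs.
* The image-separability check uses 500 synthetic 30 s recordings (100 per
  class) and 20 training epochs of the compact architecture, preceded by a
  nearest-centroid sanity oracle on beegram vectors.
* Degenerate inputs are contracts, not errors: constant matrices map to
  all-zero images; single-class training runs log a warning; datasets too
  small for a validation slice validate on the training data itself.
* Rule-engine ties (equal class activations) resolve to the lowest class
  id via argmax; the same convention is used by the brute-force test
  oracle.

## 9. Known limitations

* Synthetic fixtures are structural stand-ins; no claim of acoustic or
  micro-climatic realism is made (no public corpus exists to validate
  against).
* The beegram's 13 intermediate band ranges are a documented default, not
  a calibrated fact; if calibrated band data surface they should be set in
  configuration.
* Whether the condition-measure limits apply to normalised or raw
  magnitudes is not stated in the source procedure; the normalised reading
  is implemented and recorded here.
* The 20 s Mel display excerpt rule is internally inconsistent in its
  source ("0.2X − 0.2X + 20 s"); the implemented rule is
  [0.2·duration, 0.2·duration + 20 s], clamped to the recording.
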