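# Methods

This note documents the models, numerical choices and deliberate
assumptions behind `ratseiz`, and what the synthetic-data tests do and do
not demonstrate.

## Segmentation and labeling

Time is measured in seconds from recording start; all intervals are
half-open `[onset, offset)`.  The 2-s segment grid is anchored at t = 0 and
the trailing partial window is dropped rather than padded — padding would
fabricate samples that feed every downstream statistic.  A segment is
ICTAL when its intersection with the union of annotated intervals is
*strictly* greater than 1.0 s; an overlap of exactly 1.0 s is BASELINE.
Annotations are recording-wide (seizure marks are not per-channel), so all
channels of one segment index share a ground-truth label, while predicted
labels remain per-channel.  Overlapping or touching annotation intervals
are merged on read, so labeling always works against a disjoint union.

## Features

- **Kurtosis** is the Pearson (non-excess) fourth standardized moment with
  no bias correction, the convention of the numerical toolbox this
  workflow originated in.  Gaussian background scores 3; rhythmic spike
  discharges score well above.
- **Spectral entropy** is the Shannon entropy of `|rfft(x)|²` normalized
  over the N/2+1 half-spectrum bins, divided by log of the bin count.  The
  un-doubled rfft power is used instead of a one-sided periodogram scaling
  precisely so that a flat-magnitude signal (unit impulse) attains exactly
  1.0 and the value is a clean 0–1 index; an on-grid pure tone attains 0.
  The raw segment is not windowed (windowing is configurable in principle
  but the 2-s segments are long relative to the 1–24 Hz band of interest).
  Degenerate inputs (constant / zero power) raise rather than return a
  boundary value, because the multiplex factor needs 1/H.
- **Line length** is the plain sum of absolute first differences, in
  microvolts.

## Scalogram and multiplexing

The continuous wavelet transform uses the analytic (complex) Morlet
`cmor1.5-1.0`; the frequency axis is a geometric grid of
`ceil(12·log2(24/1)) + 1 = 57` centre frequencies spanning 1–24 Hz, i.e.
12 voices per octave with both endpoints included.  The magnitude is
min–max normalized **per image** (the image is a relative energy map; no
cross-segment calibration is assumed), bilinearly resampled to 224×224,
and mapped through a 128-level jet colormap.  An all-zero segment maps to
the constant colormap-of-zero image.

The multiplex factor is a weight-normalized convex combination
`(w_K·K + w_H/H)/(w_K + w_H)`.  This specific arithmetic was an open
design choice; the convex form was adopted because it places pure-kurtosis
(1,0), pure-inverse-entropy (0,1), the 5:1 mixes, and equal weighting on a
single axis, and it reduces to the identity (factor 1) for K = H = 1.
Weights scale out: (a,a) behaves as (1,1).  The factor multiplies the RGB
image after colormapping, clipping at 1 — saturation is the intended
signal carrier (ictal segments saturate more) — and a pre-colormap variant
(multiply the normalized magnitude before the colormap) is available via
`iter_segment_images(stage="pre-colormap")`.

## Classifier

The backbone is pluggable.  The packaged default, `tiny-cnn`, is a small
network sized for CPU test runs: images are block-averaged to 32×32×3 and
centred; three 3×3 conv blocks (8, 16, 32 filters, ReLU, 2×2 average
pooling after the first two) feed a flattened, layer-normalized feature
vector into a 2-way softmax head.  Training is momentum SGD (momentum 0.9)
with batch size 15, at most 20 epochs and initial learning rate 1e-4 — the
published recipe.  Two choices make that small learning rate effective in
a from-scratch network: layer normalization fixes the feature scale
entering the head, and the head's parameters carry a learning-rate factor
of 20, mirroring the transfer-learning convention of boosting the
replacement classification layers relative to a pretrained backbone.  The
best-validation-accuracy parameters across epochs are kept (no early
stopping).  Inverse-frequency class weighting is available but off by
default.  An ImageNet-pretrained backbone can be registered through
`register_backbone("pretrained-imagenet", factory)`; the factory wraps the
pretrained feature extractor and only the replacement head is trained.

Training-window selection scans candidate windows (default 2 h, stepping
60 s) for an annotated-ictal fraction in the closed interval [1%, 10%] and
picks the qualifying window with the lowest clipped-sample fraction
(samples at the recording's amplitude rails) as a technical-quality proxy,
ties going to the earliest window.

## Seizure calling and matching

Within a channel, maximal runs of ≥ 2 consecutive ICTAL segments become
candidate intervals (hence no event is shorter than 4 s); isolated ICTAL
segments are interictal marks.  Candidates that overlap *or abut* across
channels merge into one event whose channel set is the union of
contributing channels — simultaneous multi-channel activity is one
seizure, and an abutting boundary is treated as the same discharge
crossing a segment edge.  A mark that falls inside another channel's event
is absorbed by that event rather than reported as interictal.

Matching is by overlap: a detection sharing positive duration with any
reference interval is a true positive.  Pairing is greedy in chronological
order for determinism (a maximum-weight matching would differ only in
pathological overlap patterns); several detections inside one reference
all count toward that one matched reference and add no false positives.
Sensitivity is matched references over references; the false-positive
fraction is FP over all detections; FP/h divides by recorded hours.

## Line-length comparator

The comparator's published description leaves its internals open, so they
are parameters with documented defaults: Daubechies-4 DWT with symmetric
boundary extension, detail coefficients at the single requested level
(levels 2–5), non-overlapping windows of 125/250/500 ms, and a threshold
of `mean + k·SD` (k = 5 by default) computed over a seizure-free baseline
interval of the same recording.  The coefficient series is treated as
uniformly spanning the recording when mapping windows back to seconds (the
symmetric extension makes it slightly longer than n/2^level).  Windows
above threshold are grouped with the same ≥2-consecutive/merging rules as
the image detector, on the window grid, and events shorter than the 4-s
scoring floor are discarded.  The parameter sweep evaluates all 12
level×window combinations and returns the argmax by seizure sensitivity,
ties broken by lower FP/h and then sweep order.

## Feature-selection GLM

`fit_segment_glm` fits a binary logistic regression (maximum likelihood,
IRLS via statsmodels) of segment label on kurtosis, entropy and line
length, reporting per-coefficient Wald p-values and LogWorth (−log10 p) in
the style of the statistical package the original analysis used.  Wald
rather than likelihood-ratio tests match that output format.  Constant
features are dropped with a warning; quasi-complete separation is flagged
(not fatal).  Segment metrics pool all channels.

## Synthetic EEG generator

The generator emulates the statistical structure the detector exploits,
not the biophysics:

- **Background**: 1/f^α noise (α = 1) plus a broadband noise floor (white
  fraction 0.5 of SD), scaled to 50 µV SD per channel.  The floor mimics
  the sensor/EMG wideband content of real recordings and keeps baseline
  spectral entropy high.
- **Seizures**: placed by a Poisson count at 14/h (the event rate observed
  months after injury in the target model, 95% CI ≈ 11–18/h), durations
  uniform on 4–60 s, non-overlapping with 10-s gaps and 5-s edge margins.
  Each is a spike-wave train at 5–9 Hz with ±10% per-cycle period jitter;
  one cycle is a difference-of-Gaussians sharp transient (σ = 6 ms spike,
  σ = 30 ms negative lobe) on a half-sine slow wave, with raised-cosine
  amplitude ramps.  Peak amplitude 400 µV; the background is attenuated to
  0.3× inside the event, since real discharges dominate the trace.
  Seizures are generalized (all channels, gains jittered 0.8–1.2) or, with
  probability 0.3, focal (full amplitude in one channel, 0.2× attenuated
  spread elsewhere).
- **Artifacts** (20/h): 0.2–1.0 s broadband high-amplitude bursts on a
  random channel subset, kept clear of seizures and *not* annotated.
- **Post-ictal suppression**: background halved for 8 s after each event,
  not annotated.

Annotations exactly cover the planted events, and a fixed seed reproduces
the recording bit for bit.  `validate_feature_separation` checks the
generated data delivers the assumed structure — mean ictal kurtosis above
baseline and mean ictal entropy below — before it is used to exercise the
detector.

**What the synthetic tests show, and what they do not.**  The generator's
seizures are stereotyped, stationary in morphology, and far above
background; the detector's perfect sensitivity on this material verifies
the machinery (featurization, multiplexing, training, calling, scoring),
not field performance.  Real rodent EEG varies across animals and
electrodes, contains ictal-interictal ambiguity, drifting baselines and
artifact classes the simulator does not model, and published sensitivities
on such data are materially below 1.  The comparator's weakness relative
to the image classifier on synthetic data should likewise be read
qualitatively, not as a measured effect size.

## Problem sizes and experiment design

The packaged experiment trains on a 20-min record simulated at 12/h with
4–20-s seizures — chosen so the annotated fraction (~5%) sits inside the
1–10% training-window criterion — and evaluates on a held-out 60-min
record under the default conditions.  These sizes keep a full run around
ten minutes on a single CPU while leaving ≥ 10 reference events for
event-level metrics.  The line-length sweep runs on the same held-out
record with a 4-s seizure-free baseline interval taken from the guaranteed
event-free recording head.

## Known limitations

- The exact wavelet, colormap and normalization of the original scalogram
  pipeline are unstated upstream; the defaults here are documented
  assumptions and configurable.
- `tiny-cnn` is a desk-scale stand-in for a large pretrained image
  network; inter-animal generalization questions cannot be studied with
  it.
- EDF writing uses 1-s records and 16-bit quantization; non-integer
  sampling rates must go through CSV.
- Event timing from the comparator is quantized to its window grid, so
  detected boundaries can be offset from sample-accurate onsets by up to
  one window.
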