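# Methods

`cyclesense` re-implements a wearable-sensor analysis of cycling activity:
tri-axial phone-accelerometer segments recorded at seven body positions,
fused with Garmin GPS/heart-rate tracks, are reduced to spectral band-power
features, screened for the most discriminative sensor placement, and
classified into uphill vs downhill riding.  The original recordings are
not publicly deposited; the package therefore ships a first-class
synthetic-data generator parameterized by the study's published per-class
statistics, and every claim the test suite makes is a claim about data
with exactly that statistical structure.

## Processing model

Each segment carries an irregularly sampled acceleration series (mean rate
142 Hz, instantaneous rate varying roughly 15–300 Hz) and a sparse track
(0.48 Hz) with speed, altitude, distance and heart rate.

1. **Quality control.** A segment is rejected when the sample standard
   deviation of its speed exceeds `qc_alpha` times its mean speed
   (default `qc_alpha = 0.5`), or when its mean speed is nonpositive.  The
   source study quotes only "a selected fraction" for this threshold; 0.5
   is our default, and the synthetic study fixture is constructed so that
   exactly the published number of segments (39 of 1293) fails it.  The
   sample (ddof = 1) convention is used for the speed STD.
2. **Uniform resampling.** Each axis is linearly interpolated onto a
   uniform grid with the same endpoints and sample count as the raw
   series.
3. **FIR low-pass.** A causal order-4 Hamming-windowed-sinc filter with
   unity DC gain.  The study pairs a 60 Hz cutoff with resampling *to*
   60 Hz, which cannot anti-alias (Nyquist 30 Hz); by default the
   effective cutoff is clamped to `0.45 * fs_target` (27 Hz), and
   `clamp_cutoff=False` restores the literal printed parameters.  The
   filter family is unstated in the study; windowed-sinc is our choice
   (standard, linear phase).
4. **Resampling to 60 Hz and modulus.** The filtered axes are resampled
   to the target rate and combined into the per-sample Euclidean modulus
   A(n) = sqrt(ax² + ay² + az²).  Filtering precedes the modulus: the
   modulus is nonnegative, and low-passing it would distort its mean
   level, whereas the recorded axis components are ordinary signed
   signals.

## Features

The feature vector of a segment is (PV₍₀,₃₎, PV₍₃,₈₎, PV₍₈,₁₅₎,
PV₍₁₅,₃₀₎, mean HR), where PV is the relative DFT power

    PV = Σ_{k∈Φ} |Y(k)|² / Σ_{k=0}^{N/2} |Y(k)|²

over a single spectrum per segment (no windowing or Welch averaging).
Band membership is half-open [fc1, fc2) with the final band closed at
Nyquist, so the four bands partition the spectrum and sum to exactly 1.

**De-meaning.** `segment_features` removes the segment mean of the
modulus before the DFT.  This is a deliberate, load-bearing choice: the
modulus is a nonnegative signal, every DFT magnitude of a nonnegative
sequence is bounded by its DC bin, and retaining DC would force the
⟨0,3⟩ Hz fraction of any realistic recording above ~85%.  The published
per-class tables report ⟨0,3⟩ fractions of 39–71% — values only a
de-meaned spectrum can produce — so the pipeline computes band powers of
the de-meaned modulus (`detrend=True`, configurable).  The `band_power`
primitive itself evaluates the quoted formula verbatim on whatever series
it receives, DC included.

## Synthetic data

Two generators share the published per-class parameter table (band-power
means/STDs in percent and heart rate in bpm for every position × class
cell, plus per-class slope statistics).

**Feature-level.**  Independent Gaussians per feature; band fractions are
clipped to [0, 1] and renormalized to sum to 1.  The renormalization
projects draws onto the simplex, which shifts the means only slightly
(under 2e-3 absolute for every study cell) but shrinks the band STDs by
the delta-method factor
`var(xᵢ/s) = σᵢ²(1-mᵢ)² + mᵢ² Σ_{j≠i} σⱼ²`.  The generator's analytic
first-order moments under this design (including the clip-at-zero
correction) are exposed as `synth.expected_feature_moments`, and the
tests assert sample moments against them.  A consequence worth
knowing: within-class scatter is slightly tighter than the printed STDs,
so classification accuracies on synthetic features are, if anything,
optimistic relative to data with the raw printed STDs.

**Raw-signal level.**  The acceleration modulus is built as an offset plus
a sinusoid mixture: ten spectral lines per band, placed on the segment's
DFT bin grid strictly inside each band (margins keep leakage from crossing
a band edge), with one-sided line weights summing to the drawn band
targets and random phases.  The offset is set 5% above the mixture's
crest, so the waveform is nonnegative by construction — it is a valid
modulus — and disappears downstream under de-meaning.  A fixed random
unit vector distributes the modulus across the three axes, so the
per-axis filtering commutes with the modulus reduction.

Because the downstream chain (irregular sampling, two linear
interpolations, the order-4 FIR) attenuates the upper bands slightly, the
generator runs a two-round calibration: it measures the band fractions of
the candidate waveform through the exact default chain evaluated at the
segment's own timestamps, and rescales the per-band weights
multiplicatively.  Delivered fractions match the drawn targets to ~1e-3,
comfortably inside the 0.02 tolerance the tests assert.

Timestamps use log-normal inter-sample intervals with sigma 0.35
calibrated to the 142 Hz mean rate (the study quotes the observed range
15–300 Hz; the exact jitter law is unknowable from the text and is the
module's choice).  Heart rate is a per-segment level drawn from the
class profile plus a first-order autoregressive fluctuation (phi = 0.9,
stationary std 1.5 bpm) sampled at the 0.48 Hz track rate.  Altitude is
exactly `slope/100 × distance` for a per-segment slope drawn from the
class profile, so the rise-over-run slope recovers the draw.  Speed is a
stable level with 4% noise, or — for the injected QC-fail segments — an
alternating ±85% swing whose sample STD robustly exceeds half the mean.
Segment duration is a free parameter (default 60 s; the study does not
state one) and the dataset layout places segments on one global timeline
with 2 s gaps, one accelerometer CSV per segment, a single track CSV and
a manifest.

What the generator does *not* emulate: pedaling biomechanics, broadband
measurement noise (the spectra are pure line spectra plus offset),
GPS trajectory noise, and any correlation between features beyond the
class structure.  Passing tests therefore demonstrate the pipeline's
correctness and the method's behaviour under the published statistical
structure, not performance on new field recordings.

## Placement criterion

For classes (k, l) at one position, in a plane of two features, the
criterion compares the Euclidean centroid distance D with the sum ST of
the cluster spreads, where a cluster's spread is the root-mean-square
Euclidean distance of its points to the centroid (rotation invariant;
reduces to the ordinary σ in 1-D; equals sqrt(σx² + σy²) for axis-aligned
scatter).  The study's normalizing denominator is not defined in its
text, so the package defines

    Z = (D − ST) / D,

which is dimensionless, bounded above by 1, invariant under rigid motions
and common rescaling, and positive exactly when the clusters are compact
and well separated — the only property the study states.  The raw
difference D − ST is available via `normalization="none"`.  Features are
not standardized before the criterion by default (the study plots raw
percent/bpm axes); a flag enables z-scoring, which is advisable when the
two features carry very different units.

On features regenerated from the published table, the lower-spine
position ranks first for the steep-class pair on both studied feature
pairs, reproducing the study's placement conclusion.

## Classifiers

All four families expose `fit(X, y)` / `predict(X)` on samples-by-features
arrays and are deterministic given (data, seed).

* **Two-layer network** — sigmoid hidden layer (S1 = 10 by default),
  softmax output, trained by full-batch gradient descent on the
  cross-entropy with a step-halving line search (initial step 1.0, at most
  150 epochs, relative-improvement stop 1e-8, small-uniform seeded
  initialization).  The study gives the architecture but not S1, the
  loss, or the optimizer; this is the simplest scheme that satisfies the
  probabilistic output contract, and the line search makes the training
  loss non-increasing by construction.
* **Gaussian naive Bayes** — per-feature normal densities with a variance
  floor; equal priors by default (the only Bayes classifier trainable
  from per-feature moments alone).
* **k-NN** — k = 5, Euclidean metric; vote ties break by smallest summed
  neighbour distance, then lowest class label.
* **Linear SVM** — soft margin, C = 1, binary tasks only.  The bias is
  folded into the weight vector through a constant feature, leaving a
  box-constrained dual solved by deterministic coordinate ascent
  (sweep tolerance 1e-10).  The kernel is unstated in the study; linear
  matches the near-linear two-feature class geometry.

k-NN, the SVM and the network z-score features internally from the
training data (mixed units, percent vs bpm); naive Bayes is
scale-equivariant and uses raw features.

## Evaluation

Sensitivity, specificity, accuracy, precision and F1 are evaluated
exactly from the confusion counts; any metric with a zero denominator is
reported as undefined (`None`), never as 0.  ROC curves group tied scores
into single operating points, which makes the trapezoidal area equal the
concordance probability with half-credit ties.  Leave-one-out
cross-validation refits the model once per held-out sample with no
caching; folds whose training set loses a class entirely are flagged and
excluded from both numerator and denominator.  Whether the study's
printed accuracies are resubstitution or held-out is not stated; the
report tables carry both resubstitution accuracy and the LOOCV error,
labeled explicitly, with LOOCV as the headline generalization measure.

## Problem sizes and numerical choices

The shipped study fixture matches the published bookkeeping: 1293
segments across seven positions, 39 speed-unstable, 1254 surviving QC.
Statistical tests use n = 10⁴ draws for moment recovery (4-standard-error
bands), n = 500 per class for the placement ranking and the
classification echo, 100 random segments (N ≤ 256) for the spectral
oracle at 1e-9, and 20–40-point toys for the classifier oracles
(finite-difference gradients at 1e-6 relative, dual objective at 1e-4,
exhaustive k-NN and LOOCV loops exact).  Unit-test segments use shorter
durations (4–10 s) where the check does not depend on length.

Known limitations: the linear SVM is binary-only (the 4-class task runs
the other three families); the generator's line spectra make individual
synthetic segments easier to classify than broadband field data; and the
criterion's normalization, the QC threshold, the filter family and the
training scheme are package choices where the study is silent — each is
configurable, and the defaults are documented above.
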