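# Methods

`eegdem` implements an EEG → spectrogram-image → CNN screening pipeline for
dementia (Alzheimer's disease, AD; frontotemporal dementia, FTD; cognitively
normal controls, CN), evaluated with strictly subject-disjoint
cross-validation, together with a synthetic cohort generator that makes
every stage testable without clinical data.

## Signal model and montage

Recordings are 19 scalp channels of the international 10–20 system
(Fp1 … O2, in a fixed canonical order that also defines image rows) plus two
ear reference electrodes (A1/A2), sampled at 500 Hz, in µV.  The interchange
format is 16-bit EDF with a fixed physical range of ±3276.7 µV, so one
digital count is exactly 0.1 µV; a headered plain-text matrix format exists
for desk-scale fixtures.  T7/T8/P7/P8 labels are accepted as aliases of
T3/T4/T5/T6; matching is case-insensitive.

## Preprocessing

Fixed order: re-reference → band-pass → burst rejection.

1. **Linked-ear re-referencing.** Each scalp channel minus the mean of A1
   and A2; the reference channels are then dropped.  Their absence is only a
   warning, since some acquisitions apply the ear reference in hardware.
2. **Band-pass.** Butterworth 0.5–45 Hz, applied forward–backward (zero
   phase).  The order is not dictated by the protocol; the default is 4, a
   common EEG choice, and it is configurable.  Note that a zero-phase
   order-4 design attenuates a 50 Hz line component by ~71 %, not >90 %;
   the filter's own frequency response is the contract the tests check.
3. **Burst rejection.** A windowed variant of ASR-style cleaning that honors
   the stated parameters (SD cutoff 17 on 0.5 s windows) without subspace
   reconstruction: per channel, a baseline scale in SD units is
   1.4826 × MAD of the samples in the calibration windows — the 50 % of
   windows with lowest RMS, which bursts cannot reach.  A window is removed
   outright when any channel's within-window SD exceeds cutoff × baseline;
   kept windows are concatenated in order.  `cutoff = ∞` is the identity.
   Removal (not reconstruction) matches a protocol in which flagged periods
   "are removed"; with a cutoff as high as 17 only gross artifacts trigger.

ICA-based component rejection requires a pretrained component labeler and is
out of scope; `apply_component_mask` accepts an externally computed
channels×channels projection so such cleaning can be injected.

## Spectrogram images

Each preprocessed recording is cut into non-overlapping 30 s epochs from the
start (20 per subject at the full 600 s; shorter recordings yield fewer, with
a warning, or uniformly spaced overlapping windows on request).  At 500 Hz
an epoch has 15,000 samples, giving an exact bin spacing of 1/30 ≈ 0.033 Hz.

The DFT is computed by a decimation-in-time Cooley–Tukey transform written
for this package: power-of-two lengths use the radix-2 even/odd recursion;
composite lengths split by their smallest prime factor (15000 = 2³·3·5⁴);
large prime lengths fall back to Bluestein's chirp-z algorithm.  Exact-length
transforms matter — zero padding would change the bin spacing.  A literal
O(N²) evaluation of the DFT sum serves as the oracle in tests (agreement to
1e−9 relative for all N ≤ 256 and for N = 15000).

Single-sided amplitudes (`2|X_k|/N`, with DC and Nyquist unhalved) for bins
with `f_lo ≤ k·fs/N < f_hi` form the raw 19 × W image; the default band
[0.5, 40) Hz yields W = 1185 columns (bins 15 … 1199).  Amplitudes are
normalized per image to the 1st–99th percentile (clipped; global bounds can
be fixed instead), mapped through a fixed 256-entry perceptually-uniform
monotone-luminance colormap (viridis) to RGB in [0, 1], and bilinearly
resized to 150 × 150 × 3 for the classifier (nearest-neighbour available for
ablation).  These images are one spectrum per channel, not time–frequency
spectrograms.

## Classifier

The CNN is three blocks of [3×3 conv (linear, valid padding) →
LeakyReLU(0.1) → 2×2 same-padded max-pool → dropout] with 32/64/128 filters
and dropout 0.25/0.25/0.4, then Flatten → Dense 128 (linear) → LeakyReLU(0.1)
→ Dropout 0.3 → Dense n_classes → softmax, trained with Adam (1e−3, batch
32, categorical cross-entropy) for a fixed number of passes (default 100).
Only the pooling layers are specified as same-padded, so convolutions use
the conventional valid padding and a 150×150 input reaches the dense layers
as a 17×17×128 feature map (150→148→74→72→36→34→17), 4,828,610 parameters
in the binary model.

The implementation is plain numpy (float32, im2col convolutions on BLAS,
hand-written backpropagation, verified against finite differences in
float64).  A deliberate consequence: training is bit-exactly reproducible
from the seed — initialization, shuffling and dropout masks come from one
seeded generator — which GPU frameworks do not guarantee.  Optimizer, batch
size and learning rate are not protocol-fixed and are configurable.  Class
weighting is off by default (the cohort imbalance is mild).

## Evaluation

Leave-N-subjects-out: each diagnostic group is independently shuffled
(seeded) and dealt round-robin into K = 5 subsets; fold k tests on the union
of the k-th subsets, trains on the rest.  Splits are made at the subject
level and every epoch inherits its subject's side, asserted per fold at the
image level.  Per-fold confusion matrices are summed into a pooled matrix;
accuracies are summarized as mean, sample SD (n−1), and a Student-t 95 %
interval `t_{0.975,K−1}·sd/√K` (this convention reproduces published
five-fold summary rows exactly; a normal-quantile option exists).  Per-class
precision/recall/F1 come from the pooled matrix with zero-denominator
entries flagged undefined and excluded from macro means; because the "total"
F1 of such tables is convention-dependent, macro, support-weighted, and
pooled-PR-harmonic aggregates are all reported.

## Baselines

For the classical-learner comparison, recordings are cut into 2 s epochs and
described by Welch relative band power: per channel, PSD (Hann, 1 s
segments, 50 % overlap — the within-epoch parameters are a package choice)
integrated over delta/theta/alpha/beta/gamma and divided by the channel
total, so the five values sum to 1 (95 features).  The canonical band
edges are delta 0.5–4, theta 4–8, alpha 8–13, beta 13–25, gamma 25–45 Hz;
the scheme is configurable.  Learners: gradient-boosted trees (one adapter
for the boosting family), RBF SVM on PCA scores, k-NN on PCA scores, and an
MLP whose single hidden layer is fixed at 96 units.  Hyperparameters are
chosen by a budgeted, seeded random search scored on a subject-disjoint
validation split carved from the training subjects; PCA and scaling live
inside the fitted pipeline, so no test statistics leak into fitting.

## Synthetic cohort

Each channel is the sum of (a) 1/f-shaped background noise (exponent 1,
RMS 5 µV), (b) five band-limited oscillations — band-pass filtered Gaussian
noise, not sinusoids, so the classifier cannot key on line spectra — with
per-band base RMS (delta 4, theta 3, alpha 4, beta 2, gamma 1 µV) scaled by
a class gain and a per-region weight, and (c) 1 µV white sensor noise.  The
19 channels are assigned to five regions (frontal 7, temporal 4, central 3,
parietal 3, occipital 2).  Class profiles: CN has posterior-dominant alpha
(occipital ×3, parietal ×2, temporal ×1.5); AD shows generalized slowing
(theta ×1.5, delta ×1.15, alpha ×0.65, beta ×0.8, with its residual alpha
still posteriorly weighted); FTD shows frontotemporal theta (×1.3, frontal/
temporal ×1.6) with milder alpha loss (×0.8).  Every subject additionally
draws one log-normal factor per band (and one for the background), SD 0.25,
so groups overlap spectrally as clinical cohorts do.  Artifact bursts
(1/min by default) are band-limited 1–30 Hz noise with raised-cosine
envelopes, RMS 20–30× the channel SD, 0.3–1 s, on all channels; blink
transients (2/min) are 0.3 s raised-cosine pulses of 100 µV at Fp1/Fp2
fading into the other frontal electrodes — large enough to be visible,
small enough (by design) not to trigger the cutoff-17 rejector.

Effect sizes are **artifact parameters**, not estimates of any clinical
dataset: they were calibrated once so that the default cohort is separable
by the pipeline at realistic, non-ceiling LNSO accuracy (the target window
is 75–95 %; a reduced 12-per-group AD/CN run lands at ≈93 %).  What a green
recovery test establishes is that the pipeline can extract class-conditional
spectral structure it is pointed at without subject leakage — not any
clinical effect size.  The generator has no biophysical forward model, no
interchannel correlation beyond shared regional gains, and no
ECG/EMG-realistic artifacts.

Everything is deterministic: subject i of a cohort draws from
`SeedSequence([cohort_seed, i])`, so cohorts are byte-identical across runs
and subjects keep their identity when a group subset is generated.

## Scaled-down testing

Two compromises keep the test suite inside a single-CPU budget, both
documented where they occur: the parameter-recovery acceptance test feeds
the CNN 32×32 (instead of 150×150) resized images, and trains 30 (instead
of 100) passes on a 12-subject-per-group cohort.  The chance band for that
test uses the number of test *subjects* (24), not images: epochs of one
subject are strongly correlated, and an image-level binomial band would be
dishonestly narrow.

## Known limitations

* The burst rejector removes windows; it does not reconstruct them, and it
  shares only its threshold parameterization with full ASR.
* The generator's group differences are stationary; drowsiness drift,
  eyes-open segments and montage faults are not modeled.
* The CNN is CPU-bound numpy; at the full 150×150/100-epoch setting a
  five-fold run on 88 subjects is an overnight job, not a test.
* EDF support covers continuous single-session recordings (identical
  sampling rate across channels, no annotations).
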