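# Methods

## Problem and pipeline

The package classifies 5-second segments of interictal (between-seizure)
scalp EEG into three groups: subjects with epileptic seizures (ES),
subjects with psychogenic non-epileptic seizures (PNES), and healthy
controls (CS).  Interictal EEG in all three groups is typically normal on
visual inspection, so the classifier must pick up distributed spectral
structure rather than visible discharges.

The processing chain is:

1. **Acquisition / ingest** — 19-channel recordings in the standard 10-20
   montage, read from EDF or an HDF5 array container and reordered to a
   fixed canonical channel order (Fp1, Fp2, F7, F3, Fz, F4, F8, T3, C3,
   Cz, C4, T4, T5, P3, Pz, P4, T6, O1, O2).
2. **Preprocessing** — polyphase resampling to 256 Hz, zero-phase FIR
   band-pass 0.5–32 Hz, segmentation into 1280-sample epochs overlapping
   by 50% (start offsets 0, 640, 1280, …; trailing remainders are
   dropped so the classifier input size never varies).
3. **Empirical mode decomposition** — each epoch channel is decomposed by
   iterative sifting; the first three intrinsic mode functions (IMFs)
   form a 19 × 1280 × 3 tensor per epoch.
4. **Classification** — a fixed convolutional network maps the tensor to
   ES/PNES/CS probabilities; performance is estimated by stratified
   5-fold cross-validation with a freshly initialized network per fold.

## EMD: algorithm and numerical choices

Sifting extracts one IMF at a time.  For the current signal, all strict
local extrema are located (a plateau of equal samples counts once, at
its midpoint — this keeps the extrema/zero-crossing count well defined on
quantized data).  Natural cubic splines through the maxima and through
the minima give the upper and lower envelopes; their pointwise mean is
subtracted, and the step repeats until the candidate satisfies the IMF
count condition (|#extrema − #zero-crossings| ≤ 1) and a Cauchy-type
convergence criterion

    SD = Σ(d_prev − d_new)² / Σ d_prev² < 0.2,

with a hard cap of 100 sift iterations per IMF.  Before spline fitting,
the two extrema nearest each end are mirrored across the signal edge;
this standard extension suppresses envelope end-swings without inventing
data.  Decomposition stops after 3 IMFs (the classifier's input depth)
or earlier when the residual becomes monotone; a channel yielding fewer
than 3 IMFs has its missing tensor planes zero-filled and logs a
warning.  Because every residual is formed by exact subtraction, the
reconstruction identity Σ IMFs + residual = input holds to machine
precision by construction, and is asserted to 1e-8 relative tolerance in
the tests.  Local orthogonality between components is a *tendency* of
the method, not a guarantee; the package reports a normalized
inner-product diagnostic but never asserts it.

Numbers that are this package's own choices (the method itself does not
fix them): SD threshold 0.2 and the 100-iteration cap (the classical
values of the original sifting literature), natural spline boundary
conditions, two-point mirror extension, and decomposition applied per
epoch (after segmentation) rather than per recording.

## Preprocessing choices

The band edges (0.5–32 Hz) and rates are fixed by the pipeline
definition; the realization is ours: a cascade of a windowed-sinc
(Hamming) high-pass with 0.5 Hz transition width and a low-pass with
8 Hz transition width, each a symmetric kernel applied once with reflect
padding — hence exactly zero phase.  Resampling uses polyphase filtering
with the rational rate ratio, anti-aliased by construction.  The
documented stage order is resample → filter → segment.  Amplitudes are
microvolts throughout; no normalization happens at this stage.

## The classifier

Input 19 × 1280 × 3 (channels × samples × IMF planes).  All kernels have
height 1: channels are processed independently until the flatten layer.

| layer | kernel / units | stride | padding | output | parameters |
|---|---|---|---|---|---|
| conv + ReLU | 64 @ 1×6 | 1×2 | same | 19×640×64 | 1,216 |
| maxpool | 1×2 | 1×2 | valid | 19×320×64 | 0 |
| conv + ReLU | 32 @ 1×3 | 1×2 | same | 19×160×32 | 6,176 |
| maxpool | 1×3 | 1×2 | same | 19×80×32 | 0 |
| flatten | | | | 48,640 | 0 |
| dense + ReLU | 128 | | | 128 | 6,226,048 |
| dense + ReLU | 32 | | | 32 | 4,128 |
| dropout 0.3 | | | | 32 | 0 |
| dense + ReLU | 16 | | | 16 | 528 |
| dense + softmax | 3 | | | 3 | 51 |

Total 6,238,147 learnable parameters.  The padding assignment (same /
valid / same / same) is the unique combination under which every strided
stage exactly halves the sample axis (1280 → 640 → 320 → 160 → 80); any
other assignment contradicts at least one printed intermediate shape.
Parameter counts are computed twice — closed form ((k·c_in + 1)·filters
for convolutions, (n_in + 1)·units for dense layers) and from the
instantiated network — and must agree layer by layer.

The network is implemented directly in NumPy (`emdnet._net`): im2col
convolutions lowered to BLAS matrix products, explicit backward passes,
inverted dropout, and Adam with bias correction.  A finite-difference
gradient check and a batch-invariance check guard the implementation.
Dense-layer activations are ReLU (the published description fixes ReLU
only for the convolutions; ReLU is the conventional default and is
documented here).  The three-way output uses softmax with categorical
cross-entropy.  Class codes are fixed: ES=0, PNES=1, CS=2; prediction
ties break toward the lowest code.

### Training settings and the small-sample stability caveat

Defaults mirror the published optimizer: Adam with α=1e-2, β1=0.9,
β2=0.999; batch size 32 and 50 epochs are package defaults (the source
states neither), early stopping off.  All randomness — initialization,
shuffling, dropout — derives from one user seed, so loss histories are
bit-reproducible.  The recorded per-epoch loss is the full-training-set
cross-entropy evaluated in inference mode at each epoch end (hence
exactly constant at learning rate 0).

α=1e-2 deserves a caveat: Adam's per-update step is approximately ±α per
parameter, while the big dense layer's weights are initialized at scale
√(2/48640) ≈ 6e-3.  At desk scale (a few hundred training epochs, tens
of optimizer updates) a single update can therefore move every weight by
more than its own magnitude, which in practice collapses the ReLU stacks
(we observed the second convolution going fully inactive within one
epoch).  With tens of thousands of segments and hundreds of updates per
epoch this regime can still anneal, but it is not reproducible at small
n.  Desk-scale experiments in this package therefore use
`desk_scale_train_config()`: α=1e-3 and 12 training epochs.  The library
default `TrainConfig()` keeps the published triple.

Optional per-(channel, IMF-plane) z-scoring of the input (training-set
statistics) is available behind the `normalize` flag, off by default;
the desk-scale synthetic experiments switch it on, since raw microvolt
inputs through a 6.2M-parameter dense layer otherwise produce very large
initial logits.

## Evaluation

Stratified 5-fold cross-validation, fresh seeded initialization per
fold.  Two granularities are implemented: `segment_level` (each epoch
assigned independently; the default, matching the 80/20-of-epochs
description of the original experiment) and `subject_level` (all epochs
of a subject on one side of every split; recommended for real data —
overlapping epochs of one subject are strongly correlated, and
segment-level splits therefore overstate generalization to new
patients).

Metrics are computed from the 3×3 confusion matrix via per-class
one-vs-rest TP/TN/FP/FN.  Accuracy is trace/total.  Micro averaging
pools the per-class counts; macro averaging takes the unweighted mean of
per-class values.  For single-label multiclass data the pooled false
positives equal the pooled false negatives, so micro precision = micro
recall = micro F1 = accuracy exactly — which is why a correctly
micro-averaged report shows four identical percentages.  Zero
denominators (a class never predicted) yield a defined 0 with a warning.

## Synthetic data: what it emulates and what it does not

The real cohort (42 ES / 42 PNES / 19 CS subjects) is not public, so the
generator produces seeded surrogate cohorts: per subject, 19 channels of
1/f^β background (β=1, spectrally shaped Gaussian noise) plus
class-dependent band-limited oscillations (Gaussian spectral bumps with
random phases), mixed at a configured oscillatory-to-background power
ratio (SNR) and scaled to 30 µV RMS.  Class profiles are deliberately
distinct fixtures — ES: 4 Hz and 16 Hz excess power; PNES: 10 Hz; CS:
weak broad alpha — chosen to be separable by spectral content, and *not*
claimed to model pathophysiology.  Presets: `easy` (SNR 3), `moderate`
(SNR 1), `hard` (one shared profile for all classes — chance level by
construction, used as the negative control).

The default desk-scale cohort is 4 subjects per class × 60 s, giving
276 epochs — chosen so a full 5-fold experiment (EMD plus training)
completes in minutes on one CPU core.  The true 42/42/19 imbalance can
be requested via `class_counts`.

What passing the synthetic experiments shows: the pipeline preserves
class-discriminative spectral structure through filtering, segmentation
and EMD, and the classifier can recover it; the shuffled-label control
shows the evaluation machinery does not leak.  What it does not show:
performance on real interictal EEG, where class differences are far
subtler than the synthetic profiles, artifacts exist, and inter-subject
variability dominates (which is why `subject_level` folding matters
there).

## Degenerate inputs and tie-breaks

Constant signals decompose to zero IMFs (residual = input); monotone
residuals end decomposition early; recordings shorter than one epoch
yield an empty epoch set with a warning (configurable to an error);
flat EDF channels are written with a widened physical range to keep the
scaling well defined; prediction ties break to the lowest class code;
zero-denominator metrics are defined as 0 with a warning.

## Known limitations

* The NumPy network trains on CPU only and is minutes-per-experiment at
  desk scale; it is not a general deep-learning framework.
* EMD is implemented in its classical single-channel form; ensemble or
  multivariate variants are out of scope.
* Subject-level folding with very few subjects per class cannot always
  hit exact global class proportions per fold.
* The generator's surrogate classes are spectrally separable on purpose;
  absolute accuracy numbers on synthetic cohorts say nothing about
  clinical accuracy.
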