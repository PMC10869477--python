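# Methods

This note documents the models, the synthetic data, the numerical
choices, and the open design decisions behind `seizadapt`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Seizure prediction is framed as discriminating **pre-ictal** windows
(within a horizon before seizure onset; positive class) from
**inter-ictal** windows (baseline activity; negative class) in
multichannel scalp EEG. Ictal and post-ictal time is excluded from both
classes. Three evaluation regimes matter:

* *multiple-subject*: windows from all subjects pooled, stratified
  train/validation/test split — measures in-distribution performance;
* *cross-subject (LOPO)*: train on N−1 subjects, test on the held-out
  subject, rotate — measures generalization to a new patient;
* *cross-subject with domain adaptation*: as LOPO, but the held-out
  subject's **unlabeled** windows participate in training as the target
  domain.

## Preprocessing

Defaults follow the standard clinical protocol: a 50 Hz notch
(second-order IIR, quality factor 30) and a 0.5–70 Hz band-pass
(4th-order Butterworth), both applied forward–backward for zero phase;
a 3600 s pre-ictal horizon; post-ictal exclusion of 3600 s (the
literature uses hour-scale exclusions; the duration is configurable
because protocols differ); non-overlapping 10 s windows tiled
left-to-right with partial trailers discarded; per-channel
z-normalization per window (constant channels map to zeros); class
balancing by uniform random under-sampling of the majority class; and
stratified splitting. Balancing is applied to the *training* portion
after splitting by default, keeping test distributions honest; a
balance-before-split mode exists for strict protocol reproduction.
Interval rules around each seizure onset t: `[t − horizon, t)` is
pre-ictal, clipped at the record start and at the previous seizure's
exclusion end; `[onset, offset + postictal)` is excluded; the rest is
inter-ictal. All intervals are half-open, in seconds from record start.

Recordings keep their native sampling rate; optional polyphase
resampling is available (the temporal kernel then spans a different
physical duration, which is why the window length in samples, T, is a
model parameter rather than a constant).

## Architecture

The classifier is a compact, interpretable three-block CNN in the
filter-bank-CSP tradition:

| stage | kernel | weights | output |
|---|---|---|---|
| temporal conv, F1 maps | (1, 128) | 128·F1 | (F1, C, T) |
| batch norm | | 2·F1 | |
| depthwise spatial conv, multiplier F2 | (C, 1) | C·F2·F1 | (F2·F1, 1, T) |
| batch norm + ReLU + avg-pool (1, 16) + dropout | | 2·F2·F1 | (F2·F1, 1, T′) |
| feature conv, F3 maps | (1, 64) | 64·F3 | (F3, F2·F1, T′) |
| batch norm + ReLU + avg-pool (1, 16) + dropout | | 2·F3 | (F3, F2·F1, T′/16) |
| flatten → dense → softmax | | (d+1)·N | N = 2 |

with T′ = T/16 and embedding dimension d = F3·F2·F1·(T′/16).
Convolutions are linear and carry no bias (batch norm supplies the
affine shift); temporal convolutions use same-padding. Before the third
convolution the F2·F1 pooled maps are stacked into the *spatial* axis of
a single-map tensor; the F3 kernels therefore hold 64 weights each
(64·F3 total) and are shared across the stacked maps. A per-map third
convolution would instead cost 64·F3·F2·F1 weights and is inconsistent
with both the intended weight count and the output shape
(F3, F2·F1, T′); the reshape reading is the only internally consistent
one and is the package's choice. Defaults F1=8, F2=2, F3=16,
dropout 0.25 follow the compact-CNN convention of this architecture
family; all are configurable. The dense layer includes a bias.

## Adversarial domain adaptation

All three objectives share the saddle structure

    min_{φ,F} L_task(F(φ(X_S)), y_S) + λ·L_domain,   max_D −L_domain

realized with a **gradient-reversal** node between the features and the
discriminator: the forward pass is the identity, the backward pass
multiplies the upstream gradient by −λ, so a single ADAM minimization
performs the two-player update. Domain labels are source = 0,
target = 1. All domain losses are batch means (an uninformative
discriminator scoring 0.5 yields exactly ln 2).

* **DANN**: D is an MLP (input → 128 → 128 → 1, ReLU, sigmoid output)
  on φ(x).
* **CDAN**: D consumes the flattened outer product φ(x) ⊗ F(φ(x))
  (feature-major, dimension d·c; with c = 2 the full map is always used
  — no randomized approximation is needed at this dimensionality).
* **CDAN+E**: each example's discriminator loss term is weighted by
  1 + e^(−H(p)), H the prediction entropy (natural log, 0·log 0 := 0);
  weights lie in [1, 2] for two classes, are used raw (not
  batch-normalized), and are detached so no gradient reaches the
  classifier through them.

λ follows the standard ramp 2/(1 + e^(−γ·p)) − 1 over training progress
p ∈ [0, 1] with γ = 10 (a constant-λ mode exists). Each step pairs one
source batch with one target batch, the smaller side cycling with
reshuffles.

**Batch-norm handling** (a genuinely open design point): source and
target pass the encoder *separately*, each normalized by its own batch
statistics, and both passes update the shared running statistics — the
same unlabeled-data usage a concatenated source+target batch makes.
Separate passes keep a λ = 0 run step-identical (in optimizer-updated
parameters) to supervised training, which pins down the reversal
semantics exactly. An alternative in which the target pass uses
eval-mode running statistics was rejected: early in training those
statistics are still moving, which destabilized the adversarial signal
in pilot runs.

## Training protocol

ADAM with learning rate 0.005, β₁ = 0.9, β₂ = 0.999; batch size 64
(unspecified in the protocol this follows; exposed in config). Training
stops at 500 epochs or when the validation loss has not improved on its
running best by more than 1e-4 for 20 consecutive epochs, and the
best-validation weights are restored. In the adapted regime the
monitored loss is computed on held-out *source* windows — target labels
do not exist at training time and are not part of the function
signature. For a fixed (seed, config, data) runs are bit-reproducible.

## Synthetic cohorts

Each subject's recording is a channel mixture of three components plus
seizure bursts:

* **pink background** (1/f spectrum), standard deviation `noise_sd`;
* a **narrow-band alpha-like oscillation** at `background_peak_hz`
  (Gaussian bump, σ = 1 Hz), gain `background_gain` — the main carrier
  of subject identity;
* a **class band component** in `preictal_band` with inter-ictal RMS 2.0
  whose amplitude is multiplied by `preictal_gain` (default 2, hence a
  4× power increase) during pre-ictal intervals;
* **ictal bursts**: broadband noise at 5× `noise_sd` during annotated
  seizures — enough structure for exclusion logic to matter; waveform
  realism is a non-goal.

Sources are mixed by a per-subject near-orthonormal matrix.
`shift_strength` s ∈ [0, 1] scales every between-subject dispersion:
background peak 10.5 ± 2.5·s Hz, background gain 1.5·(1 ± 0.8·s), noise
level 1 ± 0.5·s, class-band center 12 ± 1·s Hz (band width 8 Hz), and
mixing matrices interpolate from one shared matrix (s = 0) to fully
subject-specific ones (s = 1). Two properties were design goals: at
s = 0 subjects are identically distributed, and at s = 1 the class band
*overlaps* the dispersed background peak, so absolute in-band power —
the easiest discriminant — is confounded across subjects while a
subject-invariant contrast still exists. Without that overlap,
orthonormal mixing preserves total in-band power and cross-subject
transfer is trivially easy, which matches neither real EEG nor the
phenomenon under study. Seeds follow a spawn hierarchy
(master → subject → stream), so adding a subject never changes existing
subjects' data.

What the generator does *not* emulate: artifacts (EMG/EOG), electrode
drift and dropout, non-stationary background, realistic ictal
morphology, age/montage heterogeneity. Passing tests on these cohorts
demonstrate that the pipeline, the optimization, and the adaptation
machinery behave as designed under controlled shift — not clinical
performance on real EEG.

## Reduced-scale study conditions

The end-to-end study (acceptance tests and `scripts/acceptance.py`)
uses: 6 subjects, 4 channels, 256 Hz generation resampled to 128 Hz
after a 0.5–60 Hz band-pass (so 10 s windows give T = 1280), one
seizure per 2100 s record, a 1000 s pre-ictal horizon and 600 s
post-ictal exclusion (≈100 windows per class per subject; balanced to
~200 windows/subject), model F1 = 2, F2 = 2, F3 = 4 (embedding
dimension 80), batch 64, up to 6 epochs with patience 5, and 5 seed
replicates with matched fold seeds across methods. These sizes keep the
full 4-method LOPO comparison at interactive runtimes while leaving
enough windows for stable per-subject estimates; medians over replicates
absorb seed-level variance. The 1 h horizon arithmetic and the
full-scale window counts are checked separately at full parameter
values.

## Numerical choices and edge cases

* Temporal convolutions run via real FFTs (float32 throughout training);
  adjoints are exercised against finite differences.
* Batch-norm ε = 1e-5, momentum 0.1, biased batch variance in the
  running update.
* Decision threshold 0.5 on the pre-ictal probability for
  confusion-based metrics; ROC by threshold sweep; AUC by trapezoid,
  equal to the pairwise ranking probability with mid-rank ties.
* Single-class truth makes threshold metrics undefined: reported as NaN
  and flagged, never silently zero.
* Summary rows use the population standard deviation across subjects.
* LOPO with adaptation is **transductive** by default (the adapted
  subject's windows are the scored windows — they are unlabeled at
  training time, so no label leakage is possible and fold hash-overlap
  checks run in every fold); an inductive mode (adapt on half, score the
  other half) is available.
* EDF output uses 16-bit quantization with per-channel physical ranges;
  round trips are lossless up to one digital step.

## Known limitations

* The NumPy training stack is single-threaded and CPU-bound; it is
  sized for research-scale studies, not for the full CHB-MIT corpus.
* Only two classes are supported end to end (N = 2), matching the
  prediction task.
* No artifact rejection or montage re-referencing; recordings are used
  as stored.
* Adversarial training at very small batch or epoch counts can be
  unstable; the study conditions above were chosen inside the stable
  regime observed in pilots.
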