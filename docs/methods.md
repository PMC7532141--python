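# Methods

## Model

The classifier is a 1-D fully convolutional network over `[channels, time]`
tensors.  Its computational unit is the *dilated causal convolution*: output
`y[t] = Σ_j w_j · x[t − (k−1−j)·d]`, realised by left-padding the input with
`(k−1)·d` zeros so the sequence length is preserved and the dependency cone
is exactly backward-looking.  Dilation `d` spaces the kernel taps, widening
the temporal context without pooling; the receptive field of a stack is
`1 + Σ_i (k_i−1)·d_i·Π_{j<i} s_j` (the *span* of the dependency cone —
sparse tap patterns may skip positions inside it).

Blocks are densely connected: each block's `g` new channels (growth rate)
are concatenated onto its input, so features are reused rather than summed
as in residual networks.  A block is bottleneck-conv (`k=3`, `d=1`, width
`4g`) → ReLU → dilated conv (`k=3`, `d_i`) → ReLU → concat.  Per stage the
dilation schedule is `d_i = min(cap, 2^(i+2))` with `i` restarting at 0 in
every stage and `cap = 128`; with the default stage sizes (2, 6, 8, 4) the
6- and 8-block stages reach the cap.  The cap reflects that, at common
clinical sampling rates, contexts beyond a few hundred samples generalise
poorly.

Entry (plain conv `k=7` stride 2 → ReLU → max pool 3/2) and transitions
(average pool 2/2 → `k=1` conv, compression `θ=0.5`, no activation) are
deliberately *non-causal*: they aggregate locally and only the dense stages
carry the causal, dilated machinery.  The head is global average pooling
plus one affine map emitting raw scores; softmax/sigmoid live in the loss
for numerical stability.  No normalisation layers, no dropout.

### Defaults the architecture leaves open

Growth rate `g = 32`, bottleneck width `4g`, entry stride 2 with pool 3/2,
compression `θ = 0.5`, ReLU activations, a transition after *every* stage
(including the last, before global pooling), both block convolutions causal
with the schedule dilation only on the second — all standard dense-network
conventions, all configurable on `ModelConfig`.  A `k=1` convolution is
dilation-invariant, so assigning `d=1` to the bottleneck keeps the
per-stage schedule indexing well defined.

## Training

Adam (β = 0.9/0.999), batch 64, initial rate 1e-4 over 100 epochs at full
scale.  The loss is the head-matched cross entropy with label smoothing
`ε = 0.1` — for multiclass, `(1−ε)·CE(scores, y) + ε·CE(scores, uniform)`;
for binary/multilabel, element-wise BCE with targets relaxed to
`{ε/2, 1−ε/2}` — plus an explicit penalty `λ·Σ‖w‖²` with `λ = 0.01` over
**all** parameters (biases included), kept in the loss rather than folded
into the optimizer so the recorded loss is self-contained.  Gradients are
clipped by global L2 norm at 1.0.  The learning rate follows cosine
annealing with warm restarts at epoch granularity: cycle `j` lasts
`T0·mult^j` epochs (`T0 = 10`, `mult = 2`, floor `eta_min = 0`), and the
rate is exactly `lr_max` at each restart.  Smoothing amount, clip norm and
restart cadence are conventional values for these techniques; none is
modality-specific.

Desk-scale runs (the shrunk model with stages (1, 2), `g = 8`, used in the
examples, tests and acceptance script) use rate 1e-3 — the conventional
Adam rate for a ~10⁴-parameter model — with everything else unchanged.

The stack is implemented directly in numpy with hand-written backward
passes (convolution via per-tap strided slices and `einsum`, pooling via
sliding windows); Adam state, shuffling and initialisation all derive from
explicit `numpy.random.Generator` seeds, so two runs with the same seed
produce bit-identical parameter trajectories and histories on any platform.

## Featurization

**EEG.** Recordings are re-referenced onto the standard 22-pair transverse
central parietal bipolar montage (the pair list ships as editable data).
Each montage channel is resampled 250→100 Hz (polyphase, anti-aliased) and
framed with a 2000-sample Hann window hopped every 100 samples, *centred*
(the signal is zero-padded by half a window each side), giving
`1 + floor(T/100)` frames — 301 for five minutes; the alternative reading
of "overlap 100" as hop 1900 cannot produce that frame count and was
rejected.  Power spectra pass a 40-band triangular mel filterbank
(0–50 Hz), a floored log (`1e-10`, so silence stays finite) and an
orthonormal DCT-II keeping all 40 coefficients (coefficient 0 is kept as
is), stacking to `22 × 40 = 880` channels.

**ECG.** The lead is resampled to 125 Hz and split into non-overlapping
10 s windows, each min–max normalised to [0, 1] (zero-range windows are
skipped with a warning).  R-peaks are local maxima above 0.9 of the
normalised range with a 0.36 s refractory gap, detected on a 3-sample
moving average of the window so single-sample noise cannot drop a genuine
peak below threshold (beats are cut from the unsmoothed window).  Each beat
spans 1.2× the window's median R–R interval from its peak, truncated or
zero-padded to 187 samples; a single-peak window has no R–R interval, so
the beat is cut at 187 samples directly.

**EHR.** An episode's (timestamp, feature, value) rows are bucketed onto a
uniform grid of 256 bins of 2 h anchored at the first observation; the last
observation inside a bin wins, gaps are forward-filled and leading gaps take
the per-feature default 0 (features are assumed standardized, so 0 is the
population mean).  The 76-name feature catalog mirrors the usual ICU
benchmark layout (vitals, coma-scale levels, numbered labs) and is
replaceable.  Re-binning an already-gridded episode is a no-op.

## Synthetic data

The generators are statistical stand-ins that exercise each pipeline
contract — they are not physiological simulations (no dynamical heart or
brain model, no artifacts, no inter-subject variability), so passing tests
demonstrate the *mechanics* (shapes, causality, multi-scale learning,
detector recovery), not clinical performance.

* `gen_multiscale` — class `c` is a sum of a short-period (12 or 20
  samples) and long-period (160, 240, 192 or 320 samples) unit sinusoid
  with random phases plus i.i.d. Gaussian noise (`σ = 0.3` default).
  Classes tile a (short, long) grid, so neighbouring classes share one
  scale and all four are separable only with both; every long period is at
  least 8× every short one.  `gen_long_scale_pair` keeps the short
  component fixed and varies only the long period (160 vs 240) — a probe on
  which a kernel-3 undilated single-layer baseline stays near chance while
  the dilated model separates cleanly.
* `gen_ecg_like` — Gaussian-bump R-peaks (class-coded rate and width) at
  jittered intervals on Gaussian noise, with the planted peak indices
  returned as annotations.
* `gen_eeg_like` — per-electrode 10 Hz alpha plus 2 Hz slow activity whose
  amplitudes swap with the binary label, over the electrode set the montage
  needs.
* `gen_ehr_multilabel` — independent Bernoulli labels; each label shifts a
  disjoint block of three catalog features by the effect size after a
  random onset; observation times follow per-feature Poisson processes
  (every feature is observed at least once).

All generators are pure functions of their spec; 1/f background noise is
deliberately absent by default (i.i.d. Gaussian is the simplest null the
tests need).

## Evaluation

Confusion-count metrics use the standard definitions (accuracy, per-class
one-vs-rest precision/recall/f1, macro f1); zero-denominator metrics report
0 and flag the class.  AUROC is the Mann–Whitney rank statistic with
tie-averaged ranks — identical to pairwise concordance with ties counted ½
— pooled over all (sample, label) pairs for *micro*, averaged per label for
*macro*, and positive-count-weighted for *weighted*.  Degenerate label
columns (no positives or no negatives) are excluded from macro/weighted
with a logged warning rather than scored 0.5; for binary tasks the reported
recall/precision are those of the positive (abnormal) class.

## Numerical choices and edge cases

* Non-causal convolutions use symmetric zero padding (left-biased for even
  totals) and preserve length at stride 1.
* Pooling is unpadded; an input shorter than the network's total
  downsampling chain raises at forward time, with the minimum supported
  length computed exactly by shape simulation.
* Max-pool ties break toward the earliest index (numpy argmax convention).
* `floor` in the transition channel count; compression 1.0 disables it.
* BCE uses the `max(s,0) − s·y + log1p(exp(−|s|))` stable form; log-mel
  energies are floored at 1e-10.
* A non-finite training loss aborts with the epoch index rather than
  continuing silently.

## Problem sizes

Tests and the acceptance script run the shrunk configuration (stages
(1, 2), `g = 8`, ~8k parameters) on 400 sequences of 512 samples for 30
epochs over three seeds, 50 seeded ECG generations and one 5-minute EEG
featurization — sizes chosen so the whole suite replays in about a minute
on a single CPU while still exercising every code path at the tensor shapes
the featurizers contract to produce.

## Known limitations

* The numpy implementation targets clarity and reproducibility, not
  throughput; full-scale benchmark training (10⁶-parameter default model,
  10⁵ samples, 100 epochs) is out of its intended envelope.
* The R-peak detector is a thresholded local-maximum rule, adequate for
  normalised single-lead beats but not a clinical-grade QRS delineator.
* EEG artifact rejection, 12-lead delineation and clinical-concept
  embeddings for coded EHR entities are out of scope.
* `min_input_length` grows with the number of stages; very short sequences
  need a shallower configuration.
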