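# Methods

This note documents the models, the synthetic study conditions, the numerical
choices, and the places where the design was genuinely open.

## Clip model and corpus standardization

All audio is mono, 16 kHz, in [−1, 1]. Recordings are standardized before any
mixing: files over 16 s are truncated to 16 s; files of at least 8 s yield two
independent random 4-s crops; files of 4–8 s yield one crop; shorter files are
discarded. The 8–16 s case is not separately constrained by the
standardization rules we follow, so it takes the two-crop branch (enough
material exists, and it maximizes data). "Independent" crops may overlap; crop
offsets are uniform over the valid range. Manual spectrogram screening is
replaced by an automatic energy gate: crops with RMS < 1e-4 are dropped.
Resampling uses a polyphase windowed-sinc filter (anti-aliasing built in);
multi-channel audio is averaged to mono.

Train/valid/test partitioning is group-aware: clips cut from one recording
always share a partition. Quotas come from largest-remainder rounding of the
7:2:1 ratios; shuffled groups (largest first) are greedily packed into the
partition with the most unfilled quota. When every item is its own group the
shares are exact (50,000 → 35,000/10,000/5,000). A group larger than the
largest remaining quota triggers a warning, not a failure.

## Synthetic songs and noise

Four species profiles span distinct bands: 1–2 kHz (nocturnal heron-like),
2.2–3.2 kHz, 3.5–5 kHz, and 5.2–7 kHz (diurnal wagtail-like). A song is a
sequence of Hann-windowed linear chirps whose instantaneous frequency is
clamped inside the band (a 5% margin keeps spectral leakage in band; weak
harmonics are added only when they fit under the band ceiling), with random
syllable durations, slopes and gaps per profile. Noise kinds: `wind`
(low-passed Gaussian noise with slow amplitude gusts), `rain` (broadband noise
plus exponentially decaying impulses), `insect` (an amplitude-modulated tone
placed at 3.5–6 kHz so it collides with the wagtail band). All generators are
bit-reproducible under a fixed seed.

What this corpus does *not* emulate: syllable syntax, amplitude modulation
within syllables, reverberation, overlapping conspecifics, or recorder
frequency response. Passing tests therefore demonstrate the mechanics of the
pipeline (mixing algebra, learnability of band-separated sources, contract
correctness), not field-grade separation quality.

## Mixing and normalization

Per mixture: N distinct species (N ∈ {2, 3, 4} by default), one clip each,
per-source SNR offsets i.i.d. uniform on [−5, +5] dB (the offset law is
otherwise underdetermined; i.i.d. uniform is the simplest consistent reading).
Weights act in the amplitude domain, `w_i = 10^(SNR_i/20)`. One scale factor
`0.9 / max(|mixed|, |data_i|…)` normalizes the mixture and every source, so
the clean references remain exact targets and the global peak is exactly 0.9.
Background noise is added after normalization, to the mixture channel only,
with RMS-based SNR against the bird mixture drawn from [−5, 10] dB; if the
noisy mixture exceeds full scale it is hard-clamped and flagged rather than
re-normalized (re-normalizing would silently detune the references). The
dataset builder applies noise to every mixture by default (`noise_prob` is
exposed); whether single-source "mixtures" are included is likewise exposed
(default: N starts at 2).

## Network

* Encoder: length-32 frames, stride 16, linear to 32 channels, ReLU
  (full-scale default: kernel 16 / stride 8 / 64 channels). The frame
  transform is initialized as a frequency-ordered cosine/sine filterbank
  (trainable): neighbouring channels are then spectrally adjacent, which
  makes the feature map meaningful to 2-D convolutions and gives mask
  learning a spectrally structured starting point.
* Separator: linear projection to a 48-dim hidden size, then dual-path blocks
  (2 at fixture scale, 6 at full scale): frames are chunked (50 frames, 50%
  hop); each block runs an Elman recurrence with a residual, layer-normalized
  projection first within chunks, then across chunks; chunks are reassembled
  by normalized overlap-add. Recurrences are unidirectional and
  hand-backpropagated (`avisep.nn.elman_scan`) for speed. The trunk output is
  deliberately *not* layer-normalized: per-frame feature energy is evidence
  downstream consumers need.
* Masks/decoders: per candidate count k ∈ {1..4}, one linear head emits k
  sigmoid masks over encoder channels and one transposed-frame decoder
  reconstructs k waveforms trimmed to the input length. Masks are independent;
  no constraint makes masks or reconstructions sum to the mixture.
* Counter: reads the encoder's frequency-ordered latent map. (The full-scale
  design reads deep separator features; at desk scale those only become
  count-informative after far more separation training than the fixtures can
  afford, while the frequency-ordered encoder map exposes which species
  bands are active from the start — the latent-feature contract covers
  both.) Baseline head = 1×1 conv (width 32) → global average pool → linear
  to 4 logits. Improved head = time-pooled (factor 8) single-channel
  time×channel map → [3×3 conv branch] ⊕ [3×3 dilated convs, dilation 2 then
  4] → channel concat → squeeze-and-excitation gate (reduction 4) → pooling →
  classification head, where pooling = per-channel mean/std/max statistics of
  the recalibrated conv maps plus an identity branch of the raw map at full
  time resolution (syllables are sparse; peak statistics carry band-presence
  evidence that averaging dilutes), layer-normalized, and the classification
  head is a small MLP (32 hidden units) — counting active bands is a
  threshold-and-sum that a linear readout of averaged activations cannot
  express. Branch depths, the SE ratio and the pooling statistics are our
  choices; the component list is fixed. Argmax ties break toward the smaller
  count (prefer under-segmentation).

## Training

Adam, initial learning rate 1e-3, decayed ×0.98 every 2 epochs; gradient-norm
clip 5; batch 16 at fixture scale. The joint objective is
`PIT-SI-SNR + 0.5 · cross-entropy` with the true count teacher-forcing the
decoder head. By default the count loss back-propagates into the shared
features (`TrainConfig.counter_backprop`; a detached mode is available). The
counter heads form their own optimizer/clipping group: clipping them jointly
with the much larger separation gradients would scale head gradients by
~5/50 and stall head learning (observed, and the reason for the split). PIT
assignment is exhaustive over k! ≤ 24 permutations. SI-SNR uses ε = 1e-8
regularization and a ±60 dB clamp so perfect reconstructions are finite.
Validation (when a validation set is supplied) selects the best checkpoint by
teacher-forced SI-SNR.

## Fixture scales

The corpus-scale experiments (50,000 4-s mixtures, 100 epochs) exceed a
single CPU; the package's experiments use quarter-second clips at 16 kHz and
the `SeparatorConfig.tiny()` model:

* **Separation recovery**: 500 train / 50 valid / 100 test two-band mixtures
  (1–2 kHz vs 5.2–7 kHz species), 30 epochs, no background noise. A
  quarter-second clip carries 2–4 syllables — enough for band-selective
  masking to emerge while one epoch stays near 6 s.
* **Counter comparison**: 500 train / 100 test half-second mixtures with
  N ∈ {2, 3} drawn from all four species, no background noise. Both heads
  read the frozen model's encoder map and are trained identically (same
  features, schedule and seed), then compared held-out. Half-second clips:
  at quarter-second scale too few syllables land in the clip for per-clip
  band evidence to be reliable (the paper-scale condition is 4-s clips; 0.5 s
  retains the evidence at an eighth of that). Noise-free: a −5 dB
  wind/rain/insect layer on clips this short removes the band-count evidence
  outright (even a direct band-energy oracle on the raw mixture drops to
  ~0.6), which would test the noise, not the counter.

## Detection-study generator

One recording of 1 min every 5 min, 15 4-s clips per recording → 180 clips per
hour; 6 days by default at one site. Truth presence per (clip, species) is
Bernoulli from hourly activity profiles: nocturnal bimodal (peaks 04–05 h and
19 h) for the heron-like species, dawn-biased (peak 06 h) for the wagtail-like
species. The raw strategy misses positives at an hour-dependent masking rate
(base 0.18, 0.40 through the dawn chorus, 0.30 at dusk) and adds false
positives (0.01 baseline; 0.35 per clip at 16–18 h for the wagtail,
emulating evening insect choruses). The separated strategy recovers each
missed positive with probability 0.4 (recall ≈ 0.83 vs ≈ 0.72 raw, matching
the magnitude of field-scale validation tables), keeps only 10% of raw false
positives, and adds one new false detection per ~f/(1−f) recoveries with
f = 0.12, so the measured VIR concentrates at 1 − f by construction.
Detection confidences are drawn in [0.7, 1): the tables represent
post-threshold output at the 0.7 operating point. Timestamps are ISO-8601
local; hour strata are clock hours [h, h+1). The VAR denominator is all
recorded clips in the stratum; the detection unit is (clip, species) —
multiple calls within one clip count once.

Wind speed is assigned no effect by default (its non-effect is a modelling
default, not an asserted result).

## Climate-response fits

Mixed-model machinery is deliberately out of scope (the random-effects
structure of the field analysis is unspecified); responses are fit as
fixed-effects cubic polynomials by OLS. The 95% CI at covariate value x is
`fit(x) ± 1.96 · sqrt(d(x)ᵀ Cov d(x))` with d(x) the design row — the
prediction-mean band, not a prediction interval for new observations. R² is
reported as 0 for a constant response (the usual formula is 0/0 there).
Coverage of this band is checked empirically over 500 simulated cubic
datasets (n = 60 each, Gaussian noise): mean pointwise coverage must land in
[0.90, 0.99].

## Ranking metrics

CMAP is the unweighted mean over classes-with-positives of per-class average
precision; AUC is macro-averaged over classes with both label values, with
midrank tie handling; lwlrap is label-weighted (each positive label
contributes one precision term; terms pool across clips), with average-rank
tie handling — this differs from scikit-learn's sample-averaged
`label_ranking_average_precision_score`, hence the in-package implementation.
Top-1 is the fraction of clips whose highest-scoring class is a true label.
The "mix + separation" strategy combines channels by per-class maximum:
order-invariant, threshold-compatible, and monotone (adding channels can only
raise scores).

## Known limitations

* The separation model is CPU-sized; its SI-SNR numbers on synthetic two-band
  mixtures say nothing quantitative about 30-species field mixtures.
* The band-energy classifier is a test oracle, not a species classifier; the
  classifier interface is where a trained model (e.g. an ECAPA-TDNN) plugs in.
* The detection-study generator draws clips independently across hours; it
  has no autocorrelation, weather coupling, or site random effects.
* Checkpoints store raw parameter arrays plus a JSON config; they are not
  portable across architecture changes.
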