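# avisep

Count-and-separate source separation for overlapping birdsong, with the
downstream ecological statistics that a separation front-end makes reliable.

## The problem

Passive acoustic monitoring (PAM) recorders collect months of single-channel
field audio in which several bird species often vocalize at once. Automated
species classifiers degrade on these overlapped clips: masked calls are missed
(false negatives at the dawn chorus) and loud non-target sound is
misattributed (e.g. evening insect choruses scored as a diurnal passerine).
Both failure modes bias the *vocal activity rate* (VAR) — the proportion of
fixed-length clips in a sampling period containing a target species — which is
the workhorse statistic for diurnal rhythms, climate-response and phenology
analyses.

`avisep` implements a dynamic **count-and-separate** framework for mixtures
with an *unknown* number of sources (1..N, N = 4):

* **Mixture simulation.** Supervised mixtures are built from single-species
  clips with per-source amplitude weights `w_i = 10^(SNR_i/20)`,
  `mixed[n] = Σ_i w_i · data_i[n]`, then jointly normalized with
  `scale = 0.9 / max(|mixed|, |data_1|, …, |data_N|)` so that the mixture
  *and* every clean reference peak at exactly 0.9 (no clipping, references
  stay aligned). Background noise (wind / rain / insect) is added to the
  mixture channel at a bird-to-noise SNR drawn from [−5, 10] dB.
* **Separation network.** A learned frame encoder lifts the waveform to a
  time–channel feature map; a stack of dual-path blocks alternates recurrent
  processing within and across chunks; per candidate count k, a head emits k
  independent sigmoid masks (nothing forces masks to sum to one) and a
  count-specific decoder reconstructs k waveforms of the input length.
* **Counter.** A classification head predicts the source count from the
  network's latent time–channel feature map (in this package the encoder's
  frequency-ordered map). The baseline head is a 1×1 convolution with global
  pooling; the improved head fuses a local 3×3 branch with a dilated-conv
  branch and recalibrates channels with a squeeze-and-excitation gate —
  better suited to the mid/high-frequency structure of birdsong.
* **Objective.** Scale-invariant SNR (SI-SNR) with permutation-invariant
  assignment:
  `SI-SNR(ŝ, s) = 10 log₁₀(‖αs‖² / ‖ŝ − αs‖²)`, `α = sᵀŝ/‖s‖²`,
  maximized over the k! output-to-reference permutations; the counter is
  trained with cross-entropy on detached features (teacher-forced counts
  select the decoder during training).
* **Ecology.** Detection tables → VAR per stratum, 30% stratified-sample
  precision/recall validation at a 0.7 confidence threshold, the valid
  increment ratio (VIR: among detections newly produced by separation, the
  verified-true fraction), diurnal curves, and third-order polynomial
  climate-response fits with 95% CIs from the coefficient covariance.

Everything runs on synthetic data: a generator renders band-limited chirped
songs for four species profiles (including a 1–2 kHz nocturnal-heron band and
a 3–7 kHz wagtail band), field-like noise, and a detection-study simulator
with known diurnal activity, masking and false-positive processes. The neural
components run on a small self-contained NumPy autodiff core (`avisep.nn`),
sized for CPU training.

## Worked example

```python
import numpy as np
from avisep.experiments import separation_recovery

result = separation_recovery(seed=0)   # ~8 min on one CPU core
print(round(result["untrained"]["improvement_db"], 1))
print(round(result["trained"]["improvement_db"], 1))
print(result["trained"]["count_accuracy"])
```

prints (seed 0)

```
-24.5
28.5
1.0
```

i.e. a randomly initialized model *destroys* 24 dB of SI-SNR relative to just
passing the mixture through, while the same architecture trained for 30 epochs
on 500 quarter-second two-band mixtures *improves* held-out mixtures by about
+28 dB SI-SNR, and its counter identifies the source count on every held-out
clip. The ecological side has an equivalent one-liner:

```python
from avisep import ecology as eco
study = eco.simulate_detection_study(seed=0)
print(eco.precision_recall(study["raw"], study["truth"], "white_wagtail"))
print(eco.precision_recall(study["separated"], study["truth"], "white_wagtail"))
print(round(eco.compute_vir(study["raw"], study["separated"], study["truth"],
                            species="white_wagtail"), 3))
```

printing

```
ValidationSummary(precision=0.5504555010511563, recall=0.7153916211293261, vir=None)
ValidationSummary(precision=0.9140980293077312, recall=0.8237704918032787, vir=None)
0.869
```

— the separated strategy's higher precision and recall, and a valid increment
ratio near 1 − (injected false fraction of 0.12).

A `click` CLI wraps the main workflows: `avisep synth`, `avisep mix`,
`avisep train`, `avisep separate`, `avisep count`, `avisep var`,
`avisep validate`, `avisep simulate-study`.

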