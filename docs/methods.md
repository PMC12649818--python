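# Methods

This note documents the modeling and numerical choices behind
seizurestack: what each stage computes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where the design was
genuinely open.

## Signal front end

**Normalization.** Each channel of a recording is independently z-scored
(population standard deviation) over the whole recording. The published
pipeline states only that signals are "normalized for consistent
scaling"; per-channel, per-recording z-scoring was chosen because it
removes both electrode-gain and patient-level amplitude differences
while leaving within-recording dynamics intact. Zero-variance channels
map to zeros rather than NaN. Normalization is idempotent.

**Windowing and labels.** Windows of `window_s = 8` s are cut every
`step_s = 4` s; counts obey `floor((T − W)/S) + 1` computed in samples.
A window's label is 1 when the fraction of it covered by the seizure
union reaches `label_threshold = 0.5`. The labeling rule is not
specified by the source protocol; the 0.5 default balances boundary
windows and is configurable because it changes class counts. Labeling is
monotone in the threshold. Annotation intervals are half-open
`[start, end)` seconds.

**STFT and spectrogram.** The transform is defined with the *absolute*
sample index in the complex exponential,
`X(t,k) = Σ_n x[n]·w[n−tR]·e^{−2πikn/N}`, and implemented as one FFT per
frame multiplied by the frame phase factor `e^{−2πik·tR/N}`; tests pin
agreement with the O(N²) double summation to 1e−9 relative error.
The taper is the *symmetric* Hann window with the `N−1` denominator,
kept exactly as printed in the source formula even though a periodic
Hann is more common in STFT practice; for `N = 1` the formula's
`cos(0) = 1` limit gives `[0]`. The spectrogram is `|X|²` with one-sided
bins `k = 0..N/2`. Within each 8-s window the default analysis frame is
`N = 256` samples (1 s at 256 Hz, 1 Hz bins) with hop `R = 256`, giving
an 129×8 image per window; the 50% overlap of the protocol lives at the
window level (8 s / 4 s), and `N`, `R` remain configurable. Channels are
collapsed by averaging per-channel power (a "stack" mode concatenating
channels along the frequency axis is available and recorded in the
dataset manifest); whether the source pipeline log-scales its images is
unstated, so `log(1+S)` compression is on by default for classifier
inputs and off for spectral analysis.

## Synthetic cohorts

The generator replaces clinical corpora in all tests. It emulates the
two dataset shapes the pipeline supports — continuous annotated
recordings, and pre-segmented labeled clips — with the statistical
structure the method relies on:

* **Background**: 1/f-amplitude ("pink") Gaussian noise plus an
  alpha-band sinusoid (`background_alpha_hz`, drawn per patient in
  9–11 Hz), scaled to a 30 µV RMS times a per-patient `noise_scale`.
* **Background nonstationarity**: intermittent non-ictal bursts
  (2–4× amplitude, 5–20 s, covering `burst_fraction = 0.15` of the
  recording, placed independently of seizures). Without them, total
  window power alone separates the classes and any classifier
  generalizes across ictal frequencies, which would make
  frequency-targeted personalization unmeasurable. With them, class
  information is carried by *where* the energy sits in the spectrum.
* **Ictal activity**: an added spike-wave train at `ictal_freq_hz`
  (default 3 Hz) — fundamental plus 2nd/3rd harmonics plus an
  exponentially sharpened per-cycle spike — with peak scale
  `(ictal_amp_gain − 1) ×` background RMS (default gain 4, so gain → 1
  degenerates to no added amplitude). Onsets/offsets are cosine-ramped
  over 1 s.
* **Inter-patient variability**: per-patient jitter of ictal frequency
  (±0.3 Hz), amplitude gain, alpha frequency and noise scale. A target
  patient can additionally be shifted out of distribution
  (`target_shift_hz`) for the personalization experiment.
* **Placement**: seizure intervals ≥ 10 s (so each seizure spans at
  least one full window), non-overlapping, ≥ 1 s apart, summing to
  `seizure_fraction × duration` (default 0.25), positions uniform given
  the gaps.

Defaults: 4 patients, 8 channels, 256 Hz (the common scalp-EEG
convention; pre-segmented exports emulate 500 Hz corpora by setting
`fs`), 600 s per recording. Everything is reproducible from integer
seeds.

What the generator does **not** emulate: physiological waveform
morphology, electrode montage geometry, EMG/eye-blink artifacts,
inter-channel propagation delays, seizure evolution (onset patterns,
postictal suppression). Tests passing on these cohorts therefore
demonstrate that the pipeline's machinery is correct and that the
two-phase protocol behaves as designed under controlled spectral domain
shift — not that any particular clinical accuracy would be reached.

## Models

The three backbones run on the package's own numpy reverse-mode
autograd engine (`seizurestack.nn`: grouped/strided conv2d via im2col,
batch norm, max/global-average pooling, dropout, Adam with coupled L2
weight decay; float64 throughout). Gradients are pinned against finite
differences in the test suite.

* **custom2dcnn** — conv 1→64 kernel (2,4) padding (1,2), then
  64→64→128→128→256→256 with 3×3 kernels, a 2×2 max-pool after every
  second conv, adaptive average pooling to 1×1, and FC
  256→128→64→1 with ReLU and dropouts (p = 0.25) after the first two FC
  layers. The intermediate conv plan is under-specified in the source
  (only "5 more conv layers with increasing channels (up to 256)"), so
  the doubling schedule above was fixed to make the printed FC widths
  exact; the printed kernel "(2.4)" / padding "(1.2)" are read as the
  tuples (2,4) / (1,2).
* **resnet18** — standard 18-layer plan (2 basic blocks per stage,
  64/128/256/512), 1-channel stem (k7 s2 p3), head 512→256→1 with one
  dropout (p = 0.25) after the hidden ReLU. Blocks compute
  `H(x) = F(x) + x` with `F = BN(Conv(ReLU(BN(Conv(x)))))` and **no
  post-addition ReLU**, following the printed residual mapping; this
  makes a zeroed-branch block an exact identity with input gradient
  exactly 1, which the tests verify.
* **efficientnet_b0** — the standard B0 MBConv plan (expansion 1/6,
  kernels 3/5, squeeze-excitation at ¼ of block input channels, swish
  activations), 1-channel stem (k3 s2 p1), head conv to 1280, global
  pool, dropout 0.2, and a single sigmoid unit.

`width_scale` multiplies every channel/feature width (minimum 1) and
exists solely so tests and demonstrations train in seconds; parameter
counts are monotone in it. Pretrained initialization is supported
through an explicit weight-file path (a 3-channel stem is collapsed to
one channel by averaging; heads are always freshly initialized) and
raises an explicit error when no file is supplied — tests never rely on
external weights.

## Training protocol

Phase 1 trains each backbone on all patients except the target, with a
chronological per-patient train/validation split (`val_fraction = 0.15`;
the source states only the 15% *test* fraction). Phase 2 fine-tunes all
layers (no freezing — the source does not state any) from the base
weights at `base_lr × finetune_lr_factor` (factor 0.1; the source says
only that the fine-tuning rate is "kept lower"). Optimizer, base
learning rate and batch size are unstated in the source and default to
Adam, 1e−3, 32 with weight decay 1e−4; all are surfaced in
`TrainConfig`. An optional positive-class weight in the loss exists but
is off by default. Mentioned-but-unspecified data augmentation is not
implemented.

Early stopping: improvement is a *strict* decrease of the validation
loss (ties and NaNs count toward patience, NaN with a warning); training
stops when the counter reaches `patience` (default 20, maximum 200
epochs), and the returned checkpoint always holds the
best-validation-loss weights along with the full per-epoch history
(train/val loss, accuracy, precision, recall, F1, AUC — exportable as
CSV).

The target's windows are split chronologically *within each class*
(largest-remainder allocation of the floor(0.15·n) test and validation
quotas across classes, at least one window per class where possible):
the latest windows of each class form the test set. Plain chronological
cutting can leave a split without any seizure window; stratifying by
class preserves the no-leakage direction (later windows never inform
earlier splits) while guaranteeing evaluable splits.

## Ensemble

The stacking mode concatenates the three personalized models'
penultimate features (1600 dims at full width) and fits an L2-penalized
logistic regression (tolerance 1e−6) as the meta-model — on the target
*validation* split, never on windows the meta-model will be scored on;
the source does not state the meta-model's training split, and fitting
on training data the bases memorized would be optimistically biased. An
averaging mode (arithmetic mean of the three probabilities) is also
implemented because the source describes both combination styles; the
mode is recorded in every report. The decision threshold defaults to
0.5 with ties counting as positive.

AUC is the Mann–Whitney probability `P(s⁺ > s⁻) + ½P(tie)`; the
implementation (rank-based, via scikit-learn) is pinned against an
explicit all-pairs count to 1e−12 in the tests. Confusion-derived
metrics return 0 with an explicit flag when a denominator vanishes.
Published ensemble confusion counts (tp = 6503, tn = 18332, fp = 414,
fn = 416) imply accuracy 96.766%, precision 94.015%, recall 93.988% by
direct arithmetic — these differ at the third digit from the metric
table printed alongside them in the source; this package trusts its own
arithmetic and reports the derived values.

## Experiment sizes and determinism

The end-to-end experiments use 4-patient cohorts with `width_scale =
1/16` models and at most 12 epochs per phase: the in-distribution run
uses 2004-s recordings (~2000 windows, 500 per patient) and the
domain-shift runs (+2 Hz target) 1204-s recordings (~300 per patient),
three seeds each. These sizes were chosen so a full run finishes in a
few minutes on one CPU while keeping ≥ 10 seizure windows in every test
split. Every stage is deterministic given its integer seed (cohort
seeds, model-init seeds and shuffle/dropout seeds all derive from the
run seed).

## Known limitations

* The synthetic cohorts are spectrally stylized; no claim about clinical
  performance follows from them.
* EDF support is read-oriented (via mne) plus a minimal 16-bit writer
  for fixtures (integer rates, whole-second durations); EDF+ events and
  calibration editing are out of scope.
* The numpy engine is single-threaded per op and float64; it is sized
  for the width-scaled models used here, not for full-scale training.
* Batch-norm running statistics use the biased batch variance in both
  training and evaluation updates.
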