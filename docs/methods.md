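# Methods

This note records the models behind `deepbeat`, the assumptions they make,
the parameters that matter, and the choices taken where the design was
genuinely open. Empirical statements here are limited to what the test
suite and `scripts/acceptance.py` themselves compute.

## Synthetic PPG model

A simulated record is built in three stages.

**Beat timing.** Inter-beat intervals are drawn per rhythm and clipped to
the physiological range [60/220, 60/30] s:

* *Sinus*: intervals = (60/HR)·(1 + cv·z), z ~ N(0,1), with the
  coefficient of variation cv ≤ 0.1 (default range 0.02–0.08). This is a
  white, mildly jittered beat train.
* *AF*: intervals are i.i.d. gamma with mean 60/HR and shape chosen so the
  realized interval CV matches the requested `rr_variability`
  (default range 0.18–0.30) — a minimal model of the irregularly irregular
  AF pulse. A gamma law was chosen over a log-normal because the
  log-normal's heavy tail makes the *sample* CV of a 25-s record (≈ 40
  intervals) too dispersed to meet the generator's stated moment band; the
  gamma keeps right skew and serial independence while concentrating the
  realized CV. The shape uses a ×1.04 correction that compensates the CV
  shrinkage caused by interval clipping and the short record length, so
  realized ≈ requested.

Serial independence is a deliberate simplification: real AF shows weak
short-range correlation, and real sinus rhythm shows respiratory sinus
arrhythmia, neither of which is modelled.

**Waveform.** Each beat contributes a two-Gaussian template: a systolic
lobe centred at 15% of the interval (width 8%) and a dicrotic lobe at 45%
(width 12%) with amplitude ratio 0.35 — standard two-lobe PPG synthesis.
The pulse train is amplitude-modulated by
(1 + am_depth·sin(2π·am_freq·t + φ)) and offset by baseline wander
bw_amp·sin(2π·bw_freq·t + φ′). Defaults: bw_freq 0.25 Hz, am_freq 0.2 Hz
(respiratory band), bw_amp 0.3, am_depth 0.2; both phases are drawn per
record. Heart-rate defaults: sinus 50–100 bpm, AF 70–140 bpm (AF tends
faster).

**Corruption.** Additive i.i.d. Gaussian noise with standard deviation
`noise_factor × sd(clean)`. The canonical factor grid is
{0.001, 0.25, 0.5, 0.75, 1, 2, 5}. Ground-truth quality is a pure function
of the factor: ≤ 0.25 → excellent, 0.5–1 → acceptable, ≥ 2 → poor. No
motion artifacts, sensor saturation, or non-Gaussian noise are simulated,
so quality here is one-dimensional in a way real wearable data is not:
tests passing on this generator say nothing about robustness to motion
artifact classes the generator does not contain.

Determinism: each record derives its own integer seed from
(dataset seed, record index), so regeneration is bit-identical and
independent of chunking.

## Preprocessing

Fixed order: zero-phase 2nd-order Butterworth bandpass (0.5–8 Hz, covering
30–220 bpm fundamentals plus low harmonics) → anti-aliased decimation by
4 → cut into 25-s windows (stride = 25 s for evaluation, smaller stride as
training augmentation) → per-window min–max standardization to [0, 1]
(constant windows map to all zeros). At the 128 Hz device rate this yields
L = 800 samples at 32 Hz. Heterogeneous input rates are polyphase-resampled
to 128 Hz first so L never changes. Filtering precedes standardization so
slow drift cannot dominate the window range; the order is pinned by tests.

## Signal quality

Three label sources, in increasing cost:

* **Oracle** (simulated data only): the noise-factor thresholds above.
* **Rule-based score**: features are skewness, peak count (refractory
  distance = one 220-bpm interval, prominence ≥ 0.2), prominence CV, and
  clipping fraction (samples within 10⁻³ of 0 or 1). Excellent requires
  skewness > 0.6, 12–92 peaks, prominence CV < 0.5, clipping < 0.01; poor
  is declared when pulse structure is undetectable (skewness < 0.2, peak
  count outside 12–92, prominence CV > 0.9) or clipping > 0.1; otherwise
  acceptable. The skewness thresholds do the heavy lifting: PPG pulses
  point up, so a usable window is clearly right-skewed while standardized
  white noise has skewness ≈ 0 ± 0.09; a simple ">0" rule would pass noise
  half the time. Measured on the generator: the mean ordinal score is
  monotone non-increasing across the canonical factor grid, pure noise is
  rated poor in 100/100 draws, clean sinus excellent in 100/100.
* **Label propagation**: a standalone copy of the classifier's quality arm
  (trunk layers 1–3 + QA arm) trained on a scored pool — 1000 windows, the
  scoring protocol's size — with inverse-frequency class weights, then
  applied to the unscored remainder, returning a class and a max-softmax
  confidence per window.

## Denoising autoencoder

Encoder: three (conv k=5 → ReLU → maxpool 2) stages; decoder: three
(upsample 2 → conv k=5) stages with ReLU between, linear output. Latent
temporal length is L/8 = 100 < 800, enforcing compression. Desk-scale
default filters are 32/32/32 (encoder) and 32/32 (decoder): an earlier
32/16/8 bottleneck left most latent channels dead and starved the
transfer, while 32-channel maps denoise better and transfer better; the
published layer table this stands in for is not reproduced here, and all
sizes are config fields.

Training: Adam on MSE between the reconstruction of the corrupted window
and its clean counterpart. Corruption for pretraining uses the simulator's
own record-level noise followed by full preprocessing, so the autoencoder
sees exactly the input distribution the classifier will see. Learning-rate
schedule: if validation loss (10% holdout) has not improved for
`lr_patience` epochs, lr ← max(lr − 0.001, 10⁻⁵) — the decrement is read
as additive, pinned here because the prose it derives from is ambiguous
between additive and multiplicative. Full-scale defaults are 200 epochs
with patience 25; the desk benchmark trains 30 epochs on 1960 window
pairs, which already reduces held-out reconstruction error well below the
corrupted input's own error at factors ≥ 0.5.

## Multitask classifier

Trunk: hidden layers 1–3 replicate the encoder exactly (conv+ReLU+pool, so
transferred weights reproduce encoder activations bit-for-bit, verified to
< 10⁻⁶); layers 4–6 are conv k=3 → leaky-ReLU(0.1) → batch norm → dropout.
Quality arm: conv → ReLU → BN → dropout → two dense layers → 3-way
softmax. Rhythm arm: three conv blocks → two dense layers → 2-way softmax;
the 64-unit dense activation before the final classification layer is the
embedding used for projections. A 2-unit softmax is kept rather than a
single sigmoid. Library defaults use dropout 0.25; the desk benchmark uses
0.1 because at hundreds-of-windows scale the stronger rate prevents any
learning within the epoch budget.

Training: joint loss w_qa·CE(quality) + w_af·CE(rhythm), both weights 1 by
default (single-task: w_qa = 0), inverse-frequency class weights, Adam.
Checkpoint selection is by best validation weighted-macro F1 on the rhythm
task. Two optional mechanisms, both off by default and enabled by the desk
benchmark:

* **Warm restarts** — a fresh Adam state (and shuffle stream) each epoch.
  The restarted moment estimates shrink early steps, acting as an implicit
  per-epoch step-size anneal that stabilized late-epoch training in this
  regime.
* **Discriminative fine-tuning** — transferred encoder layers receive 0.1×
  the base learning rate. They remain trainable (and tests assert they
  move); the reduced rate protects pretrained features from being
  scrambled in the first noisy epochs.

Four ablation variants: {multitask, single-task} × {pretrained, random}.
Random variants never receive encoder weights (attempting it raises).

## Desk benchmark

Fixed study conditions, chosen once (records are their own subjects, so
record-level splits are subject-disjoint): 100-s records stratified evenly
over rhythm × canonical factor; labeled training 168 records cut with
12.5-s stride (1176 windows, the augmentation scheme); validation 140 and
test 175 records cut non-overlapping (560 / 700 windows — the validation
pool doubles as the checkpoint-selection set, so it is sized to keep the
per-epoch F1 estimate stable); unlabeled corpus 280 records (1960 pairs)
for pretraining; fine-tuning 10 epochs, lr 1.5·10⁻³, batch 64. These sizes
keep one full ablation sweep (3 variants × 3 seeds) plus pretraining
around 12 minutes on one CPU core; they are far below the million-window
scale the method targets, so absolute F1 values on the benchmark are not
comparable to published large-cohort figures. Roughly 2/7 of benchmark
windows carry noise at 2× and 5× signal sd and are unclassifiable by
construction, which caps attainable F1 well below 1.

**Measured outcome of the ablation.** On this benchmark the expected
ordering — pretrained multitask ahead of randomly initialized multitask
and single-task — does *not* emerge: across five model seeds the median
test F1 is 0.56/0.57/0.57 (pretrained-MT / random-MT / random-ST) at 3
fine-tuning epochs, 0.60/0.61/0.64 at 5, and 0.65/0.65/0.67 at 10, i.e.
the random single-task model is consistently at or above the others while
the pretraining contrast sits inside the ±0.04 seed-to-seed spread. A
linear probe shows the pretrained encoder's latent *is* more informative
than a random encoder's (0.79 vs 0.69 held-out accuracy), so the features
transfer; the advantage is simply not expressed when end-to-end training
from random initialization already succeeds on a test set drawn i.i.d.
from the same generator as the training set. The corresponding acceptance
test asserts the ordering as specified and therefore fails at this scale;
it is retained unmodified as an honest record. Where the advantage has
been reported, training data were two orders of magnitude larger and the
evaluation crossed devices and cohorts — conditions a desk-scale i.i.d.
synthetic benchmark cannot emulate.

## Metrics

One-vs-rest integer confusion counts; per-class sensitivity, specificity,
FPR, FNR, precision and F1 computed as exact rationals, so
sensitivity + FNR = 1 and specificity + FPR = 1 hold identically whenever
the denominators are nonzero. Zero-denominator convention: the metric is
reported as 0 with a logged warning (F1 is 0 when precision + recall = 0).
Weighted macro-averaging uses class supports; per-individual aggregation
computes each subject's support-weighted metrics and then weights subjects
by their window counts (the aggregation weights are not prescribed by the
source material; window counts are this package's choice). Accuracy is
deliberately not reported. Quality-filtered evaluation restricts to
excellent-labelled windows and reports the retention count and fraction;
zero retention is an error, not an empty report.

## Explanations

Class activation maps are gradient-weighted: the target-class logit's
gradient is taken at the last rhythm-arm convolution, channel weights are
the time-averaged gradients, the weighted sum is rectified, linearly
interpolated to L samples and max-normalized (all-zero maps are left
all-zero). Gradient weighting is required because the dense layers after
the convolutions preclude the classic global-average-pooling formulation;
the conv layer is configurable. Embedding projections use seeded UMAP
(n_neighbors capped at n−1; < 10 points is an error).

## Orchestration and determinism

One global seed fans out to per-stage seeds via SHA-256 of
(stage name, seed), so stages are independently reproducible. Containers
are HDF5 with `track_times` disabled plus a CSV manifest: regenerating
with the same config and seed is byte-identical, and retraining with a
fixed seed reproduces checkpoints exactly on a fixed thread count (the
whole stack is single-threaded numpy). Every run directory carries a
provenance file (config hash, seed, package version). Default split
fractions are 70/10/20 by subject.

## Known limitations

* The noise model is purely additive Gaussian; no motion artifact, no
  sensor dropout, no saturation.
* The AF interval law is serially independent; tachogram autocorrelation
  is not emulated.
* The pretraining advantage does not materialize on the desk benchmark
  (see the measured-outcome paragraph above); reproducing the published
  contrast would require corpus and compute scales outside this package's
  scope.
* The rule-based quality score is a surrogate calibrated on this
  generator, not a validated clinical signal-quality index.
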