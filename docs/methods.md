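# Methods

## Problem setting

Brain natriuretic peptide (BNP, pg/mL) is the standard blood biomarker for
tracking heart-failure (HF) severity, but it requires venipuncture and a
laboratory. `ecgtraj` implements a purely electrocardiographic alternative
for *monitoring change*: given two 12-lead ECGs of the same patient recorded
on different days, classify the interval as **improved**, **deteriorated**
or **no-change**, where the ground truth is defined from same-day BNP values:

    rel = (BNP_followup − BNP_baseline) / BNP_baseline × 100%
    improved      ⇔ rel ≤ −40%  and  BNP_baseline ≥ 100 pg/mL
    deteriorated  ⇔ rel ≥ +40%  and  BNP_followup ≥ 100 pg/mL
    no_change     ⇔ otherwise

Both inequalities are inclusive; exact-boundary pairs are classified as a
change. BNP enters all regression losses on the natural-log scale (a config
switch allows base-10; only the Pearson correlation is invariant to that
choice). Manifest rows with BNP ≤ 0 are rejected at load time — the rule set
is undefined there and assay floors should be resolved upstream.

Two networks share one architecture:

* **EBT** — single-ECG regressor of log-BNP (12 lead tokens);
* **DEHT** — dual-ECG three-class trajectory classifier (24 lead tokens:
  baseline leads in rows 0–11, follow-up in rows 12–23).

## Model

Each lead's 2 s window (1000 samples at 500 Hz) is encoded by the *same* 1D
residual CNN into one token, so encoder weights are shared across leads.
Because weight sharing makes the encoder permutation-equivariant over leads,
learned per-lead identity embeddings are added to the tokens, plus a learned
baseline/follow-up timepoint embedding in dual mode; without these the model
could not represent lead semantics or the direction of change. A learned
class token is prepended; the sequence passes through multi-head
self-attention encoder blocks; the encoded class token feeds a linear head
(1 output for log-BNP, 3-way softmax for trajectory classes).

Default configuration: 1D ResNet-50 (bottleneck blocks [3,4,6,3], 1D
convolutions over time, global average pooling, linear projection), 256-dim
tokens, 8 heads, 4 encoder layers. The `tiny` preset used for all desk-scale
experiments keeps the same layout at small width: a 3-stage residual CNN
(stem stride 4, two basic blocks, 32 channels), 64-dim tokens, 8 heads,
2 encoder layers. Encoder blocks are **pre-norm** (x + MHA(LN(x)), then
x + FFN(LN(x))) with a final LayerNorm before the head; in development the
post-norm variant showed a long warmup plateau under Adam without a
learning-rate schedule, while pre-norm trains stably from scratch.

The whole network, including reverse-mode gradients and Adam, is implemented
in NumPy (`ecgtraj.nn`); layer gradients are verified against central finite
differences in the test suite.

## Training protocol

Each optimization step draws a batch of samples, re-extracts a fresh uniform
random 2 s window per ECG (independent offsets for baseline and follow-up),
adds i.i.d. per-sample Uniform(−0.1, +0.1) mV noise, and takes one Adam step.
Noise and window randomization are disabled at evaluation; evaluation windows
are drawn once from a seeded generator. Losses: MSE on log-BNP (EBT);
cross-entropy with inverse-support class weights (DEHT) — the class mix is
imbalanced toward no-change, and unweighted training is prone to collapsing
onto the majority class early.

The learning-rate *search* (n log-uniform draws from [1e−7, 1e−3], scored by
validation loss after a short trial run from a common initialization) is
implemented and tested; the scaled-down experiments instead fix lr = 1e−3,
batch 16, ≤ 800 steps with validation-loss early stopping (patience 8 checks
of 50 steps, best-validation checkpoint restored), chosen once from pilot
validation-loss curves so one training run completes in minutes on one CPU.
Full-scale settings (batch 64, lr search) remain available via configuration.

## Evaluation

Per-class one-vs-rest metrics: precision, recall, specificity, F1 and
binary accuracy from argmax predictions; AUROC and AUPRC from the class
probability. "Weighted" aggregates average per-class values with weights
equal to true-class supports; overall accuracy is computed directly from
argmax. Thresholded and ranking metrics are computed with scikit-learn and
cross-checked in the tests against naive pair-counting/step-sum
implementations to 1e−9. To avoid over-representing frequently tested
patients, classification reports subsample one trajectory per patient
(uniformly, seeded) before computing metrics. All confidence intervals are
95% percentile bootstrap over evaluation samples (default 1000 resamples;
resamples on which a metric is undefined are redrawn).

## Synthetic cohort

Real ECG–BNP pairs of this kind come from restricted hospital records, so the
package ships a generator whose latent per-visit severity s ∈ [0,1] drives
both observables:

* BNP = exp(α + β·s + ε), ε ~ N(0, σ). Defaults α = ln 15, β = 3 give a
  median of ≈ 67 pg/mL and an interquartile range of ≈ 32–140 pg/mL over
  s ~ U(0,1), matching the scale of a mixed cardiology population; σ = 0.3
  by default.
* ECG beats are Gaussian-sum P/Q/R/S/T templates per lead (12 leads with
  fixed polarities, aVR and V1 negative), tiled at a per-visit heart rate
  (uniform 60–90 bpm) with multiplicative lognormal RR jitter (SD 0.04),
  plus sinusoidal baseline wander (0.05 mV, 0.15–0.4 Hz) and Gaussian noise
  (0.01 mV). Severity multiplies the R amplitude by (1 − e_R·s), Q/R/S widths
  by (1 + e_W·s) and the T amplitude by (1 − e_T·s) — a stylized low-voltage /
  wide-QRS / flat-T picture of worsening failure.
* Visits per patient are uniform on {2, 3, 4}; inter-visit gaps are lognormal
  with median 172 days (metadata only). Records are 15 s at 500 Hz, written
  as CSV in mV with ground-truth severities and R-peak indices in a JSON
  sidecar.

Effect presets: `moderate` (default: e_R = 0.3, e_W = 0.15, e_T = 0.3,
σ = 0.3) and `strong` (e_R = 0.5, e_W = 0.25, e_T = 0, σ = 0.1). The strong
preset deliberately confines the severity deformation to the QRS complex so
that recovery experiments and attention-localization checks share one trained
model with a known ground-truth locus of evidence.

What the generator does **not** emulate: arrhythmia, conduction disease,
vectorcardiographic consistency between leads, electrode artefacts,
medication effects, or any real covariance between heart rate and severity.
Passing the synthetic-recovery checks therefore demonstrates that the
pipeline can extract a morphology signal the generator encodes — not that
the models reach any particular performance on hospital data.

## Reference desk-scale experiments

Defined once in `ecgtraj.experiments` and shared by the tests and
`scripts/acceptance.py`; problem sizes were chosen so the whole suite runs on
a single CPU in minutes:

* **Recovery** — 200 patients, strong preset, patient-level 70/15/15 split;
  tiny DEHT and tiny EBT trained as above; DEHT evaluated one-per-patient on
  held-out patients, EBT on all held-out visits.
* **Chance floor** — identical training with labels permuted (train and
  validation); evaluated on all held-out samples with 3 independent window
  draws each (n ≈ 300) because the ±0.05 chance band is narrower than the
  AUROC sampling error at n ≈ 30.
* **Attention localization** — per-sample heatmaps = final-layer head-averaged
  class-token attention (one weight per lead, renormalized) × Grad-CAM at the
  last backbone feature map (channel gradients time-averaged, rectified,
  linearly upsampled to 1000 samples), fused row-wise and max-normalized.
  QRS peaks are detected per timepoint on lead II with a Pan-Tompkins-style
  detector (5–15 Hz band-pass, derivative, squaring, 150 ms integration,
  adaptive signal/noise thresholds, 200 ms refractory, ±50 ms |signal|-max
  refinement); every R–R segment is linearly resampled to a 500-sample beat
  grid (1 s at 500 Hz) and beats are averaged per class. Localization is
  summarized by the mean heatmap value within ±60 ms of the beat-grid R
  positions divided by the mean elsewhere.
* **QRS recovery** — detector recall against generator ground truth within
  ±20 ms on noiseless records.

## Numerical choices and edge cases

* Window extraction is a pure slice (no filtering/resampling); a record
  exactly one window long forces offset 0.
* The 150 Hz acquisition low-pass is treated as a property of the recorder
  and never re-applied.
* ECG CSVs store mV with fixed 6-decimal formatting — bit-exact round trips;
  the `counts` dialect calibrates integers at 1.25 µV per count.
* Split sizes use largest-remainder rounding (deterministic, within one
  patient of the exact fractions); the split permutation is seeded.
* RR normalization maps each R–R interval [r0, r1) onto 500 samples via
  linear interpolation at r0 + (r1−r0)·k/500, so a 500-sample interval is
  returned unchanged and constant maps are fixed points.
* Attention capture defaults to the final encoder layer's class-token row,
  averaged over heads and renormalized; a config switch averages layers
  instead. Grad-CAM for the regression head targets the scalar output.
* The tiny-preset capacity check fits 32 *fixed* windows (2 s records);
  with per-step re-windowing of 15 s records the same check measures
  cross-window generalization and converges several times slower.
* `init_deht_from_ebt` (warm-starting the classifier from a trained
  regressor's backbone and encoder) is provided but off by default; both
  models train from scratch in the reference experiments.

## Known limitations

* The NumPy implementation is single-threaded BLAS-bound; the full-scale
  ResNet-50/256-dim configuration is validated for correctness (shapes,
  forward determinism) but not trained end-to-end here.
* The synthetic severity-to-morphology map is monotone and noise-free by
  construction, so recovery numbers are an upper bound on what the same
  pipeline could achieve under label noise of clinical origin.
* Bootstrap CIs resample evaluation samples after the one-per-patient
  subsampling; they do not propagate training-seed variability.
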