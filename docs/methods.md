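# Methods

`minet` implements a complete experimental chain for myocardial-infarction
(MI) detection and localization from 12-lead ECG beats: a synthetic cohort
generator, preprocessing, balanced dataset construction with subject-disjoint
cross-validation, a family of small multi-lead convolutional networks, and a
clinical-index evaluation protocol with nonparametric model comparison.

## Synthetic 12-lead cohorts

Real diagnostic ECG archives (the obvious reference being the PhysioNet PTB
diagnostic database) cannot be bundled, so the package ships a generator that
emulates the statistical structure the pipeline depends on.

**Beat model.** A beat is a sum of five Gaussians (P, Q, R, S, T), each with
amplitude (µV), center (s, relative to the R peak) and width (s), projected
onto the 12 leads by a fixed dimensionless scaling vector with conventional
signs (aVR inverted, V1 predominantly negative, R-wave growth toward V4).
Defaults: P (120 µV, −0.200 s, 0.025 s), Q (−100, −0.045, 0.010),
R (1100, 0, 0.012), S (−250, 0.040, 0.012), T (300, 0.300, 0.060), chosen as
round textbook magnitudes for a limb-lead-II-normalized adult ECG.

**Class effects.** Each of the five MI locations perturbs a conventional ECG
territory lead set — ALMI {I, aVL, V5, V6}, AMI {V1–V4}, ASMI {V1–V3},
ILMI {II, III, aVF, V5, V6}, IMI {II, III, aVF} — along the three classic
abnormality axes: an ST-segment offset (default 200 µV) applied uniformly
between S-wave end (S center + 2 widths) and T-wave onset (T center − 2
widths) with 20 ms cosine ramps, Q-wave amplification (default ×3), and
per-lead T-wave inversion (default probability 0.5, drawn once per patient).
A single `effect_scale` dial interpolates all three toward zero; at zero the
class-conditional signal distributions are identical by construction, which
the tests exploit as a negative control.

**Variability model.** Two nested jitter scales mirror the two variability
scales of real ECG: patient-level template jitter (inter-individual, RIV;
default 10% multiplicative on amplitudes/widths, plus heart-rate draw
70 ± 5 bpm) and beat-level jitter (intra-individual, AIV; default 3%,
deliberately smaller than RIV). Baseline wander is a two-component sinusoid
in 0.15–0.45 Hz with 100 µV total amplitude; measurement noise is white
Gaussian with 25 µV sd. Signals are sampled at 1000 Hz, quantized to
0.5 µV/LSB and clipped to the signed-16-bit range (−16 384 to +16 383.5 µV).

**Seed scoping.** `patient_seed` drives all patient-level draws and
`beat_seed` all beat-level draws, so a record is a pure function of
(class, patient_seed, beat_seed, cohort spec); cohorts derive both from a
master seed and are bit-reproducible.

**What the generator does not emulate:** conduction abnormalities,
arrhythmia, electrode artefacts, pathological morphologies beyond the three
effect axes, inter-lead timing differences, or realistic inter-patient
covariance of morphology parameters. Passing tests on this generator
demonstrate that the pipeline's machinery (filtering, detection,
bookkeeping, learning, statistics) behaves correctly under controlled
conditions; they are not evidence about classification accuracy on clinical
data.

**Cohort presets.** `table1` reproduces the full-scale study shape: 96
subjects, 40 records per class (HC 25 subjects, ALMI 14, AMI 14, ASMI 13,
ILMI 16, IMI 14; records assigned round-robin so subject multiplicity is
uneven). `tiny` is the smoke/experiment scale: 8 subjects × 12 records per
class, chosen so that subject-disjoint 3-fold splits still contain several
patients per class per fold while end-to-end runs stay in the minutes range.
Record duration is 40 s everywhere, enough for the ≥ 35 beats the selection
arithmetic requires at the slowest plausible heart rate.

## Preprocessing

Order: anti-aliased downsampling → baseline removal → R-peak detection →
segmentation.

* **Downsampling** 1000 → 100 Hz by polyphase FIR decimation (Kaiser window,
  unity DC gain). The filter's measured response satisfies the contracts the
  tests assert: ≥ 20 dB attenuation at 60 Hz and ≤ 5% ripple at 5 Hz.
* **Baseline removal** subtracts a running median with a 0.857 s window (the
  duration of one cardiac cycle at 70 bpm). The window in samples is rounded
  and then forced odd downward: 85 samples at 100 Hz. Edges are reflected.
* **R-peak detection** follows Christov's combined adaptive threshold on a
  "complex lead" (moving-average-smoothed absolute first difference, windows
  20/28/40 ms): a steep-slope component M (refreshed to 0.6 × the complex-lead
  maximum after each QRS, held 200 ms, decaying linearly to 0.6 M over 1 s),
  an integrating noise follower F, and a beat-expectation component R that
  lowers the threshold once two thirds of the expected RR interval has
  elapsed. A 200 ms refractory period is enforced and every threshold
  crossing is relocated to the raw-lead absolute maximum within ±50 ms, so
  the reported index marks the R wave itself — a requirement for the
  fixed "50 before / 349 after" window semantics to be meaningful. All
  constants sit in `ChristovConfig`. Detection runs on lead II by default
  (configurable); the lead choice follows standard practice.
* **Segmentation** cuts 12 × 400 windows: 50 samples before the R peak, the
  R sample, 349 after. Windows that would cross a record edge are dropped and
  counted, never padded. The variant that excludes the R sample (length 399)
  is available by configuration.

## Dataset construction

Random undersampling balances classes. Per class, 40 records are drawn
uniformly (seeded) from the eligible pool (records with ≥ 30 usable beats),
and 30 beats per record form the 6-class locating dataset: 7200 pieces, 1200
per class at full scale. The 2-class detection dataset reuses that
selection: HC keeps all 1200 pieces and each MI record contributes a seeded
subsample of 6 of its 30, giving 1200 MI pieces (240 per location). The
identity `detection_pieces × 5 = locating_pieces_per_record` is enforced;
plans violating it are rejected.

Folds are assigned to patients, never to beats: within each diagnostic
class, patients are shuffled (seeded) and greedily placed into the fold
currently lightest in that class's piece count. This guarantees subject
disjointness exactly and balance up to the largest single patient's piece
count. A leakage audit (empty patient-ID intersection between every
train/test pair) runs on every build and inside every CV fold.

## Network family

Every model processes the 12 leads in independent branches. Scale path *s*
(of S) applies *s* − 1 learnable pooling convolutions (kernel = stride =
pooling factor 2, F filters), then two unpadded kernel-3 stride-1
convolutions (F filters), then global average pooling over time. All
convolutions use ReLU; unpadded kernel-3 convolutions shorten the temporal
axis by exactly 2 each. The 12·S·F pooled features are concatenated, passed
through dropout (rate 0.5) and a softmax dense layer with C units (2 for
detection, 6 for locating). S = 1 is the single-scale "narrow" N-Net;
S > 1 is the multi-scale MSN-Net. No batch normalization anywhere.

The trainable-parameter count has the closed form

    12 · Σ_s [ Σ_pool (P·c_in + 1)F + (3·c_in + 1)F + (3F + 1)F ] + (12·S·F + 1)·C

with c_in = 1 for the first convolution of each scale path and F thereafter;
the tests verify it equals the instantiated graph's count for every grid
configuration (e.g. 3674 parameters for S=1, F=9, C=2).

Design points that were genuinely open: pooling convolutions use F filters,
kernel = stride = 2 per stage and ReLU, matching the other convolutions;
scale paths do not share weights; convolutions are valid (unpadded), which
the stated −2 length bookkeeping forces; GAP averages each filter over time.

The implementation is a small NumPy engine (lead-batched GEMMs for the
convolutions, analytic backward pass verified against finite differences,
Adam with the standard bias correction, inverted dropout). Training is
deterministic given the initialization seed and data order. Network inputs
are in millivolts so amplitudes are of order one under Glorot
initialization.

## Training and evaluation protocol

Categorical cross-entropy, Adam at learning rate 0.001, parameter updates
every 300 samples, at most 200 epochs, early stopping after 20 epochs
without strict improvement of the monitored quantity, best-epoch weights
restored. The monitored quantity defaults to training loss: under
subject-wise CV the held-out fold must not steer training; monitoring
validation quantities remains available behind a flag for fidelity
experiments.

Repeated subject-based k-fold CV (default k = 5, 15 repeats at full scale):
each repeat draws a fresh subject-disjoint split (seed = base + repeat),
trains one model per fold and pools all held-out predictions of the repeat
into one confusion matrix. The within-epoch sample order is a fixed seeded
permutation shared across model configurations for a given (repeat, fold);
weight-initialization seeds vary across repeats. Re-splitting per repeat is
the default because repeats must vary something beyond initialization;
fixed-split mode is available.

The grid search covers S ∈ 1..5 × F ∈ 1..10 for detection (50 models) and
additionally single-scale F ∈ 11..15 for locating (55 models), in
deterministic scale-major order. The best configuration maximizes mean
per-repeat accuracy, ties broken toward fewer parameters.

Metrics: ACC/SEN/SPE/F1 in percent from the pooled 2×2 confusion matrix
(zero denominators yield an explicit undefined marker), accuracy only for
the 6-class task, and AUC computed as the Mann–Whitney rank statistic so the
identity AUC = U/(n₊·n₋) is exact. Model comparison uses the two-sided
Mann–Whitney U test on per-repeat index vectors (midranks for ties; exact
null distribution by dynamic programming for tie-free samples up to n = 20,
verified against brute-force enumeration; tie- and continuity-corrected
normal approximation otherwise), with the usual star convention
(* p<0.05, ** p<0.01, *** p<0.001). `compare_models` accepts externally
produced per-repeat vectors so published models can be compared without
re-implementation.

## Reduced problem sizes

The full protocol (15 × 5-fold CV over 50–55 configurations on 7200 pieces)
is a multi-day CPU computation; the package's own experiments therefore run
at deliberately reduced scale: the tiny cohort preset, k = 3, 2 repeats, and
batch size 30 (scaled to the ~130-sample fold training sets so the number of
gradient updates per epoch matches the spirit of the full-scale protocol).
The headline checks — chance-level accuracy on zero-effect cohorts,
≥ 90% detection accuracy at default effects, monotone accuracy in effect
size — are stable at this scale with fixed seeds.

## Numerical choices and degenerate inputs

* Quantization 0.5 µV/LSB; +16 384.0 µV saturates to +16 383.5 (one LSB) on
  write because signed 16 bit is asymmetric; round-trips are exact for all
  generator output.
* The all-zero signal yields no R-peak detections (the threshold must be
  strictly positive); signals shorter than 2 s are rejected because the
  detector's thresholds cannot initialize.
* Median window ≥ signal length, non-integer decimation ratios, empty
  training sets, label/class mismatches, unbalanced detection plans and
  classes with fewer patients than folds are all rejected with specific
  errors rather than silently repaired.
* Early-stopping "improvement" is a strict inequality with zero tolerance.

## Known limitations

* The generator's simplicity means classification results on it bound
  nothing about clinical performance; it is a correctness instrument.
* The Christov constants are tuned to the cited description, not re-fitted;
  at 100 Hz the smoothing windows are only 2–4 samples long.
* The WFDB support is deliberately the PTB dialect subset (format 16,
  single-segment); it reads/writes this package's records and PTB-style
  headers but is not a general WFDB implementation.
* Exact U p-values are limited to tie-free samples with n ≤ 20 per group;
  beyond that the corrected normal approximation is used.
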