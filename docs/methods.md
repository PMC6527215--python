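# Methods

`vfdetect` implements a complete shock/no-shock decision pipeline for
single-channel ECG: signal conditioning, rhythm segmentation with
exclusion rules, a mixed 1D-convolutional + LSTM classifier with
CNN-only and SVM baselines, and an evaluation suite. This note records
the model, the parameters that matter, the numerical choices, and what
the synthetic cohorts do and do not establish.

## Signal model and conditioning

Records are continuous single-channel ECG in millivolts with half-open,
0-based sample intervals carrying rhythm labels from a closed
vocabulary (VF, VT, ventricular flutter; NSR, SVT, AF, heart block,
ectopic activity, PR, PEA; and the excluded asystole, fine-VF, slow-VT,
noise and saturation classes). The conditioning chain is the front-end
typical of AED monitoring: mean subtraction, a 5-point moving average
(reflect-padded, length-preserving), and a 1–30 Hz bandpass. The
bandpass is a 4th-order Butterworth applied forward–backward, so the
chain is zero-phase and strictly linear; the order, corners, causality
and smoothing window are all exposed in `PreprocessConfig` because only
the band itself is canonical — different AED models differ in the rest.

Resampling to the 250 Hz working rate is polyphase rational resampling
with an anti-alias FIR low-pass cut at 0.45·fs_out. The input is
extended antisymmetrically (as `filtfilt` does) before filtering so
edge transients fall outside the kept span; tones below 30 Hz survive
with amplitude error under 2%.

## Segmentation and labeling

Windows of L seconds (2, 3, 4, 8 by default; any positive L with
integer L·fs accepted) tile each rhythm interval from its start, so
every emitted segment has a unique rhythm label by construction; the
sub-window tail of an interval is dropped, as is any window overlapping
a noise or saturation interval. Binary labels: VF/VT/flutter → shock;
organized, paced and supraventricular rhythms → no-shock. Three
borderline classes are excluded from the binary decision because the
benefit of defibrillation is unclear: asystole (rate < 12 bpm or
peak-to-peak < 100 μV), fine VF (peak amplitude < 200 μV) and slow VT
(< 150 bpm). All comparisons are strict; the asystole rule is applied
first; "peak amplitude" is operationalized as max |x − median(x)|,
"peak-to-peak" as max − min. Rate estimation (used only for
synthetic/self-measured rhythms — real data carry annotations) counts
local maxima above half the peak amplitude with a 200 ms refractory
period.

Windows are anchored per rhythm interval rather than per record. This
maximizes usable whole-rhythm windows; the anchoring convention is a
package choice and is fixed here for reproducibility.

## The classifier

The input is the column of N = L·fs preprocessed samples. Two
convolutional sub-blocks, each J = 32 filters of size M = 3 (valid
cross-correlation, ReLU) followed by max-pooling of size K = 7, give a
time-compressed feature map; its temporal length follows
N_ℓ = ⌊(N_{ℓ−1} + 2p − M)/s⌋ + 1 with p = 0, s = 1 for convolutions
and s = K for pooling (2000 → 1998 → 285 → 283 → 40 for an 8-s
segment). A forward LSTM with Q = 20 units consumes the map; its final
hidden state feeds a single sigmoid unit that outputs p_Sh, the
probability of a shockable rhythm. The whole network — forward passes,
backpropagation through time, and the optimizer — is implemented
directly in NumPy so every kernel can be verified against naive loop
oracles, which the test suite does to 1e-10.

Training minimizes the class-weighted binary cross-entropy
−Σ η_i [y_i ln p_i + (1−y_i) ln(1−p_i)] (probabilities clipped to
[1e-7, 1−1e-7]); the per-batch gradient uses the batch mean of the same
weighted terms. Instance weights η_i = n/(2·n_class(i)) give the two
classes equal total weight. Optimization is mini-batch SGD with
Nesterov momentum 0.9, learning rate 1e-3 and a per-update decay
schedule lr_t = lr/(1 + 1e-6·t). After training, the decision threshold
θ maximizes the balanced accuracy of the *training* predictions over
the midpoints of consecutive sorted unique probabilities (plus 0 and
1), ties broken toward the smallest θ; the decision is shock iff
p_Sh ≥ θ (ties fail toward sensitivity).

Initialization is fan-in-scaled uniform for convolutional and dense
weights, orthogonal for the LSTM recurrence matrices, and zero biases
except the forget gate (bias 1); everything is seed-controlled and
training is bit-deterministic for a fixed seed and data.

Design points that were genuinely open and are fixed here: the dense
head is a single sigmoid on the final LSTM state (no hidden layer);
only that final state is used (no sequence output); the CNN-only
comparison architectures (two to four conv blocks per the published
descriptions summarized in `build_variant`) use ReLU activations,
stride 1, no padding, and a hidden dense width of 32 where two dense
layers are specified, since those details are not part of their
defining tables. CNN-only models flatten the final feature map into the
dense head.

## SVM baselines

The classical baseline standardizes a registry of hand-crafted
VF-detection features (mean absolute slope, dominant spectral
frequency, spectral flatness, 0.5–9 vs 9–30 Hz band-power ratio,
threshold-crossing rate, peak-to-peak amplitude, kurtosis, a
sample-entropy-style complexity on a decimated copy, RMS amplitude,
spectral centroid) and fits a Gaussian-kernel soft-margin SVM. The
quadratic program is delegated to a standard solver; the stored model
keeps only support vectors, multipliers, bias and standardization
constants, and the package's own decision function re-evaluates the
explicit kernel sum (the tests check both routes agree to 1e-8). The
registry is a documented, versioned surrogate for the larger classical
feature sets in the literature; exact parity with any published set is
a non-goal.

Hyperparameters (C, γ) are searched in the box 1e-3 ≤ C, γ ≤ 2·10² by
Bayesian optimization: log-uniform initial design, Gaussian-process
surrogate (Matérn 5/2), expected-improvement acquisition over a seeded
candidate cloud, 60 evaluations by default, objective = 5-fold
(patient-grouped when groups are available) cross-validated balanced
accuracy. Class imbalance scales the per-instance penalty. Outlier
trimming is one-shot: fit, rank hinge violations 1 − y·f(x), drop at
most ⌊0.005·n⌋ instances and only those on the wrong side of the
boundary (violation > 1), so clean separable data loses nothing.

The learned-feature experiment feeds the same SVM machinery with the 20
LSTM features; the best k-feature subset is chosen on training data by
greedy forward selection under a linear-discriminant score (exhaustive
subset search is combinatorial; greedy LDA is the package's reading of
"a simple LDA classifier selects the best combination").

## Evaluation

Balanced accuracy BAC = (Se + Sp)/2 ranks all models, because total
accuracy is dominated by the ~4:1 nonshockable majority. Undefined
predictive values are reported as missing, not zero. The McNemar
comparison is one-sided on the discordant counts (b, c): exact binomial
tail P(X ≥ b | b+c, ½) for b+c < 25, else continuity-corrected χ²
halved. Feature discriminability is rank-based (Mann-Whitney) AUC.
Separability uses Barnes-Hut t-SNE (perplexity 30, θ = 0.5, 1000
iterations, PCA init, standardized input, seed-controlled) to 2-D,
then the Davies-Bouldin index on paired bootstrap resamples of the
embedded points; the comparison p-value is the fraction of replicas
where the learned features are not better. Note the reported bootstrap
standard deviation is the spread across replicas — it stabilizes as B
grows rather than shrinking. AHA compliance is the inclusive check
Se ≥ 90 and Sp ≥ 95.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not cardiac electrophysiology. Organized rhythms are PQRST-like
Gaussian-bump pulse trains (rate jitter; wide-QRS and P-less variants
for aberrant conduction, AF and SVT surrogates); VF is an amplitude-
and frequency-modulated oscillation (random-walk instantaneous
frequency around 4–6.5 Hz) with no QRS-like spikes; edge cases are
generated to sit on the correct side of the exclusion thresholds. The
default cohort is 20 patients × 120 s at 250 Hz, a rhythm mix with 5%
excluded-rhythm time and usable time split 4:1
nonshockable:shockable, a 30% chance of one noise burst per record, and
optional amplitude quantization at the 1.031 μV/LSB defibrillator-pad
resolution. An "OHCA-like" mode lowers VF amplitude and frequency,
widens QRS complexes and increases rate irregularity, mimicking the
harder regime of ECG captured minutes after collapse. All randomness
derives from the single cohort seed.

Because the two synthetic classes are morphologically well separated,
held-out balanced accuracies near 100% on these cohorts demonstrate
that the pipeline trains, thresholds and evaluates correctly — they say
nothing about accuracy on clinical Holter or defibrillator data, where
borderline rhythms, noise and inter-patient variability dominate.

## Problem sizes and profiles

The desk profile used throughout the tests and examples trains for 50
epochs with mini-batches of 32 on the default 20-patient cohort
(roughly 470 four-second segments); one such training takes tens of
seconds on one CPU. The headline-scale profile (600 epochs, batches of
256) remains the `TrainConfig` default for full-size runs on real
data. The segment-length sweep retrains per L ∈ {2, 3, 4, 8} s, where
the feature-map sequence entering the LSTM has length 9, 14, 20 and 40
respectively.

## Known limitations

- The WFDB reader covers the physionet dialect used by the target
  Holter databases (formats 16 and 212, rhythm-change and VF on/off
  annotations); it is not a general-purpose WFDB implementation.
- The rate estimator is peak-counting and meaningful only for the
  synthetic morphologies; real-data labels come from annotations.
- The classical feature registry is representative, not a reimplementation
  of any published 30-feature set; absolute SVM baselines on real data
  would differ.
- Training is single-threaded NumPy: correct and deterministic, but not
  suited to 600-epoch runs on hundreds of thousands of segments.
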