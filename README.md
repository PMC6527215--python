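# vfdetect

Shock/no-shock decision algorithms for lethal ventricular arrhythmia.

Automated external defibrillators (AEDs) must decide from a few seconds
of single-channel ECG whether the rhythm is *shockable* — ventricular
fibrillation (VF), pulseless ventricular tachycardia (VT) or
ventricular flutter — or *nonshockable* (organized, paced or
supraventricular rhythms), with American Heart Association minimum
goals of sensitivity ≥ 90% and specificity ≥ 95%. `vfdetect` is a
research toolkit for building and evaluating such shock-advice
algorithms. It is aimed at biomedical-signal researchers who want a
fully inspectable, deterministic pipeline: every numerical kernel is
implemented in NumPy and tested against naive oracles.

The package provides:

- **signal_io** — annotated ECG records (WFDB `.hea/.dat/.atr` triplets
  and a plain-text fixture format), polyphase resampling to 250 Hz, and
  random patient-wise 80/20 splits performed per source database.
- **preprocess** — the AED conditioning chain: mean subtraction,
  5-point moving average, zero-phase 1–30 Hz Butterworth bandpass.
- **segmenter** — non-overlapping L-second windows with a unique rhythm
  label each; exclusion of noisy windows, asystole (rate < 12 bpm or
  peak-to-peak < 100 μV), fine VF (peak < 200 μV) and slow VT
  (< 150 bpm); binary Sh/NSh labeling.
- **net** — the mixed CNN+LSTM classifier: two convolutional sub-blocks
  (J = 32 filters of size M = 3, ReLU, max-pool K = 7), a forward LSTM
  with Q = 20 units, and a sigmoid head giving p_Sh. Feature-map
  lengths follow N_ℓ = ⌊(N_{ℓ−1} + 2p − M)/s⌋ + 1, so an 8-s segment
  (N = 2000) compresses to a 40-step LSTM input. Training is
  mini-batch SGD with Nesterov momentum on the class-weighted
  cross-entropy −Σ η_i[y_i ln p_i + (1−y_i) ln(1−p_i)]; the decision
  threshold maximizes training-set balanced accuracy. Three CNN-only
  comparison architectures are included.
- **svm_baseline** — Gaussian-kernel SVM on a classical VF-feature
  registry or on the learned LSTM features, with Bayesian (C, γ) search
  in 10⁻³…2·10² and class-balancing instance weights; the decision is
  the explicit support-vector sum sign(Σ αᵢyᵢ e^{−γ‖x−xᵢ‖²} + b).
- **metrics** — Se/Sp/PPV/NPV/Acc and balanced accuracy
  BAC = (Se + Sp)/2, one-sided McNemar comparisons, rank-based AUC,
  t-SNE + Davies-Bouldin separability with bootstrap, AHA compliance.
- **synthgen** — patient-structured synthetic cohorts (PQRST-like pulse
  trains vs modulated VF oscillations, edge cases, noise bursts, ~4:1
  class imbalance) so the whole pipeline runs with no data downloads.
- **pipeline / cli** — experiment orchestration (training/evaluation,
  segment-length sweep, model comparison) and a thin `vfdetect`
  command-line interface (`synth`, `train`, `evaluate`, `sweep`,
  `compare`, `features`).

## Worked example

```bash
python examples/train_and_evaluate.py
```

trains the CNN+LSTM on a 20-patient synthetic cohort (80/20 patient
split, 4-s segments, 50 epochs) and prints:

```
   model    subset    Se   Sp  BAC   Acc  AHA
proposed synthetic 100.0 95.0 97.5 95.92 True
decision threshold (train-set BAC-optimal): 0.679
training loss: 0.652 (epoch 1) -> 0.139 (epoch 50)
```

Reading: on the held-out patients every shockable segment was flagged
(Se 100%), 95% of nonshockable segments were correctly left unshocked
(Sp), and the balanced accuracy — the unweighted mean of the two, the
headline metric under the ~4:1 class imbalance — is 97.5%. The AHA
column applies the inclusive Se ≥ 90 / Sp ≥ 95 check. The threshold is
chosen on training data only. Because the synthetic classes are
morphologically well separated, these numbers validate the pipeline
mechanics, not clinical performance (see `docs/methods.md`).

Other examples: `examples/generate_cohort.py` (cohort composition),
`examples/segment_length_sweep.py` (accuracy vs 2/3/4/8-s windows),
`examples/feature_analysis.py` (AUC ranking of the 20 learned LSTM
features and their separability against classical VF features).

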