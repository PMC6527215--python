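"""How short can the analysis segment get?

Retrains the CNN+LSTM for 2-, 3-, 4- and 8-s ECG windows on a small
synthetic cohort and tabulates Se/Sp/BAC per length, together with the
length of the feature-map sequence entering the recurrent block (9, 14,
20 and 40 steps — the valid-convolution recurrence applied twice through
conv(M=3)/pool(K=7)).  Shorter windows mean shorter hands-off pauses in
CPR, at some cost in accuracy.
"""

from vfdetect import net, pipeline, synthgen

cfg = pipeline.ExperimentConfig(
    cohort=synthgen.CohortConfig(n_patients=10, record_seconds=90, seed=3),
    models=("proposed",),
    split_seed=3,
    train=net.TrainConfig(epochs=25, batch_size=32, seed=3),
)
table = pipeline.sweep_segment_lengths(cfg)
print(table.round(2).to_string(index=False))
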