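"""Generate a synthetic ECG cohort and inspect its composition.

Builds a 20-patient cohort with the default rhythm mix (roughly 4
nonshockable segments per shockable one), writes it in the plain-text
fixture format, and prints the per-class 4-s segment counts.  The ratio
printed should land near 4:1 — the imbalance the classifiers are
weighted against.
"""

from vfdetect import segmenter, signal_io, synthgen

cfg = synthgen.CohortConfig(n_patients=20, record_seconds=120, seed=3)
records = synthgen.gen_cohort(cfg)
for rec in records:
    signal_io.write_fixture(rec, "scratch/example_cohort")

segs = segmenter.extract_all(records, L=4.0)
y = segs.labels()
print(f"{len(records)} records -> {len(segs)} usable 4-s segments")
print(segs.counts())
print(f"NSh:Sh ratio = {(y == 0).sum() / y.sum():.2f}  (target {cfg.imbalance_ratio}:1)")
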