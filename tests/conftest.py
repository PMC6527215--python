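"""Shared fixtures.

The expensive artifacts (the default-cohort experiment, the segment-length
sweep, the paired determinism/leakage runs) are session-scoped so each is
computed once and reused by the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from vfdetect import net, pipeline, segmenter, synthgen
from vfdetect.segmenter import Segment, SegmentSet

#: Study conditions for the synthetic end-to-end experiments.
DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort_records():
    """The default 20-patient synthetic cohort (the study conditions)."""
    return synthgen.gen_cohort(synthgen.CohortConfig(n_patients=20, seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_experiment(default_cohort_records):
    """Full desk-profile experiment: proposed CNN+LSTM, 50 epochs, 4-s segments."""
    cfg = pipeline.ExperimentConfig(
        cohort=synthgen.CohortConfig(n_patients=20, seed=DEFAULT_SEED),
        models=("proposed",),
        split_seed=DEFAULT_SEED,
        train=pipeline.desk_train_config(DEFAULT_SEED),
    )
    return cfg, pipeline.run_experiment(cfg, records=default_cohort_records)


def _tiny_config(tmp_dir=None, models=("proposed",), epochs=3):
    return pipeline.ExperimentConfig(
        cohort=synthgen.CohortConfig(n_patients=8, record_seconds=80, seed=11),
        models=models,
        split_seed=11,
        train=net.TrainConfig(epochs=epochs, batch_size=32, seed=11),
        out_dir=tmp_dir,
    )


@pytest.fixture(scope="session")
def tiny_experiment_twice(tmp_path_factory):
    """The same tiny experiment run twice into two output directories."""
    outs = []
    for name in ("runA", "runB"):
        d = tmp_path_factory.mktemp(name)
        cfg = _tiny_config(str(d))
        pipeline.run_experiment(cfg)
        outs.append(d)
    return outs


@pytest.fixture(scope="session")
def leakage_pair():
    """Trained parameters from two cohorts that differ only in test-side signals."""
    records = synthgen.gen_cohort(synthgen.CohortConfig(n_patients=8, record_seconds=80, seed=11))
    cfg = _tiny_config()
    results = []
    for permute in (False, True):
        recs = records
        if permute:
            split = pipeline.prepare_segments(records, cfg)[2]
            rng = np.random.default_rng(99)
            recs = []
            for r in records:
                if r.patient_id in split.all_test:
                    shuffled = r.samples[rng.permutation(len(r.samples))]
                    recs.append(
                        type(r)(
                            r.patient_id, r.source_db, shuffled, r.fs,
                            list(r.rhythm_intervals), list(r.noise_intervals),
                        )
                    )
                else:
                    recs.append(r)
        train_set, _, _ = pipeline.prepare_segments(recs, cfg)
        fitted = pipeline.fit_model("proposed", train_set, cfg).fitted
        results.append(fitted)
    return results


@pytest.fixture(scope="session")
def tiny_sweep():
    """Segment-length sweep (2/3/4/8 s) on a small cohort, short training."""
    cfg = _tiny_config(epochs=2)
    return pipeline.sweep_segment_lengths(cfg)


def make_separable_segments(n: int = 200, L: float = 2.0, fs: float = 250.0) -> SegmentSet:
    """A cleanly separable cohort: VF-like oscillations vs sinus trains.

    One segment in four is shockable, mirroring the 4:1 imbalance.
    """
    n_samp = int(round(L * fs))
    segs = []
    for i in range(n):
        pid = f"p{i % 8}"
        if i % 4 == 0:
            x = synthgen.gen_vf(4.5 + 0.3 * (i % 3), amp=0.9, fs=fs, dur=L, seed=1000 + i)
            segs.append(Segment(x[:n_samp], "Sh", "VF", pid, "synthetic", 0.0))
        else:
            x = synthgen.gen_sinus(60 + (i % 5) * 8, amp=1.0, fs=fs, dur=L + 1, seed=2000 + i)
            segs.append(Segment(x[:n_samp], "NSh", "NSR", pid, "synthetic", 0.0))
    return SegmentSet(segs, L, fs)


@pytest.fixture(scope="session")
def separable_training():
    """Trained proposed network on the separable cohort (scaled-down run)."""
    segs = make_separable_segments()
    model = net.build_network(net.proposed_spec(), segs.L, segs.fs, seed=3)
    cfg = net.TrainConfig(epochs=50, batch_size=32, seed=3)
    fitted = net.train(model, segs, cfg)
    return segs, fitted, cfg
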