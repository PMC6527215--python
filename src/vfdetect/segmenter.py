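"""Cut records into fixed-length windows, apply exclusion rules, assign labels.

Shockable (Sh) rhythms are VF, VT and ventricular flutter; organized,
paced and supraventricular rhythms are nonshockable (NSh).  Asystole,
fine VF (peak amplitude below 200 uV) and slow VT (rate below 150 bpm)
are excluded from the binary decision because the benefit of
defibrillation is unclear for them, as are noisy or saturated windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import LabelingError
from .signal_io import EcgRecord, RHYTHM_LABELS

SHOCKABLE = frozenset({"VF", "VT", "ventricular_flutter"})
NONSHOCKABLE = frozenset({"NSR", "SVT", "AF", "block", "ectopic", "PR", "PEA"})
EXCLUDED = frozenset({"AS", "fine_VF", "slow_VT", "noise", "saturation"})

# Exclusion-rule thresholds (amplitudes in microvolts, rates in bpm).
FINE_VF_PEAK_UV = 200.0
SLOW_VT_RATE_BPM = 150.0
ASYSTOLE_RATE_BPM = 12.0
ASYSTOLE_P2P_UV = 100.0


@dataclass(frozen=True)
class Segment:
    """One fixed-length ECG window with its binary shock label."""

    samples: np.ndarray
    label: str  # "Sh" | "NSh"
    rhythm: str
    patient_id: str
    source_db: str
    t_start: float  # seconds from record start

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


@dataclass
class SegmentSet:
    segments: list[Segment]
    L: float  # seconds
    fs: float

    def __post_init__(self) -> None:
        n = int(round(self.L * self.fs))
        for seg in self.segments:
            if len(seg.samples) != n:
                raise ValueError(f"segment of {len(seg.samples)} samples; expected {n}")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_samples(self) -> int:
        return int(round(self.L * self.fs))

    def counts(self) -> pd.DataFrame:
        rows = [(s.label, s.source_db) for s in self.segments]
        df = pd.DataFrame(rows, columns=["label", "source_db"])
        return df.groupby(["source_db", "label"]).size().unstack(fill_value=0)

    def labels(self) -> np.ndarray:
        return np.array([1 if s.label == "Sh" else 0 for s in self.segments])

    def matrix(self) -> np.ndarray:
        return np.stack([s.samples for s in self.segments])

    def patients(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.segments])

    def subset(self, mask) -> "SegmentSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SegmentSet([self.segments[i] for i in idx], self.L, self.fs)

    def to_csv(self, index_path: str | Path, samples_path: str | Path | None = None) -> None:
        df = pd.DataFrame(
            [
                (s.patient_id, s.source_db, s.label, s.rhythm, s.t_start)
                for s in self.segments
            ],
            columns=["patient_id", "source_db", "label", "rhythm", "t_start"],
        )
        df.to_csv(index_path, index=False)
        if samples_path is not None:
            np.savetxt(samples_path, self.matrix() if self.segments else np.empty((0, 0)), fmt="%.6f")


def to_binary_label(rhythm: str) -> str:
    """Map a rhythm label to Sh / NSh / excluded."""
    if rhythm in SHOCKABLE:
        return "Sh"
    if rhythm in NONSHOCKABLE:
        return "NSh"
    if rhythm in EXCLUDED:
        return "excluded"
    raise LabelingError(f"unknown rhythm label {rhythm!r}")


def check_special_rhythm(
    rate: float, peak_amp: float, p2p_amp: float, base_label: str
) -> str:
    """Re-label borderline rhythms from measured rate/amplitude.

    Any rhythm with rate under 12 bpm or peak-to-peak amplitude under
    100 uV is asystole; VF with peak amplitude under 200 uV is fine VF;
    VT below 150 bpm is slow VT.  All comparisons are strict.
    """
    if base_label not in RHYTHM_LABELS:
        raise LabelingError(f"unknown rhythm label {base_label!r}")
    if rate < ASYSTOLE_RATE_BPM or p2p_amp < ASYSTOLE_P2P_UV:
        return "AS"
    if base_label == "VF" and peak_amp < FINE_VF_PEAK_UV:
        return "fine_VF"
    if base_label == "VT" and rate < SLOW_VT_RATE_BPM:
        return "slow_VT"
    return base_label


def measure_segment(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """Return (rate bpm, peak amplitude uV, peak-to-peak amplitude uV).

    Peak amplitude is the largest deviation from the median; rate comes
    from local maxima above half the peak amplitude with a 200 ms
    refractory period.  Used for synthetic/self-measured labels only.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < fs:
        raise ValueError("need at least 1 s of signal")
    p2p_mv = float(x.max() - x.min())
    med = float(np.median(x))
    peak_mv = float(np.abs(x - med).max())
    if peak_mv == 0.0:
        return 0.0, 0.0, 0.0
    d = x - med
    peaks, _ = sps.find_peaks(d, height=0.5 * peak_mv, distance=max(1, int(round(0.2 * fs))))
    rate = len(peaks) / (len(x) / fs) * 60.0
    return rate, peak_mv * 1000.0, p2p_mv * 1000.0


def _overlaps(a0: int, a1: int, spans: list[tuple[int, int]]) -> bool:
    return any(a0 < e and s < a1 for s, e in spans)


def extract_segments(rec: EcgRecord, L: float, fs: float | None = None) -> SegmentSet:
    """Tile each rhythm interval with non-overlapping L-second windows.

    Windows start at the beginning of each rhythm interval (a leftover
    tail shorter than L is dropped, as is any window overlapping a
    noise/saturation interval).  Only rhythms with a Sh/NSh mapping are
    emitted, so every segment carries a unique rhythm label.
    """
    fs = fs or rec.fs
    n = L * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"L*fs = {n} is not an integer")
    n = int(round(n))
    noise_spans = list(rec.noise_intervals) + [
        (iv.start, iv.end) for iv in rec.rhythm_intervals if iv.label in ("noise", "saturation")
    ]
    segments: list[Segment] = []
    for iv in rec.rhythm_intervals:
        binary = to_binary_label(iv.label)
        if binary == "excluded":
            continue
        for s0 in range(iv.start, iv.end - n + 1, n):
            if _overlaps(s0, s0 + n, noise_spans):
                continue
            segments.append(
                Segment(
                    samples=rec.samples[s0 : s0 + n],
                    label=binary,
                    rhythm=iv.label,
                    patient_id=rec.patient_id,
                    source_db=rec.source_db,
                    t_start=s0 / fs,
                )
            )
    return SegmentSet(segments, L, fs)


def extract_all(records: list[EcgRecord], L: float, fs: float | None = None) -> SegmentSet:
    """Concatenate per-record extraction across a cohort."""
    segs: list[Segment] = []
    fs_eff = fs or (records[0].fs if records else 250.0)
    for rec in records:
        segs.extend(extract_segments(rec, L, fs or rec.fs).segments)
    return SegmentSet(segs, L, fs_eff)
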