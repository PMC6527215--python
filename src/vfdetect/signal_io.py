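"""Annotated single-channel ECG records: WFDB and fixture I/O, resampling, splits.

The record container uses 0-based, half-open sample intervals throughout.
WFDB annotation sample numbers are converted to this convention on read.
Amplitudes are always millivolts.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import LabelingError, ReadError, SplitError

#: Closed rhythm vocabulary.  Shock/no-shock mapping lives in :mod:`segmenter`.
RHYTHM_LABELS = frozenset(
    {
        "VF",
        "VT",
        "ventricular_flutter",
        "NSR",
        "SVT",
        "AF",
        "block",
        "ectopic",
        "PR",
        "PEA",
        "AS",
        "fine_VF",
        "slow_VT",
        "noise",
        "saturation",
    }
)

SOURCE_DBS = ("vfdb", "cudb", "ahadb", "ohca", "synthetic")


@dataclass(frozen=True)
class RhythmInterval:
    """Half-open sample interval ``[start, end)`` carrying one rhythm label."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.label not in RHYTHM_LABELS:
            raise LabelingError(f"unknown rhythm label {self.label!r}")


@dataclass
class EcgRecord:
    """Continuous annotated ECG of one patient (first channel, millivolts)."""

    patient_id: str
    source_db: str
    samples: np.ndarray
    fs: float
    rhythm_intervals: list[RhythmInterval] = field(default_factory=list)
    noise_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        n = len(self.samples)
        ivals = sorted(self.rhythm_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivals, ivals[1:]):
            if a.end > b.start:
                raise ValueError("rhythm intervals overlap")
        for iv in ivals:
            if iv.start < 0 or iv.end > n:
                raise ValueError(f"interval [{iv.start}, {iv.end}) outside record of {n} samples")
        self.rhythm_intervals = ivals
        for s, e in self.noise_intervals:
            if not (0 <= s < e <= n):
                raise ValueError("noise interval outside record")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class SplitResult:
    """Patient-wise train/test partition, kept separate per source database."""

    train_ids: dict[str, tuple[str, ...]]
    test_ids: dict[str, tuple[str, ...]]
    seed: int

    @property
    def all_train(self) -> frozenset[str]:
        return frozenset(p for ids in self.train_ids.values() for p in ids)

    @property
    def all_test(self) -> frozenset[str]:
        return frozenset(p for ids in self.test_ids.values() for p in ids)


# ---------------------------------------------------------------------------
# WFDB (physionet dialect): .hea / .dat / .atr
# ---------------------------------------------------------------------------

#: Physionet rhythm-change aux strings mapped onto the closed vocabulary.
#: The public Holter databases annotate rhythm onsets with '+' annotations
#: whose aux field is '(CODE'; codes below cover the rhythms those
#: databases contain.  Paced rhythms are grouped with the organized pulsed
#: class; bigeminy/trigeminy/idioventricular with ectopic activity.
WFDB_RHYTHM_MAP = {
    "(N": "NSR",
    "(NSR": "NSR",
    "(SBR": "NSR",
    "(VF": "VF",
    "(VFIB": "VF",
    "(VFL": "ventricular_flutter",
    "(VT": "VT",
    "(AFIB": "AF",
    "(AF": "AF",
    "(AFL": "AF",
    "(SVTA": "SVT",
    "(SVT": "SVT",
    "(NOD": "SVT",
    "(B": "ectopic",
    "(T": "ectopic",
    "(IVR": "ectopic",
    "(PVC": "ectopic",
    "(BII": "block",
    "(HGEA": "block",
    "(P": "PR",
    "(ASYS": "AS",
    "(NOISE": "noise",
}

_ANN_RHYTHM = 28  # '+' rhythm change
_ANN_VFON = 32
_ANN_VFOFF = 33


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ReadError(f"empty header {hea_path}")
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    nsig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    nsamp = int(rec[3]) if len(rec) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        signals.append({"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline})
    if len(signals) != nsig:
        raise ReadError(f"header {hea_path} declares {nsig} signals, found {len(signals)}")
    return name, nsig, fs, nsamp, signals


def _read_dat(dat_path: Path, fmt: int, nsig: int, nsamp: int) -> np.ndarray:
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        n = len(data) // nsig
        return data[: n * nsig].reshape(n, nsig).astype(float)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3)
        s1 = ((b[:, 1].astype(np.int32) & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1].astype(np.int32) & 0xF0) << 4) | b[:, 2]
        out = np.empty(2 * len(b), dtype=np.int32)
        out[0::2], out[1::2] = s1, s2
        out[out > 2047] -= 4096  # 12-bit two's complement
        n = len(out) // nsig
        return out[: n * nsig].reshape(n, nsig).astype(float)
    raise ReadError(f"unsupported WFDB signal format {fmt}")


def _read_annotations(atr_path: Path):
    """Decode the MIT annotation format: (sample, code, aux) triples."""
    raw = atr_path.read_bytes()
    words = struct.unpack(f"<{len(raw) // 2}H", raw[: (len(raw) // 2) * 2])
    anns: list[tuple[int, int, str]] = []
    t = 0
    i = 0
    while i < len(words):
        w = words[i]
        code, inc = w >> 10, w & 0x3FF
        if w == 0:
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            if i + 2 >= len(words):
                raise ReadError(f"truncated SKIP in {atr_path}")
            t += (words[i + 1] << 16) | words[i + 2]
            i += 3
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers: ignored
            i += 1
            continue
        if code == 63:  # AUX: inc bytes of string attached to previous annotation
            nb = inc
            start = 2 * (i + 1)
            aux = raw[start : start + nb].rstrip(b"\x00").decode("ascii", "replace")
            if anns:
                s, c, _ = anns[-1]
                anns[-1] = (s, c, aux)
            i += 1 + (nb + 1) // 2
            continue
        t += inc
        anns.append((t, code, ""))
        i += 1
    return anns


def _intervals_from_annotations(anns, nsamp: int) -> list[RhythmInterval]:
    """Rhythm-change annotations -> half-open labeled intervals.

    WFDB annotation samples are 0-based already; the half-open convention
    means each rhythm runs from its onset annotation to the next onset (or
    end of record).
    """
    events: list[tuple[int, str]] = []
    for sample, code, aux in anns:
        if code == _ANN_RHYTHM:
            aux = aux.strip().split("\x00")[0]
            if not aux:
                continue
            key = aux.split()[0]
            if key not in WFDB_RHYTHM_MAP:
                raise LabelingError(f"unknown rhythm annotation code {key!r}")
            events.append((sample, WFDB_RHYTHM_MAP[key]))
        elif code == _ANN_VFON:
            events.append((sample, "VF"))
        elif code == _ANN_VFOFF:
            events.append((sample, "NSR"))
    events.sort(key=lambda e: e[0])
    out: list[RhythmInterval] = []
    for (s, lab), nxt in zip(events, events[1:] + [(nsamp, "")]):
        e = min(nxt[0], nsamp)
        if s < e:
            out.append(RhythmInterval(s, e, lab))
    return out


def read_wfdb_record(
    path: str | Path,
    channel_policy: str = "first",
    source_db: str | None = None,
) -> EcgRecord:
    """Read a physionet ``.hea``/``.dat``(/``.atr``) triplet.

    Only the first channel is extracted (multi-lead Holter records are
    redundant for the shock decision).  Raw ADC units are converted to
    millivolts with the header gain/baseline.
    """
    if channel_policy != "first":
        raise ValueError(f"unsupported channel_policy {channel_policy!r}")
    base = Path(path)
    if base.suffix == ".hea":
        base = base.with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise ReadError(f"missing header file {hea}")
    name, nsig, fs, nsamp, sigs = _parse_header(hea)
    dat = base.parent / sigs[0]["file"]
    if not dat.exists():
        raise ReadError(f"missing signal file {dat}")
    adc = _read_dat(dat, sigs[0]["fmt"], nsig, nsamp)
    if nsamp and len(adc) < nsamp:
        raise ReadError(f"{dat} holds {len(adc)} samples, header declares {nsamp}")
    if nsamp:
        adc = adc[:nsamp]
    mv = (adc[:, 0] - sigs[0]["baseline"]) / sigs[0]["gain"]
    atr = base.with_suffix(".atr")
    intervals = _intervals_from_annotations(_read_annotations(atr), len(mv)) if atr.exists() else []
    noise = [(iv.start, iv.end) for iv in intervals if iv.label in ("noise", "saturation")]
    intervals = [iv for iv in intervals if iv.label not in ("noise", "saturation")]
    if source_db is None:
        parts = {p.lower() for p in base.parts}
        source_db = next((db for db in SOURCE_DBS if db in parts), "synthetic")
    return EcgRecord(
        patient_id=name,
        source_db=source_db,
        samples=mv,
        fs=fs,
        rhythm_intervals=intervals,
        noise_intervals=noise,
    )


# ---------------------------------------------------------------------------
# Fixture format: <id>.json + <id>.txt (one mV sample per line, 6 decimals)
# ---------------------------------------------------------------------------


def write_fixture(rec: EcgRecord, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "patient_id": rec.patient_id,
        "source_db": rec.source_db,
        "fs": rec.fs,
        "amplitude_quantization_mv": 1e-6,
        "rhythm_intervals": [[iv.start, iv.end, iv.label] for iv in rec.rhythm_intervals],
        "noise_intervals": [list(t) for t in rec.noise_intervals],
    }
    jpath = directory / f"{rec.patient_id}.json"
    jpath.write_text(json.dumps(header, indent=1))
    np.savetxt(directory / f"{rec.patient_id}.txt", rec.samples, fmt="%.6f")
    return jpath


def read_fixture(json_path: str | Path) -> EcgRecord:
    jpath = Path(json_path)
    if not jpath.exists():
        raise ReadError(f"missing fixture header {jpath}")
    hdr = json.loads(jpath.read_text())
    tpath = jpath.with_suffix(".txt")
    if not tpath.exists():
        raise ReadError(f"missing fixture samples {tpath}")
    samples = np.loadtxt(tpath, ndmin=1)
    return EcgRecord(
        patient_id=hdr["patient_id"],
        source_db=hdr["source_db"],
        samples=samples,
        fs=hdr["fs"],
        rhythm_intervals=[RhythmInterval(s, e, lab) for s, e, lab in hdr["rhythm_intervals"]],
        noise_intervals=[tuple(t) for t in hdr["noise_intervals"]],
    )


def read_fixture_dir(directory: str | Path) -> list[EcgRecord]:
    return [read_fixture(p) for p in sorted(Path(directory).glob("*.json"))]


# ---------------------------------------------------------------------------
# Resampling and patient-wise splitting
# ---------------------------------------------------------------------------


def resample_to_target(x: np.ndarray, fs_in: float, fs_out: float = 250.0) -> np.ndarray:
    """Polyphase rational resampling with an anti-alias low-pass at 0.45*fs_out.

    Output length is ``round(len(x) * fs_out / fs_in)``; band-limited
    content below 0.4*fs_out is preserved.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    n_out = int(round(len(x) * fs_out / fs_in))
    if fs_in == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    # FIR designed at the upsampled rate fs_in*up.  Cutoff 0.45*fs_out when
    # decimating (anti-alias); 0.45*fs_in when interpolating (anti-image).
    # resample_poly applies the gain `up` to a user-supplied window itself.
    cutoff = min(0.45 * min(fs_out, fs_in) / (fs_in * up / 2.0), 0.999)
    ntaps = 2 * 16 * max(up, down) + 1
    h = sps.firwin(ntaps, cutoff)
    # Odd (antisymmetric) extension keeps the waveform smooth across the
    # boundary so filter edge transients fall outside the kept span.
    pad = min(max(1, ntaps // down) * down, len(x) - 1)
    xp = np.concatenate([2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2 : -pad - 2 : -1]])
    y = sps.resample_poly(xp, up, down, window=h)
    off = int(round(pad * up / down))
    y = y[off : off + n_out]
    if len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y


def split_patients(
    records: list[EcgRecord], train_frac: float = 0.8, seed: int = 0
) -> SplitResult:
    """Random patient-wise split, performed independently per source database.

    All segments of one patient land on one side; per database the train
    side holds ``round(train_frac * n_patients)`` patients.
    """
    by_db: dict[str, list[str]] = {}
    for rec in records:
        by_db.setdefault(rec.source_db, [])
        if rec.patient_id not in by_db[rec.source_db]:
            by_db[rec.source_db].append(rec.patient_id)
    rng = np.random.default_rng(seed)
    train: dict[str, tuple[str, ...]] = {}
    test: dict[str, tuple[str, ...]] = {}
    for db in sorted(by_db):
        ids = sorted(by_db[db])
        if len(ids) < 2:
            raise SplitError(f"database {db!r} has {len(ids)} patient(s); need >= 2 to split")
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train[db] = tuple(sorted(ids[i] for i in perm[:n_train]))
        test[db] = tuple(sorted(ids[i] for i in perm[n_train:]))
    return SplitResult(train_ids=train, test_ids=test, seed=seed)
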