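"""Synthetic patient-structured ECG cohorts for desk-scale experiments.

Morphologies are deliberately simple surrogates: organized rhythms are
periodic PQRST-like pulse trains (sums of Gaussian bumps with rate
jitter), and VF is an amplitude- and frequency-modulated oscillation
with a random-walk instantaneous frequency and no isolated QRS spikes.
The point is to reproduce the *statistical structure* the pipeline
assumes — patient-level variability, shockable vs nonshockable
morphology contrast, asystole/fine-VF/slow-VT edge cases, noise
intervals, and the roughly 4:1 nonshockable:shockable imbalance — not
clinical fidelity.

All randomness flows from a single cohort seed through per-record
derived seeds, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError
from .signal_io import EcgRecord, RhythmInterval

#: OHCA defibrillator pad ADC resolution emulated by the quantization option.
OHCA_QUANT_UV = 1.031


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, tau_s: float) -> np.ndarray:
    """Zero-mean unit-ish band-limited noise (moving average of white noise)."""
    w = max(3, int(tau_s * fs) | 1)
    x = uniform_filter1d(rng.standard_normal(n + 2 * w), w)[w : n + w]
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_sinus(
    rate: float,
    amp: float = 1.0,
    fs: float = 250.0,
    dur: float = 10.0,
    jitter: float = 0.03,
    seed: int = 0,
    wide: bool = False,
    with_p: bool = True,
    with_t: bool = True,
) -> np.ndarray:
    """Organized-rhythm surrogate: a PQRST-like Gaussian-bump pulse train.

    ``wide`` triples the QRS width and drops the P wave (aberrant
    conduction / ventricular morphology, also used for VT trains).
    Peak-to-peak amplitude is about 2*amp (R up 1.2*amp, S down 0.8*amp).
    """
    if not 20 <= rate <= 220:
        raise ValueError("rate must lie in [20, 220] bpm")
    rng = np.random.default_rng(seed)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    widen = 3.0 if wide else 1.0
    bumps = [(-0.03, -0.15, 0.012 * widen), (0.0, 1.2, 0.014 * widen), (0.03, -0.8, 0.016 * widen)]
    if with_p and not wide:
        bumps.append((-0.18, 0.15, 0.035))
    if with_t:
        bumps.append((0.25, 0.35, 0.07))
    beat_t = 0.25
    period = 60.0 / rate
    while beat_t < dur + 0.5:
        for dt, a, sig in bumps:
            x += a * amp * np.exp(-0.5 * ((t - beat_t - dt) / sig) ** 2)
        beat_t += period * (1.0 + jitter * rng.standard_normal())
    return x


def gen_vf(
    center_freq: float,
    amp: float = 1.0,
    fs: float = 250.0,
    dur: float = 10.0,
    drift: float = 0.12,
    seed: int = 0,
) -> np.ndarray:
    """Shockable-rhythm surrogate: modulated oscillation without QRS spikes.

    The instantaneous frequency random-walks around ``center_freq``
    (fractional excursion ~ drift) and a band-limited envelope modulates
    the amplitude, giving the irregular, narrow-band waveform typical of
    fibrillation.  Strictly linear in ``amp`` for a fixed seed.
    """
    if not 3 <= center_freq <= 8:
        raise ValueError("center_freq must lie in [3, 8] Hz")
    rng = np.random.default_rng(seed)
    n = int(round(dur * fs))
    f_inst = center_freq * (1.0 + drift * _smooth_noise(rng, n, fs, 0.7))
    f_inst = np.clip(f_inst, 2.0, 9.0)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    env = 1.0 + 0.25 * _smooth_noise(rng, n, fs, 1.0)
    env = np.clip(env, 0.3, None)
    x = env * np.sin(phase) + 0.2 * env * np.sin(2.0 * phase + rng.uniform(0, 2 * np.pi))
    return amp * x


def gen_edge_case(
    kind: str, fs: float = 250.0, dur: float = 10.0, seed: int = 0
) -> tuple[np.ndarray, str]:
    """Borderline rhythms excluded from the binary decision.

    asystole: near-flat trace (p2p < 100 uV); fine_vf: VF morphology with
    peak amplitude < 200 uV; slow_vt: monomorphic wide-QRS train at 140
    bpm; noise_burst: broadband artifact.  Returns (signal, rhythm label).
    """
    if kind == "asystole":
        rng = np.random.default_rng(seed)
        n = int(round(dur * fs))
        return 0.012 * _smooth_noise(rng, n, fs, 0.5), "AS"
    if kind == "fine_vf":
        return gen_vf(4.0, amp=0.07, fs=fs, dur=dur, seed=seed), "fine_VF"
    if kind == "slow_vt":
        return (
            gen_sinus(140.0, amp=1.0, fs=fs, dur=dur, jitter=0.01, seed=seed, wide=True, with_t=False),
            "slow_VT",
        )
    if kind == "noise_burst":
        rng = np.random.default_rng(seed)
        n = int(round(dur * fs))
        x = 0.8 * rng.standard_normal(n) + 1.5 * _smooth_noise(rng, n, fs, 2.0)
        return x, "noise"
    raise ValueError(f"unknown edge case {kind!r}")


@dataclass
class CohortConfig:
    """Synthetic study conditions.

    imbalance_ratio is the target nonshockable:shockable ratio of usable
    segment time (the headline datasets are imbalanced roughly 4:1);
    excluded_frac is the time share of asystole/fine-VF/slow-VT edge
    intervals.  quant_step_uv > 0 applies ADC amplitude quantization (the
    OHCA defibrillator resolution is 1.031 uV/LSB); 0 disables it.
    """

    n_patients: int = 20
    fs: float = 250.0
    record_seconds: float = 120.0
    imbalance_ratio: float = 4.0
    rhythm_mix: dict[str, float] | None = None
    excluded_frac: float = 0.05
    noise_prob: float = 0.3
    quant_step_uv: float = 0.0
    ohca_like: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("need at least 2 synthetic patients")
        if self.imbalance_ratio <= 0:
            raise ConfigError("imbalance_ratio must be positive")
        if self.rhythm_mix is not None:
            total = sum(self.rhythm_mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"rhythm mix proportions sum to {total}, not 1")
            sh = sum(v for k, v in self.rhythm_mix.items() if k in ("VF", "VT", "ventricular_flutter"))
            if sh == 0 and np.isfinite(self.imbalance_ratio):
                raise ConfigError("finite imbalance ratio with zero shockable proportion")

    def mix(self) -> dict[str, float]:
        if self.rhythm_mix is not None:
            return dict(self.rhythm_mix)
        usable = 1.0 - self.excluded_frac
        sh = usable / (1.0 + self.imbalance_ratio)
        nsh = usable - sh
        return {
            "NSR": 0.50 * nsh,
            "AF": 0.22 * nsh,
            "SVT": 0.14 * nsh,
            "block": 0.08 * nsh,
            "ectopic": 0.06 * nsh,
            "VF": 0.60 * sh,
            "VT": 0.35 * sh,
            "ventricular_flutter": 0.05 * sh,
            "AS": 0.40 * self.excluded_frac,
            "fine_VF": 0.30 * self.excluded_frac,
            "slow_VT": 0.30 * self.excluded_frac,
        }


def _gen_interval(kind: str, patient, fs, dur, rng) -> np.ndarray:
    """One rhythm interval with patient-level morphology parameters."""
    seed = int(rng.integers(2**31))
    hr, amp, vf_f = patient["hr"], patient["amp"], patient["vf_freq"]
    wide = patient["wide"]
    jit = patient["jitter"]
    if kind == "NSR":
        return gen_sinus(hr, amp, fs, dur, jitter=jit, seed=seed, wide=wide)
    if kind == "AF":  # irregularly irregular, no P wave
        return gen_sinus(hr * 1.15, amp, fs, dur, jitter=0.18, seed=seed, wide=wide, with_p=False)
    if kind == "SVT":  # fast narrow-complex
        return gen_sinus(min(190.0, hr * 2.2), amp, fs, dur, jitter=0.02, seed=seed, with_p=False)
    if kind == "block":  # slow with dropped beats
        return gen_sinus(max(30.0, hr * 0.55), amp, fs, dur, jitter=0.10, seed=seed, wide=wide)
    if kind == "ectopic":  # bigeminy-like: alternating narrow/wide handled as jittered wide
        return gen_sinus(hr, amp * 1.1, fs, dur, jitter=0.12, seed=seed, wide=True)
    if kind == "VT":
        return gen_sinus(patient["vt_rate"], amp, fs, dur, jitter=0.02, seed=seed, wide=True, with_t=False)
    if kind == "VF":
        return gen_vf(vf_f, amp * patient["vf_amp"], fs, dur, seed=seed)
    if kind == "ventricular_flutter":
        return gen_vf(max(3.0, vf_f * 0.8), amp * patient["vf_amp"], fs, dur, drift=0.03, seed=seed)
    if kind in ("AS", "fine_VF", "slow_VT"):
        ec = {"AS": "asystole", "fine_VF": "fine_vf", "slow_VT": "slow_vt"}[kind]
        return gen_edge_case(ec, fs, dur, seed)[0]
    raise ConfigError(f"no generator for rhythm {kind!r}")


def gen_record(cfg: CohortConfig, patient_index: int) -> EcgRecord:
    """One synthetic patient record: a labeled sequence of rhythm intervals."""
    rng = np.random.default_rng([cfg.seed, patient_index])
    ohca = cfg.ohca_like
    patient = {
        "hr": rng.uniform(55.0, 100.0),
        "amp": rng.uniform(0.6, 1.4) * (0.8 if ohca else 1.0),
        "vf_freq": rng.uniform(4.0, 6.5) - (1.0 if ohca else 0.0),
        "vf_amp": rng.uniform(0.5, 0.9) * (0.6 if ohca else 1.0),
        "vt_rate": rng.uniform(160.0, 200.0),
        "wide": bool(ohca and rng.random() < 0.6),
        "jitter": 0.10 if ohca else 0.03,
    }
    mix = cfg.mix()
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds])
    probs = probs / probs.sum()
    n_total = int(round(cfg.record_seconds * cfg.fs))
    samples = np.zeros(n_total)
    intervals: list[RhythmInterval] = []
    pos = 0
    while pos < n_total:
        remaining = (n_total - pos) / cfg.fs
        if remaining < 4.0:
            break
        dur = float(min(rng.uniform(8.0, 20.0), remaining))
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        sig = _gen_interval(kind, patient, cfg.fs, dur, rng)
        end = min(pos + len(sig), n_total)
        samples[pos:end] = sig[: end - pos]
        intervals.append(RhythmInterval(pos, end, kind))
        pos = end
    noise_spans: list[tuple[int, int]] = []
    if rng.random() < cfg.noise_prob:
        ndur = int(rng.uniform(3.0, 6.0) * cfg.fs)
        s0 = int(rng.integers(0, max(1, n_total - ndur)))
        burst, _ = gen_edge_case("noise_burst", cfg.fs, ndur / cfg.fs, int(rng.integers(2**31)))
        samples[s0 : s0 + len(burst)] += burst
        noise_spans.append((s0, s0 + ndur))
    if cfg.quant_step_uv > 0:
        step_mv = cfg.quant_step_uv / 1000.0
        samples = np.round(samples / step_mv) * step_mv
    return EcgRecord(
        patient_id=f"syn{patient_index:03d}",
        source_db="synthetic",
        samples=samples,
        fs=cfg.fs,
        rhythm_intervals=intervals,
        noise_intervals=noise_spans,
    )


def gen_cohort(cfg: CohortConfig) -> list[EcgRecord]:
    """One record per synthetic patient, all randomness derived from cfg.seed."""
    return [gen_record(cfg, i) for i in range(cfg.n_patients)]
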