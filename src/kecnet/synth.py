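"""Seeded synthetic single-lead ECG with per-class morphology and rhythm.

Each beat is a sum of Gaussian bumps (P wave, QRS complex, T wave); beats
are placed at RR intervals drawn as mean_RR * (1 + jitter * z) with z
standard normal truncated at +-3 SD.  Classes differ in QRS width and
amplitude, P-wave presence, waveform distortion, rhythm regularity, and
premature-beat rate, so they are separable both morphologically (for the
convolutional path) and rhythmically (for the CV feature).  A 0.2 Hz
sinusoidal baseline wander at 5% of QRS amplitude is always present.

Every record carries its ground-truth R-peak positions, which serve as the
oracle for the QRS detector and downstream CV tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import rhythm
from .preprocessing import Segment, SegmentDataset, stratified_split, zscore_normalize

__all__ = [
    "SynthClassSpec",
    "SynthRecord",
    "default_class_specs",
    "rhythm_pair_specs",
    "synth_beat",
    "synth_record",
    "synth_dataset",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # Gaussian FWHM / sigma


@dataclass(frozen=True)
class SynthClassSpec:
    """Morphology and rhythm of one synthetic beat class."""

    class_label: str
    mean_hr: float = 75.0  # bpm
    rr_jitter: float = 0.01  # relative SD of RR intervals
    qrs_width_ms: float = 80.0  # full width at half maximum of the R bump
    qrs_amp: float = 1.0
    p_wave_present: bool = True
    premature_beat_rate: float = 0.0  # fraction of beats arriving early
    t_amp: float = 0.3
    biphasic_qrs: bool = False  # distorted morphology (Q-like class)
    #: wide complexes are notched (two merged sharp lobes), as real
    #: ventricular and fusion beats are — a single smooth hump of the same
    #: width would be spectrally empty above ~10 Hz, which no real QRS is
    notched_qrs: bool = False
    #: relative amplitude of an alternating short/long RR pattern
    #: (bigeminy-like alternans: irregular beat-to-beat, regular on average)
    rr_alternans: float = 0.0

    def __post_init__(self) -> None:
        if not 30.0 <= self.mean_hr <= 220.0:
            raise ValueError("mean_hr must be in [30, 220] bpm")
        if self.rr_jitter < 0:
            raise ValueError("rr_jitter must be nonnegative")
        if not 40.0 <= self.qrs_width_ms <= 200.0:
            raise ValueError("qrs_width_ms must be in [40, 200]")
        if not 0.0 <= self.premature_beat_rate <= 0.5:
            raise ValueError("premature_beat_rate must be in [0, 0.5]")


@dataclass
class SynthRecord:
    signal: np.ndarray
    fs: float
    true_r_peaks: np.ndarray  # sample indices
    true_label: str

    def __post_init__(self) -> None:
        self.true_r_peaks = np.asarray(self.true_r_peaks, dtype=int)
        if self.true_r_peaks.size > 1 and np.any(np.diff(self.true_r_peaks) <= 0):
            raise ValueError("true_r_peaks must be strictly increasing")


def default_class_specs() -> dict[str, SynthClassSpec]:
    """The five default study conditions, one per AAMI class.

    N: regular narrow beats with P waves.  S: narrow beats with frequent
    premature beats and moderate irregularity.  V: wide QRS, no P wave.
    F: intermediate width (fusion morphology).  Q: low-amplitude biphasic
    (distorted) beats, no P or T, irregular.
    """
    return {
        "N": SynthClassSpec("N", mean_hr=75, rr_jitter=0.01, qrs_width_ms=80,
                            qrs_amp=1.0, p_wave_present=True),
        "S": SynthClassSpec("S", mean_hr=85, rr_jitter=0.10, qrs_width_ms=70,
                            qrs_amp=1.0, p_wave_present=True,
                            premature_beat_rate=0.3),
        "V": SynthClassSpec("V", mean_hr=70, rr_jitter=0.05, qrs_width_ms=140,
                            qrs_amp=1.2, p_wave_present=False, notched_qrs=True),
        "F": SynthClassSpec("F", mean_hr=75, rr_jitter=0.05, qrs_width_ms=110,
                            qrs_amp=0.9, p_wave_present=True, notched_qrs=True),
        "Q": SynthClassSpec("Q", mean_hr=65, rr_jitter=0.15, qrs_width_ms=60,
                            qrs_amp=0.5, p_wave_present=False, t_amp=0.0,
                            biphasic_qrs=True),
    }


def rhythm_pair_specs() -> dict[str, SynthClassSpec]:
    """Two classes with identical beat morphology, different RR regularity.

    Used by the CV-fusion ablation.  The irregular class is a bigeminy-like
    RR alternans (alternating short/long intervals, 20% swing): its beats,
    average rate, and per-window beat count match the regular class, so a
    morphology-plus-density classifier has nothing to separate on — only
    the interval dispersion (CV ~ 0.20 vs ~ 0.01) distinguishes them.  The
    slow rate (48 bpm) and bare-QRS morphology (no P or T wave) keep every
    neighboring-beat spacing beyond the ~0.8 s receptive field of the
    convolutional stack, so the rhythm difference is genuinely invisible
    to the morphology path.
    """
    base = SynthClassSpec("N", mean_hr=48, rr_jitter=0.005, qrs_width_ms=80,
                          p_wave_present=False, t_amp=0.0)
    return {
        "N": base,
        "S": replace(base, class_label="S", rr_alternans=0.20),
    }


def synth_beat(spec: SynthClassSpec, fs: float) -> tuple[np.ndarray, int]:
    """One beat template and the index of its R peak within it.

    Covers [-0.30 s, +0.45 s] around the R peak: P bump at -160 ms (when
    present), the QRS complex, T bump at +280 ms.  The R wave is a
    Laplacian (cusped) pulse, exp(-|t|/tau) with full width at half
    maximum equal to the spec's QRS width: unlike a Gaussian, its sharp
    apex carries the broadband 10-40 Hz energy real QRS deflections have,
    which both the 5-15 Hz detection band and the upper filters of the
    sinc bank rely on.  P and T stay smooth (Gaussian), as in real ECG.
    """
    t = np.arange(int(round(-0.30 * fs)), int(round(0.45 * fs))) / fs
    r_index = int(np.argmin(np.abs(t)))
    width_s = spec.qrs_width_ms / 1000.0
    tau = width_s / (2.0 * np.log(2.0))
    sigma_qrs = width_s / _FWHM
    if spec.notched_qrs:
        # two merged sharp lobes spanning the nominal width: the apexes
        # keep the high-frequency content of a narrow beat while the
        # envelope stays wide; the R peak is the leading (taller) lobe
        lobe_tau = 0.55 * width_s / (2.0 * np.log(2.0))
        offset = 0.6 * width_s
        raw = (np.exp(-np.abs(t) / lobe_tau)
               + 0.85 * np.exp(-np.abs(t - offset) / lobe_tau))
        wave = spec.qrs_amp * raw / (1.0 + 0.85 * np.exp(-offset / lobe_tau))
    else:
        wave = spec.qrs_amp * np.exp(-np.abs(t) / tau)
    if spec.biphasic_qrs:
        # notched, partly inverted complex: late negative lobe of equal width
        wave -= 0.8 * spec.qrs_amp * np.exp(-np.abs(t - 2.2 * sigma_qrs) / tau)
    else:
        wave -= 0.15 * spec.qrs_amp * np.exp(-0.5 * ((t - 1.5 * sigma_qrs) / (0.6 * sigma_qrs)) ** 2)
    if spec.p_wave_present:
        wave += 0.15 * spec.qrs_amp * np.exp(-0.5 * ((t + 0.160) / 0.025) ** 2)
    if spec.t_amp:
        wave += spec.t_amp * spec.qrs_amp * np.exp(-0.5 * ((t - 0.280) / 0.060) ** 2)
    return wave, r_index


def synth_record(
    spec: SynthClassSpec,
    duration_s: float = 10.0,
    fs: float = 360.0,
    seed: int = 0,
    sensor_noise_snr_db: float = 35.0,
) -> SynthRecord:
    """One seeded record with ground-truth R-peak positions.

    Premature beats (probability ``premature_beat_rate`` per beat) arrive at
    55% of the drawn interval and are followed by a compensatory pause at
    145%.  Baseline wander: 0.2 Hz sinusoid, 5% of QRS amplitude, random
    phase.  A broadband sensor-noise floor (white, default 35 dB SNR, the
    order of a decent ambulatory recording) is always present: real
    recordings are never spectrally silent, and a model trained on
    zero-noise bands would meet test-time noise with degenerate feature
    statistics.  Pass ``numpy.inf`` to disable it.
    """
    if duration_s < 5.0:
        raise ValueError("duration must be >= 5 s")
    mean_rr = 60.0 / spec.mean_hr
    shortest = mean_rr * max(1.0 - 3.0 * spec.rr_jitter - spec.rr_alternans, 0.0)
    if spec.premature_beat_rate > 0:
        shortest *= 0.55
    if shortest < 0.1:
        raise ValueError("infeasible spec: RR interval shorter than a beat")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    signal = np.zeros(n)
    beat, r_index = synth_beat(spec, fs)

    times = []
    t = 0.25 + 0.1 * rng.random()  # first beat clear of the record edge
    compensatory = False
    parity = 1.0
    while t < duration_s - 0.45:
        times.append(t)
        z = np.clip(rng.standard_normal(), -3.0, 3.0)
        interval = mean_rr * (1.0 + spec.rr_jitter * z + spec.rr_alternans * parity)
        parity = -parity
        if compensatory:
            interval *= 1.45
            compensatory = False
        elif rng.random() < spec.premature_beat_rate:
            interval *= 0.55
            compensatory = True
        t += max(interval, 0.12)  # beats stay distinct samples apart

    peaks = []
    for tb in times:
        center = int(round(tb * fs))
        start = center - r_index
        stop = start + beat.size
        lo, hi = max(start, 0), min(stop, n)
        signal[lo:hi] += beat[lo - start: hi - start]
        peaks.append(center)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    wander = 0.05 * spec.qrs_amp * np.sin(2.0 * np.pi * 0.2 * np.arange(n) / fs + phase)
    signal = signal + wander
    if np.isfinite(sensor_noise_snr_db):
        floor = rng.standard_normal(n)
        p_signal = float(np.mean(signal**2))
        p_target = p_signal / 10.0 ** (sensor_noise_snr_db / 10.0)
        signal = signal + floor * np.sqrt(p_target / np.mean(floor**2))
    return SynthRecord(
        signal=signal,
        fs=fs,
        true_r_peaks=np.asarray(peaks, dtype=int),
        true_label=spec.class_label,
    )


def synth_dataset(
    specs: dict[str, SynthClassSpec] | None = None,
    n_per_class: int = 100,
    duration_s: float = 10.0,
    fs: float = 360.0,
    seed: int = 0,
    split_seed: int | None = None,
    sensor_noise_snr_db: float = 35.0,
) -> SegmentDataset:
    """Balanced labeled dataset of normalized segments with CV features.

    Generates ``n_per_class`` records per class, takes each record's full
    window as one segment (M = duration * fs), computes the CV via the
    rhythm pipeline on the raw signal, Z-scores the samples, and assigns
    stratified 70/10/20 split tags.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    specs = default_class_specs() if specs is None else specs
    root = np.random.default_rng(seed)
    segments: list[Segment] = []
    for cls in sorted(specs):
        spec = specs[cls]
        child_seeds = root.integers(0, 2**31 - 1, size=n_per_class)
        for j, s in enumerate(child_seeds):
            rec = synth_record(spec, duration_s=duration_s, fs=fs, seed=int(s),
                               sensor_noise_snr_db=sensor_noise_snr_db)
            feat = rhythm.segment_cv(rec.signal, fs)
            segments.append(
                Segment(
                    samples=zscore_normalize(rec.signal),
                    label=spec.class_label,
                    cv=feat.cv,
                    record_id=f"synth-{cls}-{j}",
                    start_index=0,
                )
            )
    dataset = SegmentDataset.from_segments(segments)
    return stratified_split(dataset, seed if split_seed is None else split_seed)
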