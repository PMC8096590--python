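"""Learnable windowed-sinc bandpass filter bank.

The first convolution layer of KecNet is a bank of bandpass filters whose
only learnable parameters are the low and high cut-off frequencies of each
band.  A bandpass filter with cutoffs ``f_L < f_H`` is the difference of two
low-pass sinc kernels,

    g[n] = 2*fH*sinc(2*pi*fH*n) - 2*fL*sinc(2*pi*fL*n),

evaluated at integer tap offsets ``n`` (frequencies normalized by the
sampling rate), and multiplied by a taper window to suppress spectral
leakage.  With ``sinc(0) = 1`` the center tap equals ``2*(fH - fL)/fs``.

This module owns kernel construction, the reparameterization that keeps
learned cutoffs inside ``[0, fs/2]``, frequency-response analysis, and the
parameter-gain arithmetic of a sinc layer versus a standard convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "WindowSpec",
    "SincParams",
    "FilterBank",
    "FrequencyResponse",
    "constrain_cutoffs",
    "window_values",
    "build_sinc_kernel",
    "init_cutoffs",
    "magnitude_response",
    "cumulative_frequency_response",
    "extract_bandwidths",
    "sinc_param_gain",
]

DEFAULT_MIN_BAND_HZ = 1.0
#: upper edge of the diagnostic ECG band used by the band_limited init (Hz)
ECG_BAND_HZ = 60.0


@dataclass(frozen=True)
class WindowSpec:
    """Taper applied to the truncated sinc kernel.

    ``hamming`` is the default (0.54 - 0.46*cos); ``hanning`` and ``kaiser``
    give near-identical trained models and are retained for the
    window-insensitivity checks.
    """

    kind: Literal["hamming", "hanning", "kaiser"] = "hamming"
    kaiser_beta: float = 8.0

    def __post_init__(self) -> None:
        if self.kind not in ("hamming", "hanning", "kaiser"):
            raise ValueError(f"unknown window kind: {self.kind!r}")
        if self.kaiser_beta < 0:
            raise ValueError("kaiser_beta must be nonnegative")


@dataclass
class SincParams:
    """Unconstrained per-filter parameters of a sinc layer.

    ``raw_low`` and ``raw_band`` are the free reals the optimizer touches;
    :func:`constrain_cutoffs` maps them to a valid band
    ``0 <= f_L < f_H <= fs/2``.
    """

    raw_low: np.ndarray
    raw_band: np.ndarray
    kernel_length: int
    sample_rate: float
    min_band: float = DEFAULT_MIN_BAND_HZ

    def __post_init__(self) -> None:
        self.raw_low = np.atleast_1d(np.asarray(self.raw_low, dtype=float))
        self.raw_band = np.atleast_1d(np.asarray(self.raw_band, dtype=float))
        if self.raw_low.shape != self.raw_band.shape:
            raise ValueError("raw_low and raw_band must have the same length")
        if self.n_filters < 1:
            raise ValueError("need at least one filter")
        _check_kernel_length(self.kernel_length)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_filters(self) -> int:
        return self.raw_low.size

    def cutoffs(self) -> np.ndarray:
        """(F, 2) array of constrained (f_L, f_H) pairs in Hz."""
        pairs = [
            constrain_cutoffs(lo, bw, self.sample_rate, self.min_band)
            for lo, bw in zip(self.raw_low, self.raw_band)
        ]
        return np.asarray(pairs, dtype=float)


@dataclass
class FilterBank:
    """Materialized kernels of a sinc layer with their cutoff pairs."""

    kernels: np.ndarray  # (F, L)
    cutoffs: np.ndarray  # (F, 2) Hz
    sample_rate: float

    def __post_init__(self) -> None:
        self.kernels = np.atleast_2d(np.asarray(self.kernels, dtype=float))
        self.cutoffs = np.atleast_2d(np.asarray(self.cutoffs, dtype=float))
        if self.kernels.shape[0] != self.cutoffs.shape[0]:
            raise ValueError("kernel count and cutoff count differ")


@dataclass
class FrequencyResponse:
    freqs: np.ndarray  # Hz on [0, fs/2]
    magnitude: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freqs, "magnitude": self.magnitude})


def _check_kernel_length(L: int) -> None:
    if L < 3 or L % 2 == 0:
        raise ValueError(f"kernel length must be odd and >= 3, got {L}")


def constrain_cutoffs(
    raw_low: float,
    raw_band: float,
    fs: float,
    min_band: float = DEFAULT_MIN_BAND_HZ,
) -> tuple[float, float]:
    """Map unconstrained reals to a valid cutoff pair.

    ``f_L = |raw_low|`` and ``f_H = f_L + max(|raw_band|, min_band)``, with
    both clipped to the Nyquist frequency ``fs/2``.  The optimizer can then
    move the raw values freely while every materialized kernel stays a valid
    bandpass.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if min_band <= 0:
        raise ValueError("min_band must be positive")
    if not (np.isfinite(raw_low) and np.isfinite(raw_band)):
        raise ValueError("non-finite cutoff parameters (corrupt state)")
    nyquist = fs / 2.0
    f_low = min(abs(raw_low), nyquist - min_band)
    f_high = min(f_low + max(abs(raw_band), min_band), nyquist)
    return float(f_low), float(f_high)


def window_values(L: int, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Length-``L`` symmetric taper with value 1 at the center tap.

    The cosine argument uses denominator ``L - 1`` so that
    ``w[n] = w[L-1-n]`` and the center sample of an odd-length window is
    exactly 1 (hamming: 0.54 - 0.46 = ... peaks at 0.54 + 0.46 = 1).
    """
    _check_kernel_length(L)
    half = (L - 1) // 2
    n = np.arange(half, dtype=float)
    if window.kind == "hamming":
        left = 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (L - 1))
    elif window.kind == "hanning":
        left = 0.5 - 0.5 * np.cos(2.0 * np.pi * n / (L - 1))
    else:  # kaiser
        left = np.kaiser(L, window.kaiser_beta)[:half]
    # center value is exactly 1 for all three kinds; the right half mirrors
    # the left bit-for-bit so windowed kernels stay exactly even-symmetric
    return np.concatenate([left, [1.0], left[::-1]])


def build_sinc_kernel(
    f_low: float,
    f_high: float,
    L: int,
    fs: float,
    window: WindowSpec = WindowSpec(),
) -> np.ndarray:
    """Materialize one windowed-sinc bandpass kernel.

    Taps are evaluated at symmetric integer offsets ``-(L-1)/2 .. (L-1)/2``
    with normalized frequencies ``f/fs``.  The kernel is an even function of
    the offset, so only the left half is computed and the right half is a
    bitwise mirror; the center tap is ``2*(f_high - f_low)/fs``.  A
    degenerate band ``f_low == f_high`` yields the zero kernel.
    """
    _check_kernel_length(L)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not (0.0 <= f_low <= f_high <= fs / 2.0):
        raise ValueError(
            f"cutoffs must satisfy 0 <= f_L <= f_H <= fs/2, got ({f_low}, {f_high})"
        )
    half = (L - 1) // 2
    n_left = np.arange(-half, 0, dtype=float)  # strictly negative offsets
    fl, fh = f_low / fs, f_high / fs

    def lowpass(f_hat: float, n: np.ndarray) -> np.ndarray:
        # 2*f*sinc(2*pi*f*n) with sinc(x) = sin(x)/x; n != 0 here
        x = 2.0 * np.pi * f_hat * n
        with np.errstate(invalid="ignore"):
            vals = np.where(x == 0.0, 2.0 * f_hat, 2.0 * f_hat * np.sin(x) / np.where(x == 0.0, 1.0, x))
        return vals

    left = lowpass(fh, n_left) - lowpass(fl, n_left)
    center = 2.0 * (fh - fl)
    kernel = np.concatenate([left, [center], left[::-1]])
    return kernel * window_values(L, window)


def init_cutoffs(
    n_filters: int,
    fs: float,
    strategy: Literal["uniform", "band_limited"] = "band_limited",
    seed: int = 0,
    kernel_length: int = 251,
    min_band: float = DEFAULT_MIN_BAND_HZ,
) -> SincParams:
    """Seeded initial cutoff pairs spanning the target band.

    ``uniform`` spreads contiguous bands over the full ``[0, fs/2]``;
    ``band_limited`` (the default) spreads them over the 0-60 Hz diagnostic
    ECG band, where P/T-wave and QRS energy lives.  Band edges are jittered
    slightly so filters are not exact translates of each other.
    """
    if n_filters < 1:
        raise ValueError("n_filters must be >= 1")
    rng = np.random.default_rng(seed)
    top = fs / 2.0 if strategy == "uniform" else min(ECG_BAND_HZ, fs / 2.0)
    edges = np.linspace(0.0, top, n_filters + 1)
    width = edges[1] - edges[0]
    lows = edges[:-1] + rng.uniform(0.0, 0.1 * width, size=n_filters)
    bands = np.maximum(
        (edges[1:] - lows) * rng.uniform(0.9, 1.1, size=n_filters), min_band
    )
    bands = np.minimum(bands, top - lows)  # keep every f_H inside the band
    return SincParams(
        raw_low=lows,
        raw_band=bands,
        kernel_length=kernel_length,
        sample_rate=fs,
        min_band=min_band,
    )


def build_filterbank(
    params: SincParams, window: WindowSpec = WindowSpec()
) -> FilterBank:
    """Materialize every filter of ``params`` into a :class:`FilterBank`."""
    cut = params.cutoffs()
    kernels = np.stack(
        [
            build_sinc_kernel(fl, fh, params.kernel_length, params.sample_rate, window)
            for fl, fh in cut
        ]
    )
    return FilterBank(kernels=kernels, cutoffs=cut, sample_rate=params.sample_rate)


def magnitude_response(
    kernel: np.ndarray, fs: float, n_freq: int = 2048
) -> FrequencyResponse:
    """DFT magnitude of one kernel on ``n_freq`` points over ``[0, fs/2]``."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("empty kernel")
    if n_freq < kernel.size:
        raise ValueError("n_freq must be >= kernel length")
    mag = np.abs(np.fft.rfft(kernel, n=2 * (n_freq - 1)))
    freqs = np.linspace(0.0, fs / 2.0, mag.size)
    return FrequencyResponse(freqs=freqs, magnitude=mag)


def cumulative_frequency_response(
    bank: FilterBank, n_freq: int = 2048
) -> FrequencyResponse:
    """Sum of per-filter magnitudes, normalized to peak 1.

    Shows which frequency bands the whole bank covers; on a trained model the
    mass concentrates where the class-discriminating ECG energy is.
    """
    if bank.kernels.shape[0] == 0:
        raise ValueError("empty filter bank")
    total = None
    for row in bank.kernels:
        resp = magnitude_response(row, bank.sample_rate, n_freq)
        total = resp.magnitude if total is None else total + resp.magnitude
    peak = total.max()
    if peak == 0.0:
        raise ValueError("all-zero filter bank: cumulative response undefined")
    return FrequencyResponse(freqs=resp.freqs, magnitude=total / peak)


def extract_bandwidths(params: SincParams) -> pd.DataFrame:
    """Learned band table, one row per filter, sorted by ``f_L`` ascending.

    Columns ``filter_index`` (position in the bank), ``f_L_hz``, ``f_H_hz``.
    """
    cut = params.cutoffs()
    frame = pd.DataFrame(
        {
            "filter_index": np.arange(params.n_filters),
            "f_L_hz": cut[:, 0],
            "f_H_hz": cut[:, 1],
        }
    )
    return frame.sort_values(["f_L_hz", "f_H_hz"], kind="mergesort").reset_index(
        drop=True
    )


def sinc_param_gain(L: int) -> float:
    """Per-layer parameter reduction (%) of a sinc layer vs a standard one.

    A standard 1-D convolution layer with F kernels of length L learns F*L
    taps; the sinc layer learns 2 cutoffs per filter, so the reduction is
    ``(1 - 2/L) * 100`` independent of F.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    return (1.0 - 2.0 / L) * 100.0
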