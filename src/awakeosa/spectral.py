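"""Power-spectral and bispectral estimation for breath-phase signals.

Per-phase spectra use the Welch method; bispectra use the indirect
(cumulant-based) class of conventional estimators: the third-order
cumulant sequence is estimated (unbiased normalization), tapered with a
Parzen lag window, and transformed to the bifrequency plane with a 2-D
FFT. Group contrasts are summarized by the mean spectrum with a 95%
confidence envelope on the dB scale, and discriminative bands are the
frequency runs where two groups' envelopes do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft as sfft
from scipy import signal as sps

from .cohort import BreathPhaseSignal

__all__ = [
    "SpectrumEstimate",
    "BispectrumEstimate",
    "BandSet",
    "GroupSpectrum",
    "welch_psd",
    "indirect_bispectrum",
    "average_spectra",
    "average_bispectra",
    "group_average_spectrum",
    "find_discriminative_bands",
]


@dataclass
class SpectrumEstimate:
    """One-sided Welch PSD on a uniform frequency grid (power/Hz, linear)."""

    frequencies: np.ndarray
    power: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def to_frame(self):
        """Columnar (frequency, power) view for serialization/inspection."""
        import pandas as pd

        return pd.DataFrame({"frequency_hz": self.frequencies, "power": self.power})


@dataclass
class BispectrumEstimate:
    """Bispectrum over the non-negative bifrequency quadrant.

    ``values[i, j]`` estimates B(freq_grid[i], freq_grid[j]); the
    estimate is symmetric in its two arguments.
    """

    freq_grid: np.ndarray
    values: np.ndarray  # complex, shape (len(freq_grid), len(freq_grid))
    params: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def df(self) -> float:
        return float(self.freq_grid[1] - self.freq_grid[0])

    def to_frame(self):
        """Long-form (f1, f2, magnitude) view for serialization/inspection."""
        import pandas as pd

        f1, f2 = np.meshgrid(self.freq_grid, self.freq_grid, indexing="ij")
        return pd.DataFrame({
            "f1_hz": f1.ravel(), "f2_hz": f2.ravel(),
            "magnitude": self.magnitude.ravel(),
        })


@dataclass
class BandSet:
    """Sorted, non-overlapping closed frequency intervals [f_low, f_high]."""

    bands: list[tuple[float, float]]
    provenance: str = "fixed"

    def __iter__(self):
        return iter(self.bands)

    def __len__(self):
        return len(self.bands)


#: The four discriminative bands used for feature extraction (Hz).
FIXED_BANDS = BandSet(
    bands=[(100.0, 300.0), (350.0, 600.0), (1000.0, 1700.0), (2100.0, 2400.0)],
    provenance="fixed",
)


def _samples_fs(phase, sampling_rate):
    if isinstance(phase, BreathPhaseSignal):
        return phase.samples, phase.sampling_rate
    if sampling_rate is None:
        raise ValueError("sampling_rate required for raw arrays")
    return np.asarray(phase, dtype=float), float(sampling_rate)


def welch_psd(
    phase: BreathPhaseSignal | np.ndarray,
    sampling_rate: float | None = None,
    nperseg: int = 1024,
    overlap: float = 0.5,
    nfft: int | None = None,
) -> SpectrumEstimate:
    """Welch PSD with a Hann window (defaults: 1024-sample segments, 50%
    overlap), one-sided, density scaling so that the integral over
    frequency matches the signal variance."""
    x, fs = _samples_fs(phase, sampling_rate)
    if np.var(x) == 0:
        raise ValueError("zero-variance signal has no meaningful PSD")
    nperseg = min(nperseg, x.size)
    f, p = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(overlap * nperseg),
        nfft=nfft or nperseg,
        detrend="constant",
        scaling="density",
    )
    return SpectrumEstimate(f, p, {"nperseg": nperseg, "overlap": overlap, "fs": fs})


def _parzen(u: np.ndarray) -> np.ndarray:
    a = np.abs(u)
    w = np.zeros_like(a)
    inner = a <= 0.5
    outer = (a > 0.5) & (a <= 1.0)
    w[inner] = 1 - 6 * a[inner] ** 2 + 6 * a[inner] ** 3
    w[outer] = 2 * (1 - a[outer]) ** 3
    return w


def _third_cumulant(x: np.ndarray, max_lag: int, dtype=np.float64) -> np.ndarray:
    """Unbiased third-order cumulant c3(m, n) for |m|, |n| <= max_lag.

    Computed for m >= 0 via FFT cross-correlations of the lagged-product
    rows y_m(k) = x(k) x(k+m) with x, then completed by the cumulant
    symmetries c3(m, n) = c3(n, m) = c3(-m, n - m).
    """
    x = np.asarray(x, dtype=dtype)
    x = x - x.mean()
    n = x.size
    L = max_lag
    if n < 2 * L:
        raise ValueError("signal shorter than twice the cumulant max lag")
    P = sfft.next_fast_len(n + L)
    y = np.zeros((L + 1, n), dtype=dtype)
    for m in range(L + 1):
        y[m, : n - m] = x[: n - m] * x[m:]
    xf = sfft.rfft(x, P)
    yf = sfft.rfft(y, P, axis=1)
    # cross-correlation sum_k y_m(k) x(k+n): lag n at index n mod P
    cc = sfft.irfft(np.conj(yf) * xf[None, :], P, axis=1)
    half = np.empty((L + 1, 2 * L + 1))
    lags = np.arange(-L, L + 1)
    half[:, L:] = cc[:, : L + 1]
    half[:, :L] = cc[:, P - L : P]
    # unbiased normalization: number of valid products at lags (m, n)
    m = np.arange(L + 1)[:, None]
    nn = lags[None, :]
    counts = n - (np.maximum(np.maximum(m, nn), 0) - np.minimum(np.minimum(m, nn), 0))
    half /= np.maximum(counts, 1)
    half = half.astype(np.float64)

    c3 = np.empty((2 * L + 1, 2 * L + 1))
    c3[L:, :] = half  # m >= 0
    for mi in range(-L, 0):
        row = np.empty(2 * L + 1)
        nonneg = lags >= 0
        # n >= 0: c3(m, n) = c3(n, m)
        row[nonneg] = half[lags[nonneg], L + mi]
        # n < 0: c3(m, n) = c3(-m, n - m)
        neg = ~nonneg
        row[neg] = half[-mi, L + lags[neg] - mi]
        c3[L + mi, :] = row
    return c3


def indirect_bispectrum(
    phase: BreathPhaseSignal | np.ndarray,
    sampling_rate: float | None = None,
    max_lag: int = 255,
    nfft: int = 512,
    lag_window: str | None = "parzen",
    dtype=np.float64,
) -> BispectrumEstimate:
    """Indirect-class bispectrum estimate.

    The third-order cumulant is estimated to ``max_lag`` with unbiased
    normalization, tapered with the product Parzen window
    w(m) w(n) w(m - n), and Fourier transformed; the non-negative
    quadrant up to Nyquist is returned on a ``fs / nfft`` grid.
    """
    x, fs = _samples_fs(phase, sampling_rate)
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the segment length")
    if x.size < 8 * max_lag:
        # still computable, but warn-level short; enforced precondition
        # is only that the cumulant sums are non-degenerate
        pass
    c3 = _third_cumulant(x, max_lag, dtype=dtype)
    L = max_lag
    lags = np.arange(-L, L + 1)
    if lag_window == "parzen":
        w1 = _parzen(lags / L)
        w2 = w1[:, None] * w1[None, :] * _parzen((lags[:, None] - lags[None, :]) / L)
        c3 = c3 * w2
    elif lag_window is not None:
        raise ValueError(f"unknown lag window {lag_window!r}")

    if nfft < 2 * L + 1:
        raise ValueError("nfft must be at least 2 * max_lag + 1")
    full = np.zeros((nfft, nfft))
    full[: L + 1, : L + 1] = c3[L:, L:]
    full[: L + 1, nfft - L :] = c3[L:, :L]
    full[nfft - L :, : L + 1] = c3[:L, L:]
    full[nfft - L :, nfft - L :] = c3[:L, :L]
    B = sfft.fft2(full)
    half = nfft // 2
    quad = B[: half + 1, : half + 1]
    freqs = np.arange(half + 1) * fs / nfft
    # enforce exact argument symmetry (holds analytically; rounding aside)
    quad = 0.5 * (quad + quad.T)
    return BispectrumEstimate(
        freqs, quad, {"max_lag": max_lag, "nfft": nfft, "lag_window": lag_window, "fs": fs}
    )


def _common_grid(estimates: Sequence, attr: str) -> np.ndarray:
    grids = [getattr(e, attr) for e in estimates]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("estimates are not on a common frequency grid")
    return grids[0]


def average_spectra(estimates: Sequence[SpectrumEstimate]) -> SpectrumEstimate:
    """Average linear-power spectra across breath cycles."""
    f = _common_grid(estimates, "frequencies")
    p = np.mean([e.power for e in estimates], axis=0)
    return SpectrumEstimate(f, p, dict(estimates[0].params, n_averaged=len(estimates)))


def average_bispectra(estimates: Sequence[BispectrumEstimate]) -> BispectrumEstimate:
    """Average bispectra (complex) across breath cycles."""
    f = _common_grid(estimates, "freq_grid")
    v = np.mean([e.values for e in estimates], axis=0)
    return BispectrumEstimate(f, v, dict(estimates[0].params, n_averaged=len(estimates)))


@dataclass
class GroupSpectrum:
    """Mean spectrum of a subject group with a 95% CI envelope (dB scale)."""

    frequencies: np.ndarray
    mean_db: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_subjects: int


def group_average_spectrum(estimates: Sequence[SpectrumEstimate]) -> GroupSpectrum:
    """Per-frequency mean and 95% CI of the group mean, on the dB scale.

    The CI is the normal approximation mean +/- 1.96 * SE across
    subjects; at least two subjects are required.
    """
    if len(estimates) < 2:
        raise ValueError("group averaging needs at least 2 subjects")
    f = _common_grid(estimates, "frequencies")
    db = 10.0 * np.log10(np.stack([e.power for e in estimates]) + 1e-30)
    mean = db.mean(axis=0)
    se = db.std(axis=0, ddof=1) / np.sqrt(db.shape[0])
    return GroupSpectrum(f, mean, mean - 1.96 * se, mean + 1.96 * se, db.shape[0])


def find_discriminative_bands(
    group_a: GroupSpectrum,
    group_b: GroupSpectrum,
    min_bandwidth: float = 100.0,
) -> BandSet:
    """Frequency bands where the two groups' 95% CI envelopes are disjoint.

    Maximal contiguous runs of grid points with non-overlapping
    [lower, upper] envelopes are returned as closed intervals; runs
    spanning less than ``min_bandwidth`` Hz are discarded. Symmetric in
    its two arguments.
    """
    if group_a.frequencies.shape != group_b.frequencies.shape or not np.allclose(
        group_a.frequencies, group_b.frequencies
    ):
        raise ValueError("groups are not on a common frequency grid")
    f = group_a.frequencies
    disjoint = (group_a.ci_lower > group_b.ci_upper) | (group_b.ci_lower > group_a.ci_upper)
    bands = []
    if disjoint.any():
        padded = np.concatenate(([False], disjoint, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for lo, hi in zip(edges[::2], edges[1::2]):
            f_lo, f_hi = float(f[lo]), float(f[hi - 1])
            if f_hi - f_lo >= min_bandwidth:
                bands.append((f_lo, f_hi))
    return BandSet(bands, provenance="discovered")
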