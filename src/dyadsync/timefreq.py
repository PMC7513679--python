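"""Complex Morlet wavelet decomposition on the analysis frequency grid.

The transform correlates the signal with unit-energy complex Morlet
kernels; the coefficient phase of a pure sinusoid therefore advances like
the analytic phase. Samples within one kernel half-support of a recording
edge are flagged invalid so boundary effects never enter segment averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .grids import AnalysisGrid

DEFAULT_N_CYCLES = 7.0
_SUPPORT_SIGMAS = 4.0


def morlet_kernel(freq: float, fs: float,
                  n_cycles: float = DEFAULT_N_CYCLES) -> np.ndarray:
    """Unit-energy complex Morlet kernel at ``freq`` Hz (odd length).

    Gaussian envelope with sigma_t = n_cycles / (2 pi f), truncated at
    +-4 sigma.
    """
    if n_cycles < 3:
        raise ValueError("n_cycles must be >= 3")
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(_SUPPORT_SIGMAS * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    k = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return k / np.sqrt(np.sum(np.abs(k) ** 2))


def kernel_half_support(freq: float, fs: float,
                        n_cycles: float = DEFAULT_N_CYCLES) -> int:
    """Half-length in samples of the kernel at ``freq``."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    return int(np.ceil(_SUPPORT_SIGMAS * sigma_t * fs))


def _check_fs(fs: float, freqs: np.ndarray) -> None:
    if fs <= 2.0 * float(np.max(freqs)):
        raise ValueError(
            f"fs = {fs} Hz violates Nyquist for the {np.max(freqs)} Hz bin"
        )


@dataclass
class WaveletStack:
    """Complex Morlet coefficients, channel x frequency x time.

    ``valid[f, t]`` is False within one kernel half-support of an edge
    (per frequency, low frequencies have wider invalid margins).
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    fs: float
    valid: np.ndarray
    n_cycles: float = DEFAULT_N_CYCLES

    def __post_init__(self) -> None:
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (n_channels, n_freqs, n_samples)")
        if self.coeffs.shape[1] != len(self.freqs):
            raise ValueError("frequency axis does not match the grid")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite wavelet coefficients")


def morlet_transform(x: np.ndarray, fs: float,
                     grid: AnalysisGrid | np.ndarray,
                     n_cycles: float = DEFAULT_N_CYCLES) -> WaveletStack:
    """Full-length Morlet transform of one or more channels.

    Parameters
    ----------
    x : ndarray, (n_samples,) or (n_channels, n_samples)
    grid : AnalysisGrid or array of frequencies in Hz
    """
    freqs = grid.freqs if isinstance(grid, AnalysisGrid) else np.asarray(grid, float)
    _check_fs(fs, freqs)
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n_ch, n_t = x.shape
    coeffs = np.empty((n_ch, len(freqs), n_t), dtype=np.complex128)
    valid = np.zeros((len(freqs), n_t), dtype=bool)
    for fi, f in enumerate(freqs):
        k = morlet_kernel(f, fs, n_cycles)
        coeffs[:, fi, :] = fftconvolve(x, np.conj(k[::-1])[None, :],
                                       mode="same", axes=1)
        half = len(k) // 2
        if n_t > 2 * half:
            valid[fi, half:n_t - half] = True
    return WaveletStack(coeffs=coeffs, freqs=freqs, fs=fs, valid=valid,
                        n_cycles=n_cycles)


def morlet_at_times(x: np.ndarray, fs: float,
                    freqs: np.ndarray, centers: np.ndarray,
                    n_cycles: float = DEFAULT_N_CYCLES
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Morlet coefficients evaluated only at given center samples.

    Equivalent to sampling :func:`morlet_transform` at ``centers`` but
    without materialising the full time axis; used by the windowed
    coherence and pattern pipelines.

    Returns
    -------
    coeffs : (n_channels, n_freqs, n_centers) complex
    valid : (n_freqs, n_centers) bool
        False where the kernel support extends past the data edges.
    """
    freqs = np.asarray(freqs, dtype=float)
    _check_fs(fs, freqs)
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n_ch, n_t = x.shape
    centers = np.asarray(centers, dtype=int)
    max_half = kernel_half_support(float(np.min(freqs)), fs, n_cycles)
    xp = np.pad(x, ((0, 0), (max_half, max_half)))
    coeffs = np.empty((n_ch, len(freqs), len(centers)), dtype=np.complex128)
    valid = np.zeros((len(freqs), len(centers)), dtype=bool)
    for fi, f in enumerate(freqs):
        k = morlet_kernel(f, fs, n_cycles)
        half = len(k) // 2
        offs = np.arange(-half, half + 1)
        idx = centers[:, None] + max_half + offs[None, :]
        win = xp[:, idx]                       # (n_ch, n_centers, len(k))
        coeffs[:, fi, :] = win @ np.conj(k)
        valid[fi, :] = (centers - half >= 0) & (centers + half < n_t)
    return coeffs, valid


def power(stack: WaveletStack) -> np.ndarray:
    """Squared coefficient magnitude (non-negative)."""
    return np.abs(stack.coeffs) ** 2


def phase(stack: WaveletStack, tiny: float = 1e-300) -> np.ndarray:
    """Coefficient phase in (-pi, pi]; NaN where the magnitude vanishes
    or the sample is boundary-invalid."""
    ph = np.angle(stack.coeffs)
    bad = (np.abs(stack.coeffs) <= tiny) | ~stack.valid[None, :, :]
    ph = np.where(bad, np.nan, ph)
    return ph
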