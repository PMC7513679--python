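"""Analysis grid: frequency bins, reporting bands, sliding-window geometry.

The default grid spans 15-40 Hz in 0.5 Hz steps (f = 51 bins, low/high
beta and low/medium gamma), analysed in 80 ms windows stepped by 40 ms.
An 80 ms window fully represents one cycle of 12.5 Hz and above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Band:
    """Reporting band [lo, hi] Hz; ``lo_inclusive=False`` opens the lower edge.

    The four default rows are 20-24, 25-30, 30-34 and 35-39 Hz. The
    25-30/30-34 rows share the 30 Hz edge; the 30.0 Hz bin is assigned to
    the 25-30 row only, so the 30-34 band is open at its lower edge.
    """

    name: str
    lo: float
    hi: float
    lo_inclusive: bool = True

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        lo_ok = freqs >= self.lo if self.lo_inclusive else freqs > self.lo
        return lo_ok & (freqs <= self.hi)


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("20-24", 20.0, 24.0),
    Band("25-30", 25.0, 30.0),
    Band("30-34", 30.0, 34.0, lo_inclusive=False),
    Band("35-39", 35.0, 39.0),
)


@dataclass(frozen=True)
class AnalysisGrid:
    """Frequency grid plus sliding-window parameters.

    Parameters
    ----------
    f_min, f_max, f_step : float
        Frequency grid bounds and resolution in Hz (defaults 15, 40, 0.5).
    win_ms, step_ms : float
        Sliding-window length and step in ms (defaults 80, 40).
    bands : tuple of Band
        Named reporting bands; must lie inside [f_min, f_max].
    """

    f_min: float = 15.0
    f_max: float = 40.0
    f_step: float = 0.5
    win_ms: float = 80.0
    step_ms: float = 40.0
    bands: tuple[Band, ...] = field(default=DEFAULT_BANDS)

    def __post_init__(self) -> None:
        if not (self.f_min > 0 and self.f_max >= self.f_min and self.f_step > 0):
            raise ValueError("invalid frequency grid bounds")
        if self.win_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window length and step must be positive")
        for b in self.bands:
            if b.lo < self.f_min or b.hi > self.f_max:
                raise ValueError(f"band {b.name} outside grid range")

    @property
    def freqs(self) -> np.ndarray:
        """Ascending frequency bins in Hz (51 bins for the defaults)."""
        n = int(round((self.f_max - self.f_min) / self.f_step)) + 1
        return self.f_min + self.f_step * np.arange(n)

    @property
    def n_freqs(self) -> int:
        return len(self.freqs)

    @property
    def min_window_freq_hz(self) -> float:
        """Lowest frequency with a full cycle inside one window (1000/win_ms)."""
        return 1000.0 / self.win_ms

    def band(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"unknown band {name!r}")

    def band_mask(self, name: str) -> np.ndarray:
        return self.band(name).mask(self.freqs)


def state_space_dims(grid: AnalysisGrid, k: int) -> tuple[int, int]:
    """Dimensionality of the dyadic power and phase-coherence state spaces.

    For k electrodes per subject and f grid frequencies the dyadic wavelet
    power space has 2*k*f dimensions (one power per subject, electrode and
    frequency) and the phase-coherence space has k*(2k-1)*f dimensions
    (one PLV per unordered pair of the dyad's 2k electrodes and frequency).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    f = grid.n_freqs
    return 2 * k * f, k * (2 * k - 1) * f
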