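"""Sliding-window phase-locking value per electrode pair and frequency.

Phase coherence of electrodes j and k at grid frequency phi over one
behavioral segment is

    c_jk(phi) = (1/N) | sum_n exp(i (phi_n(j) - phi_n(k))) |

where n runs over the N sliding windows (80 ms, stepped by 40 ms) fully
inside the segment and phi_n is the wavelet phase of the window. Dyad
electrodes are numbered subject 1 first (j = 1..k), then subject 2
(j = k+1..2k); intra-brain coherence averages pairs within one subject
(k(k-1)/2 pairs), inter-brain coherence averages pairs spanning the two
subjects (k^2 pairs, not only anatomically corresponding ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AnalysisGrid
from .preprocess import ArtifactMask
from .recording import DualRecording, SegmentTable
from .timefreq import DEFAULT_N_CYCLES, kernel_half_support, morlet_at_times

log = logging.getLogger(__name__)

SCOPES = ("intra_1", "intra_2", "inter")


class SegmentUncomputable(ValueError):
    """Raised when a segment has fewer than 2 valid windows."""


def segment_windows(onset_ms: float, offset_ms: float, grid: AnalysisGrid,
                    fs: float, valid: np.ndarray | None = None,
                    t0: float = 0.0) -> np.ndarray:
    """Start samples of the valid sliding windows of one segment.

    Windows are [onset + m*step, onset + m*step + win) for m = 0, 1, ...
    while they fit inside the segment; windows overlapping samples
    flagged invalid (for either subject) are dropped. Raises
    :class:`SegmentUncomputable` if fewer than 2 windows remain.
    """
    if offset_ms - onset_ms < grid.win_ms:
        raise SegmentUncomputable(
            f"segment [{onset_ms}, {offset_ms}) ms shorter than one window")
    win = int(round(grid.win_ms * fs / 1000.0))
    step = int(round(grid.step_ms * fs / 1000.0))
    a = int(round((onset_ms - t0) * fs / 1000.0))
    b = int(round((offset_ms - t0) * fs / 1000.0))
    starts = np.arange(a, b - win + 1, step)
    if valid is not None:
        v = np.atleast_2d(valid).all(axis=0)
        ok = np.array([v[s:s + win].all() for s in starts])
        starts = starts[ok]
    if len(starts) < 2:
        raise SegmentUncomputable(
            f"segment [{onset_ms}, {offset_ms}) ms has "
            f"{len(starts)} valid window(s); need >= 2")
    return starts


def plv(phases_j: np.ndarray, phases_k: np.ndarray) -> float:
    """Phase-locking value of two per-window phase sequences.

    Symmetric in (j, k), invariant under a common phase offset, and in
    [0, 1]: 1 for a constant phase difference, ~1/sqrt(N) for
    independent phases.
    """
    phases_j = np.asarray(phases_j, dtype=float)
    phases_k = np.asarray(phases_k, dtype=float)
    if phases_j.shape != phases_k.shape:
        raise ValueError("phase sequences must have equal length")
    n = len(phases_j)
    if n < 2:
        raise ValueError("PLV needs at least 2 windows")
    if not (np.all(np.isfinite(phases_j)) and np.all(np.isfinite(phases_k))):
        raise ValueError("phases must be finite")
    return float(np.abs(np.sum(np.exp(1j * (phases_j - phases_k)))) / n)


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLV from a (n_electrodes, N) phase table (unit diagonal)."""
    z = np.exp(1j * phases)
    n = phases.shape[1]
    return np.abs(z @ z.conj().T) / n


@dataclass
class SegmentCoherence:
    """PLV of every dyad electrode pair and grid frequency, one segment."""

    plv: np.ndarray        # (n_freqs, 2k, 2k), symmetric, unit diagonal
    freqs: np.ndarray
    k: int                 # scalp electrodes per subject
    n_windows: int
    trial: int | None = None
    segment: str | None = None

    def scope_index(self, scope: str) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the unordered pairs in one scope."""
        k = self.k
        if scope == "intra_1":
            i, j = np.triu_indices(k, 1)
        elif scope == "intra_2":
            i, j = np.triu_indices(k, 1)
            i, j = i + k, j + k
        elif scope == "inter":
            i, j = np.meshgrid(np.arange(k), np.arange(k, 2 * k),
                               indexing="ij")
            i, j = i.ravel(), j.ravel()
        else:
            raise ValueError(f"unknown scope {scope!r}")
        return i, j

    def aggregate(self, grid: AnalysisGrid, band: str, scope: str) -> float:
        """Mean PLV over a reporting band and pair scope."""
        fmask = grid.band_mask(band)
        if not fmask.any():
            raise ValueError(f"band {band!r} covers no grid frequency")
        i, j = self.scope_index(scope)
        if len(i) == 0:
            raise ValueError(f"scope {scope!r} has no pairs")
        return float(self.plv[fmask][:, i, j].mean())


def window_phases(rec: DualRecording, starts: np.ndarray, grid: AnalysisGrid,
                  n_cycles: float = DEFAULT_N_CYCLES,
                  phase_mode: str = "center") -> np.ndarray:
    """Per-window wavelet phases of all 2k dyad electrodes.

    The representative phase of an 80 ms window is, by default, the
    coefficient phase at the window's center sample (``phase_mode
    "center"``); ``"mean"`` uses the circular mean of the per-sample
    phases inside the window. Windows whose kernel support would leave
    the recording are dropped (the caller sees fewer windows).

    Returns an array (2k, n_freqs, N).
    """
    win = int(round(grid.win_ms * rec.fs / 1000.0))
    centers = starts + win // 2
    # evaluate on a padded local slice to keep the per-segment cost low
    half = kernel_half_support(float(grid.freqs.min()), rec.fs, n_cycles)
    a = max(int(starts.min()) - half - win, 0)
    b = min(int(starts.max()) + 2 * win + half, rec.n_samples)
    local = np.vstack([rec.samples[0][rec.scalp_indices(0), a:b],
                       rec.samples[1][rec.scalp_indices(1), a:b]])
    if phase_mode == "center":
        coeffs, valid = morlet_at_times(local, rec.fs, grid.freqs,
                                        centers - a, n_cycles)
        edge_ok = (centers - half >= 0) & (centers + half < rec.n_samples)
        keep = valid.all(axis=0) & edge_ok
        return np.angle(coeffs[:, :, keep])
    if phase_mode == "mean":
        offs = np.arange(win)
        sample_idx = (starts[:, None] + offs[None, :]).ravel()
        coeffs, _ = morlet_at_times(local, rec.fs, grid.freqs,
                                    sample_idx - a, n_cycles)
        shape = coeffs.shape[:2] + (len(starts), win)
        unit = coeffs.reshape(shape)
        unit = unit / np.maximum(np.abs(unit), 1e-300)
        edge_ok = ((starts >= half) & (starts + win + half < rec.n_samples))
        return np.angle(unit.mean(axis=3))[:, :, edge_ok]
    raise ValueError(f"unknown phase_mode {phase_mode!r}")


def segment_coherence(rec: DualRecording, onset_ms: float, offset_ms: float,
                      grid: AnalysisGrid, mask: ArtifactMask | None = None,
                      n_cycles: float = DEFAULT_N_CYCLES,
                      phase_mode: str = "center",
                      trial: int | None = None,
                      segment: str | None = None) -> SegmentCoherence:
    """Windowed PLV for every pair and frequency over one trial segment."""
    valid = mask.valid if mask is not None else None
    starts = segment_windows(onset_ms, offset_ms, grid, rec.fs, valid,
                             t0=rec.t0)
    phases = window_phases(rec, starts, grid, n_cycles, phase_mode)
    n = phases.shape[2]
    if n < 2:
        raise SegmentUncomputable(
            f"segment [{onset_ms}, {offset_ms}) ms: {n} usable window(s)")
    k = rec.n_scalp
    mats = np.stack([plv_matrix(phases[:, fi, :])
                     for fi in range(phases.shape[1])])
    return SegmentCoherence(plv=mats, freqs=grid.freqs, k=k, n_windows=n,
                            trial=trial, segment=segment)


def coherence_table(rec: DualRecording, segments: SegmentTable,
                    grid: AnalysisGrid, mask: ArtifactMask | None = None,
                    segment_ids: tuple[str, ...] | None = None,
                    scopes: tuple[str, ...] = SCOPES,
                    n_cycles: float = DEFAULT_N_CYCLES,
                    phase_mode: str = "center") -> pd.DataFrame:
    """Band-averaged coherence per (trial, segment, band, scope).

    Segments with fewer than 2 valid windows are excluded with a logged
    reason. Columns: trial, segment, band, scope, mean_plv, n_windows.
    """
    rows = []
    for _, seg in segments.df.iterrows():
        if segment_ids is not None and seg["segment"] not in segment_ids:
            continue
        try:
            sc = segment_coherence(rec, seg["onset_ms"], seg["offset_ms"],
                                   grid, mask, n_cycles, phase_mode,
                                   trial=seg["trial"], segment=seg["segment"])
        except SegmentUncomputable as err:
            log.info("trial %s segment %s uncomputable: %s",
                     seg["trial"], seg["segment"], err)
            continue
        for band in grid.bands:
            for scope in scopes:
                rows.append((seg["trial"], seg["segment"], band.name, scope,
                             sc.aggregate(grid, band.name, scope),
                             sc.n_windows))
    return pd.DataFrame(rows, columns=["trial", "segment", "band", "scope",
                                       "mean_plv", "n_windows"])
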