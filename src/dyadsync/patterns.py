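"""Dyadic wavelet-power patterns and class-specificity mining.

One pattern per trial: the dyad's mean wavelet power over the valid s1
windows, flattened to a 2*k*f vector (subject-major, electrode-major,
frequency-minor; 6,120 dimensions for the defaults). The distance
between patterns x and y is

    d(x, y) = ||x - y||^2 / (||x|| ||y||)

(squared Euclidean distance over the product of Euclidean norms). A
pattern is specific to its readiness class when its 10th-percentile
distance to the other class exceeds its 10th-percentile distance within
its own class; the percentile keeps intra-class distances small while
staying robust to outliers, so specific patterns can be found even for
strongly overlapping classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .coherence import SegmentUncomputable, segment_windows
from .grids import AnalysisGrid
from .preprocess import ArtifactMask
from .recording import DualRecording, SegmentTable
from scipy import fft as _fft

from .timefreq import (DEFAULT_N_CYCLES, kernel_half_support, morlet_kernel)

log = logging.getLogger(__name__)


_KERNEL_FFT_CACHE: dict = {}


def _slice_power(data: np.ndarray, fs: float, freqs: np.ndarray,
                 n_cycles: float, sample_idx: np.ndarray) -> np.ndarray:
    """Wavelet power of ``data`` (n_ch, n_t) at ``sample_idx`` columns.

    FFT cross-correlation with conjugated Morlet kernels; kernel spectra
    are cached per (fft length, fs, n_cycles), which makes repeated
    per-trial calls cheap.
    """
    n_ch, n_t = data.shape
    nfft = _fft.next_fast_len(
        n_t + kernel_half_support(float(freqs.min()), fs, n_cycles))
    key = (nfft, fs, n_cycles, freqs.tobytes())
    if key not in _KERNEL_FFT_CACHE:
        spectra = np.empty((len(freqs), nfft), dtype=np.complex128)
        for fi, f in enumerate(freqs):
            k = morlet_kernel(f, fs, n_cycles)
            h = len(k) // 2
            ka = np.zeros(nfft, dtype=np.complex128)
            ka[: h + 1] = k[h:]
            ka[-h:] = k[:h]
            spectra[fi] = np.conj(_fft.fft(ka))
        _KERNEL_FFT_CACHE[key] = spectra
    spectra = _KERNEL_FFT_CACHE[key]
    X = _fft.fft(data, n=nfft, axis=1)
    out = np.empty((n_ch, len(freqs), len(sample_idx)))
    for fi in range(len(freqs)):
        coeff = _fft.ifft(X * spectra[fi][None, :], axis=1)[:, sample_idx]
        out[:, fi, :] = np.abs(coeff) ** 2
    return out


def flatten_pattern(tensor: np.ndarray) -> np.ndarray:
    """(2, k, f) power tensor -> 2*k*f vector (subject, electrode, freq)."""
    if tensor.ndim != 3 or tensor.shape[0] != 2:
        raise ValueError("pattern tensor must be (2, k, f)")
    return tensor.reshape(-1)

def unflatten_pattern(vec: np.ndarray, k: int, f: int) -> np.ndarray:
    return np.asarray(vec).reshape(2, k, f)


@dataclass
class PatternSet:
    """Per-trial dyadic power patterns with readiness-class labels."""

    X: np.ndarray                 # (n_patterns, 2*k*f), entries >= 0
    trials: np.ndarray
    labels: np.ndarray            # "high" / "low" / "middle"
    k: int
    f: int
    roles: tuple[str, str] = ("leader", "follower")
    df: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.X.shape[1] != 2 * self.k * self.f:
            raise ValueError("pattern length != 2*k*f")
        if np.any(self.X < 0):
            raise ValueError("power patterns must be non-negative")
        if np.any(np.linalg.norm(self.X, axis=1) == 0):
            raise ValueError("zero-norm pattern")

    def subject_block(self, subject: int) -> np.ndarray:
        """(n_patterns, k, f) power of one subject."""
        return self.X.reshape(-1, 2, self.k, self.f)[:, subject]

    def subject_of_role(self, role: str) -> int:
        return self.roles.index(role)

    def select(self, mask: np.ndarray) -> "PatternSet":
        return PatternSet(X=self.X[mask], trials=self.trials[mask],
                          labels=self.labels[mask], k=self.k, f=self.f,
                          roles=self.roles)


def build_patterns(rec: DualRecording, segments: SegmentTable,
                   grid: AnalysisGrid, mask: ArtifactMask | None = None,
                   readiness: pd.DataFrame | None = None,
                   segment_id: str = "s1", reduce: str = "mean",
                   log_power: bool = False,
                   n_cycles: float = DEFAULT_N_CYCLES) -> PatternSet:
    """One dyadic power pattern per trial from the s1 windows.

    The power of one window is the squared coefficient magnitude
    averaged over the window's samples; windows are reduced by the mean
    (or median). Trials whose segment has no valid window are excluded
    with a logged reason.
    ``readiness`` (from :func:`~dyadsync.readiness.leader_readiness`)
    supplies class labels; without it all labels are "middle".
    """
    if reduce not in ("mean", "median"):
        raise ValueError("reduce must be 'mean' or 'median'")
    k = rec.n_scalp
    f = grid.n_freqs
    win = int(round(grid.win_ms * rec.fs / 1000.0))
    labels_by_trial = {}
    if readiness is not None:
        labels_by_trial = dict(zip(readiness["trial"],
                                   readiness["readiness_class"]))
    vecs, trials, labels = [], [], []
    scalp_idx = (rec.scalp_indices(0), rec.scalp_indices(1))
    for _, seg in segments.rows(segment=segment_id).iterrows():
        valid = mask.valid if mask is not None else None
        try:
            starts = segment_windows(seg["onset_ms"], seg["offset_ms"], grid,
                                     rec.fs, valid, t0=rec.t0)
        except SegmentUncomputable as err:
            log.info("trial %s: no pattern (%s)", seg["trial"], err)
            continue
        samples_idx = np.unique((starts[:, None]
                                 + np.arange(win)[None, :]).ravel())
        half = kernel_half_support(float(grid.freqs.min()), rec.fs, n_cycles)
        a = max(int(samples_idx.min()) - half - 1, 0)
        b = min(int(samples_idx.max()) + half + 2, rec.n_samples)
        sl = np.vstack([rec.samples[0][scalp_idx[0], a:b],
                        rec.samples[1][scalp_idx[1], a:b]])
        p = _slice_power(sl, rec.fs, grid.freqs,
                         n_cycles, samples_idx - a)         # (2k, f, T)
        red = np.mean if reduce == "mean" else np.median
        pat = red(p, axis=2).reshape(2, k, f)
        if log_power:
            pat = np.log10(pat + 1e-30)
            pat -= pat.min()  # keep entries non-negative
        vecs.append(flatten_pattern(pat))
        trials.append(seg["trial"])
        labels.append(labels_by_trial.get(seg["trial"], "middle"))
    if not vecs:
        raise ValueError(f"no computable {segment_id} pattern in any trial")
    return PatternSet(X=np.array(vecs), trials=np.array(trials),
                      labels=np.array(labels), k=k, f=f, roles=rec.roles)


# -- normalized distance geometry --------------------------------------


def pattern_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Euclidean distance normalized by the product of norms.

    d(x, x) = 0; orthogonal unit vectors give 2; antipodal unit vectors
    give 4. Invariant under joint scaling of both arguments, but not
    under scaling one argument alone.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("pattern distance undefined for zero-norm input")
    return float(np.sum((x - y) ** 2) / (nx * ny))


def distance_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Pairwise normalized squared distances between pattern rows."""
    Y = X if Y is None else Y
    sq = cdist(X, Y, metric="sqeuclidean")
    norms = np.outer(np.linalg.norm(X, axis=1), np.linalg.norm(Y, axis=1))
    if np.any(norms == 0):
        raise ValueError("pattern distance undefined for zero-norm input")
    return sq / norms


def block_distance_matrix(X_high: np.ndarray, X_low: np.ndarray) -> np.ndarray:
    """(N+n) x (N+n) distance matrix, high patterns first.

    Diagonal N x N and n x n blocks hold the intra-class distances, the
    off-diagonal rectangular blocks the inter-class distances (each
    other's transpose by symmetry). The diagonal is zero.
    """
    if len(X_high) < 2 or len(X_low) < 2:
        raise ValueError("each class needs at least 2 patterns")
    top = np.hstack([distance_matrix(X_high), distance_matrix(X_high, X_low)])
    bot = np.hstack([distance_matrix(X_low, X_high), distance_matrix(X_low)])
    return np.vstack([top, bot])


def _percentile_rank(m: int, percentile: float) -> int:
    """0-based index of the smallest order statistic with cumulative
    fraction >= percentile/100 (deterministic ceiling rule)."""
    return max(int(np.ceil(percentile / 100.0 * m)), 1) - 1


def class_distances(D: np.ndarray, n_high: int,
                    percentile: float = 10.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern 10th-percentile intra- and inter-class distances.

    For each pattern (column of the block matrix) its intra-block
    distances are sorted ascending after removing the self-distance; the
    intra-class distance is the value at the percentile rank, and
    likewise for the inter block (which has no self-distance).
    """
    total = D.shape[0]
    n_low = total - n_high
    if min(n_high, n_low) < 2:
        raise ValueError("need >= 2 patterns per class "
                         "(fewer than 2 intra distances)")
    intra = np.empty(total)
    inter = np.empty(total)
    for c in range(total):
        own = slice(0, n_high) if c < n_high else slice(n_high, total)
        other = slice(n_high, total) if c < n_high else slice(0, n_high)
        col_intra = np.sort(np.delete(D[own, c], c - own.start))
        col_inter = np.sort(D[other, c])
        intra[c] = col_intra[_percentile_rank(len(col_intra), percentile)]
        inter[c] = col_inter[_percentile_rank(len(col_inter), percentile)]
    return intra, inter


def specific_patterns(intra: np.ndarray, inter: np.ndarray) -> np.ndarray:
    """Specificity flags: strictly greater inter- than intra-class
    distance (ties are not specific)."""
    return np.asarray(inter) > np.asarray(intra)


def mine_specific(patterns: PatternSet, percentile: float = 10.0
                  ) -> pd.DataFrame:
    """Specificity ledger for the high/low patterns of one dyad.

    Middle-class patterns are ignored. Returns one row per high/low
    pattern: trial, readiness_class, intra_d, inter_d, specific.
    """
    hi = patterns.labels == "high"
    lo = patterns.labels == "low"
    D = block_distance_matrix(patterns.X[hi], patterns.X[lo])
    intra, inter = class_distances(D, int(hi.sum()), percentile)
    spec = specific_patterns(intra, inter)
    trials = np.concatenate([patterns.trials[hi], patterns.trials[lo]])
    classes = ["high"] * int(hi.sum()) + ["low"] * int(lo.sum())
    return pd.DataFrame({
        "trial": trials, "readiness_class": classes,
        "intra_d": intra, "inter_d": inter, "specific": spec,
    })
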