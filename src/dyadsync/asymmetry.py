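"""Electrode clustering and cross-frequency asymmetry of power patterns.

Two analyses of the specific dyadic wavelet-power patterns:

* per team role, the k x k correlation matrix between electrode power
  profiles (concatenated over frequencies and patterns), reordered by
  spectral clustering so correlated electrode sets appear as diagonal
  blocks;
* per readiness class, the f x f inter-subject correlation matrix of
  the centro-parietal set-mean power (rows: follower frequencies,
  columns: leader frequencies), an asymmetry coefficient per element
  pair, and a paired Wilcoxon signed-rank test comparing the asymmetry
  of the high- and low-readiness matrices. Large asymmetry at (i, j)
  means follower frequency i co-occurs with leader frequency j but not
  vice versa — role-dependent, cross-frequency coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter
from sklearn.cluster import SpectralClustering

from .patterns import PatternSet

log = logging.getLogger(__name__)


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations between A (m, p) and B (m, q).

    Zero-variance columns yield NaN entries.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Az = A - A.mean(axis=0)
    Bz = B - B.mean(axis=0)
    sa = np.sqrt(np.sum(Az**2, axis=0))
    sb = np.sqrt(np.sum(Bz**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = (Az.T @ Bz) / np.outer(sa, sb)
    M[:, sb == 0] = np.nan
    M[sa == 0, :] = np.nan
    return M


def electrode_corr(patterns: PatternSet, role: str) -> np.ndarray:
    """k x k electrode correlation matrix for one team role.

    Each electrode's profile is its power concatenated over
    (pattern, frequency); entries are Pearson correlations between
    profiles (unit diagonal, symmetric). Zero-variance profiles give
    NaN rows/columns, which the clustering step excludes.
    """
    if len(patterns.X) < 2:
        raise ValueError("need at least 2 patterns")
    block = patterns.subject_block(patterns.subject_of_role(role))
    profiles = block.transpose(1, 0, 2).reshape(patterns.k, -1)  # (k, P*f)
    C = _pearson_matrix(profiles.T, profiles.T)
    np.fill_diagonal(C, np.where(np.isnan(np.diag(C)), np.nan, 1.0))
    return C


def eigengap_n_clusters(corr: np.ndarray, k_max: int = 10) -> int:
    """Cluster count from the largest eigengap of the normalized
    graph Laplacian of the affinity (corr + 1) / 2."""
    A = (corr + 1.0) / 2.0
    np.fill_diagonal(A, 0.0)
    d = A.sum(axis=1)
    d_inv = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    L = np.eye(len(A)) - d_inv[:, None] * A * d_inv[None, :]
    w = np.sort(np.linalg.eigvalsh(L))
    gaps = np.diff(w[: k_max + 1])
    return int(np.argmax(gaps[1:]) + 2)  # at least 2 clusters


def spectral_reorder(corr: np.ndarray, n_clusters: int | None = None,
                     random_state: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Reorder a correlation matrix so correlated clusters form blocks.

    Spectral clustering on the affinity (corr + 1)/2; electrodes are
    ordered by cluster, clusters by descending mean within-cluster
    correlation. NaN rows (undefined profiles) are placed last in a
    cluster of their own. Returns (permutation, cluster labels aligned
    with the original electrode order; excluded electrodes get -1).
    """
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    ok = ~np.all(np.isnan(corr), axis=1)
    sub = corr[np.ix_(ok, ok)]
    if n_clusters is None:
        n_clusters = eigengap_n_clusters(sub)
    if not 2 <= n_clusters <= sub.shape[0]:
        raise ValueError("n_clusters out of range")
    affinity = (sub + 1.0) / 2.0
    model = SpectralClustering(n_clusters=n_clusters, affinity="precomputed",
                               assign_labels="discretize",
                               random_state=random_state)
    sub_labels = model.fit_predict(affinity)
    labels = np.full(k, -1)
    labels[ok] = sub_labels
    # order clusters by descending mean within-cluster correlation
    means = {}
    for c in range(n_clusters):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            block = corr[np.ix_(idx, idx)]
            means[c] = float(np.nanmean(block[np.triu_indices(len(idx), 1)]))
        else:
            means[c] = -np.inf
    order = sorted(range(n_clusters), key=lambda c: -means[c])
    perm = np.concatenate(
        [np.flatnonzero(labels == c) for c in order]
        + [np.flatnonzero(labels == -1)]).astype(int)
    return perm, labels


def frequency_corr(patterns: PatternSet, electrode_labels: tuple[str, ...],
                   scalp_labels: tuple[str, ...]) -> np.ndarray:
    """f x f inter-subject correlation of centro-parietal set-mean power.

    Entry (i, j) is the Pearson correlation, across the given patterns,
    between the follower's set-mean power at frequency i and the
    leader's set-mean power at frequency j. Needs >= 3 patterns.
    """
    if len(patterns.X) < 3:
        raise ValueError("need at least 3 specific patterns in the class")
    idx = [scalp_labels.index(lbl) for lbl in electrode_labels]
    if not idx:
        raise ValueError("empty electrode set")
    fol = patterns.subject_block(patterns.subject_of_role("follower"))
    led = patterns.subject_block(patterns.subject_of_role("leader"))
    fol_mean = fol[:, idx, :].mean(axis=1)   # (P, f)
    led_mean = led[:, idx, :].mean(axis=1)
    return _pearson_matrix(fol_mean, led_mean)


def asymmetry_coefficient(M: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair asymmetry |M(i, j) - M(j, i)| for all i < j.

    Returns (i indices, j indices, coefficients); f(f-1)/2 values, all
    >= 0, zero for a symmetric matrix, and invariant under transposition.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    i, j = np.triu_indices(M.shape[0], 1)
    return i, j, np.abs(M[i, j] - M[j, i])


@dataclass(frozen=True)
class AsymmetryTest:
    statistic: float
    p: float
    direction: int  # sign of the median paired difference (high - low)


def asymmetry_test(a_high: np.ndarray, a_low: np.ndarray) -> AsymmetryTest:
    """Two-sided Wilcoxon signed-rank test on paired asymmetry
    coefficients (high - low); zero differences are dropped (classic
    Wilcoxon). All-zero differences give an undefined (NaN) result."""
    a_high = np.asarray(a_high, dtype=float)
    a_low = np.asarray(a_low, dtype=float)
    if a_high.shape != a_low.shape:
        raise ValueError("coefficient vectors must be paired")
    diff = a_high - a_low
    finite = np.isfinite(diff)
    diff = diff[finite]
    if np.all(diff == 0) or len(diff) == 0:
        log.warning("all paired differences zero; test undefined")
        return AsymmetryTest(float("nan"), float("nan"), 0)
    res = stats.wilcoxon(a_high[finite], a_low[finite],
                         zero_method="wilcox", alternative="two-sided")
    return AsymmetryTest(float(res.statistic), float(res.pvalue),
                         int(np.sign(np.median(diff))))


def top_asymmetric_pairs(M: np.ndarray, freqs: np.ndarray, n_pairs: int = 2,
                         smooth_hz: float = 2.0,
                         exclusion_hz: tuple[float, float] = (4.5, 6.5),
                         margin_hz: float = 2.0
                         ) -> list[tuple[float, float]]:
    """Frequency pairs with the largest asymmetry, peak-picked.

    The signed asymmetry map is built from Fisher-z transformed
    correlations (so the sampling noise of every element has equal
    variance regardless of the local power variance) and smoothed over
    ``smooth_hz``, matching the Morlet frequency resolution (sigma_f =
    f / n_cycles, 2-6 Hz over the grid) — a localization finer than the
    transform bandwidth is not meaningful. After taking the strongest
    pair, candidates sharing its orientation within
    ``exclusion_hz = (follower tol, leader tol)`` are suppressed — the
    leader tolerance is wider because an asymmetry blob's sampling noise
    is correlated along its leader axis (cells of one row share the same
    follower power series), producing ridge echoes — as are
    mirror-oriented near-duplicates. Each returned pair thus comes from
    a distinct asymmetry blob. Peaks within
    ``margin_hz`` of the grid edges are not candidates (one-sided
    smoothing support makes boundary estimates unreliable). Pairs are
    returned as (follower Hz, leader Hz), oriented so the follower-row
    entry is the larger one.
    """
    M = np.asarray(M, dtype=float)
    Z = np.arctanh(np.clip(np.nan_to_num(M), -0.999, 0.999))
    A = Z - Z.T
    step = float(freqs[1] - freqs[0])
    if smooth_hz > 0:
        # matched-filter score: kernel-weighted sum normalized by the
        # root of the summed squared weights, so the sampling noise of
        # the score is constant up to the matrix boundary (a plain
        # boundary-padded smoother over-weights edge noise)
        s = smooth_hz / step
        num = gaussian_filter(A, s, mode="constant")
        den = np.sqrt(gaussian_filter(np.ones_like(A), s / np.sqrt(2.0),
                                      mode="constant"))
        A = num / den
    i, j = np.triu_indices(M.shape[0], 1)
    a = np.abs(A[i, j]).astype(float)
    if margin_hz > 0:
        interior = ((freqs >= freqs.min() + margin_hz)
                    & (freqs <= freqs.max() - margin_hz))
        a[~(interior[i] & interior[j])] = -np.inf
    out = []
    for _ in range(n_pairs):
        best = int(np.argmax(a))
        if not np.isfinite(a[best]) or a[best] == -np.inf:
            break
        bi, bj = i[best], j[best]
        if A[bi, bj] >= 0:   # follower row co-occurs with leader column
            fol0, led0 = float(freqs[bi]), float(freqs[bj])
        else:
            fol0, led0 = float(freqs[bj]), float(freqs[bi])
        out.append((fol0, led0))
        tol_f, tol_l = exclusion_hz
        # oriented coordinates of every candidate pair
        cand_fol = np.where(A[i, j] >= 0, freqs[i], freqs[j])
        cand_led = np.where(A[i, j] >= 0, freqs[j], freqs[i])
        near = ((np.abs(cand_fol - fol0) <= tol_f)
                & (np.abs(cand_led - led0) <= tol_l))
        near |= ((np.abs(cand_fol - led0) <= 2.5)
                 & (np.abs(cand_led - fol0) <= 2.5))  # mirror duplicates
        a[near] = -np.inf
    return out
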