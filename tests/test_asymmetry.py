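"""Electrode clustering and cross-frequency asymmetry statistics."""

import numpy as np
import pytest
from scipy import stats

from dyadsync import (asymmetry_coefficient, asymmetry_test, electrode_corr,
                      frequency_corr, spectral_reorder, top_asymmetric_pairs)
from dyadsync.asymmetry import _pearson_matrix, eigengap_n_clusters
from dyadsync.patterns import PatternSet


def _pattern_set(rng, n_patterns=12, k=8, f=10, labels=None):
    X = np.abs(rng.normal(5.0, 1.0, size=(n_patterns, 2 * k * f))) + 0.1
    labels = labels if labels is not None else np.array(["high"] * n_patterns)
    return PatternSet(X=X, trials=np.arange(n_patterns), labels=labels,
                      k=k, f=f, roles=("leader", "follower"))


# ----------------------------------------------------------- correlations


def test_pearson_matrix_matches_scipy(rng):
    A = rng.normal(size=(15, 4))
    B = rng.normal(size=(15, 3))
    M = _pearson_matrix(A, B)
    for i in range(4):
        for j in range(3):
            r = stats.pearsonr(A[:, i], B[:, j])[0]
            assert M[i, j] == pytest.approx(r, abs=1e-12)


def test_electrode_corr_identical_profiles(rng):
    ps = _pattern_set(rng)
    block = ps.subject_block(0)
    block[:, 1, :] = block[:, 0, :]  # duplicate electrode profile
    ps = PatternSet(X=np.concatenate(
        [block.reshape(len(ps.X), -1), ps.subject_block(1).reshape(len(ps.X), -1)],
        axis=1), trials=ps.trials, labels=ps.labels, k=ps.k, f=ps.f,
        roles=ps.roles)
    C = electrode_corr(ps, "leader")
    assert C[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(C, C.T, equal_nan=True)
    assert np.allclose(np.diag(C), 1.0)


def test_electrode_corr_matches_bruteforce(rng):
    ps = _pattern_set(rng, n_patterns=9, k=5, f=6)
    C = electrode_corr(ps, "follower")
    block = ps.subject_block(ps.subject_of_role("follower"))
    profiles = block.transpose(1, 0, 2).reshape(5, -1)
    for i in range(5):
        for j in range(5):
            r = stats.pearsonr(profiles[i], profiles[j])[0]
            assert C[i, j] == pytest.approx(r, abs=1e-12)


# ------------------------------------------------------------ clustering


def _block_corr(rng, sizes=(7, 6, 5), within=0.9, between=0.0):
    k = sum(sizes)
    C = np.full((k, k), between)
    start = 0
    for sz in sizes:
        C[start:start + sz, start:start + sz] = within
        start += sz
    np.fill_diagonal(C, 1.0)
    perm = rng.permutation(k)
    return C[np.ix_(perm, perm)], perm


def test_spectral_reorder_recovers_planted_blocks():
    """Exact 3-block matrices are recovered for 20 random permutations."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        C, perm = _block_corr(rng)
        order, labels = spectral_reorder(C, n_clusters=3)
        # every planted block maps to exactly one recovered cluster
        truth = np.repeat([0, 1, 2], [7, 6, 5])[perm]
        for b in range(3):
            assert len(set(labels[truth == b])) == 1  # block kept together
        assert len(set(labels)) == 3
        assert sorted(order.tolist()) == list(range(18))  # a permutation


def test_eigengap_finds_three_blocks(rng):
    C, _ = _block_corr(rng)
    assert eigengap_n_clusters(C) == 3


def test_reordered_matrix_is_block_diagonal(rng):
    C, _ = _block_corr(rng)
    order, _ = spectral_reorder(C, n_clusters=3)
    R = C[np.ix_(order, order)]
    # within the first recovered block all correlations are the planted 0.9
    first = R[:5, :5]
    assert np.all(first[~np.eye(5, dtype=bool)] == 0.9)


# ------------------------------------------------------------- asymmetry


def test_symmetric_matrix_zero_asymmetry(rng):
    A = rng.normal(size=(6, 6))
    M = (A + A.T) / 2
    _, _, a = asymmetry_coefficient(M)
    assert np.allclose(a, 0.0)


def test_asymmetry_direct_value():
    M = np.eye(3)
    M[0, 1], M[1, 0] = 0.8, 0.2
    i, j, a = asymmetry_coefficient(M)
    pair = np.flatnonzero((i == 0) & (j == 1))[0]
    assert a[pair] == pytest.approx(0.6)


def test_asymmetry_transpose_invariant(rng):
    M = rng.normal(size=(8, 8))
    _, _, a1 = asymmetry_coefficient(M)
    _, _, a2 = asymmetry_coefficient(M.T)
    assert np.allclose(a1, a2)


def test_asymmetry_test_undefined_for_equal_inputs(rng):
    a = np.abs(rng.normal(size=20))
    res = asymmetry_test(a, a.copy())
    assert np.isnan(res.p) and res.direction == 0


def test_asymmetry_test_matches_manual_signed_rank():
    """Exact signed-rank enumeration oracle on a small fixture."""
    a_high = np.array([0.9, 0.8, 0.6, 0.7, 0.85, 0.4])
    a_low = np.array([0.2, 0.5, 0.7, 0.3, 0.25, 0.45])
    res = asymmetry_test(a_high, a_low)
    d = a_high - a_low
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    w = min(w_pos, w_neg)
    # exact two-sided p: enumerate all sign assignments
    n = len(d)
    count = 0
    for m in range(2**n):
        signs = [(m >> b) & 1 for b in range(n)]
        ws = sum(r for r, s in zip(ranks, signs) if s)
        if min(ws, n * (n + 1) / 2 - ws) <= w:
            count += 1
    p_exact = count / 2**n
    assert res.statistic == pytest.approx(w)
    assert res.p == pytest.approx(p_exact, abs=1e-12)
    assert res.direction == 1


def test_asymmetry_test_null_calibration():
    """Type-I rate near alpha for matrices built from iid patterns."""
    rng = np.random.default_rng(99)
    hits = 0
    reps = 400
    for _ in range(reps):
        Mh = _pearson_matrix(rng.normal(size=(12, 20)),
                             rng.normal(size=(12, 20)))
        Ml = _pearson_matrix(rng.normal(size=(12, 20)),
                             rng.normal(size=(12, 20)))
        _, _, ah = asymmetry_coefficient(Mh)
        _, _, al = asymmetry_coefficient(Ml)
        res = asymmetry_test(ah, al)
        hits += res.p < 0.05
    assert 0.02 <= hits / reps <= 0.08


def test_top_pairs_recover_planted_asymmetric_entries(rng):
    f = np.arange(15.0, 40.5, 0.5)
    M = 0.05 * rng.normal(size=(51, 51))
    def bi(x): return int(np.argmin(np.abs(f - x)))
    M[bi(25), bi(18)] = 0.9   # follower 25 <-> leader 18
    M[bi(20), bi(30)] = 0.9   # follower 20 <-> leader 30
    pairs = top_asymmetric_pairs(M, f, smooth_hz=0.5)
    assert len(pairs) == 2
    assert all(any(abs(p[0] - q[0]) <= 1.0 and abs(p[1] - q[1]) <= 1.0
                   for q in ((25.0, 18.0), (20.0, 30.0))) for p in pairs)
    # transposing the matrix flips the orientation
    pairs_t = top_asymmetric_pairs(M.T, f, smooth_hz=0.5)
    assert {tuple(p) for p in pairs} == {(b, a) for a, b in pairs_t}


def test_frequency_corr_planted_symmetric_diag(rng):
    """Shared set-mean amplitudes at equal frequencies produce a large
    diagonal in the follower-by-leader matrix."""
    from dyadsync.montage import CENTRO_PARIETAL, SCALP_CHANNELS
    k, f = 60, 10
    n_pat = 40
    shared = rng.lognormal(0, 0.6, size=(n_pat, f))
    X = np.abs(rng.normal(1.0, 0.05, size=(n_pat, 2, k, f)))
    idx = [SCALP_CHANNELS.index(l) for l in CENTRO_PARIETAL]
    for s in (0, 1):
        X[:, s, idx, :] += shared[:, None, :]
    ps = PatternSet(X=X.reshape(n_pat, -1), trials=np.arange(n_pat),
                    labels=np.array(["high"] * n_pat), k=k, f=f,
                    roles=("leader", "follower"))
    M = frequency_corr(ps, CENTRO_PARIETAL, SCALP_CHANNELS)
    assert np.mean(np.diag(M)) > 0.9
    off = M[~np.eye(f, dtype=bool)]
    assert np.abs(off).mean() < 0.3


def test_frequency_corr_needs_three_patterns(rng):
    from dyadsync.montage import CENTRO_PARIETAL, SCALP_CHANNELS
    ps = _pattern_set(rng, n_patterns=2, k=60, f=4)
    with pytest.raises(ValueError, match="at least 3"):
        frequency_corr(ps, CENTRO_PARIETAL, SCALP_CHANNELS)
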