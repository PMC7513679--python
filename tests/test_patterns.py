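"""Dyadic power patterns and the distance-based specificity miner."""

import numpy as np
import pandas as pd
import pytest

from dyadsync import (AnalysisGrid, DualRecording, SegmentTable,
                      block_distance_matrix, build_patterns, class_distances,
                      distance_matrix, flatten_pattern, mine_specific,
                      pattern_distance, specific_patterns, unflatten_pattern)
from dyadsync.montage import CENTRO_PARIETAL, EOG_CHANNELS, SCALP_CHANNELS
from dyadsync.patterns import _percentile_rank


# ------------------------------------------------------------- distance


def test_distance_identities():
    x = np.array([1.0, 0.0])
    y = np.array([0.0, 1.0])
    assert pattern_distance(x, x) == 0.0
    assert pattern_distance(x, y) == pytest.approx(2.0)      # orthogonal
    assert pattern_distance(x, -x) == pytest.approx(4.0)     # antipodal


def test_distance_joint_scaling_invariance(rng):
    for _ in range(20):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a = float(rng.uniform(0.1, 9.0))
        assert pattern_distance(a * x, a * y) == pytest.approx(
            pattern_distance(x, y), rel=1e-12)


def test_distance_not_one_sided_scale_invariant(rng):
    x = np.abs(rng.normal(size=20)) + 0.1
    y = np.abs(rng.normal(size=20)) + 0.1
    assert pattern_distance(3.0 * x, y) != pytest.approx(
        pattern_distance(x, y), rel=1e-3)


def test_zero_norm_rejected():
    with pytest.raises(ValueError, match="zero-norm"):
        pattern_distance(np.zeros(4), np.ones(4))


def test_block_matrix_hand_computed():
    """N = n = 2 block matrix matches element-wise hand computation."""
    Xh = np.array([[1.0, 0.0], [1.0, 1.0]])
    Xl = np.array([[0.0, 1.0], [2.0, 0.0]])
    D = block_distance_matrix(Xh, Xl)
    expect = np.zeros((4, 4))
    allv = np.vstack([Xh, Xl])
    for i in range(4):
        for j in range(4):
            if i != j:
                expect[i, j] = pattern_distance(allv[i], allv[j])
    assert np.allclose(D, expect)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)


def test_block_matrix_class_permutation(rng):
    Xh = np.abs(rng.normal(size=(4, 10))) + 0.1
    Xl = np.abs(rng.normal(size=(5, 10))) + 0.1
    D = block_distance_matrix(Xh, Xl)
    perm = rng.permutation(4)
    Dp = block_distance_matrix(Xh[perm], Xl)
    idx = np.concatenate([perm, np.arange(4, 9)])
    assert np.allclose(Dp, D[np.ix_(idx, idx)])


def test_small_class_rejected(rng):
    with pytest.raises(ValueError):
        block_distance_matrix(np.ones((1, 5)), np.ones((3, 5)))


# ----------------------------------------------------- class distances


def test_percentile_rank_ceiling_rule():
    assert _percentile_rank(10, 10.0) == 0    # value 1 in {1..10}
    assert _percentile_rank(25, 10.0) == 2    # ceil(2.5) = 3 -> index 2
    assert _percentile_rank(3, 10.0) == 0


def test_class_distances_order_statistics_example():
    """A column with intra distances {1..10} has 10th-percentile 1."""
    n = 11
    D = np.zeros((n + 5, n + 5))
    # column 0 intra distances 1..10
    D[1:n, 0] = D[0, 1:n] = np.arange(1, n)
    D[n:, 0] = D[0, n:] = 100.0
    # fill remaining entries symmetrically with arbitrary positives
    rng = np.random.default_rng(0)
    fill = np.abs(rng.normal(5, 1, size=(n + 5, n + 5)))
    fill = (fill + fill.T) / 2
    upper = np.triu(np.ones_like(D, dtype=bool), 1)
    blank = (D == 0) & upper
    D[blank] = fill[blank]
    D = np.triu(D, 1) + np.triu(D, 1).T
    intra, inter = class_distances(D, n)
    assert intra[0] == 1.0
    assert inter[0] == pytest.approx(100.0)


def test_equal_distances_not_specific():
    D = np.full((6, 6), 2.0)
    np.fill_diagonal(D, 0.0)
    intra, inter = class_distances(D, 3)
    assert np.allclose(intra, inter)
    assert not specific_patterns(intra, inter).any()


def test_percentile_robust_to_outlier_column_entry():
    rng = np.random.default_rng(1)
    X = np.abs(rng.normal(5, 0.5, size=(30, 8)))
    D = block_distance_matrix(X[:15], X[15:])
    intra0, _ = class_distances(D, 15)
    D2 = D.copy()
    D2[14, 0] = D2[0, 14] = 1e6  # one extreme intra distance
    intra1, _ = class_distances(D2, 15)
    assert intra1[0] == intra0[0]


def test_duplicated_pattern_in_both_classes_not_specific(rng):
    v = np.abs(rng.normal(size=12)) + 0.5
    Xh = np.vstack([v, np.abs(rng.normal(size=(3, 12))) + 0.5])
    Xl = np.vstack([v, np.abs(rng.normal(size=(3, 12))) + 0.5])
    D = block_distance_matrix(Xh, Xl)
    intra, inter = class_distances(D, 4)
    spec = specific_patterns(intra, inter)
    assert not spec[0] and not spec[4]  # the twins see inter distance 0


def test_specificity_invariant_under_joint_rescaling(rng):
    X = np.abs(rng.normal(size=(20, 15))) + 0.2
    D1 = block_distance_matrix(X[:10], X[10:])
    D2 = block_distance_matrix(7.0 * X[:10], 7.0 * X[10:])
    i1, e1 = class_distances(D1, 10)
    i2, e2 = class_distances(D2, 10)
    assert np.array_equal(specific_patterns(i1, e1),
                          specific_patterns(i2, e2))


# ------------------------------------------------------------ patterns


def test_flatten_unflatten_roundtrip(rng):
    tensor = np.abs(rng.normal(size=(2, 5, 7)))
    assert np.array_equal(unflatten_pattern(flatten_pattern(tensor), 5, 7),
                          tensor)
    with pytest.raises(ValueError):
        flatten_pattern(np.zeros((3, 5, 7)))


def _sine_recording(freq_by_subject, fs=250.0, dur_s=4.0):
    channels = SCALP_CHANNELS + EOG_CHANNELS
    t = np.arange(int(dur_s * fs)) / fs
    rng = np.random.default_rng(0)
    samples = 0.5 * rng.normal(size=(2, len(channels), len(t)))
    for s, f0 in enumerate(freq_by_subject):
        for lbl in CENTRO_PARIETAL:
            ci = channels.index(lbl)
            samples[s, ci] += 10.0 * np.cos(2 * np.pi * f0 * t)
    return DualRecording(samples=samples, fs=fs,
                         channels=(channels, channels))


def test_patterns_reflect_planted_frequencies(grid):
    """Leader at 18 Hz and follower at 25 Hz dominate the respective
    subject/frequency slots of the pattern vector."""
    rec = _sine_recording((18.0, 25.0))
    segs = SegmentTable(pd.DataFrame(
        [(0, "s1", 1500.0, 2500.0)],
        columns=["trial", "segment", "onset_ms", "offset_ms"]))
    pats = build_patterns(rec, segs, grid)
    assert pats.X.shape == (1, 6120)
    tensor = unflatten_pattern(pats.X[0], 60, 51)
    cz = SCALP_CHANNELS.index("Cz")
    assert grid.freqs[np.argmax(tensor[0, cz])] == 18.0
    assert grid.freqs[np.argmax(tensor[1, cz])] == 25.0


def test_mine_specific_ledger_shape(small_session, grid):
    rec, segs, _ = small_session
    from dyadsync import leader_readiness
    ready = leader_readiness(segs)
    pats = build_patterns(rec, segs, grid, readiness=ready)
    ledger = mine_specific(pats)
    n_hi = (pats.labels == "high").sum()
    n_lo = (pats.labels == "low").sum()
    assert len(ledger) == n_hi + n_lo
    assert set(ledger.columns) >= {"trial", "readiness_class", "intra_d",
                                   "inter_d", "specific"}
    assert ((ledger["inter_d"] > ledger["intra_d"])
            == ledger["specific"]).all()
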