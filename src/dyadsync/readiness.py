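"""Leader readiness: behavioral scoring, trimmed correlations, class split.

Leader readiness is the promptness of the leader's movement onset on the
follower's cue: short s1 durations mean high readiness. The readiness
score is the negated s1 duration, so positive correlations read as
"stronger coupling with better coordination". Trials are split into
high/low readiness classes at the 35th/65th percentiles of the s1
durations pooled over all trials (and teams, when several sessions are
pooled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recording import SegmentTable

log = logging.getLogger(__name__)


def percentile_split(durations: np.ndarray, lo: float = 35.0,
                     hi: float = 65.0) -> tuple[float, float, list[str]]:
    """Class cutoffs and labels from s1 durations.

    Cutoffs are the ``lo``-th and ``hi``-th percentiles (linear
    interpolation between order statistics). A trial is ``high`` iff its
    duration is strictly below the low cutoff, ``low`` iff strictly
    above the high cutoff, else ``middle``. If all durations are equal
    the split is degenerate and every trial is ``middle``.
    """
    durations = np.asarray(durations, dtype=float)
    lo_cut = float(np.percentile(durations, lo))
    hi_cut = float(np.percentile(durations, hi))
    labels = ["high" if d < lo_cut else "low" if d > hi_cut else "middle"
              for d in durations]
    return lo_cut, hi_cut, labels


def leader_readiness(segments: SegmentTable, lo: float = 35.0,
                     hi: float = 65.0) -> pd.DataFrame:
    """Readiness table: one row per trial with an s1 segment.

    Columns: trial, s1_duration_ms, score (negated duration),
    readiness_class. Cutoffs are stored in ``df.attrs['cutoffs_ms']``.
    Trials without an s1 row are excluded with a logged reason.
    """
    durs = segments.s1_durations()
    missing = set(segments.trials) - set(durs.index)
    if missing:
        log.warning("trials without s1 excluded from readiness: %s",
                    sorted(missing))
    lo_cut, hi_cut, labels = percentile_split(durs.to_numpy(), lo, hi)
    df = pd.DataFrame({
        "trial": durs.index,
        "s1_duration_ms": durs.to_numpy(),
        "score": -durs.to_numpy(),
        "readiness_class": labels,
    }).reset_index(drop=True)
    df.attrs["cutoffs_ms"] = (lo_cut, hi_cut)
    if lo_cut == hi_cut:
        log.warning("degenerate readiness split: all trials 'middle'")
    return df


@dataclass(frozen=True)
class TrimmedCorrelation:
    r: float
    p: float
    n_used: int


def trimmed_correlation(x: np.ndarray, y: np.ndarray, trim: float = 0.05,
                        method: str = "pearson") -> TrimmedCorrelation:
    """Correlation after 5% two-sided tail exclusion on each variable.

    Trials whose x value lies in the lowest or highest ``trim`` fraction
    of x, or whose y value lies in the corresponding tails of y, are
    dropped (union) before computing the correlation; this guards the
    coherence/readiness correlations against outliers. Zero variance
    after trimming yields r = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 10:
        raise ValueError("need at least 10 paired trials")
    keep = np.ones(len(x), dtype=bool)
    for v in (x, y):
        lo = np.percentile(v, 100.0 * trim)
        hi = np.percentile(v, 100.0 * (1.0 - trim))
        keep &= (v >= lo) & (v <= hi)
    xs, ys = x[keep], y[keep]
    if xs.std() == 0 or ys.std() == 0:
        log.warning("zero variance after trimming; correlation undefined")
        return TrimmedCorrelation(float("nan"), float("nan"), int(keep.sum()))
    if method == "pearson":
        r, p = stats.pearsonr(xs, ys)
    elif method == "spearman":
        r, p = stats.spearmanr(xs, ys)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrimmedCorrelation(float(r), float(p), int(keep.sum()))


def significance_tier(p: float) -> str:
    """Conventional star notation: + p<0.10, * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "+"
    return ""


SCAN_SEGMENTS: tuple[str, ...] = ("s9", "s0", "s1", "s2", "s3", "s4", "s5")


def coherence_readiness_scan(coherence: pd.DataFrame,
                             readiness: pd.DataFrame,
                             segments: tuple[str, ...] = SCAN_SEGMENTS,
                             bands: tuple[str, ...] | None = None,
                             scopes: tuple[str, ...] = ("inter", "intra_1",
                                                        "intra_2"),
                             trim: float = 0.05,
                             method: str = "pearson") -> pd.DataFrame:
    """Correlate band coherence with readiness per (segment, band, scope).

    ``coherence`` must have columns (trial, segment, band, scope,
    mean_plv); the 5% tail exclusion is applied per cell, using that
    cell's coherence values. Cells with no rows are reported absent
    (NaN), not zero.
    """
    if bands is None:
        bands = tuple(coherence["band"].unique())
    scores = readiness.set_index("trial")["score"]
    out = []
    for seg in segments:
        for band in bands:
            for scope in scopes:
                cell = coherence[(coherence["segment"] == seg)
                                 & (coherence["band"] == band)
                                 & (coherence["scope"] == scope)]
                cell = cell[cell["trial"].isin(scores.index)]
                if len(cell) < 10:
                    out.append((seg, band, scope, np.nan, np.nan, len(cell), ""))
                    continue
                tc = trimmed_correlation(cell["mean_plv"].to_numpy(),
                                         scores.loc[cell["trial"]].to_numpy(),
                                         trim=trim, method=method)
                out.append((seg, band, scope, tc.r, tc.p, tc.n_used,
                            significance_tier(tc.p)))
    return pd.DataFrame(out, columns=["segment", "band", "scope", "r", "p",
                                      "n_used", "tier"])
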