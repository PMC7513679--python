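"""Artifact correction: blink epochs, muscle bursts, linear trends.

Blinks are found on the EOG channels by a windowed linear approximation:
residuals from a sliding local linear fit flag peaked transients, which a
straight line cannot produce. Muscle bursts are flagged by thresholding
wavelet power in the 40-60 Hz band against the per-channel median. Both
feed a per-sample validity mask; downstream windowing drops (never
interpolates) windows that touch invalid samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend as _sp_detrend
from scipy.signal import savgol_filter

from .recording import DualRecording
from .timefreq import morlet_at_times

MUSCLE_BAND = (40.0, 60.0)


def detrend(x: np.ndarray) -> np.ndarray:
    """Subtract the least-squares line; output has zero mean and slope."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("detrend needs at least 2 samples")
    return _sp_detrend(x, axis=-1, type="linear")


def _merge_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean vector as half-open sample spans."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        stops.append(len(flags))
    return list(zip(starts, stops))


def detect_blinks(eog: np.ndarray, fs: float, win_ms: float = 200.0,
                  residual_thresh: float = 6.0) -> list[tuple[float, float]]:
    """Blink intervals (onset_ms, offset_ms) on one EOG channel.

    A local linear fit over sliding ``win_ms`` windows approximates the
    slow EOG baseline exactly wherever the signal is locally linear;
    samples whose residual exceeds ``residual_thresh`` robust scales
    (1.4826 * MAD) seed peak regions, which are merged and expanded to the
    surrounding zero-crossings of the residual.
    """
    eog = np.asarray(eog, dtype=np.float64)
    win = int(round(win_ms * fs / 1000.0))
    if win < 2:
        raise ValueError("blink window must span at least 2 samples")
    win += 1 - win % 2  # savgol needs odd length
    win = min(win, len(eog) - (1 - len(eog) % 2))
    baseline = savgol_filter(eog, win, polyorder=1, mode="interp")
    resid = eog - baseline
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale <= 1e-9 * max(1.0, float(np.max(np.abs(eog)))):
        return []  # flat or exactly linear signal (numerical residue only)
    seeds = np.abs(resid) > residual_thresh * scale
    sign = np.signbit(resid)
    out: list[tuple[float, float]] = []
    for a, b in _merge_runs(seeds):
        # expand to surrounding residual zero-crossings
        while a > 0 and sign[a - 1] == sign[a]:
            a -= 1
        while b < len(resid) and sign[b] == sign[b - 1]:
            b += 1
        span = (a * 1000.0 / fs, b * 1000.0 / fs)
        # merge spans separated by less than a blink's rise time
        if out and span[0] <= out[-1][1] + 50.0:
            out[-1] = (out[-1][0], max(out[-1][1], span[1]))
        else:
            out.append(span)
    return out


def detect_muscle(rec: DualRecording, band: tuple[float, float] = MUSCLE_BAND,
                  power_thresh: float = 5.0, win_ms: float = 400.0,
                  step_ms: float = 200.0, f_step: float = 2.0,
                  n_cycles: float = 10.0,
                  ) -> list[tuple[float, float, int, str]]:
    """Muscle-burst intervals as (onset_ms, offset_ms, subject, channel).

    Wavelet power on a ``band`` grid is averaged over the band and over
    each sliding window; windows exceeding ``power_thresh`` x the
    per-channel median window power are flagged and contiguous flags
    merged. Window averaging pools several independent power samples
    (the 40-60 Hz wavelet decorrelates within ~25 ms), so stationary
    noise essentially never crosses the threshold while genuine
    broadband bursts do; the median is stable under sparse bursts.
    """
    if rec.fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the muscle band")
    freqs = np.arange(band[0], band[1] + 1e-9, f_step)
    win = int(round(win_ms * rec.fs / 1000.0))
    step = int(round(step_ms * rec.fs / 1000.0))
    starts = np.arange(0, rec.n_samples - win + 1, step)
    stride = max(1, int(round(0.008 * rec.fs)))  # ~8 ms power sampling
    points = np.arange(0, rec.n_samples, stride)
    out: list[tuple[float, float, int, str]] = []
    for s in (0, 1):
        labels = rec.scalp_labels(s)
        data = rec.scalp_data(s)
        coeffs, _ = morlet_at_times(data, rec.fs, freqs, points,
                                    n_cycles=n_cycles)
        pp = np.mean(np.abs(coeffs) ** 2, axis=1)  # (n_ch, n_points)
        p = np.stack([pp[:, (points >= a) & (points < a + win)].mean(axis=1)
                      for a in starts], axis=1)    # (n_ch, n_windows)
        med = np.median(p, axis=1, keepdims=True)
        flagged = p > power_thresh * np.maximum(med, 1e-30)
        for ci, lbl in enumerate(labels):
            for a, b in _merge_runs(flagged[ci]):
                onset = starts[a] * 1000.0 / rec.fs
                offset = (starts[b - 1] + win) * 1000.0 / rec.fs
                out.append((onset, offset, s, lbl))
    return out


@dataclass
class ArtifactMask:
    """Per-subject, per-sample validity plus artifact provenance."""

    valid: np.ndarray  # (2, n_samples) bool
    provenance: pd.DataFrame = field(repr=False)

    PROV_COLUMNS = ("kind", "subject", "channel", "onset_ms", "offset_ms")

    def __post_init__(self) -> None:
        if self.valid.ndim != 2 or self.valid.shape[0] != 2:
            raise ValueError("valid mask must be (2, n_samples)")

    def fraction_masked(self, subject: int | None = None) -> float:
        v = self.valid if subject is None else self.valid[subject]
        return float(1.0 - np.mean(v))

    @classmethod
    def all_valid(cls, n_samples: int) -> "ArtifactMask":
        return cls(valid=np.ones((2, n_samples), dtype=bool),
                   provenance=pd.DataFrame(columns=list(cls.PROV_COLUMNS)))


def build_mask(blinks: dict[int, list[tuple[float, float]]],
               muscle: list[tuple[float, float, int, str]],
               rec: DualRecording) -> ArtifactMask:
    """Union of artifact intervals per subject as an :class:`ArtifactMask`.

    ``blinks`` maps subject index -> blink intervals from that subject's
    EOG. Intervals outside the recording span raise.
    """
    valid = np.ones((2, rec.n_samples), dtype=bool)
    rows = []

    def _apply(kind: str, subject: int, channel: str,
               onset_ms: float, offset_ms: float) -> None:
        a = rec.ms_to_sample(onset_ms)
        b = rec.ms_to_sample(offset_ms)
        if a < 0 or b > rec.n_samples or b <= a:
            raise ValueError(
                f"{kind} interval [{onset_ms}, {offset_ms}) ms outside recording"
            )
        valid[subject, a:b] = False
        rows.append((kind, subject, channel, onset_ms, offset_ms))

    for subject, spans in blinks.items():
        for onset, offset in spans:
            _apply("blink", subject, "EOG", onset, offset)
    for onset, offset, subject, channel in muscle:
        _apply("muscle", subject, channel, onset, offset)
    prov = pd.DataFrame(rows, columns=list(ArtifactMask.PROV_COLUMNS))
    return ArtifactMask(valid=valid, provenance=prov)


def preprocess_recording(rec: DualRecording, blink_thresh: float = 6.0,
                         muscle_thresh: float = 5.0,
                         ) -> tuple[DualRecording, ArtifactMask]:
    """Full artifact correction: detrend, detect blinks and muscle, mask."""
    blinks: dict[int, list[tuple[float, float]]] = {}
    for s in (0, 1):
        spans: list[tuple[float, float]] = []
        for lbl in rec.eog_labels:
            if lbl in rec.channels[s]:
                spans += detect_blinks(rec.eog_data(s, lbl), rec.fs,
                                       residual_thresh=blink_thresh)
        blinks[s] = sorted(spans)
    muscle = detect_muscle(rec, power_thresh=muscle_thresh)
    mask = build_mask(blinks, muscle, rec)
    cleaned = DualRecording(
        samples=detrend(rec.samples), fs=rec.fs, channels=rec.channels,
        roles=rec.roles, t0=rec.t0, eog_labels=rec.eog_labels,
    )
    return cleaned, mask
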