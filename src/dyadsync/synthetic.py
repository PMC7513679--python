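"""Synthetic dual-EEG sessions with controllable coordination structure.

Each session emulates a block of room-clearing trials recorded from a
leader/follower dyad:

* trials are tiled from behavioral segments (s9 lead-in, then s0..s8)
  with randomized durations; segment s1 (follower's tap to leader's
  movement onset) is the behavioral readiness measure,
* each subject carries band-limited oscillators whose phase mixes a
  common drive with private phase noise; the programmed inter-brain
  coupling strength g in [0, 1] weights the shared part (private part
  weighted sqrt(1 - g^2), so each subject's phase statistics are the
  same at every g). g is an affine decreasing function of the trial's
  s1 duration, applied only during the information-exchange segments,
* during s1 the medial centro-parietal electrodes carry planted power
  components whose amplitudes co-modulate across trials: same-frequency
  leader/follower coupling in low-readiness trials, cross-frequency
  coupling (follower 25 Hz with leader 18 Hz, follower 20 Hz with
  leader 30 Hz) in high-readiness trials,
* 1/f background noise everywhere; ocular blinks, 40-60 Hz muscle
  bursts and linear drifts are injected separately with a ground-truth
  ledger.

All randomness flows through one seeded generator, so identical seeds
give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, sosfiltfilt

from .montage import (CENTRO_PARIETAL, EOG_CHANNELS, SCALP_CHANNELS,
                      set_topography, topography)
from .readiness import percentile_split
from .recording import DualRecording, SegmentTable

TRIAL_SEGMENT_ORDER: tuple[str, ...] = (
    "s9", "s0", "s1", "s2", "s3", "s4", "s5", "s6", "s7a", "s7b", "s8",
)

#: segments carrying inter-subject information exchange (coupled by default)
COUPLED_SEGMENTS: tuple[str, ...] = ("s9", "s0", "s1", "s2", "s3", "s4")


@dataclass(frozen=True)
class SegmentSpec:
    """Truncated-normal duration model for one segment (ms)."""

    mean_ms: float
    sd_ms: float
    min_ms: float = 150.0
    max_ms: float = 2000.0


DEFAULT_SEGMENTS: dict[str, SegmentSpec] = {
    "s9": SegmentSpec(1000.0, 150.0),
    "s0": SegmentSpec(900.0, 150.0),
    "s2": SegmentSpec(400.0, 80.0, min_ms=200.0),
    "s3": SegmentSpec(1100.0, 180.0),
    "s4": SegmentSpec(900.0, 150.0),
    "s5": SegmentSpec(1000.0, 150.0),
    "s6": SegmentSpec(500.0, 100.0),
    "s7a": SegmentSpec(400.0, 80.0, min_ms=200.0),
    "s7b": SegmentSpec(300.0, 60.0),
    "s8": SegmentSpec(600.0, 120.0),
}


@dataclass(frozen=True)
class CouplingBand:
    """One coupled oscillator: carrier frequency, topography, segments."""

    name: str
    freq_hz: float
    center: str = "Cz"
    width: float = 0.6        # lateral (x) Gaussian width
    width_y: float | None = None
    segments: tuple[str, ...] = COUPLED_SEGMENTS


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic session.

    The defaults are desk-scale study conditions: 16 trials per session
    at 250 Hz (1000 Hz available by config), frontal coupled oscillators
    at the broadband-noise amplitude scale, a readiness-dependent
    phase-coupling strength g in [0.55, 0.98] during the
    information-exchange segments, and centro-parietal power components
    with log-normal across-trial amplitudes.
    """

    n_trials: int = 16
    fs: float = 250.0
    seed: int = 0
    # segment durations
    segments: dict[str, SegmentSpec] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS))
    s1_median_ms: float = 420.0
    s1_log_sd: float = 0.45
    s1_bounds_ms: tuple[float, float] = (120.0, 1400.0)
    inter_trial_gap_ms: float = 300.0
    # readiness -> coupling map: affine decreasing in s1 duration
    # carriers cover the frontal rows broadly but fall off steeply toward
    # the centro-parietal pattern electrodes, so coupling and
    # power-pattern structure stay separable
    coupling_bands: tuple[CouplingBand, ...] = (
        CouplingBand("beta", 27.0, center="F3", width=0.8, width_y=0.22),
        CouplingBand("gamma", 32.0, center="F4", width=0.8, width_y=0.22),
    )
    # the affine readiness map spans [coupling_min, coupling_max]: with
    # variance-preserving mixing the phase-difference variance scales
    # with 1 - g^2, so the PLV-responsive range of g sits near 1
    coupling_max: float = 0.98
    coupling_min: float = 0.55
    coupling_baseline: float = 0.0
    coupling_const: float | None = None  # overrides the readiness map
    readiness_map_ms: tuple[float, float] = (250.0, 650.0)
    osc_amp_uv: float = 10.0
    # Ornstein-Uhlenbeck phase noise: bounded stationary sd (rad) and
    # correlation time (s). Inter-brain PLV at a well-covered electrode
    # pair is ~exp(-(1 - g^2) * sd^2), from ~0.05 uncoupled to ~0.9 at
    # the strongest coupling.
    phase_noise_sd: float = 1.8
    phase_noise_tau_s: float = 0.05
    # centro-parietal power-pattern model
    pattern_electrodes: tuple[str, ...] = CENTRO_PARIETAL
    symmetric_freqs: tuple[float, ...] = (18.0, 20.0, 25.0, 30.0)
    asymmetric_pairs: tuple[tuple[float, float], ...] = (
        (25.0, 18.0), (20.0, 30.0))  # (follower Hz, leader Hz)
    pattern_amp_uv: float = 6.0
    pattern_log_sd: float = 0.6
    # degenerate background activity: per-trial random-frequency components,
    # independent between subjects, filling the band with across-trial
    # power variance unrelated to the planted co-modulation
    n_distractors: int = 4
    distractor_amp_uv: float = 2.5
    # distractors stay clear of the 40-60 Hz artifact band edge
    distractor_band_hz: tuple[float, float] = (15.0, 38.5)
    # fixed spectral support: components are planted over at least this
    # span (centered on s1), so their bandwidth does not vary with the
    # trial's s1 duration
    pattern_support_ms: float = 1200.0
    class_split: tuple[float, float] = (35.0, 65.0)
    # noise and artifacts
    noise_exponent: float = 1.0
    noise_rms_uv: float = 10.0
    noise_trial_log_sd: float = 0.15  # trial-to-trial broadband power wobble
    eog_noise_rms_uv: float = 5.0
    blink_rate_hz: float = 0.08
    blink_amp_uv: float = 120.0
    blink_dur_ms: float = 300.0
    muscle_rate_hz: float = 0.04
    muscle_amp_uv: float = 20.0
    muscle_dur_ms: tuple[float, float] = (150.0, 500.0)
    drift_slope_uv_per_s: tuple[float, float] = (-1.5, 1.5)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1 (zero-length session)")
        if self.fs <= 130.0:
            raise ValueError("fs must exceed twice the 40-60 Hz artifact band")
        for name, spec in self.segments.items():
            if spec.min_ms <= 0 or spec.max_ms < spec.min_ms:
                raise ValueError(f"bad duration bounds for segment {name}")
        for rate in (self.blink_rate_hz, self.muscle_rate_hz):
            if rate < 0:
                raise ValueError("artifact rates must be >= 0")
        for g in (self.coupling_max, self.coupling_min,
                  self.coupling_baseline):
            if not 0.0 <= g <= 1.0:
                raise ValueError("coupling strengths must lie in [0, 1]")
        if self.coupling_min > self.coupling_max:
            raise ValueError("coupling_min must not exceed coupling_max")
        if self.coupling_const is not None and not 0.0 <= self.coupling_const <= 1.0:
            raise ValueError("coupling_const must lie in [0, 1]")
        if self.readiness_map_ms[1] <= self.readiness_map_ms[0]:
            raise ValueError("readiness map needs d_lo < d_hi")

    def coupling_of(self, s1_duration_ms: float) -> float:
        """Programmed coupling strength g for a trial's s1 duration."""
        if self.coupling_const is not None:
            return self.coupling_const
        d_lo, d_hi = self.readiness_map_ms
        frac = np.clip((d_hi - s1_duration_ms) / (d_hi - d_lo), 0.0, 1.0)
        return float(self.coupling_min
                     + (self.coupling_max - self.coupling_min) * frac)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, rms: float,
                n_channels: int = 1) -> np.ndarray:
    """1/f^exponent noise, band-limited below by 0.5 Hz, scaled to ``rms``.

    Returns (n_channels, n) independent channels (squeezed for 1).
    """
    nf = n // 2 + 1
    spec = (rng.normal(size=(n_channels, nf))
            + 1j * rng.normal(size=(n_channels, nf)))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.maximum(f, 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape[None, :], n, axis=1)
    sd = np.maximum(x.std(axis=1, keepdims=True), 1e-30)
    x *= rms / sd
    return x[0] if n_channels == 1 else x


def _ou_phase(rng: np.random.Generator, n: int, fs: float,
              sigma: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck phase noise (sd ``sigma`` rad,
    correlation time ``tau`` s)."""
    a = np.exp(-1.0 / (fs * tau))
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - a * a), n)
    x = lfilter([1.0], [1.0, -a], innov)
    x += rng.normal(0.0, sigma) * a ** np.arange(n)  # stationary start
    return x


def _ramp(n: int, fs: float, ramp_ms: float = 20.0) -> np.ndarray:
    """Cosine on/off ramps to soften segment-local oscillator onsets."""
    r = min(int(round(ramp_ms * fs / 1000.0)), n // 2)
    env = np.ones(n)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def generate_session(cfg: ScenarioConfig, seed: int | None = None
                     ) -> tuple[DualRecording, SegmentTable, pd.DataFrame]:
    """Generate one synthetic session.

    Returns the recording (clean of blink/muscle/drift artifacts — use
    :func:`inject_artifacts` for those), the segment table, and the
    ground-truth ledger with one row per trial: s1 duration, readiness
    class under the configured percentile split, programmed coupling per
    band, and the planted pattern id.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = cfg.fs
    n_trials = cfg.n_trials
    to_samples = lambda ms: max(int(round(ms * fs / 1000.0)), 2)

    # --- draw all durations, then the class split over s1 durations
    s1_ms = np.exp(rng.normal(np.log(cfg.s1_median_ms), cfg.s1_log_sd,
                              size=n_trials))
    s1_ms = np.clip(s1_ms, *cfg.s1_bounds_ms)
    seg_samples: dict[tuple[int, str], int] = {}
    for trial in range(n_trials):
        for seg in TRIAL_SEGMENT_ORDER:
            if seg == "s1":
                d = s1_ms[trial]
            else:
                spec = cfg.segments[seg]
                d = np.clip(rng.normal(spec.mean_ms, spec.sd_ms),
                            spec.min_ms, spec.max_ms)
            seg_samples[(trial, seg)] = to_samples(d)
    s1_ms = np.array([seg_samples[(t, "s1")] * 1000.0 / fs
                      for t in range(n_trials)])
    lo_cut, hi_cut, labels = percentile_split(s1_ms, *cfg.class_split)
    g_trial = np.array([cfg.coupling_of(d) for d in s1_ms])

    # --- timeline
    gap = to_samples(cfg.inter_trial_gap_ms)
    rows = []
    spans: dict[tuple[int, str], tuple[int, int]] = {}
    cursor = gap
    for trial in range(n_trials):
        for seg in TRIAL_SEGMENT_ORDER:
            n = seg_samples[(trial, seg)]
            spans[(trial, seg)] = (cursor, cursor + n)
            rows.append((trial, seg, cursor * 1000.0 / fs,
                         (cursor + n) * 1000.0 / fs))
            cursor += n
        cursor += gap
    n_t = cursor
    segments = SegmentTable(pd.DataFrame(
        rows, columns=["trial", "segment", "onset_ms", "offset_ms"]))

    # --- background noise; broadband power wobbles trial to trial
    channels = SCALP_CHANNELS + EOG_CHANNELS
    samples = np.zeros((2, len(channels), n_t))
    rms_vec = np.array([cfg.eog_noise_rms_uv if lbl in EOG_CHANNELS
                        else cfg.noise_rms_uv for lbl in channels])
    if np.any(rms_vec > 0):
        for s in (0, 1):
            bank = _pink_noise(rng, n_t, fs, cfg.noise_exponent, 1.0,
                               n_channels=len(channels))
            samples[s] = bank * rms_vec[:, None]
    if cfg.noise_trial_log_sd > 0:
        # slow per-subject power wobble, drawn per behavioral segment
        for trial in range(n_trials):
            for seg in TRIAL_SEGMENT_ORDER:
                a, b = spans[(trial, seg)]
                for s in (0, 1):
                    samples[s, :, a:b] *= rng.lognormal(
                        0.0, cfg.noise_trial_log_sd)

    scalp = slice(0, len(SCALP_CHANNELS))
    band_topos = {b.name: topography(b.center, b.width, b.width_y)
                  for b in cfg.coupling_bands}

    # --- coupled oscillators, segment by segment. Variance-preserving
    # phase mixing: shared OU phase noise weighted g, private OU noise
    # weighted sqrt(1 - g^2), same stationary sd, so each subject's
    # oscillator statistics are identical at every coupling level and
    # only the shared fraction of phase noise varies with g.
    for trial in range(n_trials):
        for seg in TRIAL_SEGMENT_ORDER:
            a, b = spans[(trial, seg)]
            n = b - a
            t = np.arange(n) / fs
            env = _ramp(n, fs)
            for band in cfg.coupling_bands:
                g = (g_trial[trial] if seg in band.segments
                     else cfg.coupling_baseline)
                theta_c = (2.0 * np.pi * band.freq_hz * t
                           + rng.uniform(-np.pi, np.pi)
                           + g * _ou_phase(rng, n, fs, cfg.phase_noise_sd,
                                           cfg.phase_noise_tau_s))
                w_priv = np.sqrt(max(1.0 - g * g, 0.0))
                for s in (0, 1):
                    priv = _ou_phase(rng, n, fs, cfg.phase_noise_sd,
                                     cfg.phase_noise_tau_s)
                    phi = theta_c + w_priv * priv
                    sig = cfg.osc_amp_uv * env * np.cos(phi)
                    samples[s, scalp, a:b] += \
                        band_topos[band.name][:, None] * sig[None, :]

    # --- planted centro-parietal power components during s1
    u = set_topography(cfg.pattern_electrodes)
    follower = 1  # roles are (leader, follower) in subject order
    leader = 0
    support = to_samples(cfg.pattern_support_ms)
    for trial in range(n_trials):
        a, b = spans[(trial, "s1")]
        if b - a < support:  # widen symmetrically to the fixed support
            mid = (a + b) // 2
            a = max(mid - support // 2, 0)
            b = min(a + support, n_t)
        n = b - a
        t = np.arange(n) / fs
        # smooth envelope (no spectral sidelobe leakage), unit RMS so the
        # configured amplitude stays an effective RMS amplitude
        env = np.hanning(n)
        env /= np.sqrt(np.mean(env**2))
        comps = []
        if labels[trial] == "high":
            # cross-frequency co-modulation: shared amplitude per pair
            for f_follower, f_leader in cfg.asymmetric_pairs:
                amp = cfg.pattern_amp_uv * rng.lognormal(0.0, cfg.pattern_log_sd)
                comps.append((follower, f_follower, amp))
                comps.append((leader, f_leader, amp))
        else:
            # same-frequency co-modulation: shared amplitude per frequency
            for f in cfg.symmetric_freqs:
                amp = cfg.pattern_amp_uv * rng.lognormal(0.0, cfg.pattern_log_sd)
                comps.append((follower, f, amp))
                comps.append((leader, f, amp))
        for subj in (0, 1):
            for _ in range(cfg.n_distractors):
                f = rng.uniform(*cfg.distractor_band_hz)
                amp = (cfg.distractor_amp_uv
                       * rng.lognormal(0.0, cfg.pattern_log_sd))
                comps.append((subj, f, amp))
        for subj, f, amp in comps:
            theta = rng.uniform(-np.pi, np.pi)
            sig = amp * env * np.cos(2.0 * np.pi * f * t + theta)
            samples[subj, scalp, a:b] += u[:, None] * sig[None, :]

    rec = DualRecording(samples=samples, fs=fs,
                        channels=(channels, channels),
                        roles=("leader", "follower"))
    truth = pd.DataFrame({
        "trial": np.arange(n_trials),
        "s1_duration_ms": s1_ms,
        "readiness_class": labels,
        "pattern_id": np.where(np.asarray(labels) == "high",
                               "asymmetric", "symmetric"),
        **{f"g_{band.name}": g_trial for band in cfg.coupling_bands},
    })
    truth.attrs["cutoffs_ms"] = (lo_cut, hi_cut)
    return rec, segments, truth


def inject_artifacts(rec: DualRecording, cfg: ScenarioConfig,
                     seed: int | None = None
                     ) -> tuple[DualRecording, pd.DataFrame]:
    """Add blinks, 40-60 Hz muscle bursts and linear drifts.

    Returns a new recording and a ledger DataFrame (kind, subject,
    channel, onset_ms, offset_ms, value) where ``value`` is the blink or
    burst amplitude in microvolts, or the drift slope in microvolts per
    second. With zero rates and a degenerate zero slope range the output
    equals the input exactly.
    """
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    fs = rec.fs
    n_t = rec.n_samples
    dur_s = n_t / fs
    samples = rec.samples.copy()
    rows = []

    # ocular blinks on the EOG channels
    blink_n = int(rng.poisson(cfg.blink_rate_hz * dur_s)) if cfg.blink_rate_hz > 0 else 0
    blink_len = int(round(cfg.blink_dur_ms * fs / 1000.0))
    for s in (0, 1):
        onsets = np.sort(rng.uniform(0, n_t - blink_len, size=blink_n)).astype(int)
        for a in onsets:
            tt = np.arange(blink_len)
            bump = cfg.blink_amp_uv * np.exp(
                -((tt - blink_len / 2.0) ** 2) / (2.0 * (blink_len / 6.0) ** 2))
            for lbl, scale in (("VEOG", 1.0), ("HEOG", 0.3)):
                if lbl in rec.channels[s]:
                    ci = rec.channels[s].index(lbl)
                    samples[s, ci, a:a + blink_len] += scale * bump
            rows.append(("blink", s, "VEOG", a * 1000.0 / fs,
                         (a + blink_len) * 1000.0 / fs, cfg.blink_amp_uv))

    # muscle bursts: 40-60 Hz band-limited noise on one scalp channel
    burst_n = int(rng.poisson(cfg.muscle_rate_hz * dur_s * 2)) if cfg.muscle_rate_hz > 0 else 0
    if burst_n:
        sos = butter(4, (40.0, 60.0), btype="bandpass", fs=fs, output="sos")
    for _ in range(burst_n):
        s = int(rng.integers(0, 2))
        ci = int(rng.integers(0, len(rec.scalp_indices(s))))
        chan = rec.scalp_indices(s)[ci]
        dur = rng.uniform(*cfg.muscle_dur_ms)
        ln = max(int(round(dur * fs / 1000.0)), int(0.2 * fs))
        a = int(rng.integers(0, n_t - ln))
        burst = sosfiltfilt(sos, rng.normal(size=ln + 2 * int(fs)))[int(fs):int(fs) + ln]
        burst *= cfg.muscle_amp_uv / max(burst.std(), 1e-12)
        burst *= np.hanning(ln)
        samples[s, chan, a:a + ln] += burst
        rows.append(("muscle", s, rec.channels[s][chan], a * 1000.0 / fs,
                     (a + ln) * 1000.0 / fs, cfg.muscle_amp_uv))

    # linear drift per scalp channel
    lo, hi = cfg.drift_slope_uv_per_s
    if lo != 0.0 or hi != 0.0:
        t_s = np.arange(n_t) / fs
        for s in (0, 1):
            for chan in rec.scalp_indices(s):
                slope = float(rng.uniform(lo, hi))
                samples[s, chan] += slope * t_s
                rows.append(("drift", s, rec.channels[s][chan], 0.0,
                             n_t * 1000.0 / fs, slope))

    ledger = pd.DataFrame(rows, columns=[
        "kind", "subject", "channel", "onset_ms", "offset_ms", "value"])
    out = DualRecording(samples=samples, fs=rec.fs, channels=rec.channels,
                        roles=rec.roles, t0=rec.t0, eog_labels=rec.eog_labels)
    return out, ledger
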