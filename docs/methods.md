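# Methods

This note documents the models, estimators and numerical choices behind
`dyadsync`, and what the synthetic validation does and does not show.

## Time–frequency decomposition

All spectral quantities come from convolution with unit-energy complex
Morlet kernels on a fixed grid of 51 frequencies, 15–40 Hz in 0.5 Hz
steps. The kernel at frequency *f* has Gaussian envelope
σ_t = n_cycles/(2πf), truncated at ±4σ_t; its spectral width is
σ_f = f/n_cycles. Samples within one kernel half-support of a data edge
are flagged invalid and never enter segment averages.

Two widths are used, by analysis:

* **Phase coherence: n_cycles = 7.** The 80 ms analysis windows demand
  temporal sharpness; 7 cycles give σ_t ≈ 40–75 ms over the grid.
* **Power patterns: n_cycles = 12** (default of the study helpers; the
  library functions accept any width). The cross-frequency power
  analysis must separate components ~2–5 Hz apart; at 7 cycles
  σ_f = 2.6–4.3 Hz makes 18 vs 20 Hz indistinguishable in principle,
  while 12 cycles (σ_f = 1.5–2.7 Hz) resolves them. Segment length sets
  a second, unavoidable limit: a tone confined to a T-second segment is
  broadened by ~2/T Hz regardless of the analysis kernel.

## Phase-locking value and aggregation

The PLV of electrodes j, k at a grid frequency over one behavioral
segment is the magnitude of the mean unit phasor of their per-window
phase differences; windows are 80 ms, stepped 40 ms, restarted at each
segment onset, and a window's representative phase is the coefficient
phase at its center sample (a circular within-window mean is available
via `phase_mode="mean"`). Windows overlapping masked samples of either
subject are dropped; fewer than 2 windows makes a segment uncomputable.
For independent phases the estimator has a positive bias ≈ √(π/4N); it
decays as 1/√N in the window count, which the null calibration checks as
a −0.5 log–log slope.

Intra-brain coherence averages the 1,770 within-subject pairs, inter-brain
coherence the 3,600 cross-subject pairs (all pairs, not only homologous
ones). Band rows are 20–24, 25–30, 30–34 and 35–39 Hz; the 30.0 Hz bin is
assigned to the 25–30 row only, so no bin is double counted.

## Readiness statistics

Leader readiness is the negated s1 duration (short s1 = prompt leader =
high readiness), so positive correlations mean "more coupling with better
coordination". Correlations are Pearson after excluding, per analyzed
cell, the 5% lowest/highest coherence values and the 5% lowest/highest
readiness values (union of both trims). Classes split at the 35th/65th
percentiles of s1 duration pooled over all trials and teams (linear
interpolation between order statistics); ties or a degenerate spread
yield an all-"middle" split, which downstream stages report rather than
hide. Significance tiers use conventional thresholds (+ 0.10, * 0.05,
** 0.01, *** 0.001), uncorrected, per cell.

**A circularity worth knowing about:** in segment s1 the number of PLV
windows is itself set by the s1 duration that defines readiness, so the
1/√N bias induces a positive readiness correlation in *every* scope and
band there. The pooled dissociation study therefore averages the
carrier-band inter-brain PLV over the coupled segments *excluding s1*
(and excludes s1 from the intra-brain screen); s1's own cells are still
computed and reported. For the uncoupled control segment s5, the first
300 ms are discarded before windowing because the wavelet support of
early windows reaches back into the coupled entry segment — the same
boundary rule applied at recording edges.

## Pattern specificity

One pattern per trial: mean wavelet power over the samples covered by the
valid s1 windows, per (subject, electrode, frequency), flattened
subject-major/electrode-major/frequency-minor to a 6,120-vector. The
distance d(x, y) = ‖x−y‖²/(‖x‖‖y‖) (Euclidean norms) is invariant to a
*joint* rescaling of both patterns but deliberately not to one-sided
rescaling, so patterns are not pre-normalized. In the (N+n)×(N+n) block
distance matrix, each pattern's intra-class distance is the
10th-percentile of its sorted within-block column (self-distance removed)
using a deterministic ceiling rank (smallest order statistic with
cumulative fraction ≥ 10%), likewise for the inter block; a pattern is
specific iff inter > intra strictly. Per-dyad mining with globally pooled
class cutoffs; median time-reduction and log-power are options.

## Cross-frequency asymmetry

For each readiness class, entry (i, j) of the f×f matrix M is the Pearson
correlation, across that class's specific patterns, between the
follower's centro-parietal set-mean power at frequency i and the
leader's at frequency j (set: C1, Cz, C2, CP1, CPz, CP2, P3, P1, Pz, P2,
POz). The asymmetry coefficient per unordered pair is
a(i,j) = |M(i,j) − M(j,i)| (a normalized variant is available); the
high- and low-class coefficient vectors are compared element-paired with
a two-sided Wilcoxon signed-rank test (zeros dropped), direction = sign
of the median difference.

Peak localization (`top_asymmetric_pairs`) works on the *signed*
asymmetry of Fisher-z transformed correlations, so every element has the
same sampling variance regardless of the local power variance, smoothed
with a matched-filter Gaussian (2 Hz) whose normalization keeps the noise
level constant up to the matrix boundary; a 2 Hz edge margin keeps unreliable
boundary cells out, and an oriented deduplication (follower tolerance
4.5 Hz, leader tolerance 6.5 Hz — blob sampling noise is correlated
along rows and columns, producing ridge echoes) makes the returned
pairs one-per-blob.
Recovery of planted pairs is judged at ±5 Hz — the localization limit set
by segment-length broadening (2/T ≈ 6–8 Hz for the short high-readiness
segments), not by the wavelet.

Electrode-set discovery uses spectral clustering (scikit-learn,
precomputed affinity (corr+1)/2, deterministic discretize assignment) on
the k×k electrode-profile correlation matrix per role, with an eigengap
default for the cluster count and reordering by descending within-cluster
correlation.

## The synthetic generator

Each session tiles trials from segments (s9 lead-in, then s0…s8; the
restacking segment is attached to the trial whose readiness it precedes)
with truncated-normal durations; s1 is log-normal (median 420 ms,
log-sd 0.45, clipped to 120–1400 ms). Signals are built from:

* **Coupled oscillators** at 27 Hz (β) and 32 Hz (γ) with anisotropic
  frontal topographies (broad across the frontal row, steep toward the
  centro-parietal electrodes, so coupling and power-pattern structure
  stay separable). Oscillator phase = carrier + g·(shared OU noise) +
  √(1−g²)·(private OU noise), both OU processes with stationary sd
  1.8 rad and correlation time 50 ms. The variance-preserving mixing
  keeps each subject's oscillator statistics identical at every coupling
  level — otherwise in-bin SNR, and with it intra-brain PLV, would track
  g. A well-covered pair's PLV is ≈ exp(−(1−g²)·sd²): ~0.04 uncoupled,
  ~0.9 at the strongest coupling. g maps affinely from s1 duration
  (650 ms → 0.55, 250 ms → 0.98; the responsive range of g sits near 1,
  so the map covers the bulk of the duration distribution) during the
  information-exchange segments s9, s0–s4 and is 0 elsewhere.
* **Centro-parietal power components** during s1, planted on a fixed
  1200 ms Hann support centered on s1 (unit-RMS envelope). Fixing a wide
  support keeps both the component bandwidth and the envelope level seen
  by the s1 windows essentially independent of the trial's s1 duration;
  otherwise duration acts as a shared latent (spectral broadening, or
  the envelope level itself) that contaminates the inter-subject
  correlation matrices across trials. In
  low/middle-readiness trials, one log-normal amplitude per frequency
  {18, 20, 25, 30} Hz is shared by both subjects (same-frequency
  co-modulation); in high-readiness trials the shared amplitudes link
  follower 25 ↔ leader 18 Hz and follower 20 ↔ leader 30 Hz. Four
  "distractor" components per subject and trial at uniform random
  frequencies (15–38.5 Hz, clear of the artifact band) model degenerate
  background activity and supply across-trial power variance unrelated
  to the planted structure.
* **Noise and artifacts.** 1/f background (10 µV RMS, exponent 1) with a
  per-segment, per-subject log-normal power wobble (sd 0.15); blinks
  (Gaussian bumps on the EOG channels), 40–60 Hz band-passed muscle
  bursts on single channels, and per-channel linear drifts are injected
  separately with a complete ledger of onsets, channels and slopes.

Default fs is 250 Hz (Nyquist comfortably above the 60 Hz artifact band;
1000 Hz available by config). All randomness flows through one seeded
generator: identical seeds give bit-identical sessions.

### What the validation shows — and does not

Passing the recovery studies shows that the estimators detect the
*programmed* structure at realistic SNR: readiness-coupled inter-brain
phase locking confined to the right segments, and class-dependent
symmetric vs cross-frequency power co-modulation recoverable through
mining, correlation and the Wilcoxon contrast. The generator does not
model volume conduction, saccades, non-stationary spectra, inter-subject
anatomical variability, or genuine neural dynamics; green tests say the
pipeline is correct and sensitive, not that real recordings would show
these effects.

## Study problem sizes

* Coherence dissociation: 8 dyads × 16 trials (pooled readiness cutoffs
  over all trials and teams), generated without the s1-locked power
  components: their fixed spectral support overflows into the adjacent
  segments by an amount that tracks s1 duration, which would confound
  the coherence–readiness correlation with a mechanism that belongs to
  the pattern study.
* Asymmetry recovery: 50 replicate sessions of 216 trials each (the task
  design supports up to 160 trials per dyad; inter-subject correlation
  matrices across specific patterns need on the order of 50 patterns per
  class to be interpretable). Non-s1 segments are kept compact in this
  study since only s1 feeds the pattern analysis.
* Null calibrations: 500 trimmed-correlation scans at 200 trials; PLV
  scaling over N ∈ {8 … 256} with 1000 replicates per N.
* Specificity contrast: 100 + 100 patterns per run, dimension 200,
  between/within separation 10; the null level is established by an
  independent second simulation rather than an assumed constant.

## Known limitations

* The PLV window-count bias couples segment duration to coherence; analyses
  correlating a segment's coherence with that same segment's duration
  inherit the circularity described above.
* The 10th-percentile specificity rule needs ≥ 2 patterns per class and
  loses meaning for very small classes; classes with fewer than 3
  specific patterns are skipped with a message in the asymmetry stage.
* Blink handling masks rather than corrects; no ICA/regression ocular
  correction, channel interpolation or re-referencing is provided.
* The muscle detector thresholds window-averaged 40–60 Hz power
  (10-cycle kernels, 400 ms windows) at 5× the per-channel median;
  sustained (non-burst) EMG raises the median itself and would be
  missed.
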