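# dyadsync

Dual-EEG (hyperscanning) analysis of team coordination in leader/follower
dyads performing a segmented joint task, together with a fully controllable
synthetic dual-EEG generator that makes every stage of the analysis testable
against known ground truth.

## The problem

Two people performing a tightly coordinated task (here: a virtual
room-clearing exercise, segmented into behavioral stages s0–s9 per trial)
show coordination signatures in their simultaneous EEG. The package
quantifies two of them:

1. **Inter-brain phase coherence.** For electrodes *j, k* ∈ {1, …, 120}
   (subject 1 → 1..60, subject 2 → 61..120) and grid frequency φ, the
   phase-locking value over the N sliding 80 ms windows (step 40 ms) of a
   trial segment is

   c_jk(φ) = (1/N) | Σₙ exp(i(φₙ(j) − φₙ(k))) |,

   with φₙ the complex-Morlet wavelet phase at the window. Averaging c_jk
   over within-subject pairs gives intra-brain coherence, over
   cross-subject pairs inter-brain coherence. These band averages are
   correlated (Pearson, with 5% two-sided tail exclusion on both
   variables) with **leader readiness** — the negated duration of segment
   s1, the interval from the follower's cue to the leader's movement
   onset.

2. **Class-specific dyadic wavelet-power patterns.** Each trial's s1
   window yields one dyadic power vector of length 2·k·f = 2·60·51 = 6,120
   (subject × electrode × frequency, 15–40 Hz at 0.5 Hz). Trials split
   into high/low readiness classes at the 35th/65th percentiles of the s1
   duration. With the normalized squared distance

   d(**x**, **y**) = ‖x − y‖² / (‖x‖‖y‖),

   a pattern is *specific* to its class when its 10th-percentile distance
   to the other class exceeds its 10th-percentile distance within its own
   class. Specific patterns feed an f×f inter-subject correlation matrix
   of centro-parietal set-mean power (rows: follower frequencies, columns:
   leader frequencies); the per-pair asymmetry |M(i,j) − M(j,i)| is
   compared between classes with a paired Wilcoxon signed-rank test, and
   the strongest asymmetric frequency pairs are localized by matched-filter
   peak-picking.

Because dual-EEG recordings of this kind are not openly deposited, the
package ships a synthetic session generator (`dyadsync.synthetic`) whose
programmed structure — readiness-dependent inter-brain phase coupling in
the information-exchange segments, symmetric vs cross-frequency power
co-modulation over the centro-parietal electrodes, 1/f noise, blinks,
muscle bursts and drifts with a ground-truth ledger — lets every estimator
be validated end to end.

## Worked example

Generate a session and inspect its ground truth:

```python
import dyadsync as ds

cfg = ds.ScenarioConfig(n_trials=16, seed=1)
rec, segments, truth = ds.generate_session(cfg)
print(rec.samples.shape, rec.fs)                # (2, 62, 31017) 250.0
print(truth[["trial", "s1_duration_ms", "readiness_class",
             "g_beta"]].head(4).to_string(index=False))
```

```
 trial  s1_duration_ms readiness_class  g_beta
     0           492.0          middle 0.71985
     1           608.0             low 0.59515
     2           488.0          middle 0.72415
     3           232.0            high 0.98000
```

Run the pooled coherence–readiness study (8 dyads × 16 trials: windowed
PLV per segment, carrier-band averages, trimmed correlations):

```python
from dyadsync import studies

res = studies.coherence_readiness_study(seed=7)
print(f"coupled-segments inter-brain r = {res.coupled_inter_r:.3f} "
      f"(p = {res.coupled_inter_p:.2g})")
print(f"uncoupled control (s5)       r = {res.s5_r:.3f} (p = {res.s5_p:.2f})")
print("intra-brain r:", {k: round(v, 3) for k, v in res.coupled_intra_r.items()})
```

```
coupled-segments inter-brain r = 0.397 (p = 3.3e-05)
uncoupled control (s5)       r = -0.003 (p = 0.97)
intra-brain r: {'intra_1': 0.05, 'intra_2': 0.057}
```

Inter-brain coherence in the information-exchange segments rises with
leader readiness; the movement-to-corners control shows nothing, and
intra-brain coherence shows no systematic effect — the qualitative
dissociation the analysis is designed to detect.

One session's cross-frequency asymmetry analysis (pattern mining,
frequency-correlation matrices, Wilcoxon test, peak localization):

```python
r = studies.asymmetry_session_study(seed=11)
print(f"Wilcoxon p = {r.p:.3g}, direction = {r.direction}")
print("top asymmetric (follower Hz, leader Hz):",
      [(round(a, 1), round(b, 1)) for a, b in r.pairs])
```

```
Wilcoxon p = 3.97e-115, direction = 1
top asymmetric (follower Hz, leader Hz): [(20.0, 31.0), (24.0, 18.5)]
```

The high-readiness class is significantly more asymmetric than the
low-readiness class, and the two strongest asymmetric pairs localize the
planted follower-20 ↔ leader-30 and follower-25 ↔ leader-18 Hz
co-modulation (within the spectral resolution set by the short segment
lengths).

A command-line pipeline mirrors the library:

```bash
dyadsync --seed 1 --out-dir run1 simulate
dyadsync --out-dir run1 preprocess
dyadsync --out-dir run1 coherence
dyadsync --out-dir run1 correlate
dyadsync --out-dir run1 patterns
dyadsync --out-dir run1 asymmetry
dyadsync --out-dir run1 report
```

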