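# Methods notes

## Signal model of the synthetic generator

Each channel of a synthetic recording is generated at 100 Hz as

```
v(t) = base · (1 + depth·c(φ(t)) + e(t)/100 + d(t)) + ε(t)
```

* `base` — per-channel mean velocity (left 55, right 53 cm/s; values in
  the mid-range of adult middle-cerebral-artery velocities).
* `c(φ)` — cardiac waveform, a gamma-like systolic upstroke peaking at
  cycle phase 0.12 with a slow diastolic decay, shifted to zero mean
  over the cycle so that cycle-averaged velocity equals the slow
  component. The cycle phase advances beat by beat with heart rate
  drawn per beat from N(70, 3²) bpm; `depth` = 0.25 of base.
* `e(t)` — evoked response in percent of base: zero until 2.5 s after
  stimulus onset (cerebral blood flow responds with a 2–3 s delay),
  a 1.5-s half-cosine rise to a plateau sustained through the 2-s
  stimulus display and the 10-s covert generation phase (until 12 s
  post-onset), then a 3-s half-cosine return. On the plateau the
  bilateral mean is `evoked_amplitude_pct` (3) and the left-minus-right
  difference equals the planted per-task LI (defaults: list 0,
  sentence 5, word 2.5 percentage points). The multiplicative
  formulation means that after normalisation to a channel mean of 100
  the planted LI reads directly in the units the pipeline reports.
* `d(t)` — slow probe/physiological drift, an independent per-channel
  Gaussian random walk with step sd 0.02 % of base per native sample
  (≈8 % sd over a half-hour session — large-scale drift that the
  epoch-wise baseline correction largely absorbs).
* `ε(t)` — white Gaussian noise, sd 0.8 % of base.

Artifacts are injected at most once per trial: with probability 0.05 a
single-sample spike of ±3×base in one channel (beyond the recording's
0.9999 quantile even after 4-sample block averaging), with probability
0.03 a 0.5–1.5-s flat-line dropout to exactly zero in one channel
(signal loss). Sixty trials (20 per task) are interleaved
pseudorandomly in two runs of 30, one trial every 30 s, emulated as one
continuous recording since the pipeline is run-agnostic.

**What the generator does not model:** respiratory modulation,
probe-angle drift that changes pulsatility rather than gain, motor
artefacts during the overt report phase (the covert-generation design
exists precisely to keep them out of the period of interest), and
task-difficulty or attention effects on evoked amplitude. Passing
recovery tests therefore demonstrate correctness of the analysis
chain under a plausible stationary noise model, not robustness to every
failure mode of real probes.

The per-trial simulated word counts (Poisson with means 10/9/4 for
list/sentence/word) are behavioural metadata only; nothing downstream
consumes them.

### Cohorts

`simulate_cohort` draws per-participant planted LIs around the config
values with between-participant sds 2.0/2.0/1.5 (list/sentence/word,
matching the dispersion typical of adult samples) and a shared trait
giving cross-task correlation 0.6. Recovery checks use spread 0 (every
participant at the nominal planted values) so the group mean has a
fixed target; reliability and method-agreement checks use the spread
cohort, since rank correlations are meaningless without
between-participant variance.

## Pipeline conventions and numerical choices

* All timing configuration is in seconds, converted to sample indices
  by rounding half-up at the working rate; windows are half-open
  `[start, end)` except the 2-s LI window, which is symmetric and
  inclusive about the peak sample (51 samples at 25 Hz).
* Trigger convention: the marker sample is stimulus onset; epoch time 0
  is 5 s earlier, so the baseline window is [0, 5) and the default POI
  [7, 17) covers 2–12 s post-onset. The alternative reading of the
  covert window (onset + 4 s for 10 s, i.e. [9, 19)) is available by
  configuration; the default follows the trial-schematic convention.
* De-spiking thresholds are the per-channel empirical 0.0001/0.9999
  quantiles over all epoch samples of the recording (a stabler tail
  estimate than per-epoch quantiles). Comparisons are inclusive so
  that flat-line dropouts, which tie with the quantile when they
  dominate the tail, are still flagged. Because empirical quantiles
  by construction flag ~0.02 % of samples on any recording, and the
  pulse shape clusters extremes at systolic peaks and diastolic
  troughs, chance runs of 2–4 extreme samples occur in most
  artifact-free recordings; only runs of at least `min_loss_run_s`
  (0.25 s — well above chance clusters, well below any genuine
  dropout) are treated as signal loss and exclude the trial, shorter
  excursions being repaired by linear interpolation between the
  nearest in-range neighbours.
* Normalisation divides each channel by its mean over included epochs
  (not the whole recording, so inter-trial gaps and breaks cannot bias
  it) and multiplies by 100.
* Heart-cycle detection runs on the mean of the two channels (the
  cycle is common to both) with a minimum peak separation of 0.33 s
  (≈180 bpm ceiling) and a prominence of 25 % of the epoch's
  peak-to-trough amplitude; an epoch with fewer than three detected
  peaks cannot be integrated and is excluded. Within each
  peak-to-peak interval both channels take the interval's mean; edge
  samples take the nearest interval's mean.
* The 60–140 % artifact bounds refer to the normalised, pre-baseline
  signal (mean 100): after baseline correction the epoch mean is zero
  and a percent-of-mean criterion would be undefined, so the stored
  baseline offsets are added back for the check.
* The interactive trial-inspection step of the original workflow is
  replaced by these automatic rules — reproducibility over fidelity to
  a manual procedure.
* Peak search maximises |L−R| (not the signed value) so right-dominant
  participants get correct latencies and negative LIs; ties break to
  the earliest time. Per-trial LIs use the group-wave latency — one
  fixed window per task — so that their t-interval estimates the
  uncertainty of the group LI itself (and their mean equals it by
  linearity).
* Confidence intervals use the t distribution. Spearman CIs use a
  seeded percentile bootstrap over pairs (1999 resamples by default);
  a Fisher-z analytic interval is available. Signed-rank tests report
  the V statistic (sum of positive-deviation ranks, average ranks for
  ties, zeros dropped) with the exact null for n ≤ 25 without ties and
  the continuity-corrected normal approximation otherwise.
* Bland–Altman limits of agreement use the 1.96 normal multiplier; the
  equivalence verdict keys on the *mean* difference lying within the
  predetermined ±2.5 bounds, with the fraction of individual
  differences inside the bounds also reported for the stricter
  every-point rule.
* Degenerate inputs fail loudly: zero included trials for a task,
  constant vectors in a correlation, fewer than two trial LIs for a
  CI, non-positive channel means, all-extreme epochs.

## Calibration of the CI classification

The bilateral/left/right rule classifies on a 95 % t-interval of
per-trial LIs, so one might expect ~95 % of truly non-lateralised
participants to be called bilateral. The acceptance suite measures the
actual rate under the generator's default conditions and finds it
substantially lower (roughly three quarters). Two mechanisms, both
properties of the method rather than of the implementation:

1. **Peak selection.** The LI window is centred on the maximal |L−R|
   within the POI. Under a planted null this selects the largest of
   roughly a dozen effectively independent cycle-level noise values,
   and because the selected extreme and the CI half-width both scale
   with the same noise sigma, the inflation is independent of the
   noise level. This is the same selection effect that makes
   peak-based LI distributions bimodal with a trough at zero, and it
   is why the fixed-window (POI-mean) LI is offered alongside.
2. **Gain mismatch.** Independent slow drift shifts the two channels'
   normalisation constants differently; that relative gain error
   multiplies the *bilateral* evoked rise into a small session-constant
   spurious L−R offset shared by every trial of a participant, which a
   t-interval over trials cannot see.

Consequently the classification should be read as "lateralised relative
to this session's measurement" rather than as a calibrated 5 %-error
test of the null; studies needing calibrated type-I control should use
the fixed-window LI and, ideally, a between-session design.

## Problem sizes

The simulation studies are desk-scale by design: recovery and
method-agreement cohorts use 31 participants (20 trials per task), the
null-calibration cohort 200 participants, the symmetry suite 50 short
recordings of 6 trials. The full test suite runs in well under a
minute; the acceptance script in ~15 s on one CPU.

## Known limitations

* The raw-signal TSV is a package-defined interchange format, not a
  vendor export; proprietary Doppler formats and EDF are out of scope.
* The plateau-shaped evoked response is an assumption; only the onset
  delay and the covert-phase timing are constrained by the trial
  design, and a peaked response would shift peak latencies earlier.
* Word counts are simulated metadata; behavioural exclusion
  (`behavioural` reason) is supported on epochs but no automatic
  behavioural rule is applied.
* Split-half halves with fewer than two included trials yield NaN
  rather than a value.
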