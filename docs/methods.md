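# Methods

This note documents the models, conventions and numerical choices behind
`hcsleep`: a pipeline for rodent sleep electrophysiology that stages
wake/NREM/REM sleep from EEG/EMG, detects hippocampal sharp-wave ripples and
prefrontal delta waves and sleep spindles from LFP, counts cross-regional
coupled sequences (delta→spindle, ripple→delta, ripple→delta→spindle), and
compares their rates between pre- and post-encoding recording windows. A
synthetic session generator supplies ground truth for every stage of the
pipeline.

## Time and data conventions

All times are seconds from session start (float64). Sample `i` of a trace
sampled at rate `r` covers the half-open interval `[i/r, (i+1)/r)`; event
boundaries are reported at sample edges and peaks at sample centers, so a
peak is always strictly interior to its event. Signals are stored as EDF+
(1-s data records, 16-bit), which bounds round-trip error by one quantization
step of `(phys_max − phys_min)/65535` per channel. Channel roles
(EEG/EMG/LFP; CA1, mPFC, parietal, neck) come from a JSON sidecar because
EDF labels are free text. Hypnograms and event tables are TSV.

## Sleep staging

Staging is rule-based and deterministic, per 4-s epoch (rodent convention;
configurable):

1. **EMG tone.** Per-epoch EMG RMS is converted to a robust z score against
   the *sleep baseline*: center = 20th percentile of epoch RMS, scale = MAD
   of the lower half of the distribution, floored at 10% of the baseline.
   Centering on a low quantile rather than the median matters because the
   wake mode captures the median whenever wake occupies more than half the
   recording; the 10% floor absorbs the few-percent within-stage jitter of
   epoch RMS. Epochs with z > 1 are WAKE.
2. **EEG rhythms.** Remaining epochs are REM if the Welch theta/delta power
   ratio (6–9 Hz over 0.5–4 Hz) exceeds 1.5, else NREM.
3. **Post-processing.** Majority smoothing over 3 epochs (ties keep the
   epoch's own label), then REM epochs directly preceded by WAKE are
   relabeled NREM (REM is entered only from sleep).

If the EMG RMS distribution carries no wake/sleep contrast (95th percentile
within 20% of the baseline — an all-sleep or all-wake recording), the EMG
rule is vacuous and the EEG decides: epochs with relative delta power ≤ 0.35
of the 0.5–30 Hz total are WAKE. This keeps both degenerate cases correct
(an all-NREM recording stays NREM; a flat-EEG/high-EMG recording is WAKE).

Stage spectra are per-epoch Welch periodograms (Hann window spanning the
epoch), averaged within a stage and normalized to unit sum over the 0.5–30 Hz
analysis band, i.e. expressed relative to the total power of the same stage.
Band summaries use delta 0.5–4, theta 6–9, alpha 9–12, beta 12–30 Hz; the
alpha/beta edges are package conventions.

## Event detection

All three detectors share the scheme: zero-phase Butterworth bandpass →
envelope → z-score over **all** samples of the transformed trace → threshold
and duration rules. Zero-phase (forward–backward) filtering keeps peak times
unbiased, which matters for coupling lags. Normalizing over the whole
recording rather than sleep only follows the convention that the SD is taken
across all filtered signal points.

* **Ripples (CA1).** 100–250 Hz, squared, low-passed at 25 Hz, z-scored.
  Candidates are maximal runs ≥ 3 SD (boundary threshold; configurable
  separately from the peak threshold because two-threshold variants are
  common); kept if the run peak ≥ 3 SD and the run lasts 30–100 ms
  (inclusive). The 25 Hz envelope corner is chosen so measured run durations
  stay faithful near the 30 ms floor — a slower corner smears even a 20 ms
  burst into a ≥ 30 ms run.
* **Delta waves (mPFC).** 0.1–5 Hz (order-2 sections; the 0.1 Hz corner is
  extreme relative to the sampling rate and higher orders are numerically
  fragile), z-scored. Candidates are half-waves delimited by zero crossings
  (both polarities by default); kept if |extremum| > 2 SD and the half-wave
  lasts 150–500 ms (inclusive).
* **Spindles (mPFC).** 9–17 Hz, squared, Gaussian-smoothed (σ = 100 ms),
  z-scored. Candidates are maximal runs ≥ 2.5 SD; kept if they last strictly
  more than 500 ms (and at most a 3 s sanity cap) and the run maximum
  reaches 5 SD. The reported peak time is the **midpoint of the
  suprathreshold run** by default (`peak_time="ARGMAX"` restores the argmax):
  on a heavily smoothed, plateau-shaped spindle envelope the argmax position
  wanders by roughly the smoothing scale under background interference,
  whereas the midpoint between the steep threshold crossings is stable at
  the few-tens-of-milliseconds level. The amplitude (`peak_z`) is still the
  envelope maximum.

Runs touching the first or last sample have no threshold crossing on one
side and are discarded. Raising any threshold never increases the event
count, and detections are invariant to positive rescaling of the trace.

## Coupling

Lag windows are half-open `(lo, hi]` measured peak to peak: delta→spindle
(0.100, 1.300] s and ripple→delta (0.050, 0.250] s. A lag exactly at the
lower edge is not coupled; one exactly at the upper edge is. The default
`GREEDY_ONE_TO_ONE` pairing scans leaders in time order and assigns each the
earliest unassigned in-window follower, so counts represent discrete joint
occurrences and every event participates at most once; `ALL_PAIRS` is kept
for sensitivity analysis and always counts at least as many pairs. An
R–D–S sequence is an R–D pair whose delta also leads a D–S pair (conjunction
through the shared delta).

Counts are taken during sleep (NREM by default) and normalized per minute of
time in those stages within the session window; because the right
denominator for a "joint occurrence rate" is a reporting choice, rates per
minute of total recording and per leader event are also emitted. Pre/post
comparisons pair replicates by position, form per-replicate post−pre rate
differences, and summarize them with a seeded bootstrap percentile CI
(2000 resamples, 95%); a single replicate yields a point estimate with the
CI flagged undefined.

Under independent Poisson streams the probability that a leader has at
least one follower in a window of width `w` is `1 − exp(−w·λ)`; this closed
form is the null oracle for the pairing machinery.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
the biophysics of the circuits.

* **States.** A semi-Markov chain with exponential bout durations (means:
  wake 200 s, NREM 120 s, REM 60 s) and transitions WAKE→NREM always,
  NREM→REM with probability 0.3 else WAKE, REM→NREM with 0.5 else WAKE;
  REM is never entered from wake. Epochs take the state at their midpoint.
* **Background.** 1/f (α = 1, flattened below 0.1 Hz) broadband noise plus
  stage-gated narrowband components, cross-faded over 0.5 s at stage
  boundaries. The EEG channel carries the staging rhythms (NREM delta at 3×
  the wake amplitude; REM theta dominant); LFP backgrounds are only mildly
  stage-modulated because cortical delta-band power is supposed to come from
  the discrete injected delta waves rather than a continuous rhythm. EMG is
  white noise with stage-dependent variance (wake ≫ NREM > REM).
* **Events.** Ripples are Gaussian-windowed 150 Hz bursts (75–95 ms) on CA1.
  Delta waves are smooth biphasic deflections on mPFC — a raised-cosine main
  lobe (250–400 ms) flanked by slow, small opposite-polarity lobes, finally
  Gaussian-smoothed (σ = 25 ms): the undershoots pin the zero crossings of
  the band-filtered trace to the main-lobe edges, and the smoothing removes
  9–17 Hz leakage that would otherwise let a large delta wave distort a
  nearby spindle's envelope on the same channel. Spindles are 12 Hz bursts
  (700–1000 ms) whose amplitude envelope is a Tukey plateau carrying a
  sharper central bump, giving both a sustained suprathreshold run and an
  unambiguous center. Events are placed as Poisson processes in NREM
  (ripples 12/min, deltas 40/min, independent spindles 1.5/min of NREM) with
  same-kind refractory gaps; with probability 0.20 a ripple schedules a
  delta child at lag U[0.05, 0.25] s and with 0.05 each delta schedules a
  spindle child at lag U[0.2, 0.8] s, inside the coupling windows by
  construction. Children that would leave NREM or overlap a same-kind event
  retry a new lag a few times, then are dropped.
* **Amplitude calibration.** Targets are specified in SD units of each
  detector's own normalized envelope (ripple 12, delta 4.5, spindle 12), so
  detector tests are self-calibrating. Because the z-score is taken over
  the whole trace *including* the injected events, the map from waveform
  amplitude to measured SD is implicit: the calibrator starts from the
  background-only envelope statistics and iterates (inject → measure the
  mean achieved peak z → correct multiplicatively) to within 2% or six
  rounds. mPFC kinds are calibrated sequentially so spindles see the
  injected delta waves in their normalization. A useful identity for
  choosing conditions: with event duty cycle `q` and envelope shape factor
  `k`, the achievable z is capped near `1/sqrt(q·k)`, and the background's
  share of band variance is pinned at `sqrt(1 − z²·q·k)` regardless of the
  background's absolute power.
* **Behavior.** Exploration times are gamma (shape 4, mean 12 s); the
  displaced object's mean is scaled by a preference multiplier, so
  multiplier 1 gives expected DI 0 by exchangeability.

What the generator does **not** model: biophysical waveform diversity,
travelling-wave geometry, EMG artifacts, state-dependent event amplitudes,
or any genotype mechanism. Passing the recovery tests therefore shows the
pipeline is correct *given* its detection model — events that exceed the
thresholds, respect the duration bounds and ride on approximately Gaussian
band-limited background — not that the detectors are optimal on real LFP.

## Behavioral metrics

The discrimination index is
`DI = (t_displaced − t_stationary) / (t_displaced + t_stationary) × 100`,
antisymmetric under swapping the two times, with ±100 attained only when one
time is zero and undefined when both are. Zero-maze summaries attribute each
inter-sample interval (time and Euclidean step) to the zone of its starting
sample, so zone-crossing steps deterministically belong to the zone being
left. Zone labels are consumed, not computed from arena geometry.

## Pipeline and reproducibility

`run_pipeline` executes simulate → score → detect → couple → report for a
PRE and a POST phase (the post phase may override the coupling
probabilities), recording SHA-256 digests, output paths and wall-clock per
stage in `manifest.json`. A stage whose outputs exist with matching digests
is skipped on re-run. The single config seed fans out to per-stage child
seeds by stable hashing of the stage name, so inserting a stage does not
reshuffle the randomness of the others; identical config and seed reproduce
event tables and coupling reports byte for byte.

## Problem sizes

The validation suite uses ten 30-minute sessions (LFP 1 kHz) for detector
recovery, two 2-hour sessions for staging, twenty 600-s draws for the
analytic coupling null, and ten six-animal cohorts (event-level simulation,
no LFP synthesis) for the pre/post comparison; `scripts/acceptance.py`
recomputes the same quantities at the same sizes. Cohort simulation runs at
the event level because the comparison concerns coupling rates, which are
fully determined by event times.

## Known limitations

* The staging fallback for unimodal EMG uses an absolute relative-delta
  threshold (0.35) that is generator-calibrated; on real data with different
  spectral slopes it should be revisited.
* The delta detector's half-wave convention (zero-crossing delimited, either
  polarity) counts each large biphasic slow wave as up to two events if both
  lobes cross threshold.
* Spindle peak-time = run midpoint is a timing convention; studies defining
  the spindle peak as the largest trough of the filtered trace will see
  systematic lags of up to half a spindle duration relative to ours.
* EDF writing requires integer sampling rates and whole-second sessions
  (1-s records); arbitrary-rate storage is out of scope.
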