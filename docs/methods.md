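# Methods

This note documents the analysis pipeline, the synthetic-data model used
to validate it, and the numerical and design choices that were genuinely
open.

## Signal model and conventions

All computation assumes continuous scalp EEG in microvolts at a fixed
200 Hz sampling rate; inputs at other rates are rejected rather than
resampled (resampling and other acquisition-side preprocessing — ICA,
re-referencing, bad-channel interpolation — are out of scope; the package
starts from clean signals).  Time is in seconds from recording start with
half-open intervals `[start, end)`.  Sleep stages come from an external
hypnogram (30-s epochs, labels W/N1/N2/N3/REM); artifacts from an external
interval table (overlaps merged on load).  Event detection and density
normalisation use only artifact-free N2/N3 samples; "artifact-free NREM
minutes" is computed sample-wise, so `density × minutes = count` holds
exactly.  A built-in 58-channel extended 10-20 montage (schematic 2-D
layout on the unit disk) ships with the package; channel neighborhoods are
the Delaunay edges of the layout with edges longer than 1.5× the median
removed.

## Wake encoding pattern

Per participant, encoding-task and PVT recordings are cut into 1-s epochs
with 50 % overlap, Hanning-tapered and Fourier-transformed; power is
scaled so a sinusoid of amplitude A contributes A²/2 to its bin; the 1–20
Hz bins (1 Hz resolution) are kept.  Outlier epochs are excluded per
channel × frequency cell: strictly above that cell's 95th percentile
(linear-interpolation definition) across epochs.  The per-cell
retained-epoch means are differenced (encoding − PVT).

Two readings of the exclusion rule exist — drop the epoch in that cell
only, or drop it everywhere.  The per-cell reading is the default
(whole-epoch exclusion at the 95th percentile of 58 × 20 cells would
discard nearly every epoch); the percentile itself is configurable.

The group test against zero is a two-sided cluster-based permutation
test: one-sample t per cell across participants, cells with |t| above the
two-sided α = 0.05 critical value clustered by channel adjacency at the
same frequency plus ±1 bin at the same channel (no diagonal neighbors),
cluster statistic = summed t, null = maximal |cluster statistic| under
participant-wise random sign flips, cluster p = (1 + #{null ≥ obs}) /
(1 + n_perm).  Observed cluster formation and statistics are
cross-checked against MNE-Python's implementation in the test suite.  The
per-participant topography is the *mean* (scale-stable, rather than the
sum) of the contrast over the significant bins, per channel; if no
cluster is significant the caller may fall back to the fixed 6–20 Hz
band.

## Sleep event detection

Spindles (per channel, artifact-free N2/N3): 12–15 Hz zero-phase
Butterworth (order 4, applied forward and backward, so the effective
response is the squared magnitude), envelope = |Hilbert analytic signal|
smoothed by a centered 200-ms moving average, threshold = mean + 1.25·SD
of that envelope over artifact-free NREM samples, events = maximal
strictly-supra-threshold runs with duration in the open interval
(0.5, 3) s.  The envelope recipe is ambiguous in the field between
"smooth, then Hilbert" and "Hilbert, then smooth"; the default smooths the
magnitude (smoothing a 12–15 Hz carrier with a 200-ms average would
attenuate the band itself); the alternative order is available by
configuration.  Amplitude = envelope maximum; its time anchors the
coupling analysis.

SOs: 0.3–1.25 Hz zero-phase Butterworth; candidates = intervals between
consecutive positive-to-negative zero crossings lasting 0.8–2 s (closed
bounds); over all candidates of the night (pooled, per channel) the mean
+ 1.25·SD of trough-to-peak amplitude and of |trough| define two
thresholds; events must strictly exceed both.  Amplitude is stored as
|trough| so all six sleep measures are positively scaled.  A degenerate
consequence, exercised in the tests: a population of identical candidates
yields no events, because nothing exceeds mean + 1.25·SD of itself.

Both detectors keep an event only if every sample lies in N2/N3 and the
span from 1 s before onset to 1 s after offset is artifact-free.
Supra-threshold runs separated by sub-threshold gaps are separate events
(no merge rule).  Threshold statistics pool N2 and N3.

Coupling: a ±2.5 s window around each spindle's envelope maximum is
band-passed 0.3–1.25 Hz, Hilbert-transformed, and the analytic phase at
the center sample taken; 0° is the SO positive peak (up-state), ±180° the
trough.  Events too close to the recording edges are skipped (logged).
Spindles whose local SO-band envelope falls in the lowest decile of their
channel's events are flagged `low_so_amplitude`.  The higher-coupling
half per channel is the 50 % of events with the smallest circular
distance to 0° (ties → earlier onset; odd counts → extra event to the
higher set).

## Behavior

Sequence performance is the correlation of the reported object order with
1..n — both are rank vectors, so Pearson and Spearman coincide and no
correlation-type ambiguity remains.  |r| is clipped to 1 − 10⁻⁶ before the
Fisher z-transform so perfect orders stay finite.  Retention =
100·(post/pre) on the z scores, undefined (flagged missing) when the
pre-sleep score is not positive.

## Overlap and group statistics

Overlap per participant = Spearman's ρ (mid-ranks; NaN channels deleted
pairwise; at least 10 common channels) between the encoding topography
and one sleep topography, Fisher-z for group statistics.  Encoding values
are negative where engagement was high and sleep values positive, so
overlap is signified by ρ < 0.

The 2 × 3 fully-within ANOVA (event type × characteristic) is computed by
direct sums-of-squares decomposition with uncorrected degrees of freedom
(no sphericity correction) and partial η² = SS_effect / (SS_effect +
SS_error); it is cross-checked against pingouin in the tests.  Post-hoc
paired t (spindle vs SO per characteristic) and one-sample t (spindle
characteristics vs 0) are Holm-corrected within each family of three;
Cohen's d = mean/SD of the tested difference.  Partial rank correlations
use the first-order formula on mid-ranks.  The behavior correlation is
Spearman with an exact (full-enumeration) p for n ≤ 9 and the
t-approximation above that — enumeration beyond 9! permutations costs
more than the approximation error justifies.

The two permutation nulls shuffle one topography set (encoding or
spindle) across participants with uniform random permutations (identity
allowed), recompute every participant's overlap z and its Spearman
correlation with the unshuffled retention scores, and compare the
observed r to that null.  The reported p is one-sided in the
*hypothesized* direction (negative r = overlap predicts retention), with
the (1 + #)/(1 + n_perm) correction; a one-sided p in the *observed*
direction would reject at twice the nominal rate under the null, which
the calibration tests would catch.  A two-sided p on |r| is also
reported.

## Synthetic cohort: what it emulates

Each synthetic participant has wake encoding and PVT recordings, a nap,
hypnogram, artifact table and behavior row, with complete ground truth.

Background: 1/f^β noise (β = 1, 15 µV RMS) plus white noise (5 µV RMS) —
realistic envelope statistics so the mean + 1.25·SD criterion faces a
genuine noise floor.  Wake recordings share one background realization;
a 6–20 Hz band-limited oscillatory component (10 µV RMS) is attenuated
per channel by the encoding loadings (power factor 1 + loading,
loadings ≤ 0), emulating alpha/beta desynchronisation over engaged sites.

Sleep events are placed on jittered slots spread over the artifact-free
NREM time (counts = rate × minutes, floored — deterministic by
construction), independently per channel, with same-kind events ≥ 2 s
apart.  Spindles are Hann-windowed 13 Hz bursts: the raised-cosine
envelope has compact support (2 × duration), so each burst has a genuine
onset, and the logged duration is the envelope's full width at half
maximum.  An earlier Gaussian-envelope design was abandoned: its infinite
flanks let background envelope excursions merge with the rising edge,
making the "true onset" ill-defined at exactly the time resolution the
validation uses.  SOs are single-cycle −sin pulses *pre-filtered to the
0.3–1.25 Hz band* (what a band-limited SO actually looks like to the
detector), with truth onset/offset/trough read off the filtered waveform;
an unfiltered single cycle would lose up to a third of its trough in the
detection filter and shift its zero crossings.  Each spindle is coupled
to a partner SO: its envelope maximum is placed at the time where the
partner pulse's analytic phase equals a von Mises(0°, κ) draw, so the
planted phase uses exactly the convention the extraction measures.

SNR conventions: spindle amplitude = `spindle_snr` × SD of the
channel's background 12–15 Hz signal (default 3, moderate); SO trough =
`so_snr` × the mean |trough| of background SO-band cycles in the same
0.8–2 s duration class the detector considers (default 3).  Event
amplitudes carry lognormal jitter (σ = 0.15 by default).

The planted encoding–spindle overlap works through a Gaussian copula
across channels: encoding loadings decrease monotonically in one latent
normal, spindle amplitude loadings increase in a second, correlated at
r = 2·sin(π·|ρ|/6) so the population Spearman correlation equals the
requested ρ (monotone transforms leave Spearman invariant; the
small-sample bias at 58 channels is < 0.01).  Per-participant planted
overlaps jitter around the configured mean (SD 0.15).  Retention = 100 +
behavior_effect × (ρᵢ − mean ρ) + Gaussian noise, clipped into
(0, 150] % to mimic the 100·(post/pre) scale; the default slope −40 %/ρ
with 10 % noise gives a behavior correlation of realistic strength
(|r| ≈ 0.5).

Default cohort conditions: 19 participants, 58 channels, 5-min wake
recordings (the control task lasts about 5 min), 30-min naps of which
~24 min are N2/N3 plus two planted 5-s artifacts.  These are desk-scale
stand-ins for a 2-h nap; validation tests use naps of 7–32 NREM minutes
and cohorts of 10–12 participants so the full suite runs on one CPU in
minutes — chosen as the smallest sizes at which the tested properties
have adequate statistical power.

What the generator does **not** emulate: spatially smooth topographies
(channel values are i.i.d. draws from the copula, with no
volume-conduction correlation between neighboring channels), non-Gaussian
or non-stationary background (no infraslow sigma-power fluctuations, no
slow-spindle 9–12 Hz activity, no arousals), imperfect staging, ocular or
muscle artifacts beyond the planted intervals, and within-night dynamics
(constant event rates).  Passing tests therefore demonstrate algorithmic
correctness and calibration under a controlled noise model, not detector
performance on real polysomnography.

## Known limitations

* With the mean + 1.25·SD envelope criterion, a Gaussian background alone
  produces spurious supra-threshold runs longer than 0.5 s at ≈ 0.18 per
  channel-minute (threshold inflation from planted events already
  included).  At a planted rate of 2/min this bounds precision against a
  planted event log at about 0.9 even for perfect event matching; together
  with onset-matching losses the spindle precision measured at a ±0.25-s
  onset tolerance plateaus near 0.82.  This is a property of the detector
  on featureless noise, not an implementation defect; on real EEG such
  detections are simply low-amplitude spindle-band events with no ground
  truth to contradict them.
* SO onsets are shallow zero crossings, so their timing is intrinsically
  noisier than spindle onsets; detection matching for SOs uses a
  quarter-cycle (0.5 s) onset tolerance.
* The cluster test's FWER calibration and the permutation-null uniformity
  are verified on direct contrast/topography cohorts (the relevant
  statistical surface), not by thousands of full EEG simulations.
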