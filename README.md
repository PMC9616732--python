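# spindletopo

Do sleep spindles preferentially occur over the cortical sites that were
engaged during learning — and does the degree of that overlap predict how
well memories survive sleep?  `spindletopo` implements the complete
scalp-EEG analysis chain behind that question, for researchers who want to
run, validate or stress-test it without access to a real polysomnography
cohort:

* **Wake encoding patterns** — oscillatory power (1–20 Hz, 1-s Hanning
  epochs, 50 % overlap) during a learning task is contrasted against a
  vigilance control (PVT); outlier epochs are rejected per
  channel × frequency cell at the 95th percentile; a two-sided
  cluster-based permutation test (participant-wise sign flips, channel
  adjacency from the montage plus ±1 frequency bin) defines the
  significant band; collapsing the contrast across those bins gives one
  per-channel topography per participant.  Task engagement appears as an
  alpha/beta (6–20 Hz) power *decrease*, so encoding topographies are
  negatively scaled.
* **Sleep events** — fast spindles are detected per channel on N2/N3 as
  runs where the Hilbert envelope of the 12–15 Hz signal (200-ms moving
  average) exceeds mean + 1.25·SD for 0.5–3 s; slow oscillations (SOs) as
  0.8–2 s intervals between positive-to-negative zero crossings of the
  0.3–1.25 Hz signal whose trough-to-peak and |trough| amplitudes both
  exceed mean + 1.25·SD of the candidate population.  Amplitude, duration
  and density (events per artifact-free NREM minute) per channel give six
  sleep topographies.
* **SO–spindle coupling** — the analytic phase of the SO-band signal at
  each spindle's envelope maximum (0° = up-state peak), and the
  higher- vs lower-coupling split of spindle events.
* **Overlap statistics** — per participant, Spearman's ρ across channels
  between the encoding topography and each sleep topography (overlap ⇒
  negative ρ, Fisher-z transformed); a 2 (event type) × 3 (characteristic)
  repeated-measures ANOVA with partial η², Holm-corrected post-hoc
  t-tests, partial rank correlations; the across-participant Spearman
  correlation between the encoding–spindle-amplitude overlap and the
  behavioral retention score `100·(post/pre)`; and two permutation nulls
  that shuffle either the encoding or the spindle topographies between
  participants (1 000 permutations) to show the behavior link is
  participant-specific.
* **A synthetic cohort generator** with complete ground truth: 58-channel
  200 Hz recordings with 1/f background, channel-selective 6–20 Hz wake
  power decreases, NREM naps with Hann-windowed spindle bursts and
  band-limited single-cycle SOs, von Mises SO-phase coupling, a Gaussian
  copula that plants any requested encoding–spindle rank overlap, and
  retention scores tied linearly to the planted overlap.

## Worked example

```python
import numpy as np
from spindletopo import (SynthConfig, detect_spindles, spindle_so_phase,
                         characterize, spearman)
from spindletopo.circular import circ_mean_deg
from spindletopo.synthetic import generate_participant

config = SynthConfig(n_participants=1, sleep_duration_s=900, seed=7)
bundle, truth = generate_participant(config, "sub-01",
                                     np.random.default_rng(7))

spindles = detect_spindles(bundle.sleep, bundle.hypnogram, bundle.artifacts)
spindles = spindle_so_phase(bundle.sleep, spindles)
topo = characterize(spindles, bundle.hypnogram, bundle.artifacts,
                    bundle.sleep.fs, bundle.sleep.n_samples,
                    bundle.sleep.channel_labels)

print(f"detected {len(spindles)} spindles on {bundle.sleep.n_channels} channels")
print(f"mean density: {topo.table['density_per_min'].mean():.2f} per NREM minute")
rho = spearman(topo.vector('amplitude').to_numpy(),
               truth.spindle_topo.to_numpy())
print(f"planted vs detected amplitude topography: Spearman rho = {rho:.2f}")
print(f"SO phase at spindle peaks: circular mean = "
      f"{circ_mean_deg(spindles['so_phase_deg']):.1f} deg")
```

prints

```
detected 1530 spindles on 58 channels
mean density: 2.06 per NREM minute
planted vs detected amplitude topography: Spearman rho = 0.90
SO phase at spindle peaks: circular mean = -3.2 deg
```

i.e. on a 15-min synthetic nap the detector recovers the planted ~2/min
spindle rate, reproduces the planted per-channel amplitude topography with
ρ = 0.90, and finds spindle peaks clustered at the SO up-state (0°), as
planted.

The same analyses are available from the shell:

```bash
spindletopo simulate --out cohort/ --participants 19 --seed 7
spindletopo detect --eeg cohort/sub-01/sleep.npz \
    --hypno cohort/sub-01/hypnogram.tsv \
    --artifacts cohort/sub-01/artifacts.tsv --out events.tsv
spindletopo run --config run.yaml --seed 7 --out report/
```

`run` writes per-participant topographies, event tables, the overlap
table, group statistics, permutation nulls and a manifest; identical
config + seed reproduces every output byte for byte.

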