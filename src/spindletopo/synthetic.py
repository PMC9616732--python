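"""Synthetic cohort generator with full ground truth.

Each synthetic participant consists of a wake encoding recording, a wake
vigilance (PVT) recording, a nap recording with embedded sleep events, a
hypnogram, artifact annotations and a behavior row.  The generator plants:

* a per-channel *encoding topography*: the 6-20 Hz oscillatory component of
  the encoding recording is attenuated channel-selectively relative to the
  PVT (power decreases only, matching the alpha/beta desynchronisation that
  indexes task engagement);
* spindle (12-15 Hz Hann-windowed sinusoid, compact support so each burst
  has a genuine onset) and SO (band-limited single-cycle 0.3-1.25 Hz wave)
  events during N2/N3 with per-channel amplitude topographies,
  non-overlapping within each kind and >= 2 s apart;
* von Mises-distributed SO-phase coupling: each spindle's envelope maximum
  is placed at a phase drawn from vonMises(0 deg, kappa) of its partner SO
  (0 deg = up-state peak);
* a controllable rank correlation (Gaussian copula across channels) between
  the encoding topography and the spindle amplitude topography — the
  *planted overlap* — and a behavior retention score linearly tied to it.

The planted overlap works through a Gaussian copula: encoding loadings are
a strictly decreasing transform of one latent normal, spindle amplitudes a
strictly increasing transform of a second latent correlated at
r = 2 sin(pi * |rho| / 6), which makes the population Spearman correlation
between the two topographies equal the requested rho (monotone transforms
leave Spearman invariant).

Background activity is 1/f^beta noise plus white noise — it has realistic
envelope statistics, so the mean + 1.25*SD detection criterion is
meaningfully exercised.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from scipy.stats import norm

from .events import bandpass_array
from .io_core import ArtifactMask, Hypnogram, Montage, Recording
from .montage import standard_montage_58

WAKE_BAND = (6.0, 20.0)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Sizes default to a desk-scale cohort: 19 participants, 58 channels at
    200 Hz, 5-min wake recordings and a 30-min nap of which ~24 min are
    N2/N3.  Event SNRs are expressed relative to the background signal
    band-limited to the detector's band: the spindle envelope peak as a
    multiple of the background 12-15 Hz SD, the SO trough as a multiple of
    the background 0.3-1.25 Hz SD.
    """

    n_participants: int = 19
    montage: Montage | None = None          # default: built-in 58-channel
    fs: float = 200.0
    wake_duration_s: float = 300.0
    sleep_duration_s: float = 1800.0
    # planted encoding-spindle overlap (population Spearman, negative for
    # overlap) and its per-participant SD
    planted_overlap: float = -0.4
    overlap_noise: float = 0.15
    # per-channel parameter ranges (mapped from the copula latents)
    encoding_loading_range: tuple[float, float] = (-0.8, -0.2)
    spindle_topo_range: tuple[float, float] = (0.7, 1.3)
    so_topo_range: tuple[float, float] = (0.7, 1.3)
    # optional explicit per-channel values overriding the copula draw
    encoding_loadings: np.ndarray | None = None
    spindle_topo: np.ndarray | None = None
    so_topo: np.ndarray | None = None
    # sleep events
    spindle_rate: float = 2.0               # events / artifact-free NREM min
    so_rate: float = 3.0
    spindle_freq_hz: float = 13.0
    spindle_dur_s: tuple[float, float] = (0.7, 1.2)
    so_dur_s: tuple[float, float] = (0.9, 1.3)
    coupling_kappa: float = 2.0
    spindle_snr: float = 3.0
    so_snr: float = 4.0
    amp_jitter: float = 0.15                # lognormal sigma per event
    min_event_spacing_s: float = 2.0
    # behavior
    behavior_effect: float = -40.0          # % retention per unit rho
    behavior_noise: float = 10.0
    # background noise model
    background_exponent: float = 1.0
    background_rms_uV: float = 15.0
    white_rms_uV: float = 5.0
    osc_rms_uV: float = 10.0                # wake 6-20 Hz component
    # artifacts planted into the nap
    n_sleep_artifacts: int = 2
    artifact_dur_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.montage is None:
            self.montage = standard_montage_58()
        for name in ("spindle_rate", "so_rate", "coupling_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("wake_duration_s", "sleep_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_ch = self.montage.n_channels
        for name in ("encoding_loadings", "spindle_topo", "so_topo"):
            v = getattr(self, name)
            if v is not None and np.asarray(v).shape != (n_ch,):
                raise ValueError(
                    f"{name} must have one entry per montage channel "
                    f"({n_ch})")
        if self.encoding_loadings is not None and np.any(
                np.asarray(self.encoding_loadings) > 0):
            raise ValueError("encoding loadings must be <= 0 "
                             "(decrease-only convention)")

    @property
    def n_channels(self) -> int:
        return self.montage.n_channels


@dataclass
class SynthTruth:
    """Ground truth for one synthetic participant."""

    participant_id: str
    encoding_topo: pd.Series       # expected in-band power change, uV^2 (<=0)
    spindle_topo: pd.Series        # expected spindle amplitude, uV (> 0)
    so_topo: pd.Series             # expected |trough| amplitude, uV (> 0)
    events: pd.DataFrame           # channel, kind, onset/offset, amplitude...
    planted_overlap: float         # this participant's target Spearman rho
    pre_z: float
    post_z: float
    retention_pct: float


@dataclass
class ParticipantBundle:
    """The observable data for one synthetic participant."""

    participant_id: str
    encoding: Recording
    pvt: Recording
    sleep: Recording
    hypnogram: Hypnogram
    artifacts: ArtifactMask
    behavior: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# noise and hypnogram scaffolding


def one_over_f_noise(rng: np.random.Generator, n_channels: int,
                     n_samples: int, fs: float, exponent: float,
                     rms: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, scaled to the requested RMS."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= rms / x.std(axis=1, keepdims=True)
    return x


def default_hypnogram(sleep_duration_s: float,
                      epoch_len: float = 30.0) -> Hypnogram:
    """Nap-like staging: brief wake/N1 onset, then alternating N2/N3."""
    n_epochs = int(np.ceil(sleep_duration_s / epoch_len))
    stages = ["W", "W", "N1", "N1"][:max(n_epochs - 4, 0)]
    block = ["N2"] * 10 + ["N3"] * 8
    while len(stages) < n_epochs:
        stages.extend(block)
    return Hypnogram(stages[:n_epochs], epoch_len)


def _dilate(mask: np.ndarray, n: int) -> np.ndarray:
    if n <= 0 or not mask.any():
        return mask.copy()
    idx = np.flatnonzero(mask)
    out = np.zeros_like(mask)
    for i in idx:
        out[max(i - n, 0):i + n + 1] = True
    return out


# ---------------------------------------------------------------------------
# wake


def generate_wake_pair(config: SynthConfig, encoding_loadings: np.ndarray,
                       rng: np.random.Generator
                       ) -> tuple[Recording, Recording]:
    """Encoding and PVT recordings sharing one 1/f background.

    The 6-20 Hz oscillatory component has per-channel power 1 + loading
    (relative to the PVT) in the encoding condition; loadings must be <= 0.
    """
    loadings = np.asarray(encoding_loadings, dtype=float)
    if np.any(loadings > 0):
        raise ValueError("encoding loadings must be <= 0")
    fs = config.fs
    n = int(round(config.wake_duration_s * fs))
    n_ch = config.n_channels
    background = one_over_f_noise(rng, n_ch, n, fs,
                                  config.background_exponent,
                                  config.background_rms_uV)

    def osc_component(scale_per_channel: np.ndarray) -> np.ndarray:
        raw = bandpass_array(rng.standard_normal((n_ch, n)), WAKE_BAND, fs)
        raw *= config.osc_rms_uV / raw.std(axis=1, keepdims=True)
        return raw * scale_per_channel[:, None]

    white = config.white_rms_uV
    labels = config.montage.channel_labels
    enc = Recording(
        background + osc_component(np.sqrt(1.0 + loadings))
        + white * rng.standard_normal((n_ch, n)), fs, labels)
    pvt = Recording(
        background + osc_component(np.ones(n_ch))
        + white * rng.standard_normal((n_ch, n)), fs, labels)
    return enc, pvt


# ---------------------------------------------------------------------------
# sleep


def _so_pulse_library(durations_s: np.ndarray, fs: float,
                      band: tuple[float, float] = (0.3, 1.25)
                      ) -> dict[int, dict]:
    """Band-limited single-cycle SO pulses, one per distinct duration.

    The raw cycle -sin(2*pi*t/T) is zero-phase band-passed so the planted
    waveform is what the SO detector's filter would pass unchanged; truth
    onset/offset (positive-to-negative crossings), trough time and the
    analytic-phase trajectory are read off the filtered pulse itself.
    Units: the returned pulse has trough amplitude 1.
    """
    pad = int(round(6.0 * fs))
    lib: dict[int, dict] = {}
    for m in np.unique(np.round(durations_s * fs).astype(int)):
        raw = np.zeros(2 * pad + m)
        tt = np.arange(m) / fs
        raw[pad:pad + m] = -np.sin(2 * np.pi * tt / (m / fs))
        w = bandpass_array(raw, band, fs)
        trough = pad + int(np.argmin(w[pad:pad + m]))
        down = np.flatnonzero((w[:-1] > 0) & (w[1:] <= 0)) + 1
        d1 = int(down[down <= trough].max())
        d2 = int(down[down > trough].min())
        w = w / (-w[trough])
        phase = np.unwrap(np.angle(hilbert(w)))
        # keep +-3 s around the cycle; the ringing beyond is negligible
        c1 = pad - int(round(3.0 * fs))
        c2 = pad + m + int(round(3.0 * fs))
        lib[m] = {"pulse": w[c1:c2], "pad": pad - c1, "trough": trough - c1,
                  "d1": d1 - c1, "d2": d2 - c1, "phase": phase[c1:c2]}
    return lib


def _phase_to_time(entry: dict, theta: float, fs: float) -> float:
    """Time (s, relative to raw pulse start) at SO phase theta.

    Phase convention: 0 at the positive peak (up-state), +-pi at the
    trough.  The analytic phase increases monotonically through the cycle;
    theta is mapped into the [d1, d2] crossing-to-crossing interval.
    """
    d1, d2, pad = entry["d1"], entry["d2"], entry["pad"]
    seg = entry["phase"][d1:d2 + 1]
    seg = np.maximum.accumulate(seg)  # guard tiny non-monotonic ripples
    u = seg[0] + np.mod(theta - seg[0], 2 * np.pi)
    u = min(u, seg[-1])
    idx = float(np.interp(u, seg, np.arange(d1, d2 + 1)))
    return (idx - pad) / fs


def _placement_slots(placeable: np.ndarray, fs: float, n_events: int,
                     needed_s: float, rng: np.random.Generator,
                     label: str) -> np.ndarray:
    """Jittered event anchor times (s) spread over the placeable samples.

    Raises when the requested rate cannot be honored without violating the
    spacing requirement.
    """
    idx = np.flatnonzero(placeable)
    if n_events == 0:
        return np.empty(0)
    total_s = idx.size / fs
    spacing = total_s / n_events
    if spacing < needed_s:
        raise ValueError(
            f"channel {label}: cannot place {n_events} events in "
            f"{total_s:.0f} s of usable NREM without overlap "
            f"(need {needed_s:.1f} s per event)")
    slack = spacing - needed_s
    virtual = (np.arange(n_events) + 0.5) * spacing
    virtual += rng.uniform(-0.45, 0.45, n_events) * slack
    pos = np.clip((virtual * fs).astype(int), 0, idx.size - 1)
    return idx[pos] / fs


def generate_sleep(config: SynthConfig, spindle_topo: np.ndarray,
                   so_topo: np.ndarray, rng: np.random.Generator
                   ) -> tuple[Recording, Hypnogram, ArtifactMask,
                              pd.DataFrame]:
    """Nap recording with embedded spindle/SO events and exact event log.

    ``spindle_topo`` / ``so_topo`` are positive per-channel *relative*
    amplitude loadings; planted amplitudes are ``spindle_snr`` times the
    channel's background 12-15 Hz envelope SD (respectively ``so_snr``
    times the background SO-band SD) times the loading.  Event counts per
    channel are rate * artifact-free NREM minutes (floored), with times
    drawn independently per channel; each spindle is coupled to a partner
    SO at a vonMises(0, kappa) phase.  Events of one kind do not overlap
    and are >= 2 s apart; coupling implies spindles *do* overlap their
    partner SO.

    The realized amplitude topographies (uV) are attached to the returned
    Recording as ``planted_spindle_amp`` / ``planted_so_amp``.
    """
    spindle_topo = np.asarray(spindle_topo, dtype=float)
    so_topo = np.asarray(so_topo, dtype=float)
    if np.any(spindle_topo <= 0) or np.any(so_topo <= 0):
        raise ValueError("event amplitude topographies must be positive")
    fs = config.fs
    n = int(round(config.sleep_duration_s * fs))
    n_ch = config.n_channels
    labels = config.montage.channel_labels
    hyp = default_hypnogram(config.sleep_duration_s)
    stage_nrem = hyp.stage_mask(fs, n)

    # artifacts inside NREM so the artifact-free accounting is exercised
    art_intervals = []
    nrem_idx = np.flatnonzero(stage_nrem)
    for k in range(config.n_sleep_artifacts):
        if nrem_idx.size == 0:
            break
        pick = nrem_idx[int(rng.integers(nrem_idx.size))]
        start = min(pick / fs, n / fs - config.artifact_dur_s)
        art_intervals.append((start, start + config.artifact_dur_s))
    artifacts = ArtifactMask(art_intervals)

    art_mask = artifacts.sample_mask(fs, n)
    free_nrem_min = (stage_nrem & ~art_mask).sum() / fs / 60.0
    margin = int(round(4.0 * fs))
    placeable = stage_nrem & ~_dilate(art_mask, margin)
    placeable[:margin] = False
    placeable[-margin:] = False

    signal = one_over_f_noise(rng, n_ch, n, fs, config.background_exponent,
                              config.background_rms_uV)
    signal += config.white_rms_uV * rng.standard_normal((n_ch, n))

    # background scale references for the SNR definitions: the spindle SNR
    # is relative to the SD of the 12-15 Hz background signal; the SO SNR
    # is relative to the typical background wave amplitude — the mean
    # |trough| of background SO-band cycles in the same 0.8-2 s duration
    # class the detector considers
    sigma_sp = bandpass_array(signal, (12.0, 15.0), fs).std(axis=1)
    so_bg = bandpass_array(signal, (0.3, 1.25), fs)
    wave_so = np.empty(n_ch)
    for ci in range(n_ch):
        x = so_bg[ci]
        down = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1
        troughs = [x[i1:i2].min() for i1, i2 in zip(down[:-1], down[1:])
                   if 0.8 <= (i2 - i1) / fs <= 2.0]
        wave_so[ci] = -np.mean(troughs) if troughs else x.std()
    del so_bg

    spindle_amp = config.spindle_snr * sigma_sp * spindle_topo
    so_amp = config.so_snr * wave_so * so_topo

    n_so = int(config.so_rate * free_nrem_min)
    n_sp = int(config.spindle_rate * free_nrem_min)
    so_need = (config.so_dur_s[1] + 1.0 + config.min_event_spacing_s
               + config.spindle_dur_s[1])
    so_lib = _so_pulse_library(
        np.linspace(*config.so_dur_s, 16), fs)
    so_keys = np.array(sorted(so_lib))
    t = np.arange(n) / fs
    rows = []
    for ci in range(n_ch):
        so_anchor = _placement_slots(placeable, fs, n_so, so_need, rng,
                                     labels[ci])
        so_key = rng.choice(so_keys, size=n_so)
        so_amps = so_amp[ci] * rng.lognormal(0.0, config.amp_jitter, n_so)
        so_entries = []
        for anchor, key, amp in zip(so_anchor, so_key, so_amps):
            e = so_lib[key]
            a_idx = int(round(anchor * fs)) - e["pad"]
            signal[ci, a_idx:a_idx + e["pulse"].size] += amp * e["pulse"]
            onset = anchor + (e["d1"] - e["pad"]) / fs
            offset = anchor + (e["d2"] - e["pad"]) / fs
            rows.append((labels[ci], "so", onset, offset, offset - onset,
                         amp, anchor + (e["trough"] - e["pad"]) / fs,
                         np.nan))
            so_entries.append((anchor, e))
        if n_so == 0 and n_sp > 0:
            raise ValueError(
                f"channel {labels[ci]}: spindles require partner SOs; "
                "so_rate is 0 while spindle_rate > 0")
        if n_sp > 0:
            partners = np.unique(
                np.round(np.linspace(0, n_so - 1, n_sp)).astype(int))
            theta = rng.vonmises(0.0, config.coupling_kappa,
                                 size=partners.size)
            sp_durs = rng.uniform(*config.spindle_dur_s, size=partners.size)
            sp_amps = (spindle_amp[ci]
                       * rng.lognormal(0.0, config.amp_jitter,
                                       partners.size))
            for k, (j, th) in enumerate(zip(partners, theta)):
                anchor, entry = so_entries[j]
                t_peak = anchor + _phase_to_time(entry, th, fs)
                dur, amp = sp_durs[k], sp_amps[k]
                # Hann (raised-cosine) envelope with compact support
                # [-dur, +dur]: the envelope is at 50% of its peak at
                # +-dur/2, so the logged duration is the FWHM and the
                # event has a genuine onset (no infinite flanks)
                half = dur / 2.0
                i1 = int(round((t_peak - dur) * fs))
                i2 = int(round((t_peak + dur) * fs))
                tt = t[i1:i2] - t_peak
                envelope = 0.5 * (1 + np.cos(np.pi * tt / dur))
                signal[ci, i1:i2] += (
                    amp * envelope
                    * np.cos(2 * np.pi * config.spindle_freq_hz * tt))
                phase_deg = float(np.degrees(
                    np.mod(th + np.pi, 2 * np.pi) - np.pi))
                rows.append((labels[ci], "spindle", t_peak - half,
                             t_peak + half, dur, amp, t_peak, phase_deg))
    events = pd.DataFrame(
        rows, columns=["channel", "kind", "onset_s", "offset_s",
                       "duration_s", "amplitude_uV", "peak_time_s",
                       "so_phase_deg"],
    ).sort_values(["channel", "onset_s"]).reset_index(drop=True)
    rec = Recording(signal, fs, labels)
    # stash the realized per-channel amplitudes for ground-truth use
    rec.planted_spindle_amp = spindle_amp  # type: ignore[attr-defined]
    rec.planted_so_amp = so_amp            # type: ignore[attr-defined]
    return rec, hyp, artifacts, events


# ---------------------------------------------------------------------------
# cohort


def _copula_latents(rng: np.random.Generator, n_ch: int,
                    target_spearman: float) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal channel vectors with a chosen Spearman rho."""
    r = 2.0 * np.sin(np.pi * np.clip(target_spearman, -0.999, 0.999) / 6.0)
    z1 = rng.standard_normal(n_ch)
    z2 = r * z1 + np.sqrt(max(1 - r * r, 0.0)) * rng.standard_normal(n_ch)
    return z1, z2


def generate_participant(config: SynthConfig, participant_id: str,
                         rng: np.random.Generator
                         ) -> tuple[ParticipantBundle, SynthTruth]:
    n_ch = config.n_channels
    labels = config.montage.channel_labels

    rho_i = config.planted_overlap
    if config.overlap_noise > 0:
        rho_i = float(np.clip(
            rho_i + config.overlap_noise * rng.standard_normal(),
            -0.95, 0.95))
    # encoding decreases with z1, spindle amplitude increases with z2, so a
    # planted Spearman rho between them needs Spearman(z1, z2) = -rho
    z1, z2 = _copula_latents(rng, n_ch, -rho_i)
    z3 = rng.standard_normal(n_ch)

    lo, hi = config.encoding_loading_range
    if config.encoding_loadings is not None:
        loadings = np.asarray(config.encoding_loadings, dtype=float)
    else:
        loadings = hi + (lo - hi) * norm.cdf(z1)       # decreasing in z1
    sp_lo, sp_hi = config.spindle_topo_range
    if config.spindle_topo is not None:
        sp_rel = np.asarray(config.spindle_topo, dtype=float)
    else:
        sp_rel = sp_lo + (sp_hi - sp_lo) * norm.cdf(z2)  # increasing in z2
    so_lo, so_hi = config.so_topo_range
    if config.so_topo is not None:
        so_rel = np.asarray(config.so_topo, dtype=float)
    else:
        so_rel = so_lo + (so_hi - so_lo) * norm.cdf(z3)

    enc_rec, pvt_rec = generate_wake_pair(config, loadings, rng)
    sleep_rec, hyp, artifacts, ev = generate_sleep(config, sp_rel, so_rel,
                                                   rng)
    spindle_amp = sleep_rec.planted_spindle_amp  # type: ignore[attr-defined]
    so_amp = sleep_rec.planted_so_amp            # type: ignore[attr-defined]

    retention = (100.0
                 + config.behavior_effect * (rho_i - config.planted_overlap)
                 + config.behavior_noise * rng.standard_normal())
    retention = float(np.clip(retention, 0.5, 150.0))
    pre_z = float(np.clip(1.2 + 0.15 * rng.standard_normal(), 0.3, None))
    post_z = retention / 100.0 * pre_z

    behavior = {"participant_id": participant_id, "pre_z": pre_z,
                "post_z": post_z, "retention_pct": retention}
    bundle = ParticipantBundle(participant_id, enc_rec, pvt_rec, sleep_rec,
                               hyp, artifacts, behavior)
    truth = SynthTruth(
        participant_id=participant_id,
        encoding_topo=pd.Series(config.osc_rms_uV ** 2 * loadings,
                                index=labels),
        spindle_topo=pd.Series(spindle_amp, index=labels),
        so_topo=pd.Series(so_amp, index=labels),
        events=ev,
        planted_overlap=rho_i,
        pre_z=pre_z, post_z=post_z, retention_pct=retention,
    )
    return bundle, truth


def generate_cohort(config: SynthConfig
                    ) -> list[tuple[ParticipantBundle, SynthTruth]]:
    """Generate the full cohort; deterministic given ``config.seed``."""
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    out = []
    for i, seq in enumerate(seqs):
        pid = f"sub-{i + 1:02d}"
        out.append(generate_participant(config, pid,
                                        np.random.default_rng(seq)))
    return out


# ---------------------------------------------------------------------------
# helpers for evaluating detectors against the truth


def score_detection(detected: pd.DataFrame, truth: pd.DataFrame,
                    kind: str, onset_tol_s: float = 0.25) -> dict:
    """Recall/precision of a detected event table against the planted log.

    Events are matched one-to-one per channel by onset proximity within
    ``onset_tol_s``, using an optimal assignment (maximal number of
    matches, minimal total onset discrepancy among them).
    """
    from scipy.optimize import linear_sum_assignment

    det = detected[detected["kind"] == kind]
    tru = truth[truth["kind"] == kind]
    n_match = 0
    for ch, tru_ch in tru.groupby("channel"):
        det_on = det.loc[det["channel"] == ch, "onset_s"].to_numpy()
        tru_on = tru_ch["onset_s"].to_numpy()
        if det_on.size == 0:
            continue
        cost = np.abs(tru_on[:, None] - det_on[None, :])
        # forbidden pairs get a large but finite cost so the assignment
        # stays feasible; only pairs within tolerance count as matches
        feasible = cost <= onset_tol_s
        cost = np.where(feasible, cost, 1e6)
        rows, cols = linear_sum_assignment(cost)
        n_match += int(feasible[rows, cols].sum())
    n_true, n_det = len(tru), len(det)
    return {
        "n_true": n_true, "n_detected": n_det, "n_matched": n_match,
        "recall": n_match / n_true if n_true else float("nan"),
        "precision": n_match / n_det if n_det else float("nan"),
    }


def generate_topography_cohort(n_participants: int, n_channels: int = 58,
                               planted_overlap: float = -0.4,
                               overlap_noise: float = 0.15,
                               behavior_effect: float = -40.0,
                               behavior_noise: float = 10.0,
                               rng: np.random.Generator | int | None = None
                               ) -> tuple[np.ndarray, np.ndarray,
                                          np.ndarray]:
    """Encoding/spindle topographies plus retention, no EEG synthesis.

    Uses the same copula and behavior model as the full generator —
    encoding values negative and decreasing in the first latent, spindle
    amplitudes positive and increasing in the second — so overlap and
    behavior statistics can be calibrated at scale.  Returns
    ``(encoding (n, ch), spindle (n, ch), retention_pct (n))``.
    """
    rng = np.random.default_rng(rng)
    enc = np.empty((n_participants, n_channels))
    spin = np.empty((n_participants, n_channels))
    ret = np.empty(n_participants)
    for i in range(n_participants):
        rho_i = planted_overlap
        if overlap_noise > 0:
            rho_i = float(np.clip(
                rho_i + overlap_noise * rng.standard_normal(), -0.95, 0.95))
        z1, z2 = _copula_latents(rng, n_channels, -rho_i)
        enc[i] = -(0.2 + 0.6 * norm.cdf(z1)) * 100.0
        spin[i] = 10.0 * (0.7 + 0.6 * norm.cdf(z2))
        ret[i] = np.clip(
            100.0 + behavior_effect * (rho_i - planted_overlap)
            + behavior_noise * rng.standard_normal(), 0.5, 150.0)
    return enc, spin, ret


def generate_contrast_cohort(n_participants: int, n_channels: int,
                             n_freqs: int = 20, noise_sd: float = 1.0,
                             effect: float = 0.0,
                             effect_bins: np.ndarray | None = None,
                             rng: np.random.Generator | int | None = None
                             ) -> np.ndarray:
    """Participant contrast maps with an optional planted mean decrease.

    Draws (n, channels, freqs) i.i.d. normal cell noise and subtracts
    ``effect`` on the ``effect_bins`` frequency columns of every channel —
    the minimal data model for calibrating the group cluster test.
    """
    rng = np.random.default_rng(rng)
    x = noise_sd * rng.standard_normal((n_participants, n_channels, n_freqs))
    if effect != 0.0:
        if effect_bins is None:
            raise ValueError("effect_bins required when effect != 0")
        x[:, :, np.asarray(effect_bins, dtype=int)] -= effect
    return x
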