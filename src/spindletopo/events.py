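"""Detection of sleep spindles and slow oscillations (SOs) on NREM EEG.

Fast spindles are detected per channel as runs where the Hilbert envelope of
the 12-15 Hz band-passed signal exceeds mean + 1.25*SD of that envelope over
artifact-free N2/N3 samples, with the run duration strictly between 0.5 and
3 s.  SOs are detected on the 0.3-1.25 Hz signal as intervals between
consecutive positive-to-negative zero crossings lasting 0.8-2 s whose
trough-to-peak amplitude and absolute trough amplitude both exceed
mean + 1.25*SD of the candidate population.  Events must be artifact-free
from 1 s before onset to 1 s after offset and must lie entirely within
N2/N3.

SO-phase coupling of spindles uses the analytic phase of the 0.3-1.25 Hz
signal in a +-2.5 s window around each spindle's envelope maximum; 0 deg is
the SO positive peak (up-state), +-180 deg the trough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .io_core import ArtifactMask, Hypnogram, Recording, nrem_sample_mask

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "channel", "kind", "onset_s", "offset_s", "duration_s",
    "amplitude_uV", "peak_time_s", "so_phase_deg", "low_so_amplitude",
]


@dataclass
class DetectionParams:
    """Detector settings; defaults are the values the analysis is defined at.

    Attributes
    ----------
    spindle_band, so_band : (float, float)
        Pass bands in Hz for spindle and SO detection.
    filter_order : int
        Butterworth order; filtering is two-pass (zero-phase), so the
        effective magnitude response is squared.
    envelope_smooth_s : float
        Length of the centered moving average applied to the spindle
        envelope, in seconds.
    smooth_before_hilbert : bool
        If True, the moving average is applied to the band-passed signal
        before the Hilbert transform instead of to its magnitude
        (the alternative reading of the envelope recipe).
    threshold_sd : float
        Number of SDs above the mean for the amplitude criteria.
    spindle_dur : (float, float)
        Open duration interval for spindles, seconds.
    so_dur : (float, float)
        Closed duration interval for SO candidates, seconds.
    artifact_pad_s : float
        Events must be artifact-free from this long before onset until this
        long after offset.
    coupling_window_s : float
        Half-width of the window used for SO-phase extraction.
    low_so_percentile : float
        Spindles whose local SO-band envelope falls below this percentile of
        the channel's event population are flagged ``low_so_amplitude``.
    """

    spindle_band: tuple[float, float] = (12.0, 15.0)
    so_band: tuple[float, float] = (0.3, 1.25)
    filter_order: int = 4
    envelope_smooth_s: float = 0.2
    smooth_before_hilbert: bool = False
    threshold_sd: float = 1.25
    spindle_dur: tuple[float, float] = (0.5, 3.0)
    so_dur: tuple[float, float] = (0.8, 2.0)
    artifact_pad_s: float = 1.0
    coupling_window_s: float = 2.5
    low_so_percentile: float = 10.0

    def __post_init__(self) -> None:
        for band in (self.spindle_band, self.so_band):
            if not (0 < band[0] < band[1]):
                raise ValueError(f"invalid band {band}")
        for dur in (self.spindle_dur, self.so_dur):
            if not (0 < dur[0] < dur[1]):
                raise ValueError(f"invalid duration bounds {dur}")


def bandpass(recording: Recording, band: tuple[float, float],
             order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass of all channels."""
    filtered = bandpass_array(recording.signal, band, recording.fs, order)
    return Recording(filtered, recording.fs, recording.channel_labels,
                     recording.start_time)


def bandpass_array(x: np.ndarray, band: tuple[float, float], fs: float,
                   order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq})")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def spindle_envelope(filtered: np.ndarray, fs: float,
                     smooth_s: float = 0.2,
                     smooth_before_hilbert: bool = False) -> np.ndarray:
    """Amplitude envelope of a band-passed single-channel signal.

    By default the Hilbert magnitude is computed first and then smoothed
    with a centered moving average; smoothing the carrier itself first is
    available via ``smooth_before_hilbert``.
    """
    x = np.asarray(filtered, dtype=float)
    if x.ndim != 1:
        raise ValueError("spindle_envelope expects a single channel")
    win = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(win) / win

    def smooth(v: np.ndarray) -> np.ndarray:
        # centered moving average with edge-truncated normalisation
        num = np.convolve(v, kernel, mode="same")
        norm = np.convolve(np.ones_like(v), kernel, mode="same")
        return num / norm

    if smooth_before_hilbert:
        return np.abs(hilbert(smooth(x)))
    return smooth(np.abs(hilbert(x)))


def _true_runs(mask: np.ndarray) -> np.ndarray:
    """Half-open [start, stop) index pairs of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        stops = np.r_[stops, m.size]
    return np.column_stack([starts, stops])


def _empty_events() -> pd.DataFrame:
    df = pd.DataFrame(columns=EVENT_COLUMNS)
    return df.astype({
        "onset_s": float, "offset_s": float, "duration_s": float,
        "amplitude_uV": float, "peak_time_s": float, "so_phase_deg": float,
        "low_so_amplitude": bool,
    })


def detect_spindles(recording: Recording, hypnogram: Hypnogram,
                    artifacts: ArtifactMask,
                    params: DetectionParams | None = None) -> pd.DataFrame:
    """Detect fast sleep spindles per channel.

    Returns one row per event with columns ``channel, kind, onset_s,
    offset_s, duration_s, amplitude_uV, peak_time_s`` (time of the envelope
    maximum); ``so_phase_deg`` is NaN until :func:`spindle_so_phase` runs.
    """
    params = params or DetectionParams()
    fs, n = recording.fs, recording.n_samples
    good_nrem, minutes = nrem_sample_mask(hypnogram, artifacts, fs, n)
    if minutes <= 0:
        raise ValueError("no artifact-free NREM samples to detect on")
    stage_nrem = hypnogram.stage_mask(fs, n)
    filtered = bandpass_array(recording.signal, params.spindle_band, fs,
                              params.filter_order)
    pad = params.artifact_pad_s
    rows = []
    for ci, label in enumerate(recording.channel_labels):
        env = spindle_envelope(filtered[ci], fs, params.envelope_smooth_s,
                               params.smooth_before_hilbert)
        ref = env[good_nrem]
        thr = ref.mean() + params.threshold_sd * ref.std()
        for start, stop in _true_runs(env > thr):
            dur = (stop - start) / fs
            if not (params.spindle_dur[0] < dur < params.spindle_dur[1]):
                continue
            if not stage_nrem[start:stop].all():
                continue
            onset, offset = start / fs, stop / fs
            if onset - pad < 0 or offset + pad > n / fs:
                continue
            if artifacts.covers(onset - pad, offset + pad):
                continue
            k = start + int(np.argmax(env[start:stop]))
            rows.append((label, "spindle", onset, offset, dur,
                         float(env[k]), k / fs, np.nan, False))
    if not rows:
        return _empty_events()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def detect_slow_oscillations(recording: Recording, hypnogram: Hypnogram,
                             artifacts: ArtifactMask,
                             params: DetectionParams | None = None
                             ) -> pd.DataFrame:
    """Detect slow oscillations per channel.

    Candidates are intervals between consecutive positive-to-negative zero
    crossings of the SO-band signal lasting 0.8-2 s (closed bounds); events
    are candidates whose trough-to-peak amplitude and absolute trough
    amplitude both strictly exceed mean + 1.25*SD of the candidate
    population (pooled over the night, per channel).  Amplitude is stored as
    the absolute trough (down-state) amplitude; ``peak_time_s`` is the
    trough time.
    """
    params = params or DetectionParams()
    fs, n = recording.fs, recording.n_samples
    good_nrem, minutes = nrem_sample_mask(hypnogram, artifacts, fs, n)
    if minutes <= 0:
        raise ValueError("no artifact-free NREM samples to detect on")
    stage_nrem = hypnogram.stage_mask(fs, n)
    filtered = bandpass_array(recording.signal, params.so_band, fs,
                              params.filter_order)
    pad = params.artifact_pad_s
    rows = []
    for ci, label in enumerate(recording.channel_labels):
        x = filtered[ci]
        # positive-to-negative zero crossings: x[i-1] > 0 and x[i] <= 0
        down = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1
        cands = []  # (start, stop, trough_idx, t2p, abs_trough)
        for i1, i2 in zip(down[:-1], down[1:]):
            dur = (i2 - i1) / fs
            if not (params.so_dur[0] <= dur <= params.so_dur[1]):
                continue
            if not stage_nrem[i1:i2].all():
                continue
            onset, offset = i1 / fs, i2 / fs
            if onset - pad < 0 or offset + pad > n / fs:
                continue
            if artifacts.covers(onset - pad, offset + pad):
                continue
            seg = x[i1:i2]
            ti = i1 + int(np.argmin(seg))
            cands.append((i1, i2, ti, float(seg.max() - seg.min()),
                          float(-seg.min())))
        if not cands:
            continue
        t2p = np.array([c[3] for c in cands])
        trough = np.array([c[4] for c in cands])
        thr_t2p = t2p.mean() + params.threshold_sd * t2p.std()
        thr_trough = trough.mean() + params.threshold_sd * trough.std()
        for (i1, i2, ti, a_t2p, a_tr) in cands:
            if a_t2p > thr_t2p and a_tr > thr_trough:
                rows.append((label, "so", i1 / fs, i2 / fs, (i2 - i1) / fs,
                             a_tr, ti / fs, np.nan, False))
    if not rows:
        return _empty_events()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@dataclass
class EventTopography:
    """Per-channel event characteristics for one event kind.

    ``table`` is indexed by channel label with columns ``amplitude_uV``
    (mean over events), ``duration_s`` (mean), ``density_per_min`` (events
    per artifact-free NREM minute) and ``n_events``.  Channels without any
    event carry NaN amplitude/duration and density 0.
    """

    kind: str
    table: pd.DataFrame
    nrem_minutes: float = field(default=np.nan)

    def vector(self, characteristic: str) -> pd.Series:
        """One of the per-channel vectors: amplitude, duration or density."""
        col = {"amplitude": "amplitude_uV", "duration": "duration_s",
               "density": "density_per_min"}[characteristic]
        return self.table[col]


def characterize(events: pd.DataFrame, hypnogram: Hypnogram,
                 artifacts: ArtifactMask, fs: float, n_samples: int,
                 channel_labels: list[str]) -> EventTopography:
    """Collapse an event table to per-channel amplitude/duration/density."""
    kinds = set(events["kind"]) if len(events) else set()
    if len(kinds) > 1:
        raise ValueError(f"events of mixed kinds {kinds}")
    kind = kinds.pop() if kinds else "none"
    _, minutes = nrem_sample_mask(hypnogram, artifacts, fs, n_samples)
    rows = []
    for label in channel_labels:
        ev = events[events["channel"] == label] if len(events) else events
        n_ev = len(ev)
        rows.append({
            "channel": label,
            "amplitude_uV": ev["amplitude_uV"].mean() if n_ev else np.nan,
            "duration_s": ev["duration_s"].mean() if n_ev else np.nan,
            "density_per_min": n_ev / minutes if minutes > 0 else 0.0,
            "n_events": n_ev,
        })
    table = pd.DataFrame(rows).set_index("channel")
    return EventTopography(kind=kind, table=table, nrem_minutes=minutes)


def spindle_so_phase(recording: Recording, spindle_events: pd.DataFrame,
                     params: DetectionParams | None = None) -> pd.DataFrame:
    """Attach the SO phase at each spindle's envelope maximum.

    A +-coupling_window_s window around the envelope maximum is band-passed
    0.3-1.25 Hz (zero-phase Butterworth), Hilbert-transformed, and the
    analytic phase at the center sample taken (0 deg = SO positive peak,
    +-180 deg = trough).  Events whose window exceeds the recording are
    skipped (NaN phase, logged count).  Per channel, events whose local
    SO-band envelope falls in the lowest ``low_so_percentile`` of the
    channel's events are flagged ``low_so_amplitude``.
    """
    params = params or DetectionParams()
    fs, n = recording.fs, recording.n_samples
    half = int(round(params.coupling_window_s * fs))
    events = spindle_events.copy().reset_index(drop=True)
    phases = np.full(len(events), np.nan)
    so_env = np.full(len(events), np.nan)
    ch_index = {lbl: i for i, lbl in enumerate(recording.channel_labels)}
    n_skipped = 0
    for i, row in events.iterrows():
        k = int(round(row["peak_time_s"] * fs))
        if k - half < 0 or k + half + 1 > n:
            n_skipped += 1
            continue
        seg = recording.signal[ch_index[row["channel"]], k - half:k + half + 1]
        so = bandpass_array(seg, params.so_band, fs, params.filter_order)
        analytic = hilbert(so)
        phases[i] = np.degrees(np.angle(analytic[half]))
        so_env[i] = np.abs(analytic[half])
    if n_skipped:
        logger.info("spindle_so_phase: skipped %d events too close to the "
                    "recording edges", n_skipped)
    events["so_phase_deg"] = phases
    events["low_so_amplitude"] = False
    for lbl in events["channel"].unique():
        sel = (events["channel"] == lbl) & np.isfinite(so_env)
        if sel.sum() >= 5:
            thr = np.percentile(so_env[sel.to_numpy()],
                                params.low_so_percentile)
            events.loc[sel & (so_env < thr), "low_so_amplitude"] = True
    return events


def circular_distance_deg(phase_deg: np.ndarray) -> np.ndarray:
    """Absolute circular distance to 0 degrees, in [0, 180]."""
    wrapped = np.mod(np.asarray(phase_deg, dtype=float) + 180.0, 360.0) - 180.0
    return np.abs(wrapped)


def split_by_coupling(events: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split spindles into higher- vs lower-coupling halves per channel.

    Per channel, events are ranked by circular distance of their SO phase to
    0 deg (ties broken by earlier onset); the closer half is the
    "higher coupling" set.  With an odd count the extra event goes to the
    higher-coupling set.  Events without a phase are excluded.
    """
    ev = events[np.isfinite(events["so_phase_deg"])].copy()
    higher_idx: list = []
    lower_idx: list = []
    for _, grp in ev.groupby("channel", sort=False):
        dist = circular_distance_deg(grp["so_phase_deg"].to_numpy())
        order = np.lexsort((grp["onset_s"].to_numpy(), dist))
        n_hi = (len(grp) + 1) // 2
        higher_idx.extend(grp.index[order[:n_hi]])
        lower_idx.extend(grp.index[order[n_hi:]])
    return ev.loc[higher_idx], ev.loc[lower_idx]
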