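"""Wake encoding-pattern extraction.

Per participant, oscillatory power (1-20 Hz) during the encoding task is
contrasted against the vigilance control (PVT): the signal is cut into 1-s
Hanning-tapered epochs with 50% overlap, Fourier-transformed, outlier epochs
are rejected per channel x frequency cell at the 95th percentile, and the
retained-epoch means are subtracted (encoding - PVT).  A group-level
two-sided cluster-based permutation test (participant-wise sign flips)
identifies the significant frequency bins; collapsing the contrast across
those bins yields one per-channel encoding topography per participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .io_core import Montage, Recording
from .montage import channel_adjacency

FREQ_LO, FREQ_HI = 1.0, 20.0


@dataclass
class SpectraSet:
    """Epoch-wise power spectra: ``power[epoch, channel, freq_bin]`` in uV^2."""

    power: np.ndarray
    freqs: np.ndarray
    channel_labels: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be epochs x channels x freqs")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class ContrastMap:
    """Per-cell power change (encoding mean - PVT mean), channels x freqs."""

    delta_power: np.ndarray
    freqs: np.ndarray
    channel_labels: list[str]
    participant_id: str = ""


@dataclass
class ClusterResult:
    """Outcome of the group cluster-based permutation test.

    ``clusters`` holds one dict per cluster with keys ``cells`` (array of
    (channel_idx, freq_idx) pairs), ``stat`` (summed t), ``p`` and ``sign``.
    ``mask`` marks cells belonging to significant clusters; ``sig_bins`` is
    the union of frequency-bin indices over significant clusters.
    """

    clusters: list[dict]
    mask: np.ndarray
    sig_bins: np.ndarray
    t_map: np.ndarray
    t_crit: float
    freqs: np.ndarray
    n_perm: int


@dataclass
class EncodingTopography:
    """Per-channel collapsed power change (uV^2) for one participant."""

    values: np.ndarray
    channel_labels: list[str]
    participant_id: str = ""


def epoch_psd(recording: Recording, condition: str = "",
              epoch_len_s: float = 1.0, overlap: float = 0.5) -> SpectraSet:
    """Hanning-tapered FFT power per 1-s epoch (50% overlap), 1-20 Hz bins.

    The scaling is such that a sinusoid of amplitude A landing on a bin
    center contributes A^2/2 (its mean-square power) to that bin.
    """
    if recording.duration < 2 * epoch_len_s:
        raise ValueError("recording too short for epoching")
    fs = recording.fs
    nper = int(round(epoch_len_s * fs))
    step = int(round(nper * (1 - overlap)))
    sig = recording.signal
    n_epochs = (sig.shape[1] - nper) // step + 1
    idx = np.arange(nper)[None, :] + step * np.arange(n_epochs)[:, None]
    epochs = sig[:, idx]                        # channels x epochs x nper
    window = np.hanning(nper)
    spec = np.fft.rfft(epochs * window, axis=-1)
    power = 2.0 * np.abs(spec) ** 2 / window.sum() ** 2
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    keep = (freqs >= FREQ_LO - 1e-9) & (freqs <= FREQ_HI + 1e-9)
    return SpectraSet(
        power=np.transpose(power[:, :, keep], (1, 0, 2)),
        freqs=freqs[keep],
        channel_labels=recording.channel_labels,
        condition=condition,
    )


def percentile_reject(spectra: SpectraSet, pct: float = 95.0) -> np.ndarray:
    """Per-cell epoch retention mask at the given percentile.

    For each (channel, frequency) cell independently, epochs whose power is
    strictly above that cell's pct-th percentile (linear-interpolation
    definition) are excluded.  Returns a boolean array shaped like
    ``spectra.power`` with True = retained.
    """
    if not (50.0 < pct <= 100.0):
        raise ValueError("pct must lie in (50, 100]")
    if spectra.power.shape[0] < 20:
        raise ValueError("need at least 20 epochs for percentile rejection")
    thresh = np.percentile(spectra.power, pct, axis=0, method="linear")
    return spectra.power <= thresh[None]


def contrast(enc: SpectraSet, pvt: SpectraSet,
             masks: tuple[np.ndarray, np.ndarray] | None = None,
             participant_id: str = "") -> ContrastMap:
    """Retained-epoch mean difference (encoding - PVT) per cell."""
    if enc.freqs.shape != pvt.freqs.shape or not np.allclose(enc.freqs,
                                                             pvt.freqs):
        raise ValueError("frequency bins differ between conditions")
    if enc.channel_labels != pvt.channel_labels:
        raise ValueError("channel sets differ between conditions")

    def masked_mean(s: SpectraSet, mask: np.ndarray | None) -> np.ndarray:
        if mask is None:
            return s.power.mean(axis=0)
        w = mask.astype(float)
        return (s.power * w).sum(axis=0) / w.sum(axis=0)

    m_enc, m_pvt = masks if masks is not None else (None, None)
    delta = masked_mean(enc, m_enc) - masked_mean(pvt, m_pvt)
    return ContrastMap(delta, enc.freqs.copy(), list(enc.channel_labels),
                       participant_id)


def _cell_adjacency(adj_ch: np.ndarray, n_freq: int) -> sp.csr_matrix:
    """Adjacency over flattened (channel, freq) cells.

    Cells are neighbors when they share a frequency bin and sit on adjacent
    channels, or share a channel and sit on adjacent (+-1) frequency bins.
    """
    n_ch = adj_ch.shape[0]
    adj_f = sp.diags([np.ones(n_freq - 1)] * 2, [-1, 1], format="csr")
    a = sp.kron(sp.csr_matrix(adj_ch.astype(np.int8)), sp.eye(n_freq),
                format="csr")
    a = a + sp.kron(sp.eye(n_ch), adj_f, format="csr")
    return a.tocsr()


def _cluster_sums(t_flat: np.ndarray, t_crit: float,
                  cell_adj: sp.csr_matrix,
                  return_members: bool = False):
    """Clusters of supra-threshold cells, positive and negative separately."""
    out = []
    for sign in (1.0, -1.0):
        supra = np.flatnonzero(sign * t_flat > t_crit)
        if supra.size == 0:
            continue
        sub = cell_adj[supra][:, supra]
        n_comp, labels = connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = supra[labels == comp]
            item = {"stat": float(t_flat[members].sum()), "sign": sign}
            if return_members:
                item["members"] = members
            out.append(item)
    return out


def cluster_permutation(contrasts: list[ContrastMap] | np.ndarray,
                        montage: Montage, n_perm: int = 1000,
                        cell_alpha: float = 0.05,
                        cluster_alpha: float = 0.05,
                        rng: np.random.Generator | int | None = None,
                        freqs: np.ndarray | None = None) -> ClusterResult:
    """Group-level paired cluster test of the contrast maps against zero.

    One-sample t-values across participants are computed per cell; cells
    with |t| above the two-sided ``cell_alpha`` critical value are clustered
    by channel adjacency (Delaunay neighbors) and +-1 frequency-bin
    adjacency; the cluster statistic is the summed t.  The null is the
    maximal |cluster statistic| under random participant-wise sign flips;
    cluster p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if isinstance(contrasts, np.ndarray):
        X = np.asarray(contrasts, dtype=float)
        if freqs is None:
            freqs = np.arange(1.0, X.shape[2] + 1.0)
    else:
        X = np.stack([c.delta_power for c in contrasts])
        freqs = contrasts[0].freqs
        if contrasts[0].channel_labels != montage.channel_labels:
            raise ValueError("contrast channels do not match the montage")
    n, n_ch, n_freq = X.shape
    if n < 2:
        raise ValueError("need at least 2 participants (df = n - 1 > 0)")
    rng = np.random.default_rng(rng)

    flat = X.reshape(n, -1)
    t_crit = float(t_dist.ppf(1 - cell_alpha / 2, n - 1))
    cell_adj = _cell_adjacency(channel_adjacency(montage), n_freq)

    def t_stats(means: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
        var = (sumsq - n * means ** 2) / (n - 1)
        var = np.maximum(var, 1e-300)
        return means / np.sqrt(var / n)

    sumsq = (flat ** 2).sum(axis=0)  # invariant under sign flips
    t_obs = t_stats(flat.mean(axis=0), sumsq)
    observed = _cluster_sums(t_obs, t_crit, cell_adj, return_members=True)

    null = np.zeros(n_perm)
    chunk = 200
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n))
        means = signs @ flat / n
        t_perm = t_stats(means, sumsq[None])
        for j in range(k):
            sums = _cluster_sums(t_perm[j], t_crit, cell_adj)
            if sums:
                null[done + j] = max(abs(c["stat"]) for c in sums)
        done += k

    clusters = []
    mask = np.zeros((n_ch, n_freq), dtype=bool)
    sig_bins: set[int] = set()
    for c in observed:
        p = (1 + np.sum(null >= abs(c["stat"]))) / (1 + n_perm)
        ch_idx, f_idx = np.divmod(c["members"], n_freq)
        clusters.append({
            "cells": np.column_stack([ch_idx, f_idx]),
            "stat": c["stat"], "p": float(p), "sign": c["sign"],
        })
        if p < cluster_alpha:
            mask[ch_idx, f_idx] = True
            sig_bins.update(f_idx.tolist())
    clusters.sort(key=lambda c: abs(c["stat"]), reverse=True)
    return ClusterResult(
        clusters=clusters, mask=mask,
        sig_bins=np.array(sorted(sig_bins), dtype=int),
        t_map=t_obs.reshape(n_ch, n_freq), t_crit=t_crit,
        freqs=np.asarray(freqs, dtype=float), n_perm=n_perm,
    )


def collapse_topography(cmap: ContrastMap, significant_bins: np.ndarray,
                        fallback_band: tuple[float, float] | None = None
                        ) -> EncodingTopography:
    """Mean contrast across the significant frequency bins, per channel.

    ``significant_bins`` holds bin indices into ``cmap.freqs``.  If empty, a
    fallback frequency band may be supplied (e.g. the 6-20 Hz group band);
    otherwise an error instructs the caller to do so.
    """
    bins = np.asarray(significant_bins, dtype=int)
    if bins.size == 0:
        if fallback_band is None:
            raise ValueError(
                "no significant frequency bins; pass fallback_band=(lo, hi) "
                "to collapse over a fixed band instead"
            )
        bins = np.flatnonzero((cmap.freqs >= fallback_band[0] - 1e-9)
                              & (cmap.freqs <= fallback_band[1] + 1e-9))
    values = cmap.delta_power[:, bins].mean(axis=1)
    return EncodingTopography(values, list(cmap.channel_labels),
                              cmap.participant_id)
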