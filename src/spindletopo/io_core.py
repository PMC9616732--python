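"""Shared data model and plain-format I/O for the sleep-EEG pipeline.

All pipeline computation assumes a fixed 200 Hz sampling rate (the rate the
analyses are defined at); recordings at other rates are rejected rather than
resampled.  Time is in seconds, 0-based, with half-open intervals
``[start, end)``.  Signals are stored in microvolts.

Hypnograms and artifact annotations are plain TSV files::

    hypnogram:  epoch_index<TAB>stage        (stage in W/N1/N2/N3/REM)
    artifacts:  start_s<TAB>end_s            (seconds, half-open)
    montage:    label<TAB>x<TAB>y            (2-D layout coordinates)
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The sampling rate every pipeline stage assumes, in Hz.
PIPELINE_FS = 200.0

#: Admissible sleep-stage labels.
STAGES = ("W", "N1", "N2", "N3", "REM")

#: Stages on which sleep events are detected.
NREM_STAGES = ("N2", "N3")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts; rows correspond 1:1 and in order to
        ``channel_labels``.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered 10-20 channel names.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class Montage:
    """Channel labels with 2-D layout coordinates (unitless layout space)."""

    channel_labels: list[str]
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.channel_labels = list(self.channel_labels)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.channel_labels), 2):
            raise ValueError("xy must be (n_channels, 2)")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("montage labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass
class Hypnogram:
    """Sleep stages, one label per fixed-length epoch."""

    stages: list[str]
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        self.stages = list(self.stages)
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            raise FormatError(f"unknown sleep stage label(s): {bad}")

    @property
    def duration(self) -> float:
        """Total time covered, in seconds."""
        return len(self.stages) * self.epoch_len

    def stage_mask(self, fs: float, n_samples: int,
                   stages: tuple[str, ...] = NREM_STAGES) -> np.ndarray:
        """Sample-wise boolean mask: True where the stage is in `stages`.

        Raises if the hypnogram covers less than the recording (the last
        epoch may be truncated by the recording end, not the reverse).
        """
        if self.duration < n_samples / fs - 1e-9:
            raise ValueError(
                f"hypnogram covers {self.duration:.1f} s but the recording "
                f"lasts {n_samples / fs:.1f} s"
            )
        stage_set = set(stages)
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_len * fs))  # samples per epoch
        for i, st in enumerate(self.stages):
            if st in stage_set:
                lo = i * spe
                if lo >= n_samples:
                    break
                mask[lo:min((i + 1) * spe, n_samples)] = True
        return mask


@dataclass
class ArtifactMask:
    """Half-open artifact intervals [start_s, end_s) in recording time.

    Overlapping or adjacent intervals are merged on construction (with a
    logged warning when an actual overlap was present).
    """

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: list[list[float]] = []
        had_overlap = False
        for s, e in sorted((float(s), float(e)) for s, e in self.intervals):
            if s < 0:
                raise ValueError("artifact interval with negative start")
            if e <= s:
                raise ValueError(f"empty/inverted artifact interval ({s}, {e})")
            if merged and s <= merged[-1][1]:
                had_overlap = had_overlap or s < merged[-1][1]
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if had_overlap:
            logger.warning("overlapping artifact intervals were merged")
        self.intervals = [(s, e) for s, e in merged]

    def sample_mask(self, fs: float, n_samples: int) -> np.ndarray:
        """Boolean vector, True on artifact samples."""
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.intervals:
            lo = int(np.ceil(s * fs - 1e-9))
            hi = int(np.ceil(e * fs - 1e-9))
            mask[max(lo, 0):min(hi, n_samples)] = True
        return mask

    def covers(self, start_s: float, end_s: float) -> bool:
        """True if [start_s, end_s) intersects any artifact interval."""
        return any(s < end_s and start_s < e for s, e in self.intervals)


# ---------------------------------------------------------------------------
# readers / writers


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF or the package's array+JSON-header format.

    `format` may be "edf" or "npz"; when None it is inferred from the
    suffix.  EDF physical units are converted to microvolts.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "npz"
    if format == "edf":
        from .edf import read_edf
        return read_edf(path)
    if format == "npz":
        header_path = path.with_suffix(".json")
        if not header_path.exists():
            raise FormatError(f"missing JSON header {header_path}")
        with open(header_path) as fh:
            header = json.load(fh)
        with np.load(path) as npz:
            signal = npz["signal"]
        if signal.shape[0] != len(header["channel_labels"]):
            raise FormatError(
                "channel count mismatch between JSON header and array"
            )
        return Recording(
            signal=signal,
            fs=float(header["fs"]),
            channel_labels=header["channel_labels"],
            start_time=float(header.get("start_time", 0.0)),
        )
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording as EDF or as .npz + sidecar .json header."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "npz"
    if format == "edf":
        from .edf import write_edf
        write_edf(rec, path)
    elif format == "npz":
        np.savez(path, signal=rec.signal)
        header = {
            "fs": rec.fs,
            "channel_labels": rec.channel_labels,
            "start_time": rec.start_time,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(header, fh)
    else:
        raise ValueError(f"unknown recording format {format!r}")


def read_hypnogram(path: str | Path, epoch_len: float = 30.0) -> Hypnogram:
    """Read a TSV hypnogram with columns (epoch_index, stage)."""
    df = pd.read_csv(path, sep="\t", dtype={"stage": str})
    for col in ("epoch_index", "stage"):
        if col not in df.columns:
            raise FormatError(f"hypnogram TSV lacks column {col!r}")
    df = df.sort_values("epoch_index")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise FormatError("epoch_index must be 0..n-1 without gaps")
    return Hypnogram(stages=df["stage"].tolist(), epoch_len=epoch_len)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp.stages)), "stage": hyp.stages}
    ).to_csv(path, sep="\t", index=False)


def read_artifacts(path: str | Path) -> ArtifactMask:
    """Read a TSV artifact table with columns (start_s, end_s)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"artifact TSV lacks column {col!r}")
    return ArtifactMask(list(zip(df["start_s"], df["end_s"])))


def write_artifacts(art: ArtifactMask, path: str | Path) -> None:
    pd.DataFrame(art.intervals, columns=["start_s", "end_s"]).to_csv(
        path, sep="\t", index=False
    )


def read_montage(path: str | Path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"montage TSV lacks column {col!r}")
    return Montage(df["label"].tolist(), df[["x", "y"]].to_numpy(float))


def write_montage(montage: Montage, path: str | Path) -> None:
    pd.DataFrame(
        {"label": montage.channel_labels,
         "x": montage.xy[:, 0], "y": montage.xy[:, 1]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def nrem_sample_mask(
    hypnogram: Hypnogram,
    artifacts: ArtifactMask,
    fs: float,
    n_samples: int,
) -> tuple[np.ndarray, float]:
    """Artifact-free NREM (N2/N3) sample mask and its duration in minutes.

    Returns ``(mask, minutes)`` where ``mask`` is True exactly on samples
    whose stage is N2 or N3 and which fall outside every artifact interval;
    ``minutes * 60 * fs`` equals the count of True samples exactly.
    """
    mask = hypnogram.stage_mask(fs, n_samples, NREM_STAGES)
    mask &= ~artifacts.sample_mask(fs, n_samples)
    minutes = mask.sum() / fs / 60.0
    return mask, minutes
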