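"""Minimal EDF (European Data Format) support.

Reading delegates to MNE's EDF reader; writing is implemented here directly
(16-bit samples, 1-second data records, one physical range per channel),
which is sufficient for uniform-rate scalp-EEG recordings in microvolts.
The writer and MNE's reader are independent code paths, so a round-trip
exercises both.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np

from .io_core import FormatError, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _num(value: float, width: int) -> bytes:
    for precision in range(10, 0, -1):
        s = f"{value:.{precision}g}"
        if len(s) <= width:
            return _fixed(s, width)
    raise ValueError(f"cannot format {value!r} in {width} chars")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as EDF with 1-s records and int16 samples.

    Requires an integer sampling rate. Recordings whose length is not a
    whole number of seconds are zero-padded to the next full record.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_sig = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    if n_rec * spr != rec.n_samples:
        warnings.warn("recording zero-padded to a whole number of EDF records")

    sig = rec.signal
    phys_min = np.minimum(sig.min(axis=1), -1.0)
    phys_max = np.maximum(sig.max(axis=1), 1.0)
    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    offset = phys_min - gain * _DIG_MIN

    padded = np.zeros((n_sig, n_rec * spr))
    padded[:, : rec.n_samples] = sig
    digital = np.round((padded - offset[:, None]) / gain[:, None])
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join([
        _fixed("0", 8),                      # version
        _fixed("X X X X", 80),               # patient id (anonymous)
        _fixed("Startdate X X X X", 80),     # recording id
        _fixed("01.01.00", 8),               # start date (placeholder)
        _fixed("00.00.00", 8),               # start time
        _num(256 * (1 + n_sig), 8),          # header length
        _fixed("", 44),
        _num(n_rec, 8),
        _num(1, 8),                          # record duration (s)
        _num(n_sig, 4),
    ])
    fields = [
        [_fixed(lbl, 16) for lbl in rec.channel_labels],
        [_fixed("AgAgCl electrode", 80)] * n_sig,
        [_fixed("uV", 8)] * n_sig,
        [_num(v, 8) for v in phys_min],
        [_num(v, 8) for v in phys_max],
        [_num(_DIG_MIN, 8)] * n_sig,
        [_num(_DIG_MAX, 8)] * n_sig,
        [_fixed("", 80)] * n_sig,
        [_num(spr, 8)] * n_sig,
        [_fixed("", 32)] * n_sig,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        # data records: per record, all samples of signal 0, then 1, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def _header_sample_rates(path: Path) -> list[float]:
    """Parse samples-per-record from the EDF header (format validation)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError("truncated EDF header")
        try:
            n_sig = int(head[252:256].decode("ascii").strip())
            dur = float(head[244:252].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"unparseable EDF header: {exc}") from exc
        sig_head = fh.read(256 * n_sig)
        if len(sig_head) < 256 * n_sig:
            raise FormatError("truncated EDF signal headers")
    labels = [
        sig_head[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(n_sig)
    ]
    off = n_sig * 216  # past label..prefiltering blocks
    spr = [
        int(sig_head[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_sig)
    ]
    return [
        s / dur for s, lbl in zip(spr, labels) if lbl != "EDF Annotations"
    ]


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts).

    Rejects files whose data channels do not share one sampling rate — the
    pipeline is defined at a single rate and does not resample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rates = _header_sample_rates(path)
    if len(set(rates)) > 1:
        raise FormatError(
            f"EDF channels have differing sampling rates {sorted(set(rates))}"
        )
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        signal=raw.get_data() * 1e6,  # MNE returns volts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )
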