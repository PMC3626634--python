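"""Minimal EDF writer for exporting synthetic recordings.

Writes plain EDF (16-bit) with one-second data records and per-channel
physical scaling, enough for any standard EDF reader to recover the signals
to within 16-bit quantization.  Reading EDF is done elsewhere through mne;
only writing is implemented here.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

__all__ = ["write_edf"]


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {value!r} > {width}")
    return b.ljust(width)


def _fit_range(m: float) -> float:
    """Round ``m`` up to 2 significant digits so '±x.yE±zz' fits 8 chars."""
    import math

    e = math.floor(math.log10(m))
    mant = math.ceil(m / 10 ** e * 10) / 10
    if mant >= 10:
        mant, e = 1.0, e + 1
    v = float(f"{mant * 10 ** e:.1E}")
    if v < m:  # decimal-to-binary round-down guard
        v = float(f"{(mant + 0.1) * 10 ** e:.1E}")
    return v


def write_edf(path: str | Path, data: np.ndarray, sfreq: float,
              ch_names: list[str], *, physical_dim: str = "uV",
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write ``data`` (channels x samples) to ``path`` as 16-bit EDF.

    The sampling rate must be a positive integer (samples per one-second
    record).  A trailing partial second is zero-padded.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise ValueError("ch_names length does not match data")
    spr = int(round(sfreq))
    if spr <= 0 or abs(spr - sfreq) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")

    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    # symmetric physical range per channel; avoid a zero span; round the
    # range up to a value that fits the 8-char header field exactly
    phys_max = np.array([_fit_range(m) for m in
                         np.maximum(np.abs(padded).max(axis=1), 1e-6)])
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.rint(padded * scale[:, None]), dig_min, dig_max)
    digital = digital.astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),          # record duration, seconds
        _field(str(n_ch), 4),
    ])
    sig_header = b"".join([
        b"".join(_field(n, 16) for n in ch_names),
        b"".join(_field("synthetic", 80) for _ in ch_names),
        b"".join(_field(physical_dim, 8) for _ in ch_names),
        b"".join(_field(f"{-m:.1E}", 8) for m in phys_max),
        b"".join(_field(f"{m:.1E}", 8) for m in phys_max),
        b"".join(_field(str(dig_min), 8) for _ in ch_names),
        b"".join(_field(str(dig_max), 8) for _ in ch_names),
        b"".join(_field("", 80) for _ in ch_names),
        b"".join(_field(str(spr), 8) for _ in ch_names),
        b"".join(_field("", 32) for _ in ch_names),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
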