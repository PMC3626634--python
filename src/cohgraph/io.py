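"""Reading, montage mapping, re-referencing, filtering and segmentation.

The preprocessing chain is fixed and deterministic:

    load -> resample -> notch -> band-pass -> average reference -> segment

Filtering is zero-phase: a linear-phase windowed-sinc (Hamming) band-pass
applied forward-backward, plus an IIR notch (also forward-backward) at the
mains frequency.  Filter design is fully determined by the config, so
repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .montage import ElectrodeMontage, build_standard_montage
from .synthetic import SegmentedRecording

__all__ = [
    "Record",
    "PreprocessConfig",
    "SubjectRejected",
    "load_recording",
    "average_reference",
    "filter_record",
    "assemble_segments",
    "preprocess",
    "read_segment_table",
]


class SubjectRejected(RuntimeError):
    """A subject failed a data-sufficiency rule; carries a reason code."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass
class Record:
    """A continuous multichannel recording (channels x samples)."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering/segmentation settings.

    ``bandpass`` 1–70 Hz and a 60 Hz notch are the clinical defaults; the
    notch is configurable to 50 Hz for other mains systems.  Recordings of
    mixed native rates are harmonized by resampling to ``resample_to``
    before filtering.
    """

    bandpass: tuple[float, float] = (1.0, 70.0)
    notch: float = 60.0
    min_total_duration: float = 120.0
    resample_to: float | None = 250.0
    amplitude_veto: float | None = None  # optional per-segment peak limit, µV

    def __post_init__(self):
        if not 0 < self.bandpass[0] < self.bandpass[1]:
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if self.min_total_duration <= 0:
            raise ValueError("min_total_duration must be positive")


def load_recording(path: str | Path, montage: ElectrodeMontage | None = None,
                   *, channel_map: dict[str, str] | None = None) -> Record:
    """Read an EDF file and map its channels onto the montage order.

    ``channel_map`` optionally maps raw channel labels to montage names
    (for spatially down-sampling high-density nets).  Extra channels are
    dropped; any missing montage channel is a hard error listing the gaps.
    Signal values are returned in microvolts.
    """
    import mne

    montage = montage or build_standard_montage()
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = {}
    for ch in raw.ch_names:
        name = channel_map.get(ch, ch) if channel_map else ch
        try:
            resolved = montage.resolve(name)
        except KeyError:
            continue
        labels.setdefault(resolved, ch)
    missing = [n for n in montage.names if n not in labels]
    if missing:
        raise ValueError(f"recording is missing montage channels: {missing}")
    data = raw.get_data(picks=[labels[n] for n in montage.names], units="uV")
    return Record(np.asarray(data, dtype=float), float(raw.info["sfreq"]),
                  list(montage.names))


def average_reference(record: Record) -> Record:
    """Subtract the instantaneous cross-channel mean from every sample."""
    data = record.data - record.data.mean(axis=0, keepdims=True)
    return Record(data, record.sampling_rate, list(record.channel_names))


def _bandpass_taps(low: float, high: float, fs: float) -> np.ndarray:
    # Hamming windowed-sinc; transition width 25% of the lower band edge
    trans = 0.25 * low
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1
    return signal.firwin(numtaps, [low, high], pass_zero=False,
                         window="hamming", fs=fs)


def filter_record(record: Record, config: PreprocessConfig) -> Record:
    """Zero-phase notch + band-pass."""
    fs = record.sampling_rate
    nyq = fs / 2.0
    if config.bandpass[1] >= nyq:
        raise ValueError(
            f"band edge {config.bandpass[1]} Hz >= Nyquist {nyq} Hz")
    data = record.data
    if config.notch and config.notch < nyq:
        b, a = signal.iirnotch(config.notch, Q=30.0, fs=fs)
        data = signal.filtfilt(b, a, data, axis=1)
    taps = _bandpass_taps(*config.bandpass, fs)
    if len(taps) >= data.shape[1]:
        raise ValueError("recording too short for the band-pass filter")
    padlen = min(3 * len(taps), data.shape[1] - 1)
    data = signal.filtfilt(taps, 1.0, data, axis=1, padlen=padlen)
    return Record(data, fs, list(record.channel_names))


def resample_record(record: Record, target: float) -> Record:
    if abs(record.sampling_rate - target) < 1e-9:
        return record
    from fractions import Fraction

    frac = Fraction(target / record.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(record.data, frac.numerator,
                                frac.denominator, axis=1)
    return Record(data, target, list(record.channel_names))


def read_segment_table(path: str | Path) -> list[tuple[float, float]]:
    """Read a CSV of segment boundaries (columns start_s, end_s)."""
    df = pd.read_csv(path)
    return [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]


def assemble_segments(record: Record,
                      boundaries: list[tuple[float, float]],
                      config: PreprocessConfig, *,
                      min_segment_duration: float = 2.0,
                      subject_id: str = "subject") -> SegmentedRecording:
    """Cut the record into artifact-free segments and apply retention rules.

    Segments shorter than one spectral-analysis window
    (``min_segment_duration``) are dropped; if the retained total falls
    below ``config.min_total_duration`` the subject is rejected.
    """
    fs = record.sampling_rate
    segs = []
    prev_end = -np.inf
    for start, end in sorted(boundaries):
        if start < 0 or end * fs > record.n_samples + 0.5 or end <= start:
            raise ValueError(f"segment ({start}, {end}) outside the record")
        if start < prev_end:
            raise ValueError("segment boundaries overlap")
        prev_end = end
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if (i1 - i0) / fs < min_segment_duration:
            continue  # below one analysis window
        seg = record.data[:, i0:i1]
        if (config.amplitude_veto is not None
                and np.abs(seg).max() > config.amplitude_veto):
            continue
        segs.append(seg)
    total = sum(s.shape[1] for s in segs) / fs
    if not segs or total < config.min_total_duration:
        raise SubjectRejected(
            "insufficient_data",
            f"{subject_id}: retained {total:.1f} s "
            f"< required {config.min_total_duration:.1f} s")
    return SegmentedRecording(subject_id, fs, segs,
                              channel_names=list(record.channel_names))


def preprocess(record: Record, config: PreprocessConfig,
               boundaries: list[tuple[float, float]] | None = None, *,
               subject_id: str = "subject",
               min_segment_duration: float = 2.0) -> SegmentedRecording:
    """Run the fixed chain: resample -> filter -> reference -> segment."""
    if config.resample_to is not None:
        record = resample_record(record, config.resample_to)
    record = filter_record(record, config)
    record = average_reference(record)
    if boundaries is None:
        boundaries = [(0.0, record.duration)]
    return assemble_segments(record, boundaries, config,
                             subject_id=subject_id,
                             min_segment_duration=min_segment_duration)
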