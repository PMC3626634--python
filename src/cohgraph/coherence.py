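"""Segment-weighted magnitude-squared coherence and connectivity summaries.

Coherence of a stationary pair (x, y) at frequency f is

    MSC(f) = |P_xy(f)|^2 / (P_xx(f) P_yy(f))  in [0, 1],

estimated per segment by Welch's method (2-s Hann windows, 50% overlap by
default; only whole windows inside a segment are used — segments are never
concatenated, since stitching across recording gaps injects artifactual
high-frequency power).  The per-subject band value of a pair is the
segment-length-weighted average of per-segment coherences, averaged over
the in-band frequency bins:

    C = mean_{f in band} [ Σ_i L_i MSC_i(f) / Σ_i L_i ]

so longer artifact-free segments dominate and short fragments contribute
negligibly.  Three conventional summaries condense the 19x19 matrix: the
mean over all 171 pairs, the ratio of homologous inter-hemispheric over
intra-hemispheric (non-midline) means, and the ratio of long-range over
short-range means with neighboring pairs excluded (volume conduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import ElectrodeMontage
from .synthetic import SegmentedRecording

__all__ = [
    "FrequencyBand",
    "WelchConfig",
    "CoherenceSpectrum",
    "BandCoherenceMatrix",
    "ConnectivitySummary",
    "DEFAULT_BANDS",
    "segment_coherence",
    "weighted_coherence_spectrum",
    "weighted_band_coherence",
    "band_coherence_matrices",
    "mean_coherence",
    "inter_intra_ratio",
    "long_short_ratio",
    "summarize",
]


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("band requires low < high")

    def mask(self, frequencies: np.ndarray) -> np.ndarray:
        """In-band bin selector; half-open [low, high) so adjacent bands
        never share a bin."""
        return (frequencies >= self.low) & (frequencies < self.high)


DEFAULT_BANDS = (
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("lower_alpha", 8.0, 10.0),
    FrequencyBand("upper_alpha", 10.0, 12.0),
)


@dataclass(frozen=True)
class WelchConfig:
    window_seconds: float = 2.0
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "constant"

    def nperseg(self, sampling_rate: float) -> int:
        return int(round(self.window_seconds * sampling_rate))

    def noverlap(self, sampling_rate: float) -> int:
        return int(round(self.nperseg(sampling_rate) * self.overlap))


@dataclass
class CoherenceSpectrum:
    """All-pairs MSC on the Welch frequency grid (n_ch x n_ch x n_freq)."""

    frequencies: np.ndarray
    msc: np.ndarray


@dataclass
class BandCoherenceMatrix:
    """Band-summarized, segment-weighted coherence matrix."""

    band: FrequencyBand
    values: np.ndarray      # n_ch x n_ch, symmetric, diag 1
    total_weight: float     # Σ L_i, seconds

    def __post_init__(self):
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("coherence matrix must be symmetric")
        if np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9:
            raise ValueError("coherence values must lie in [0, 1]")
        if self.total_weight <= 0:
            raise ValueError("total segment weight must be positive")


@dataclass(frozen=True)
class ConnectivitySummary:
    band: str
    mean_coherence: float
    inter_intra_ratio: float
    long_short_ratio: float


def _welch_cross_spectra(x: np.ndarray, fs: float, welch: WelchConfig
                         ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Welch cross-spectral matrix (one FFT per channel).

    Only whole windows inside the segment are used (no padding).  The
    spectral scaling constant is omitted — it cancels in the coherence
    quotient.  Agrees with ``scipy.signal.csd`` on any pair (tested).
    """
    nperseg = welch.nperseg(fs)
    step = nperseg - welch.noverlap(fs)
    win = signal.get_window(welch.window, nperseg)
    frames = np.lib.stride_tricks.sliding_window_view(
        x, nperseg, axis=-1)[:, ::step, :]  # (ch, nwin, nperseg)
    if welch.detrend == "constant":
        frames = frames - frames.mean(axis=-1, keepdims=True)
    elif welch.detrend:
        frames = signal.detrend(frames, axis=-1, type=welch.detrend)
    z = np.fft.rfft(frames * win, axis=-1)
    pxy = np.einsum("iwf,jwf->ijf", z, np.conj(z)) / frames.shape[1]
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, pxy


def segment_coherence(segment: np.ndarray, sampling_rate: float,
                      welch: WelchConfig = WelchConfig()) -> CoherenceSpectrum:
    """Welch MSC of every channel pair within one stationary segment."""
    nperseg = welch.nperseg(sampling_rate)
    if segment.shape[1] < nperseg:
        raise ValueError(
            f"segment of {segment.shape[1]} samples is shorter than one "
            f"Welch window ({nperseg} samples)")
    x = np.asarray(segment, dtype=float)
    freqs, pxy = _welch_cross_spectra(x, sampling_rate, welch)
    auto = np.einsum("iif->if", pxy).real
    denom = auto[:, np.newaxis, :] * auto[np.newaxis, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(pxy) ** 2 / denom
    msc = np.clip(np.nan_to_num(msc, nan=0.0), 0.0, 1.0)
    return CoherenceSpectrum(freqs, msc)


def weighted_coherence_spectrum(recording: SegmentedRecording,
                                welch: WelchConfig = WelchConfig(),
                                ) -> tuple[CoherenceSpectrum, float]:
    """Length-weighted average of per-segment MSC spectra.

    Segments shorter than one Welch window are skipped; at least one must
    remain.  Returns the weighted spectrum and the total weight (seconds).
    """
    fs = recording.sampling_rate
    nperseg = welch.nperseg(fs)
    acc = None
    total = 0.0
    freqs = None
    for seg in recording.segments:
        if seg.shape[1] < nperseg:
            continue
        spec = segment_coherence(seg, fs, welch)
        w = seg.shape[1] / fs
        if acc is None:
            acc = w * spec.msc
            freqs = spec.frequencies
        else:
            acc += w * spec.msc
        total += w
    if acc is None:
        raise ValueError("no segment is long enough for one Welch window")
    return CoherenceSpectrum(freqs, acc / total), total


def _band_matrix(spectrum: CoherenceSpectrum, band: FrequencyBand,
                 total_weight: float) -> BandCoherenceMatrix:
    mask = band.mask(spectrum.frequencies)
    if not mask.any():
        raise ValueError(
            f"band {band.name} contains no frequency bins at this resolution")
    values = spectrum.msc[:, :, mask].mean(axis=2)
    values = 0.5 * (values + values.T)  # exact symmetry
    np.fill_diagonal(values, 1.0)
    return BandCoherenceMatrix(band, values, total_weight)


def weighted_band_coherence(recording: SegmentedRecording,
                            band: FrequencyBand,
                            welch: WelchConfig = WelchConfig(),
                            ) -> BandCoherenceMatrix:
    """Segment-weighted band coherence matrix for one band."""
    spectrum, total = weighted_coherence_spectrum(recording, welch)
    return _band_matrix(spectrum, band, total)


def band_coherence_matrices(recording: SegmentedRecording,
                            bands=DEFAULT_BANDS,
                            welch: WelchConfig = WelchConfig(),
                            ) -> dict[str, BandCoherenceMatrix]:
    """All bands from a single pass over the segments."""
    spectrum, total = weighted_coherence_spectrum(recording, welch)
    return {b.name: _band_matrix(spectrum, b, total) for b in bands}


def _pair_mean(values: np.ndarray, pairs: list[tuple[int, int]]) -> float:
    return float(np.mean([values[i, j] for i, j in pairs]))


def mean_coherence(m: BandCoherenceMatrix) -> float:
    """Mean over all off-diagonal unordered pairs."""
    iu = np.triu_indices_from(m.values, k=1)
    return float(m.values[iu].mean())


def inter_intra_ratio(m: BandCoherenceMatrix,
                      montage: ElectrodeMontage) -> float:
    """Homologous inter-hemispheric mean over intra-hemispheric
    (non-midline) mean.  NaN when the denominator is zero."""
    inter = _pair_mean(m.values, montage.pair_indices(homologous=True))
    intra = _pair_mean(m.values, montage.pair_indices(intra_nonmidline=True))
    if intra == 0:
        return float("nan")
    return inter / intra


def long_short_ratio(m: BandCoherenceMatrix,
                     montage: ElectrodeMontage) -> float:
    """Long-range mean over short-range mean; neighbors excluded from both.
    NaN when the denominator is zero."""
    long_ = _pair_mean(m.values, montage.pair_indices(dist_class="long"))
    short = _pair_mean(m.values, montage.pair_indices(dist_class="short"))
    if short == 0:
        return float("nan")
    return long_ / short


def summarize(m: BandCoherenceMatrix,
              montage: ElectrodeMontage) -> ConnectivitySummary:
    return ConnectivitySummary(
        band=m.band.name,
        mean_coherence=mean_coherence(m),
        inter_intra_ratio=inter_intra_ratio(m, montage),
        long_short_ratio=long_short_ratio(m, montage),
    )
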