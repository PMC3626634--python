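"""Coherence estimator identities, segment weighting, summary ratios."""

import numpy as np
import pytest

import cohgraph.coherence as coh
from cohgraph.coherence import (BandCoherenceMatrix, FrequencyBand,
                                WelchConfig, band_coherence_matrices,
                                inter_intra_ratio, long_short_ratio,
                                mean_coherence, segment_coherence,
                                weighted_band_coherence,
                                weighted_coherence_spectrum)
from cohgraph.synthetic import SegmentedRecording

FS = 250.0
NOOVERLAP = WelchConfig(window_seconds=2.0, overlap=0.0)


def _phase_coded_segment(duration_s, msc_target, f0=10.0, n_ch=3):
    """Deterministic segment whose MSC at f0 is exactly ``msc_target``.

    Channel 1 repeats a sinusoid; channel 2 alternates its phase between
    +theta and -theta across whole (non-overlapping) Welch windows, giving
    |mean e^{i phi}|^2 = cos^2(theta) = msc_target exactly.
    """
    nwin = int(duration_s / 2)
    assert nwin % 2 == 0
    theta = np.arccos(np.sqrt(msc_target))
    t = np.arange(int(2 * FS)) / FS
    x1 = np.tile(np.sin(2 * np.pi * f0 * t), nwin)
    x2 = np.concatenate([
        np.sin(2 * np.pi * f0 * t + (theta if w % 2 == 0 else -theta))
        for w in range(nwin)])
    data = np.zeros((n_ch, x1.size))
    data[0], data[1] = x1, x2
    rng = np.random.default_rng(0)
    data[2:] = 1e-6 * rng.standard_normal((n_ch - 2, x1.size))
    return data


def test_self_pair_coherence_is_one_everywhere():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 2000))
    spec = segment_coherence(x, FS)
    active = spec.msc[0, 0, :][spec.frequencies > 0.5]
    np.testing.assert_allclose(active, 1.0, atol=1e-9)


def test_negated_channel_is_fully_coherent():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 2000))
    x[1] = -x[0]
    spec = segment_coherence(x, FS)
    np.testing.assert_allclose(spec.msc[0, 1, :], 1.0, atol=1e-9)


def test_segment_shorter_than_window_is_rejected():
    with pytest.raises(ValueError, match="Welch window"):
        segment_coherence(np.zeros((2, 100)), FS)


def test_weighted_average_follows_printed_formula_exactly():
    """Lengths 100 s and 300 s with band coherences 0.2 and 0.6 -> 0.5;
    equal lengths -> 0.4."""
    band = FrequencyBand("bin10", 10.0, 10.5)  # exactly one 0.5 Hz bin
    seg_a = _phase_coded_segment(100, 0.2)
    seg_b = _phase_coded_segment(300, 0.6)
    rec = SegmentedRecording("w", FS, [seg_a, seg_b])
    m = weighted_band_coherence(rec, band, NOOVERLAP)
    assert m.values[0, 1] == pytest.approx(0.5, abs=1e-12)
    assert m.total_weight == pytest.approx(400.0)

    rec_eq = SegmentedRecording("w2", FS, [_phase_coded_segment(100, 0.2),
                                           _phase_coded_segment(100, 0.6)])
    m_eq = weighted_band_coherence(rec_eq, band, NOOVERLAP)
    assert m_eq.values[0, 1] == pytest.approx(0.4, abs=1e-12)


def test_single_segment_collapses_to_segment_coherence():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((4, 4000))
    x[1] += 0.5 * x[0]
    rec = SegmentedRecording("s", FS, [x])
    band = FrequencyBand("theta", 4.0, 8.0)
    m = weighted_band_coherence(rec, band)
    spec = segment_coherence(x, FS)
    expected = spec.msc[:, :, band.mask(spec.frequencies)].mean(axis=2)
    np.testing.assert_allclose(m.values[0, 1], expected[0, 1], atol=1e-12)


def test_duplicated_segment_leaves_band_matrix_unchanged():
    """Equal-weight copies of the same data cancel out of the weighted
    average exactly; a window-aligned half/half split only agrees up to
    the estimator's nonlinearity in the window count."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal((3, int(FS * 40)))
    x[1] += 0.6 * x[0]
    band = FrequencyBand("theta", 4.0, 8.0)
    m1 = weighted_band_coherence(SegmentedRecording("a", FS, [x]), band,
                                 NOOVERLAP)
    m2 = weighted_band_coherence(SegmentedRecording("b", FS, [x, x]), band,
                                 NOOVERLAP)
    np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)

    halves = SegmentedRecording("c", FS, [x[:, :x.shape[1] // 2],
                                          x[:, x.shape[1] // 2:]])
    m3 = weighted_band_coherence(halves, band, NOOVERLAP)
    np.testing.assert_allclose(m3.values, m1.values, atol=0.1)


def test_segment_order_does_not_matter():
    rng = np.random.default_rng(4)
    segs = [rng.standard_normal((3, n)) for n in (1000, 1500, 2000)]
    band = FrequencyBand("theta", 4.0, 8.0)
    m1 = weighted_band_coherence(SegmentedRecording("a", FS, segs), band)
    m2 = weighted_band_coherence(
        SegmentedRecording("b", FS, segs[::-1]), band)
    np.testing.assert_array_equal(m1.values, m2.values)


def test_band_value_stays_within_per_segment_range():
    rng = np.random.default_rng(5)
    segs = [rng.standard_normal((3, n)) for n in (1200, 2400)]
    segs[0][1] += 0.8 * segs[0][0]
    band = FrequencyBand("theta", 4.0, 8.0)
    per_seg = []
    for s in segs:
        sp = segment_coherence(s, FS)
        per_seg.append(sp.msc[0, 1, band.mask(sp.frequencies)].mean())
    rec = SegmentedRecording("r", FS, segs)
    m = weighted_band_coherence(rec, band)
    assert min(per_seg) - 1e-12 <= m.values[0, 1] <= max(per_seg) + 1e-12


def test_too_short_segments_are_skipped_but_not_all():
    rng = np.random.default_rng(6)
    long_seg = rng.standard_normal((3, 2000))
    short_seg = rng.standard_normal((3, 100))
    rec = SegmentedRecording("r", FS, [short_seg, long_seg])
    spec, total = weighted_coherence_spectrum(rec)
    assert total == pytest.approx(2000 / FS)
    with pytest.raises(ValueError, match="no segment"):
        weighted_coherence_spectrum(SegmentedRecording("r", FS, [short_seg]))


def _matrix_from_pairs(montage, default, overrides):
    v = np.full((19, 19), default)
    for (i, j), val in overrides.items():
        v[i, j] = v[j, i] = val
    np.fill_diagonal(v, 1.0)
    return BandCoherenceMatrix(FrequencyBand("b", 4.0, 8.0), v, 100.0)


def test_mean_coherence_identities(montage):
    m = _matrix_from_pairs(montage, 0.5, {})
    assert mean_coherence(m) == pytest.approx(0.5)
    z = _matrix_from_pairs(montage, 0.0, {})
    assert mean_coherence(z) == 0.0
    rng = np.random.default_rng(7)
    rand = rng.uniform(0, 1, (19, 19))
    rand = (rand + rand.T) / 2
    np.fill_diagonal(rand, 1.0)
    m = BandCoherenceMatrix(FrequencyBand("b", 4, 8), rand, 1.0)
    brute = sum(rand[i, j] for i in range(19) for j in range(i + 1, 19)) / 171
    assert mean_coherence(m) == pytest.approx(brute, abs=1e-12)


def test_inter_intra_ratio_identities(montage):
    uniform = _matrix_from_pairs(montage, 0.3, {})
    assert inter_intra_ratio(uniform, montage) == pytest.approx(1.0)

    overrides = {p: 0.4 for p in montage.pair_indices(homologous=True)}
    overrides.update({p: 0.2 for p in
                      montage.pair_indices(intra_nonmidline=True)})
    m = _matrix_from_pairs(montage, 0.7, overrides)
    assert inter_intra_ratio(m, montage) == pytest.approx(2.0)


def test_long_short_ratio_identities(montage):
    uniform = _matrix_from_pairs(montage, 0.3, {})
    assert long_short_ratio(uniform, montage) == pytest.approx(1.0)

    overrides = {p: 0.1 for p in montage.pair_indices(dist_class="long")}
    overrides.update({p: 0.4 for p in
                      montage.pair_indices(dist_class="short")})
    m = _matrix_from_pairs(montage, 0.9, overrides)
    assert long_short_ratio(m, montage) == pytest.approx(0.25)


def test_zero_denominator_ratio_is_flagged_not_clipped(montage):
    overrides = {p: 0.0 for p in montage.pair_indices(dist_class="short")}
    overrides.update({p: 0.0 for p in
                      montage.pair_indices(intra_nonmidline=True)})
    m = _matrix_from_pairs(montage, 0.2, overrides)
    assert np.isnan(long_short_ratio(m, montage))
    assert np.isnan(inter_intra_ratio(m, montage))


def test_default_bands_match_clinical_definitions():
    names = {(b.name, b.low, b.high) for b in coh.DEFAULT_BANDS}
    assert names == {("theta", 4.0, 8.0), ("lower_alpha", 8.0, 10.0),
                     ("upper_alpha", 10.0, 12.0)}


def test_all_bands_single_pass_matches_per_band(montage):
    rng = np.random.default_rng(8)
    rec = SegmentedRecording("r", FS, [rng.standard_normal((19, 2500))])
    mats = band_coherence_matrices(rec)
    for band in coh.DEFAULT_BANDS:
        single = weighted_band_coherence(rec, band)
        np.testing.assert_array_equal(mats[band.name].values, single.values)
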