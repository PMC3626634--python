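"""Generator contracts: determinism, group structure, coherence control."""

import numpy as np
import pytest

from cohgraph.coherence import (FrequencyBand, WelchConfig,
                                band_coherence_matrices, inter_intra_ratio,
                                mean_coherence, segment_coherence)
from cohgraph.synthetic import (SyntheticCohortSpec, expected_mean_msc,
                                expected_pair_msc, generate_acc_cohort,
                                generate_cohort, generate_subject,
                                mixing_gains)

IN_BAND = FrequencyBand("inband", 5.0, 11.0)


def test_cohort_bookkeeping_and_flags(small_spec):
    recs, meta = generate_cohort(small_spec)
    assert len(recs) == 8
    assert meta.groupby(["ASD", "TSC"]).size().to_dict() == {
        (0, 0): 2, (0, 1): 2, (1, 0): 2, (1, 1): 2}
    assert (meta["age"] >= small_spec.age_range[0]).all()
    assert (meta["age"] <= small_spec.age_range[1]).all()


def test_same_seed_gives_bit_identical_cohorts(small_spec):
    recs1, meta1 = generate_cohort(small_spec)
    recs2, meta2 = generate_cohort(small_spec)
    assert meta1.equals(meta2)
    for r1, r2 in zip(recs1, recs2):
        assert len(r1.segments) == len(r2.segments)
        for s1, s2 in zip(r1.segments, r2.segments):
            np.testing.assert_array_equal(s1, s2)


def test_single_global_source_no_noise_gives_unit_coherence(montage):
    spec = SyntheticCohortSpec(
        n_per_subgroup=(1, 1, 1, 1), noise_sd=0.0, hemi_coupling=0.0,
        local_coupling=0.0, neighbor_gain=0.0, hub_gain=0.0,
        segment_length_range=(20.0, 20.0), n_segments_range=(1, 1))
    rec = generate_subject(spec, 0, 0, 5.0, np.random.default_rng(0),
                           montage=montage)
    spec_c = segment_coherence(rec.segments[0], spec.sampling_rate)
    mask = IN_BAND.mask(spec_c.frequencies)
    iu = np.triu_indices(19, k=1)
    inband = spec_c.msc[:, :, mask]
    assert inband[iu[0], iu[1], :].min() > 0.999


def test_pure_noise_coherence_shrinks_with_recording_length(montage):
    def mean_msc(duration):
        spec = SyntheticCohortSpec(
            n_per_subgroup=(1, 1, 1, 1), global_coupling=0.0,
            hemi_coupling=0.0, local_coupling=0.0, hub_gain=0.0,
            segment_length_range=(duration, duration),
            n_segments_range=(1, 1))
        rec = generate_subject(spec, 0, 0, 5.0, np.random.default_rng(7),
                               montage=montage)
        m = band_coherence_matrices(rec, bands=[IN_BAND])["inband"]
        return mean_coherence(m)

    short, long_ = mean_msc(20.0), mean_msc(160.0)
    # estimator bias floor ~ 1/n_windows
    assert long_ < short
    assert long_ < 0.05


def test_shared_source_msc_matches_analytic_oracle(montage, small_spec):
    gains = mixing_gains(small_spec, montage, 0, 0, 8.0)
    spec_long = SyntheticCohortSpec(
        **{**small_spec.__dict__, "segment_length_range": (120.0, 120.0),
           "n_segments_range": (1, 1)})
    rec = generate_subject(spec_long, 0, 0, 8.0, np.random.default_rng(3),
                           montage=montage)
    m = band_coherence_matrices(rec, bands=[IN_BAND])["inband"]
    for a, b in [("F3", "P4"), ("Fp1", "Fp2"), ("O1", "O2")]:
        i, j = montage.index(a), montage.index(b)
        expected = expected_pair_msc(gains, i, j, spec_long)
        # Welch bias inflates the estimate by roughly 1/n_windows
        assert m.values[i, j] == pytest.approx(expected, abs=0.06)


def test_tsc_reduces_expected_mean_coherence(montage):
    spec = SyntheticCohortSpec()
    ctrl = expected_mean_msc(mixing_gains(spec, montage, 0, 0, 8.0), spec)
    tsc = expected_mean_msc(mixing_gains(spec, montage, 0, 1, 8.0), spec)
    assert tsc < ctrl


def test_asd_preserves_mean_but_lowers_long_short_balance(montage):
    spec = SyntheticCohortSpec()
    g0 = mixing_gains(spec, montage, 0, 0, 8.0)
    g1 = mixing_gains(spec, montage, 1, 0, 8.0)
    assert expected_mean_msc(g1, spec) == pytest.approx(
        expected_mean_msc(g0, spec), rel=1e-6)

    def ls(g):
        long_p = montage.pair_indices(dist_class="long")
        short_p = montage.pair_indices(dist_class="short")
        lm = np.mean([expected_pair_msc(g, i, j, spec) for i, j in long_p])
        sm = np.mean([expected_pair_msc(g, i, j, spec) for i, j in short_p])
        return lm / sm

    assert ls(g1) < 0.8 * ls(g0)


def test_expected_coherence_monotone_in_global_coupling(montage):
    base = dict(hub_gain=0.0)
    prev = -1.0
    for g in (0.2, 0.5, 0.8, 1.1):
        spec = SyntheticCohortSpec(global_coupling=g, **base)
        gains = mixing_gains(spec, montage, 0, 0, 8.0)
        cur = expected_pair_msc(gains, montage.index("F3"),
                                montage.index("P4"), spec)
        assert cur > prev
        prev = cur


def test_expected_mean_coherence_increases_with_age(montage):
    spec = SyntheticCohortSpec(beta_age=0.02)
    vals = [expected_mean_msc(mixing_gains(spec, montage, 0, 0, a), spec)
            for a in (2.0, 8.0, 16.0)]
    assert vals[0] < vals[1] < vals[2]


def test_acc_subjects_lose_interhemispheric_coupling_only(montage):
    spec = SyntheticCohortSpec()
    acc = mixing_gains(spec, montage, 0, 0, 8.0, acc=True)
    ctrl = mixing_gains(spec, montage, 0, 0, 8.0)
    cross = acc.cross_power()
    for i, j in montage.pair_indices(homologous=True):
        assert cross[i, j] == 0.0
    # intra-hemispheric shared power approximately preserved (pairs that
    # shared a midline local source lose that one contribution)
    for i, j in montage.pair_indices(intra_nonmidline=True):
        assert cross[i, j] == pytest.approx(ctrl.cross_power()[i, j],
                                            rel=0.25)


def test_acc_cohort_ratio_separates_groups(montage, small_spec):
    recs, meta = generate_acc_cohort(small_spec, n_acc=3, n_control=3)
    ratios = {}
    for rec, row in zip(recs, meta.itertuples()):
        m = band_coherence_matrices(rec, bands=[IN_BAND])["inband"]
        ratios[row.subject_id] = inter_intra_ratio(m, montage)
    acc = [v for k, v in ratios.items() if k.startswith("A")]
    ctl = [v for k, v in ratios.items() if k.startswith("C")]
    assert max(acc) < min(ctl)


def test_invalid_gain_configuration_raises():
    with pytest.raises(ValueError):
        SyntheticCohortSpec(global_coupling=-0.1)
    with pytest.raises(ValueError):
        SyntheticCohortSpec(hub_flattening_asd=1.5)
    with pytest.raises(ValueError):
        SyntheticCohortSpec(source_band=(3.0, 200.0))
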