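"""Simulator: FID synthesis, chunk NUS, noise, spectra, training pairs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pureshift import simkit
from pureshift.simkit import (
    AcquisitionParams,
    ConfigurationError,
    Fid,
    NUSSchedule,
    PeakParams,
    PeakSet,
    SimConfig,
    add_noise,
    apply_nus,
    fid_to_spectrum,
    generate_dataset,
    make_nus_schedule,
    make_training_pair,
    sample_peak_set,
    synthesize_fid,
)


class TestTypes:
    def test_peak_invariants(self):
        with pytest.raises(ValueError):
            PeakParams(freq_hz=0.0, amplitude=0.0)
        with pytest.raises(ValueError):
            PeakParams(freq_hz=0.0, amplitude=1.0, lw_hz=-1.0)

    def test_empty_peak_set_rejected(self):
        with pytest.raises(ValueError):
            PeakSet(())

    def test_acquisition_geometry_must_fit_ft_length(self):
        with pytest.raises(ValueError):
            AcquisitionParams(chunk_len=64, n_chunks=93, n_ft=4096)

    def test_schedule_must_be_strictly_increasing_and_in_range(self):
        with pytest.raises(ValueError):
            NUSSchedule(sampled=(3, 3), n_chunks=8)
        with pytest.raises(ValueError):
            NUSSchedule(sampled=(0, 8), n_chunks=8)

    def test_invalid_sim_ranges_raise_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_peaks_range=(5, 2))
        with pytest.raises(ConfigurationError):
            SimConfig(amp_range=(0.0, 1.0))


class TestSamplePeakSet:
    def test_degenerate_ranges_give_single_unit_peak(self, rng, tiny_acq):
        cfg = SimConfig(acq=tiny_acq, n_peaks_range=(1, 1),
                        amp_range=(1.0, 1.0), lw_range_hz=(2.0, 2.0))
        ps = sample_peak_set(rng, cfg)
        assert len(ps) == 1
        assert ps.peaks[0].amplitude == 1.0

    def test_dynamic_range_capped_at_fifty(self, tiny_acq):
        cfg = SimConfig(acq=tiny_acq, amp_range=(0.02, 1.0),
                        n_peaks_range=(2, 5), lw_range_hz=(1.0, 8.0))
        for seed in range(200):
            ps = sample_peak_set(np.random.default_rng(seed), cfg)
            assert ps.dynamic_range <= 50.0 + 1e-12

    def test_same_seed_reproduces_peak_set(self, tiny_sim):
        a = sample_peak_set(np.random.default_rng(7), tiny_sim)
        b = sample_peak_set(np.random.default_rng(7), tiny_sim)
        assert a == b

    def test_minimum_frequency_separation_respected(self, tiny_acq):
        cfg = SimConfig(acq=tiny_acq, n_peaks_range=(5, 5),
                        min_separation_bins=4, lw_range_hz=(1.0, 2.0))
        min_sep = 4 * tiny_acq.hz_per_bin
        for seed in range(20):
            ps = sample_peak_set(np.random.default_rng(seed), cfg)
            freqs = sorted(p.freq_hz for p in ps)
            assert all(b - a >= min_sep for a, b in zip(freqs, freqs[1:]))


class TestSynthesizeFid:
    def test_zero_frequency_undamped_peak_is_constant_one(self, tiny_acq):
        ps = PeakSet((PeakParams(freq_hz=0.0, amplitude=1.0, lw_hz=0.0),))
        fid = synthesize_fid(ps, tiny_acq)
        np.testing.assert_allclose(fid.samples, np.ones(tiny_acq.n_samples))

    def test_quarter_bandwidth_tone_peaks_at_quarter_bin(self, tiny_acq):
        # DFT oracle: an undamped tone at sw/4 concentrates magnitude at
        # the +sw/4 bin of the centered transform.
        f = tiny_acq.spectral_width_hz / 4
        ps = PeakSet((PeakParams(freq_hz=f, amplitude=1.0, lw_hz=0.0),))
        fid = synthesize_fid(ps, tiny_acq)
        mag = np.abs(np.fft.fftshift(np.fft.fft(fid.samples, tiny_acq.n_ft)))
        axis = np.fft.fftshift(np.fft.fftfreq(tiny_acq.n_ft, tiny_acq.dwell_s))
        assert abs(axis[np.argmax(mag)] - f) <= tiny_acq.hz_per_bin

    def test_superposition_is_exact(self, tiny_acq, rng):
        p1 = PeakParams(freq_hz=-100.0, amplitude=0.5, lw_hz=3.0, phase_rad=0.2)
        p2 = PeakParams(freq_hz=220.0, amplitude=2.0, lw_hz=1.0)
        both = synthesize_fid(PeakSet((p1, p2)), tiny_acq)
        a = synthesize_fid(PeakSet((p1,)), tiny_acq)
        b = synthesize_fid(PeakSet((p2,)), tiny_acq)
        np.testing.assert_allclose(both.samples, a.samples + b.samples,
                                   rtol=0, atol=1e-12)

    def test_lorentzian_halfwidth_matches_parameter(self, default_acq):
        # The absorption (real) part of the spectrum of exp(-pi*lw*t) is a
        # Lorentzian whose full width at half height equals lw_hz.
        lw = 4.0
        ps = PeakSet((PeakParams(freq_hz=0.0, amplitude=1.0, lw_hz=lw),))
        # long acquisition so truncation is negligible
        acq = AcquisitionParams(spectral_width_hz=default_acq.spectral_width_hz,
                                chunk_len=64, n_chunks=128, n_ft=8192)
        spec = np.fft.fftshift(np.fft.fft(
            synthesize_fid(ps, acq).samples, acq.n_ft)).real
        axis = np.fft.fftshift(np.fft.fftfreq(acq.n_ft, acq.dwell_s))
        above = axis[spec >= spec.max() / 2]
        fwhh = above.max() - above.min()
        assert fwhh == pytest.approx(lw, rel=0.15)


class TestNUSSchedules:
    def test_full_schedule_keeps_every_chunk(self, rng):
        s = make_nus_schedule(8, 8, rng)
        assert s.sampled == tuple(range(8))
        assert s.nus_level == 1.0

    @pytest.mark.parametrize("n_keep,level,accel", [
        (5, 5.4, None), (7, 7.5, None), (15, 16.1, 6.2), (23, 24.7, None)])
    def test_93_chunk_levels_match_printed_percentages(self, rng, n_keep,
                                                       level, accel):
        s = make_nus_schedule(93, n_keep, rng)
        assert round(100 * s.nus_level, 1) == level
        if accel is not None:
            assert round(s.acceleration, 1) == accel

    def test_unique_small_denominator_for_all_four_levels(self):
        # Brute-force oracle: 93 is the smallest chunk count in [50, 200]
        # that reproduces all four NUS percentages at once (any other hit is
        # a multiple of it).
        hits = []
        for n in range(50, 201):
            ks = [round(p * n / 100) for p in (5.4, 7.5, 16.1, 24.7)]
            if all(k >= 1 and round(100 * k / n, 1) == p
                   for k, p in zip(ks, (5.4, 7.5, 16.1, 24.7))):
                hits.append(n)
        assert hits[0] == 93
        assert all(h % 93 == 0 for h in hits)

    def test_first_chunk_always_sampled_by_default_scheme(self, rng):
        for _ in range(20):
            assert 0 in make_nus_schedule(93, 5, rng).sampled

    def test_n_keep_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            make_nus_schedule(8, 0, rng)
        with pytest.raises(ValueError):
            make_nus_schedule(8, 9, rng)

    def test_schedule_deterministic_given_seed(self):
        a = make_nus_schedule(93, 15, np.random.default_rng(3))
        b = make_nus_schedule(93, 15, np.random.default_rng(3))
        assert a == b


class TestApplyNus:
    def test_full_schedule_is_identity(self, tiny_acq, tiny_sim, rng):
        fid = synthesize_fid(sample_peak_set(rng, tiny_sim), tiny_acq)
        s = NUSSchedule(tuple(range(8)), 8)
        np.testing.assert_array_equal(apply_nus(fid, s).samples, fid.samples)

    def test_omitting_one_chunk_zeroes_exactly_chunk_len_samples(
            self, tiny_acq, tiny_sim, rng):
        fid = synthesize_fid(sample_peak_set(rng, tiny_sim), tiny_acq)
        s = NUSSchedule(tuple(i for i in range(8) if i != 3), 8)
        out = apply_nus(fid, s)
        assert np.count_nonzero(out.samples == 0) == tiny_acq.chunk_len
        np.testing.assert_array_equal(out.samples[tiny_acq.chunk_slice(3)], 0)

    def test_sampled_chunks_pass_through_unchanged(self, tiny_acq, tiny_sim,
                                                   rng):
        fid = synthesize_fid(sample_peak_set(rng, tiny_sim), tiny_acq)
        s = make_nus_schedule(8, 3, rng)
        out = apply_nus(fid, s)
        mask = s.sample_mask(tiny_acq.chunk_len)
        np.testing.assert_array_equal(out.samples[mask], fid.samples[mask])
        np.testing.assert_array_equal(out.samples[~mask], 0)

    def test_idempotent(self, tiny_acq, tiny_sim, rng):
        fid = synthesize_fid(sample_peak_set(rng, tiny_sim), tiny_acq)
        s = make_nus_schedule(8, 3, rng)
        once = apply_nus(fid, s)
        twice = apply_nus(once, s)
        np.testing.assert_array_equal(once.samples, twice.samples)

    def test_geometry_mismatch_rejected(self, tiny_acq, tiny_sim, rng):
        fid = synthesize_fid(sample_peak_set(rng, tiny_sim), tiny_acq)
        with pytest.raises(ValueError):
            apply_nus(fid, NUSSchedule((0,), n_chunks=7))


class TestAddNoise:
    def test_zero_sigma_is_identity(self, tiny_acq, rng):
        fid = synthesize_fid(PeakSet((PeakParams(0.0, 1.0),)), tiny_acq)
        assert add_noise(fid, 0.0, rng) is fid

    def test_negative_sigma_rejected(self, tiny_acq, rng):
        fid = synthesize_fid(PeakSet((PeakParams(0.0, 1.0),)), tiny_acq)
        with pytest.raises(ValueError):
            add_noise(fid, -0.1, rng)

    def test_noise_std_matches_sigma(self):
        acq = AcquisitionParams(spectral_width_hz=1000.0, chunk_len=1000,
                                n_chunks=100, n_ft=100000)
        fid = synthesize_fid(PeakSet((PeakParams(0.0, 1.0, lw_hz=0.0),)), acq)
        sigma = 0.3
        noisy = add_noise(fid, sigma, np.random.default_rng(0))
        diff = noisy.samples - fid.samples
        assert np.std(diff.real) == pytest.approx(sigma, rel=0.05)
        assert np.std(diff.imag) == pytest.approx(sigma, rel=0.05)

    def test_seeded_noise_reproducible(self, tiny_acq):
        fid = synthesize_fid(PeakSet((PeakParams(0.0, 1.0),)), tiny_acq)
        a = add_noise(fid, 0.1, np.random.default_rng(5))
        b = add_noise(fid, 0.1, np.random.default_rng(5))
        np.testing.assert_array_equal(a.samples, b.samples)


class TestFidToSpectrum:
    def test_zero_fid_gives_zero_spectrum_flagged(self, tiny_acq):
        fid = Fid(np.zeros(tiny_acq.n_samples, complex), tiny_acq)
        spec = fid_to_spectrum(fid)
        assert spec.norm_factor == 0.0
        np.testing.assert_array_equal(spec.values, 0)

    def test_on_bin_tone_peaks_exactly_at_its_bin(self, tiny_acq):
        # pick a frequency landing exactly on an FT bin
        f = 32 * tiny_acq.hz_per_bin
        ps = PeakSet((PeakParams(freq_hz=f, amplitude=1.0, lw_hz=0.0),))
        spec = fid_to_spectrum(synthesize_fid(ps, tiny_acq))
        assert spec.axis_hz[np.argmax(spec.values)] == pytest.approx(f)
        assert np.max(np.abs(spec.values)) == pytest.approx(1.0)

    def test_parseval_identity(self, tiny_acq, tiny_sim, rng):
        fid = synthesize_fid(sample_peak_set(rng, tiny_sim), tiny_acq)
        padded = np.zeros(tiny_acq.n_ft, complex)
        padded[:tiny_acq.n_samples] = fid.samples
        complex_spec = np.fft.fft(padded)
        assert np.sum(np.abs(complex_spec) ** 2) == pytest.approx(
            tiny_acq.n_ft * np.sum(np.abs(padded) ** 2))

    def test_n_ft_smaller_than_data_rejected(self, tiny_acq):
        fid = synthesize_fid(PeakSet((PeakParams(0.0, 1.0),)), tiny_acq)
        with pytest.raises(ValueError):
            fid_to_spectrum(fid, n_ft=64)


class TestTrainingPairs:
    def test_noiseless_full_sampling_input_equals_label(self, tiny_acq,
                                                        tiny_sim, rng):
        peaks = sample_peak_set(rng, tiny_sim)
        full = NUSSchedule(tuple(range(8)), 8)
        pair = make_training_pair(peaks, tiny_acq, full, 0.0, rng)
        np.testing.assert_allclose(pair.input.values, pair.label.values)

    def test_label_ignores_noise_level(self, tiny_acq, tiny_sim):
        peaks = sample_peak_set(np.random.default_rng(0), tiny_sim)
        sched = make_nus_schedule(8, 3, np.random.default_rng(1))
        clean = make_training_pair(peaks, tiny_acq, sched, 0.0,
                                   np.random.default_rng(2))
        noisy = make_training_pair(peaks, tiny_acq, sched, 0.5,
                                   np.random.default_rng(2))
        np.testing.assert_array_equal(clean.label.values, noisy.label.values)
        assert not np.array_equal(clean.input.values, noisy.input.values)

    def test_label_maxima_sit_on_ground_truth_bins(self, tiny_acq):
        cfg = SimConfig(acq=tiny_acq, n_peaks_range=(3, 3),
                        min_separation_bins=12, lw_range_hz=(4.0, 8.0),
                        amp_range=(0.5, 1.0))
        peaks = sample_peak_set(np.random.default_rng(3), cfg)
        spec = fid_to_spectrum(synthesize_fid(peaks, tiny_acq))
        for p in peaks:
            true_bin = np.argmin(np.abs(spec.axis_hz - p.freq_hz))
            window = spec.values[true_bin - 2: true_bin + 3]
            local_max = np.argmax(spec.values[true_bin - 6: true_bin + 7])
            assert abs(local_max - 6) <= 1  # within one bin
            assert window.max() > 0

    def test_nus_artifact_energy_decreases_with_sampling(self, tiny_acq):
        # Average over 50 random schedules per level: RMS difference between
        # input and label should not increase with more sampled chunks.
        cfg = SimConfig(acq=tiny_acq, n_peaks_range=(4, 4),
                        lw_range_hz=(2.0, 6.0))
        peaks = sample_peak_set(np.random.default_rng(11), cfg)
        rng = np.random.default_rng(42)
        means = []
        for n_keep in (2, 4, 6, 8):
            errs = []
            for _ in range(50):
                sched = make_nus_schedule(8, n_keep, rng)
                pair = make_training_pair(peaks, tiny_acq, sched, 0.0, rng)
                errs.append(np.sqrt(np.mean(
                    (pair.input.values - pair.label.values) ** 2)))
            means.append(np.mean(errs))
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_fid_linearity_property(seed):
    """synthesize(A u B) == synthesize(A) + synthesize(B) exactly."""
    acq = AcquisitionParams(spectral_width_hz=800.0, chunk_len=8, n_chunks=6,
                            n_ft=64)
    rng = np.random.default_rng(seed)
    cfg = SimConfig(acq=acq, n_peaks_range=(2, 6), lw_range_hz=(0.0, 10.0),
                    phase_range_rad=(-0.1, 0.1))
    ps = sample_peak_set(rng, cfg)
    k = len(ps) // 2
    a, b = PeakSet(ps.peaks[:k] or ps.peaks[:1]), PeakSet(ps.peaks[k:])
    merged = PeakSet((a.peaks + b.peaks))
    lhs = synthesize_fid(merged, acq).samples
    rhs = synthesize_fid(a, acq).samples + synthesize_fid(b, acq).samples
    np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-12)


class TestGenerateDataset:
    def test_reproducible_from_seed(self, tiny_sim):
        a = generate_dataset(3, tiny_sim, seed=9, n_keep=3)
        b = generate_dataset(3, tiny_sim, seed=9, n_keep=3)
        np.testing.assert_array_equal(a.inputs, b.inputs)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert [p.schedule for p in a.pairs] == [p.schedule for p in b.pairs]

    def test_disjoint_seeds_draw_distinct_peak_sets(self, tiny_sim):
        a = generate_dataset(5, tiny_sim, seed=1, n_keep=3)
        b = generate_dataset(5, tiny_sim, seed=2, n_keep=3)
        for pa in a.pairs:
            for pb in b.pairs:
                assert pa.peaks != pb.peaks

    def test_level_accounting_per_schedule(self, tiny_sim):
        ds = generate_dataset(4, tiny_sim, seed=0, n_keep=3)
        for pair in ds.pairs:
            assert abs(pair.schedule.nus_level - 3 / 8) < 1 / 8

    def test_requested_count_produced(self, tiny_sim):
        assert len(generate_dataset(7, tiny_sim, seed=0, n_keep=2)) == 7
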