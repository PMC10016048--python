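"""Filtering, channel statistics, interpolation, epoching and rejection."""

import dataclasses

import numpy as np
import pytest

from mobidt import eeg
from mobidt.errors import DegenerateSetError, EmptySampleError, InvalidConfigError
from mobidt.synthetic import NoiseSpec, default_templates, gen_epoch_set


class TestCheby2:
    def test_dc_passes_lowpass_unchanged(self):
        y = eeg.cheby2_zero_phase(np.full(2048, 2.5), 512.0, "lowpass", 45.0, 50.0)
        assert np.allclose(y, 2.5, atol=1e-6)

    def test_stopband_attenuation_at_least_spec(self):
        fs = 512.0
        t = np.arange(int(fs * 6)) / fs
        y = eeg.cheby2_zero_phase(np.sin(2 * np.pi * 60 * t), fs, "lowpass", 45.0, 50.0)
        mid = y[int(fs):-int(fs)]
        assert 20 * np.log10(np.abs(mid).max()) < -65.0

    def test_zero_phase_impulse_symmetric(self):
        x = np.zeros(1025)
        x[512] = 1.0
        y = eeg.cheby2_zero_phase(x, 512.0, "lowpass", 45.0, 50.0)
        assert np.abs(y - y[::-1]).max() < 1e-5 * np.abs(y).max()

    def test_edges_beyond_nyquist_raise(self):
        with pytest.raises(InvalidConfigError):
            eeg.cheby2_zero_phase(np.zeros(512), 512.0, "lowpass", 250.0, 300.0)


class TestDownsample:
    def test_length_and_dc(self):
        x = np.ones(2048)
        y = eeg.downsample(x, 2048.0, 512.0)
        assert len(y) == 512
        assert np.allclose(y, 1.0, atol=1e-6)
        assert len(eeg.downsample(np.zeros(2047), 2048.0, 512.0)) == 512

    def test_passband_tone_amplitude_preserved(self):
        fs = 2048.0
        t = np.arange(int(fs * 4)) / fs
        y = eeg.downsample(np.sin(2 * np.pi * 10 * t), fs, 512.0)
        assert abs(np.abs(y[200:-200]).max() - 1.0) < 0.01

    def test_non_integer_ratio_raises(self):
        with pytest.raises(InvalidConfigError):
            eeg.downsample(np.zeros(100), 2048.0, 600.0)


class TestBadChannels:
    def _clean(self, rng, n_ch=64, n_s=5120, fs=512.0):
        t = np.arange(n_s) / fs
        base = np.array(
            [np.sin(2 * np.pi * (8 + 0.1 * i) * t) + 0.5 * np.sin(2 * np.pi * (3 + 0.05 * i) * t + i)
             for i in range(n_ch)]
        )
        return base + 0.05 * rng.normal(0, 1, base.shape)

    def test_planted_noise_channel_flagged_exactly(self, rng):
        data = self._clean(rng)
        data[13] = 20.0 * rng.normal(0, 1, data.shape[1])
        bad, _ = eeg.detect_bad_channels(data)
        assert bad == [13]

    def test_flat_channel_flagged_by_covariance(self, rng):
        data = self._clean(rng)
        data[40] = 0.0
        bad, z = eeg.detect_bad_channels(data)
        assert 40 in bad
        assert abs(z.covariance_z[40]) > 3.0

    def test_identical_channels_none_flagged(self):
        t = np.arange(5120) / 512.0
        data = np.tile(np.sin(2 * np.pi * 8 * t), (16, 1))
        assert eeg.detect_bad_channels(data)[0] == []

    def test_too_few_channels_raise(self):
        with pytest.raises(InvalidConfigError):
            eeg.detect_bad_channels(np.zeros((4, 5120)))


class TestSphericalInterpolation:
    def test_constant_field_reproduced(self, montage):
        _, pos = montage
        data = np.full((64, 20), 3.7)
        out = eeg.interpolate_spherical(data, [5, 40], pos)
        assert np.allclose(out, 3.7, atol=1e-9)

    def test_dipolar_field_leave_one_out(self, montage):
        """Hold out each electrode of a smooth dipolar field in turn; the
        spline reconstruction error stays below 5% of the field RMS."""
        _, pos = montage
        field = (pos @ np.array([0.3, 0.2, 0.9]))[:, None] * np.ones((1, 4))
        rms = np.sqrt((field[:, 0] ** 2).mean())
        for i in range(0, 64, 5):
            rec = eeg.interpolate_spherical(field, [i], pos)
            assert abs(rec[i, 0] - field[i, 0]) < 0.05 * rms

    def test_matches_mne_interpolation_matrix(self, montage):
        """Cross-check against MNE's spherical-spline operator on one split."""
        from mne.channels.interpolation import _make_interpolation_matrix

        _, pos = montage
        bad = [3, 17, 44]
        good = [i for i in range(64) if i not in bad]
        rng = np.random.default_rng(0)
        smooth = np.exp(-2.0 * (1 - pos @ pos[10])) + 0.5 * np.exp(-3.0 * (1 - pos @ pos[50]))
        data = np.outer(smooth, np.ones(3)) + 0.01 * rng.normal(0, 1, (64, 3))
        ours = eeg.interpolate_spherical(data, bad, pos)
        m = _make_interpolation_matrix(pos[good], pos[bad])
        theirs = m @ data[good]
        assert np.allclose(ours[bad], theirs, atol=0.02)

    def test_no_bads_identity_and_untouched_goods(self, montage):
        _, pos = montage
        data = np.random.default_rng(1).normal(0, 1, (64, 10))
        assert np.array_equal(eeg.interpolate_spherical(data, [], pos), data)
        out = eeg.interpolate_spherical(data, [7], pos)
        keep = [i for i in range(64) if i != 7]
        assert np.array_equal(out[keep], data[keep])

    def test_all_bad_raises(self, montage):
        _, pos = montage
        with pytest.raises(DegenerateSetError):
            eeg.interpolate_spherical(np.zeros((64, 5)), list(range(62)), pos)


class TestRereference:
    def test_constant_offset_removed(self):
        data = np.full((8, 100), 4.2)
        assert np.allclose(eeg.rereference_average(data), 0.0)

    def test_channel_sums_zero(self, rng):
        data = rng.normal(0, 1, (16, 200))
        out = eeg.rereference_average(data)
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(eeg.rereference_average(out), out)


class TestEpochAndBaseline:
    def test_epoch_samples_match_indexing_oracle(self, montage):
        names, pos = montage
        fs = 512.0
        t = np.arange(int(fs * 10)) / fs
        data = np.tile(np.sin(2 * np.pi * 3 * t), (64, 1))
        events = np.array([1024, 2048, 3000])
        es, skipped = eeg.epoch_and_baseline(
            data, events, fs, (-200.0, 800.0), (-100.0, 0.0), names, pos
        )
        assert not skipped and es.data.shape[0] == 3
        i0 = 1024 + int(round(-200 / 1000 * fs))
        raw = data[0, i0: i0 + es.data.shape[2]]
        bmask = (es.times_ms >= -100.0) & (es.times_ms <= 0.0)
        assert np.allclose(es.data[0, 0], raw - raw[bmask].mean())

    def test_baseline_window_mean_zero(self, montage):
        names, pos = montage
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (64, 5120))
        es, _ = eeg.epoch_and_baseline(
            data, np.array([1500, 2500]), 512.0, (-200.0, 800.0), (-100.0, 0.0),
            names, pos,
        )
        bmask = (es.times_ms >= -100.0) & (es.times_ms <= 0.0)
        assert np.allclose(es.data[:, :, bmask].mean(axis=2), 0.0, atol=1e-12)

    def test_edge_events_skipped_and_empty_raises(self, montage):
        names, pos = montage
        data = np.zeros((64, 1000))
        es, skipped = eeg.epoch_and_baseline(
            data, np.array([10, 500]), 512.0, (-200.0, 800.0), (-100.0, 0.0),
            names, pos,
        )
        assert skipped == [10] and es.data.shape[0] == 1
        with pytest.raises(EmptySampleError):
            eeg.epoch_and_baseline(
                data, np.array([10]), 512.0, (-200.0, 800.0), (-100.0, 0.0),
                names, pos,
            )


class TestRejectEpochs:
    def test_voltage_rule(self, noisy_cr_epochs):
        es = dataclasses.replace(noisy_cr_epochs, data=noisy_cr_epochs.data.copy())
        es.data[3, 10, 50] = 200.0
        kept, log = eeg.reject_epochs(es)
        assert (3, "voltage") in set(map(tuple, log.to_numpy()))
        assert kept.n_epochs == noisy_cr_epochs.n_epochs - len(set(log.epoch))

    def test_clean_epochs_no_voltage_rejections(self, noisy_cr_epochs):
        _, log = eeg.reject_epochs(noisy_cr_epochs)
        assert "voltage" not in set(log.rule)

    def test_high_band_burst_rejected(self, noisy_cr_epochs):
        """A strong 30-Hz burst lifts the 20-40 Hz band by >25 dB."""
        es = dataclasses.replace(noisy_cr_epochs, data=noisy_cr_epochs.data.copy())
        tvec = np.arange(es.data.shape[2]) / es.sfreq
        es.data[7, 20] += 100.0 * np.sin(2 * np.pi * 30 * tvec)
        high = eeg._band_db(es.data, es.sfreq, (20.0, 40.0))
        assert (high - high.mean(axis=0))[7, 20] > 25.0
        kept, log = eeg.reject_epochs(es)
        assert (7, "high_band") in set(map(tuple, log.to_numpy()))

    def test_low_band_drift_rejected(self, noisy_cr_epochs):
        es = dataclasses.replace(noisy_cr_epochs, data=noisy_cr_epochs.data.copy())
        tvec = np.arange(es.data.shape[2]) / es.sfreq
        es.data[11, 5] += 140.0 * np.sin(2 * np.pi * 0.9 * tvec)
        _, log = eeg.reject_epochs(es)
        assert 11 in set(log.epoch)

    def test_rejection_idempotent(self, noisy_cr_epochs):
        es = dataclasses.replace(noisy_cr_epochs, data=noisy_cr_epochs.data.copy())
        es.data[3, 10, 50] = 200.0
        kept, _ = eeg.reject_epochs(es)
        kept2, log2 = eeg.reject_epochs(kept)
        assert kept2.n_epochs == kept.n_epochs and len(log2) == 0

    def test_all_rejected_raises(self, montage):
        names, pos = montage
        from mobidt.synthetic import EpochSet

        data = np.full((3, 64, 100), 400.0)
        es = EpochSet(data, names, pos, 128.0, np.arange(100.0), "stimulus_onset",
                      "correct_rejection", "sitting")
        with pytest.raises(DegenerateSetError):
            eeg.reject_epochs(es)


class TestAverageErp:
    def test_identical_and_single_epoch(self, montage):
        names, pos = montage
        from mobidt.synthetic import EpochSet

        one = np.random.default_rng(3).normal(0, 1, (64, 50))
        es = EpochSet(np.stack([one] * 4), names, pos, 128.0, np.arange(50.0),
                      "stimulus_onset", "correct_rejection", "sitting")
        out = eeg.average_erp(es)
        assert np.allclose(out.data, one) and out.n_epochs == 4

    def test_noise_averages_toward_template(self):
        es = gen_epoch_set(
            default_templates("stimulus_onset"), 400, "stimulus_onset",
            "correct_rejection", noise=NoiseSpec(pink_sd_uv=0.0, white_sd_uv=5.0),
            sfreq=128.0, seed=4,
        )
        clean = gen_epoch_set(default_templates("stimulus_onset"), 1,
                              "stimulus_onset", "correct_rejection", sfreq=128.0)
        err = np.abs(eeg.average_erp(es).data - clean.data[0]).max()
        assert err < 5 * 5.0 / np.sqrt(400)


def test_identity_ica_hook_is_passthrough(rng):
    data = rng.normal(0, 1, (8, 100))
    assert np.array_equal(eeg.identity_ica(data), data)
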