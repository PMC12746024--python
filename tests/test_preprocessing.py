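import numpy as np
import pytest

from infantmmr.containers import ContinuousRecording, EventSequence
from infantmmr.preprocessing import (bandpass_filter, baseline_correct,
                                     detect_bad_channels, reject_artifacts,
                                     resample_epochs, segment_epochs,
                                     spatial_pca_denoise)
from infantmmr.validation import naive_rejection_mask


def make_rec(data, montage, rate=1000.0):
    return ContinuousRecording(data, rate, montage)


class TestBandpassFilter:
    def test_dc_is_removed(self, montage):
        rec = make_rec(np.full((11, 20000), 50.0), montage)
        out = bandpass_filter(rec, 1.0, 18.0, 4)
        assert np.abs(out.data[:, 5000:15000]).max() < 1e-6

    @pytest.mark.parametrize("freq,lo,hi", [(10.0, 0.95, 1.0), (50.0, 0.0, 0.01)])
    def test_passband_and_stopband_gain(self, montage, freq, lo, hi):
        # oracle: |H(f)|^2 of an order-4 Butterworth bandpass applied twice
        t = np.arange(60000) / 1000.0
        sig = np.tile(np.sin(2 * np.pi * freq * t), (11, 1)) * 20.0
        out = bandpass_filter(make_rec(sig, montage), 1.0, 18.0, 4)
        mid = out.data[0, 20000:40000]
        gain = mid.std() / sig[0, 20000:40000].std()
        w = (freq ** 2 - 1 * 18) / (freq * (18 - 1))
        analytic = (1.0 / (1.0 + w ** 8))  # filtfilt doubles the response
        assert lo <= gain <= hi
        assert gain == pytest.approx(analytic, abs=0.02)

    def test_zero_phase_keeps_symmetric_pulse_peak(self, montage):
        t = np.arange(20000)
        pulse = 40.0 * np.exp(-((t - 9000) ** 2) / (2 * 120.0 ** 2))
        rec = make_rec(np.tile(pulse, (11, 1)), montage)
        out = bandpass_filter(rec, 1.0, 18.0, 4)
        assert np.argmax(out.data[0]) == 9000

    def test_cutoff_above_nyquist_fatal(self, montage):
        rec = make_rec(np.zeros((11, 1000)), montage, rate=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, 1.0, 60.0)


class TestBadChannels:
    def test_flat_channel_flagged(self, montage):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(11, 5000))
        data[3] = 0.0
        assert detect_bad_channels(make_rec(data, montage)) == ["C5"]

    def test_high_variance_channel_flagged_by_log_variance_z(self, montage):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(11, 5000))
        data[7] *= 10.0  # 100x variance
        # oracle: z-score of log variances
        logv = np.log(data.var(axis=1))
        z = (logv - logv.mean()) / logv.std(ddof=1)
        assert z[7] > 3.0
        assert detect_bad_channels(make_rec(data, montage),
                                   z_var_thresh=3.0) == ["Pz"]

    def test_clean_channels_pass_and_too_many_bad_fatal(self, montage):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(11, 5000))
        assert detect_bad_channels(make_rec(data, montage)) == []
        data[:5] = 0.0
        with pytest.raises(ValueError, match="unusable"):
            detect_bad_channels(make_rec(data, montage))


class TestSegmentEpochs:
    def test_epoch_sample_range(self, montage):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(11, 8000))
        events = EventSequence(np.array([5000]), np.array(["standard"], dtype=object))
        ep = segment_epochs(make_rec(data, montage), events)
        assert ep.data.shape == (1, 11, 1000)
        assert np.array_equal(ep.data[0], data[:, 4800:5800])

    def test_out_of_bounds_events_dropped(self, montage):
        data = np.zeros((11, 4000))
        events = EventSequence(np.array([100, 2000, 3500]),
                               np.array(["standard"] * 3, dtype=object))
        ep = segment_epochs(make_rec(data, montage), events)
        assert ep.n_trials == 1 and ep.trial_onsets[0] == 2000
        with pytest.raises(ValueError, match="no epochs"):
            segment_epochs(make_rec(np.zeros((11, 500)), montage),
                           EventSequence(np.array([100]),
                                         np.array(["standard"], dtype=object)))


class TestRejectArtifacts:
    def test_voltage_and_step_rules(self, epochs_factory):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, size=(30, 3, 1000))
        data[4, 1, 300] = 200.0          # extreme voltage
        data[9, 0, 400:] += 60.0         # 60 uV step
        out = reject_artifacts(epochs_factory(data))
        assert out.rejection_mask[4] and out.rejection_reason[4] == "voltage"
        assert out.rejection_mask[9] and out.rejection_reason[9] == "step"
        assert out.rejection_mask.sum() >= 2

    def test_mask_matches_naive_oracle(self, epochs_factory):
        from scipy.ndimage import gaussian_filter1d
        rng = np.random.default_rng(5)
        data = gaussian_filter1d(rng.normal(size=(200, 5, 1000)), 5.0, axis=2) * 40
        for i in rng.choice(200, 30, replace=False):
            data[i, rng.integers(5), rng.integers(200, 800)] += 300.0
        out = reject_artifacts(epochs_factory(data), 150.0, 50.0, 5.0)
        ref = naive_rejection_mask(data, 150.0, 50.0, 5.0)
        assert np.array_equal(out.rejection_mask, ref)

    def test_rejection_monotone_in_voltage_threshold(self, epochs_factory):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 50, size=(50, 3, 200))
        ks = 1e9  # isolate the voltage rule
        n_prev = None
        for thresh in (150.0, 200.0, 300.0, 1000.0):
            out = reject_artifacts(epochs_factory(data, window=(0.0, 199.0)),
                                   thresh, 1e9, ks)
            n = out.rejection_mask.sum()
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_all_rejected_is_fatal(self, epochs_factory):
        data = np.full((5, 2, 1000), 300.0)
        data[:, :, ::2] = -300.0
        with pytest.raises(ValueError, match="all trials rejected"):
            reject_artifacts(epochs_factory(data))


class TestResampleEpochs:
    def test_length_ratio_and_window_preserved(self, epochs_factory):
        ep = epochs_factory(np.random.default_rng(0).normal(size=(4, 2, 1000)))
        out = resample_epochs(ep, 250.0)
        assert out.data.shape == (4, 2, 250)
        assert out.window_ms == ep.window_ms
        with pytest.raises(ValueError):
            resample_epochs(ep, 2000.0)

    def test_sinusoid_amplitude_preserved(self, epochs_factory):
        t = np.arange(1000) / 1000.0
        wave = np.sin(2 * np.pi * 10.0 * t)
        ep = epochs_factory(np.tile(wave, (3, 2, 1)))
        out = resample_epochs(ep, 250.0)
        mid = out.data[0, 0, 50:200]
        assert np.abs(mid).max() == pytest.approx(1.0, abs=0.01)

    def test_resampling_composes_for_band_limited_signals(self, epochs_factory):
        from scipy.ndimage import gaussian_filter1d
        rng = np.random.default_rng(1)
        data = gaussian_filter1d(rng.normal(size=(3, 2, 1000)), 12.0, axis=2)
        ep = epochs_factory(data)
        once = resample_epochs(ep, 250.0)
        twice = resample_epochs(resample_epochs(ep, 500.0), 250.0)
        assert np.allclose(once.data[:, :, 20:230], twice.data[:, :, 20:230],
                           atol=1e-3)


class TestBaseline:
    def test_constant_epoch_becomes_zero(self, epochs_factory):
        out = baseline_correct(epochs_factory(np.full((2, 3, 1000), 20.0)))
        assert np.allclose(out.data, 0.0)

    def test_idempotent_and_exact_shift(self, epochs_factory):
        rng = np.random.default_rng(2)
        ep = epochs_factory(rng.normal(size=(4, 3, 1000)))
        once = baseline_correct(ep)
        t = ep.times_ms
        base = ep.data[:, :, (t >= -200) & (t <= 0)].mean(axis=2, keepdims=True)
        assert np.allclose(once.data, ep.data - base)
        assert np.allclose(baseline_correct(once).data, once.data, atol=1e-12)
        idx = (t >= -200) & (t <= 0)
        assert np.allclose(once.data[:, :, idx].mean(axis=2), 0.0, atol=1e-9)


class TestSpatialPca:
    def test_full_variance_is_identity(self, epochs_factory):
        rng = np.random.default_rng(3)
        ep = baseline_correct(epochs_factory(rng.normal(size=(20, 11, 250),
                                                        scale=5.0), rate=250.0))
        out = spatial_pca_denoise(ep, var_retained=1.0)
        assert np.allclose(out.data, ep.data, atol=1e-6)

    def test_dominant_spatial_pattern_recovered(self, epochs_factory):
        rng = np.random.default_rng(4)
        pattern = rng.normal(size=11)
        time_course = rng.normal(size=(30, 250))
        clean = np.einsum("c,bt->bct", pattern, time_course)
        noisy = clean + rng.normal(scale=1e-3 * np.abs(clean).max(),
                                   size=clean.shape)
        ep = baseline_correct(epochs_factory(noisy, rate=250.0))
        ref = baseline_correct(epochs_factory(clean, rate=250.0))
        out = spatial_pca_denoise(ep, var_retained=0.95)
        scale = np.abs(ref.data).max()
        assert np.max(np.abs(out.data - ref.data)) < 0.01 * scale

    def test_projection_never_inflates_channel_variance(self, epochs_factory):
        rng = np.random.default_rng(5)
        ep = baseline_correct(epochs_factory(rng.normal(size=(15, 11, 250)),
                                             rate=250.0))
        out = spatial_pca_denoise(ep, var_retained=0.8)
        # oracle: naive eigendecomposition of the z-scored channel covariance
        flat = ep.data.transpose(1, 0, 2).reshape(11, -1)
        mu, sd = flat.mean(1, keepdims=True), flat.std(1, keepdims=True)
        z = (flat - mu) / sd
        var_in = z.var(axis=1)
        zf = (out.data.transpose(1, 0, 2).reshape(11, -1) + 0)
        # compare in the z-scored space where the projection acts
        evals = np.linalg.eigvalsh(z @ z.T / z.shape[1])
        assert evals.min() > -1e-9
        var_out = (((zf - zf.mean(1, keepdims=True))) / sd).var(axis=1)
        assert np.all(var_out <= var_in + 1e-9)
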