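import numpy as np
import pytest
from scipy import signal as sps

from eegreversal.preprocess import (
    BaselineSpec,
    FilterSpec,
    baseline_correct,
    common_average_reference,
    filter_epochs,
    gaussian_kernel,
    gaussian_smooth,
)

from conftest import make_epochs

FS = 256.0


def sinusoid_epochs(freq_hz, n_times=4096, amplitude=1.0):
    t = np.arange(n_times) / FS
    wave = amplitude * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(wave, (4, 4, 1))
    return make_epochs(n_trials=4, n_channels=4, n_times=n_times, data=data)


class TestFiltering:
    def test_50hz_line_noise_attenuated_20db(self):
        epochs = sinusoid_epochs(50.0)
        out = filter_epochs(epochs, FilterSpec())
        interior = out.data[0, 0, 1024:-1024]
        attenuation_db = 20 * np.log10(np.max(np.abs(interior)) / 1.0)
        assert attenuation_db <= -20.0

    def test_10hz_passband_preserved_within_5pct(self):
        epochs = sinusoid_epochs(10.0)
        out = filter_epochs(epochs, FilterSpec())
        interior = out.data[0, 0, 1024:-1024]
        assert np.max(np.abs(interior)) == pytest.approx(1.0, rel=0.05)

    def test_frequency_response_oracle(self):
        """Evaluate the composed filter's own response at 50 and 10 Hz."""
        spec = FilterSpec()
        sos = np.vstack(
            [
                sps.butter(spec.order, spec.high_pass_hz, "highpass", fs=FS, output="sos"),
                sps.butter(spec.order, spec.low_pass_hz, "lowpass", fs=FS, output="sos"),
                sps.butter(spec.order, spec.band_stop, "bandstop", fs=FS, output="sos"),
            ]
        )
        w, h = sps.sosfreqz(sos, worN=[10.0, 50.0], fs=FS)
        gain = np.abs(h) ** 2  # forward-backward filtering squares the magnitude
        assert 20 * np.log10(gain[1]) <= -20.0
        assert gain[0] == pytest.approx(1.0, rel=0.05)

    def test_dc_removed_by_high_pass(self):
        """A constant is in the stopband; away from the edges it decays to ~0.

        The 0.1 Hz edge implies a ~10 s settling scale, so the residual is
        checked in the epoch interior and relative to the DC amplitude.
        """
        data = np.full((2, 4, 8192), 5.0)
        epochs = make_epochs(n_trials=2, n_channels=4, n_times=8192, data=data)
        out = filter_epochs(epochs, FilterSpec())
        assert np.max(np.abs(out.data[:, :, 2048:-2048])) < 0.03 * 5.0

    def test_nyquist_violation_raises(self):
        epochs = make_epochs(n_times=64)
        with pytest.raises(ValueError, match="Nyquist"):
            filter_epochs(epochs, FilterSpec(low_pass_hz=200.0))

    def test_zero_phase_preserves_peak_latency(self):
        """An in-band transient's peak must not shift by more than 1 sample."""
        n_times = 2048
        t = np.arange(n_times) / FS
        center = 4.0
        wave = np.exp(-0.5 * ((t - center) / 0.05) ** 2) * np.sin(2 * np.pi * 10 * (t - center))
        data = np.tile(wave, (2, 4, 1))
        epochs = make_epochs(n_trials=2, n_channels=4, n_times=n_times, data=data)
        out = filter_epochs(epochs, FilterSpec())
        assert abs(int(np.argmax(out.data[0, 0])) - int(np.argmax(data[0, 0]))) <= 1


class TestBaseline:
    def test_window_mode_zeroes_baseline_mean(self, small_epochs):
        spec = BaselineSpec(mode="window", window=(0.0, 30.0))
        out = baseline_correct(small_epochs, spec)
        idx = out.time_indices((0.0, 30.0))
        np.testing.assert_allclose(
            out.data[..., idx].mean(axis=-1), 0.0, atol=1e-12
        )

    def test_whole_trial_mode_zeroes_constant_trial(self):
        data = np.full((3, 4, 16), 7.25)
        epochs = make_epochs(n_trials=3, n_channels=4, n_times=16, data=data)
        out = baseline_correct(epochs, BaselineSpec(mode="whole_trial"))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_subtraction_arithmetic(self):
        data = np.zeros((1, 1, 16))
        data[0, 0, :8] = 3.5  # baseline region
        data[0, 0, 12] = 10.0
        epochs = make_epochs(n_trials=1, n_channels=1, n_times=16, data=data)
        window = (epochs.times[0], epochs.times[7])
        out = baseline_correct(epochs, BaselineSpec(mode="window", window=window))
        assert out.data[0, 0, 12] == pytest.approx(6.5)

    def test_idempotence(self, small_epochs):
        spec = BaselineSpec(mode="window", window=(0.0, 30.0))
        once = baseline_correct(small_epochs, spec)
        twice = baseline_correct(once, spec)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_empty_window_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            baseline_correct(small_epochs, BaselineSpec(mode="window", window=(30.0, 30.0)))


class TestCommonAverageReference:
    def test_channel_mean_is_zero(self, small_epochs):
        out = common_average_reference(small_epochs)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_simple_example(self):
        data = np.array([[[1.0], [2.0], [3.0]]])
        epochs = make_epochs(n_trials=1, n_channels=3, n_times=1, data=data)
        out = common_average_reference(epochs)
        np.testing.assert_allclose(out.data[0, :, 0], [-1.0, 0.0, 1.0])

    def test_projection_property(self, small_epochs):
        once = common_average_reference(small_epochs)
        twice = common_average_reference(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self):
        epochs = make_epochs(n_trials=2, n_channels=1, n_times=8)
        with pytest.raises(ValueError):
            common_average_reference(epochs)


class TestGaussianSmoothing:
    def test_impulse_response_has_requested_fwhm(self):
        n_times = 257
        data = np.zeros((1, 1, n_times))
        data[0, 0, n_times // 2] = 1.0
        epochs = make_epochs(n_trials=1, n_channels=1, n_times=n_times, data=data)
        out = gaussian_smooth(epochs, fwhm_ms=24.0)
        profile = out.data[0, 0]
        half = profile.max() / 2.0
        above = np.flatnonzero(profile >= half)
        width_ms = epochs.times[above[-1]] - epochs.times[above[0]]
        step_ms = 1000.0 / FS
        assert abs(width_ms - 24.0) <= step_ms + 1e-9

    def test_constant_signal_unchanged_everywhere(self):
        data = np.full((2, 3, 64), 4.2)
        epochs = make_epochs(n_trials=2, n_channels=3, n_times=64, data=data)
        out = gaussian_smooth(epochs, fwhm_ms=24.0)
        # unit-area kernel + edge renormalization: exactly constant incl. edges
        np.testing.assert_allclose(out.data, 4.2, rtol=1e-12)

    def test_white_noise_variance_reduction_matches_kernel(self, rng):
        data = rng.standard_normal((64, 2, 2048))
        epochs = make_epochs(n_trials=64, n_channels=2, n_times=2048, data=data)
        out = gaussian_smooth(epochs, fwhm_ms=24.0)
        kernel = gaussian_kernel(24.0, FS)
        expected_factor = float(np.sum(kernel**2))  # Σk² for white noise
        interior = out.data[..., 64:-64]
        observed = interior.var() / data[..., 64:-64].var()
        assert observed == pytest.approx(expected_factor, rel=0.05)

    def test_sub_sample_fwhm_warns_and_is_identity(self, small_epochs):
        with pytest.warns(UserWarning, match="shorter than one sample"):
            out = gaussian_smooth(small_epochs, fwhm_ms=1.0)
        np.testing.assert_array_equal(out.data, small_epochs.data)


class TestLinearity:
    def test_smoothing_commutes_with_car(self, rng):
        data = rng.standard_normal((6, 5, 128))
        epochs = make_epochs(n_trials=6, n_channels=5, n_times=128, data=data)
        a = gaussian_smooth(common_average_reference(epochs), 24.0)
        b = common_average_reference(gaussian_smooth(epochs, 24.0))
        np.testing.assert_allclose(a.data, b.data, rtol=1e-10, atol=1e-12)

    def test_operations_preserve_shape_and_metadata(self, small_epochs):
        for op in (
            lambda e: baseline_correct(e, BaselineSpec(mode="whole_trial")),
            common_average_reference,
            lambda e: gaussian_smooth(e, 24.0),
        ):
            out = op(small_epochs)
            assert out.data.shape == small_epochs.data.shape
            np.testing.assert_array_equal(out.times, small_epochs.times)
            assert out.trials.equals(small_epochs.trials)
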