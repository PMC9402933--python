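"""Morlet decomposition, inter-trial coherence and ERSP."""

import numpy as np
import pytest

from flickersart.containers import EpochSet
from flickersart.synthgen import make_flicker_response, make_pink_noise
from flickersart.timefreq import (
    band_window_mean,
    cycles_at,
    ersp,
    itc,
    morlet_decompose,
)

FS = 512.0


def flicker_epochs(n_trials, kappa, amplitude=4.0, noise_sigma=2.0, seed=0,
                   harmonic_ratio=0.5):
    """Oz-only epochs: ramped 12.5 Hz drive with von-Mises phase + pink noise."""
    rng = np.random.default_rng(seed)
    n = int(round(1800 * FS / 1000)) + 1
    times = -500.0 + np.arange(n) * 1000.0 / FS
    onset = int(np.argmin(np.abs(times)))
    data = np.empty((n_trials, 1, n))
    for k in range(n_trials):
        if np.isinf(kappa):
            phase = 0.0
        elif kappa == 0:
            phase = rng.uniform(-np.pi, np.pi)
        else:
            phase = rng.vonmises(0.0, kappa)
        x = make_pink_noise(n, FS, exponent=1.0, sigma=noise_sigma, rng=rng)
        flick = make_flicker_response(1200.0, FS, 12.5, amplitude, phase=phase,
                                      harmonic_ratio=harmonic_ratio)
        x[onset : onset + flick.size] += flick
        data[k, 0] = x
    return EpochSet(data=data, times=times, fs=FS, channel_names=["Oz"])


class TestCyclesAt:
    def test_stated_endpoints(self):
        assert cycles_at(8.0) == pytest.approx(5.0)
        assert cycles_at(30.0) == pytest.approx(9.375)

    def test_linear_midpoint(self):
        assert cycles_at(19.0) == pytest.approx(7.1875)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cycles_at(35.0)


class TestMorletDecompose:
    def test_frequency_localization(self):
        # pure 12.5 Hz sinusoid: |coeff| maximal at the nearest grid frequency
        n = int(round(1800 * FS / 1000)) + 1
        times = -500.0 + np.arange(n) * 1000.0 / FS
        data = np.sin(2 * np.pi * 12.5 * times / 1000.0)[None, None, :]
        ep = EpochSet(data=np.tile(data, (2, 1, 1)), times=times, fs=FS,
                      channel_names=["Oz"])
        tf = morlet_decompose(ep, compute_maps=False)
        interior = (tf.times > 100) & (tf.times < 700)
        mags = np.abs(tf.coeffs[0][:, interior])
        assert np.all(tf.freqs[np.argmax(mags, axis=0)] == 12.5)

    def test_zero_input_zero_coeffs(self):
        n = int(round(1800 * FS / 1000)) + 1
        times = -500.0 + np.arange(n) * 1000.0 / FS
        ep = EpochSet(data=np.zeros((2, 1, n)), times=times, fs=FS,
                      channel_names=["Oz"])
        tf = morlet_decompose(ep, compute_maps=False)
        assert np.allclose(np.abs(tf.coeffs), 0.0)

    def test_linearity_in_amplitude(self):
        ep1 = flicker_epochs(2, np.inf, amplitude=1.0, noise_sigma=0.0)
        ep3 = flicker_epochs(2, np.inf, amplitude=3.0, noise_sigma=0.0)
        a = morlet_decompose(ep1, compute_maps=False).coeffs
        b = morlet_decompose(ep3, compute_maps=False).coeffs
        np.testing.assert_allclose(np.abs(b), 3 * np.abs(a), rtol=1e-9, atol=1e-12)

    def test_insufficient_span_rejected(self):
        times = np.arange(100) * 1000.0 / FS  # ~195 ms < longest wavelet
        ep = EpochSet(data=np.zeros((2, 1, 100)), times=times, fs=FS,
                      channel_names=["Oz"])
        with pytest.raises(ValueError, match="pad"):
            morlet_decompose(ep, compute_maps=False)


class TestItc:
    def test_identical_phases_give_unity(self):
        coeffs = np.full((8, 3, 4), 2.0 + 1.0j)
        assert np.allclose(itc(coeffs), 1.0)

    def test_antipodal_phases_cancel(self):
        coeffs = np.stack([np.full((2, 2), 1 + 0j), np.full((2, 2), -1 + 0j)])
        assert np.allclose(itc(coeffs), 0.0, atol=1e-12)

    def test_uniform_phase_null_matches_closed_form(self):
        # E[resultant length of n uniform phases] ~ sqrt(pi / (4 n))
        rng = np.random.default_rng(42)
        n = 200
        vals = []
        for _ in range(100):
            theta = rng.uniform(0, 2 * np.pi, size=(n, 1, 1))
            vals.append(itc(np.exp(1j * theta))[0, 0])
        expected = np.sqrt(np.pi / (4 * n))
        assert np.mean(vals) == pytest.approx(expected, abs=0.01)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, 2 * np.pi, size=(20, 4, 5))
        coeffs = np.exp(1j * theta)
        scales = rng.uniform(0.1, 10.0, size=(20, 1, 1))
        np.testing.assert_allclose(itc(coeffs), itc(scales * coeffs), atol=1e-12)

    def test_bounds_always_hold(self):
        rng = np.random.default_rng(4)
        coeffs = rng.standard_normal((15, 6, 7)) + 1j * rng.standard_normal((15, 6, 7))
        m = itc(coeffs)
        assert np.all(m >= 0.0) and np.all(m <= 1.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            itc(np.ones((1, 2, 2), dtype=complex))

    def test_zero_coefficient_trials_excluded(self):
        coeffs = np.ones((4, 1, 1), dtype=complex)
        coeffs[2] = 0.0  # no phase: must not drag the mean down
        assert np.allclose(itc(coeffs), 1.0)


class TestErsp:
    def test_power_doubling_adds_3dB(self):
        rng = np.random.default_rng(5)
        coeffs = rng.standard_normal((10, 3, 4)) + 1j * rng.standard_normal((10, 3, 4))
        base = ersp(coeffs)
        doubled = ersp(np.sqrt(2.0) * coeffs)
        np.testing.assert_allclose(doubled - base, 10 * np.log10(2), atol=1e-9)

    def test_zero_cells_floored(self):
        assert np.all(ersp(np.zeros((2, 2, 2), dtype=complex)) == -300.0)

    def test_single_trial_equals_own_log_power(self):
        c = np.array([[[3.0 + 4.0j]]])
        assert ersp(c)[0, 0] == pytest.approx(10 * np.log10(25.0))

    def test_monotone_in_injected_amplitude(self):
        vals = []
        for amp in (2.0, 4.0, 8.0):
            ep = flicker_epochs(20, np.inf, amplitude=amp, noise_sigma=1.0, seed=6)
            tf = morlet_decompose(ep, freqs=np.arange(10.0, 27.01, 0.5))
            vals.append(
                (band_window_mean(tf.ersp, tf.freqs, tf.times, (12, 13)),
                 band_window_mean(tf.ersp, tf.freqs, tf.times, (24.5, 25.5)))
            )
        fund = [v[0] for v in vals]
        harm = [v[1] for v in vals]
        assert fund == sorted(fund) and harm == sorted(harm)


class TestBandWindowMean:
    def grid(self):
        freqs = np.arange(8.0, 30.01, 0.5)
        times = -500.0 + np.arange(923) * 1000.0 / FS
        return freqs, times

    def test_constant_map(self):
        freqs, times = self.grid()
        m = np.full((freqs.size, times.size), 0.37)
        assert band_window_mean(m, freqs, times, (12, 13)) == pytest.approx(0.37)

    @pytest.mark.parametrize("f_range,members", [
        ((12.0, 13.0), (12.0, 12.5, 13.0)),
        ((24.5, 25.5), (24.5, 25.0, 25.5)),
    ])
    def test_selected_frequency_rows(self, f_range, members):
        freqs, times = self.grid()
        m = np.zeros((freqs.size, times.size))
        m[:] = freqs[:, None]  # each row's value identifies its frequency
        got = band_window_mean(m, freqs, times, f_range)
        assert got == pytest.approx(np.mean(members))

    def test_empty_selection_rejected(self):
        freqs, times = self.grid()
        with pytest.raises(ValueError):
            band_window_mean(np.zeros((freqs.size, times.size)), freqs, times,
                             (40.0, 45.0))


class TestItcKappaMonotonicity:
    def test_expected_itc_nondecreasing_in_kappa(self):
        # 200 trials, 5 seeds, kappa in {0, 1, 4, inf}
        freqs = np.arange(10.0, 15.01, 0.5)
        means = []
        for kappa in (0.0, 1.0, 4.0, np.inf):
            vals = []
            for seed in range(5):
                ep = flicker_epochs(200, kappa, seed=100 + seed)
                tf = morlet_decompose(ep, freqs=freqs)
                vals.append(band_window_mean(tf.itc, tf.freqs, tf.times, (12, 13)))
            means.append(np.mean(vals))
        assert all(b >= a - 1e-6 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.3  # and the span is substantial
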