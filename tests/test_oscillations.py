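"""Tests of BOSC oscillation detection, P_episode, and the oscillatory SME."""

import numpy as np
import pandas as pd
import pytest

from syncnet.oscillations import (
    bosc_background_fit,
    bosc_detect,
    detect_trials,
    oscillatory_sme,
    pepisode_fraction,
)
from syncnet.preprocess import EpochSet
from syncnet.sim import _one_over_f_noise
from syncnet.spectral import morlet_decompose

FS = 500.0
FREQS = np.arange(3.0, 31.0)


def _epochs(data):
    return EpochSet(
        data=data, fs=FS, t_start_ms=-1000.0, span_ms=(0.0, data.shape[2] / FS * 1000 - 2000),
        buffer_ms=1000.0, condition=np.zeros(data.shape[1], bool),
        pairs=pd.DataFrame({"pair": ["p"]}),
    )


def _power(data, freqs=FREQS):
    tensor = morlet_decompose(_epochs(data), freqs)
    return np.exp(tensor.log_power[0].astype(np.float64))


class TestBackgroundFit:
    def test_exact_power_law_recovered(self):
        log_power = 3.0 - 2.0 * np.log(FREQS)
        bg = bosc_background_fit(FREQS, log_power)
        assert bg.slope == pytest.approx(-2.0, abs=1e-8)
        assert bg.intercept == pytest.approx(3.0, abs=1e-8)

    def test_flat_spectrum_gives_zero_slope(self):
        bg = bosc_background_fit(FREQS, np.full(FREQS.size, 1.5))
        assert bg.slope == pytest.approx(0.0, abs=1e-8)

    def test_narrowband_peak_downweighted(self):
        rng = np.random.default_rng(0)
        log_power = 2.0 - 2.0 * np.log(FREQS) + 0.02 * rng.standard_normal(FREQS.size)
        log_power += 3.0 * np.exp(-0.5 * ((FREQS - 10.0) / 1.5) ** 2)  # peak
        bg = bosc_background_fit(FREQS, log_power)
        assert abs(bg.slope - (-2.0)) < 0.05 * 2.0

    def test_nonfinite_spectrum_rejected(self):
        y = np.full(FREQS.size, 1.0)
        y[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            bosc_background_fit(FREQS, y)

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError, match="5 frequencies"):
            bosc_background_fit(np.array([3.0, 4, 5, 6]), np.zeros(4))

    def test_threshold_scales_with_power(self):
        bg = bosc_background_fit(FREQS, 1.0 - 2.0 * np.log(FREQS))
        assert np.all(bg.power_threshold(FREQS) > 0)
        # chi2(2) 95th percentile scaling: threshold ~ 3x mean power
        ratio = bg.power_threshold(10.0) / bg.mean_power(10.0)
        assert ratio == pytest.approx(2.9957, abs=1e-3)


class TestDetection:
    def test_sustained_sinusoid_detected(self):
        rng = np.random.default_rng(1)
        n = 2000  # 2 s span + 1 s buffers
        sig = 0.5 * _one_over_f_noise(rng, n, FS, 2.0, 1.0)
        sig += np.sin(2 * np.pi * 10.0 * np.arange(n) / FS)
        power = _power(sig[None, None, :])
        bg = bosc_background_fit(FREQS, np.log(power.mean(axis=(0, 2))))
        mask = bosc_detect(power[:, 7], 10.0, bg, FS)  # 10 Hz row
        assert mask[0, 150:-150].mean() > 0.9

    def test_two_cycle_burst_entirely_unflagged(self):
        """A supra-threshold run shorter than three cycles is rejected."""
        bg = bosc_background_fit(FREQS, np.log(np.full(FREQS.size, 1.0)))
        thresh = bg.power_threshold(10.0)
        power = np.full(1000, 0.1 * thresh)
        run2 = int(2 * FS / 10.0)  # two cycles at 10 Hz
        power[400 : 400 + run2] = 2 * thresh
        assert not bosc_detect(power, 10.0, bg, FS).any()
        # ...while a four-cycle run is kept in full
        power4 = np.full(1000, 0.1 * thresh)
        power4[400 : 400 + 2 * run2] = 2 * thresh
        mask4 = bosc_detect(power4, 10.0, bg, FS)
        assert mask4.sum() == 2 * run2

    def test_pure_noise_flag_rate_below_5pct(self):
        data = np.stack(
            [_one_over_f_noise(np.random.default_rng(i + 2), 2800, FS, 2.0, 1.0)
             for i in range(30)]
        )[None]
        power = _power(data)
        bg = bosc_background_fit(FREQS, np.log(power.mean(axis=(0, 2))))
        mask = detect_trials(power, FREQS, bg, FS)
        assert mask.mean() <= 0.05

    def test_amplitude_rescaling_invariance_after_refit(self):
        rng = np.random.default_rng(3)
        data = np.stack(
            [_one_over_f_noise(rng, 2000, FS, 2.0, 1.0) for _ in range(4)]
        )[None]
        p1 = _power(data)
        p2 = _power(25.0 * data)
        bg1 = bosc_background_fit(FREQS, np.log(p1.mean(axis=(0, 2))))
        bg2 = bosc_background_fit(FREQS, np.log(p2.mean(axis=(0, 2))))
        m1 = detect_trials(p1, FREQS, bg1, FS)
        m2 = detect_trials(p2, FREQS, bg2, FS)
        assert np.array_equal(m1, m2)

    def test_frequency_outside_fitted_range_rejected(self):
        bg = bosc_background_fit(FREQS, np.zeros(FREQS.size))
        with pytest.raises(ValueError, match="outside fitted range"):
            bosc_detect(np.ones(100), 100.0, bg, FS)


class TestPepisode:
    def test_fraction_values(self):
        mask = np.zeros((1, 1, 200), bool)
        mask[0, 0, :50] = True  # 50 of first window's 100 samples
        frac = pepisode_fraction(mask, FS, 200.0)
        assert frac[0, 0].tolist() == [0.5, 0.0]

    def test_all_and_none(self):
        assert pepisode_fraction(np.ones((2, 100), bool), FS, 200.0).min() == 1.0
        assert pepisode_fraction(np.zeros((2, 100), bool), FS, 200.0).max() == 0.0

    def test_total_time_identity(self):
        rng = np.random.default_rng(4)
        mask = rng.random((3, 2, 400)) < 0.3
        frac = pepisode_fraction(mask, FS, 200.0)
        k = int(200.0 * FS / 1000.0)
        assert frac.sum() * k == mask[..., : 4 * k].sum()


class TestOscillatorySme:
    def _fractions(self, effect_pixel=None, n_trials=40, seed=5):
        rng = np.random.default_rng(seed)
        fractions = rng.beta(0.3, 6.0, (n_trials, 6, 8))
        labels = np.zeros(n_trials, bool)
        labels[: n_trials // 2] = True
        if effect_pixel is not None:
            f, w = effect_pixel
            fractions[labels, f, w] += 0.5
        return fractions, labels

    def test_injected_effect_flagged_at_correct_pixel(self):
        fractions, labels = self._fractions(effect_pixel=(3, 2))
        res = oscillatory_sme(fractions, labels)
        assert res["flagged"]
        fi, wi = np.unravel_index(np.argmax(np.abs(res["t"])), res["t"].shape)
        assert (fi, wi) == (3, 2)
        assert res["significant"][3, 2]

    def test_label_shuffle_destroys_effect(self):
        fractions, labels = self._fractions(effect_pixel=(3, 2))
        rng = np.random.default_rng(6)
        res = oscillatory_sme(fractions, rng.permutation(labels))
        assert not res["significant"][3, 2]

    def test_constant_pixels_carry_no_evidence(self):
        fractions, labels = self._fractions()
        fractions[:, 0, 0] = 0.0
        res = oscillatory_sme(fractions, labels)
        assert res["p"][0, 0] == 1.0
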