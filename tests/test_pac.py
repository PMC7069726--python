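"""Modulation index, comodulograms, waveform shape, confound regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from thetagaze.pac import (
    ComodulogramZ,
    adjust_pac_for_waveform,
    comodulogram_z,
    mi_from_distribution,
    modulation_index,
    select_theta_frequency,
    trial_mi_z,
    waveform_feature_table,
    waveform_features,
)

FS = 500.0


class TestModulationIndex:
    def test_uniform_distribution_zero(self):
        assert mi_from_distribution(np.full(20, 0.05)) == 0.0

    def test_all_mass_one_bin_is_one(self):
        p = np.zeros(20)
        p[7] = 1.0
        assert mi_from_distribution(p) == pytest.approx(1.0)

    def test_half_bins_closed_form(self):
        p = np.zeros(20)
        p[:10] = 0.1
        assert mi_from_distribution(p) == pytest.approx(
            np.log(2) / np.log(20), abs=1e-12
        )

    def test_scale_invariance_exact(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        assert modulation_index(ph, amp).mi == pytest.approx(
            modulation_index(ph, 10 * amp).mi, rel=1e-10, abs=1e-12
        )

    def test_rotation_invariance(self, rng):
        # rotating phases by a whole number of bins permutes P cyclically
        ph = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        rot = np.angle(np.exp(1j * (ph + 2 * np.pi / 20 * 3)))
        assert modulation_index(ph, amp).mi == pytest.approx(
            modulation_index(rot, amp).mi, abs=1e-12
        )

    def test_empty_bins_contribute_zero(self):
        ph = np.full(100, 0.1)  # single bin occupied
        amp = np.ones(100)
        out = modulation_index(ph, amp)
        assert out.mi == pytest.approx(1.0)
        assert (out.counts == 0).sum() == 19

    def test_all_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(np.zeros(10), np.zeros(10))

    def test_coupled_signal_nonzero_mi(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 20000)
        amp = 1.0 + 0.8 * np.cos(ph)
        assert modulation_index(ph, amp).mi > 0.01


class TestComodulogram:
    def test_recovers_coupling_location(self, coupled_epochs, rng):
        com = comodulogram_z(
            coupled_epochs, phase_freqs=np.arange(2.0, 9.0, 1.0),
            amp_freqs=np.arange(70.0, 131.0, 10.0), n_surr=150, rng=rng,
        )
        i, j = np.unravel_index(np.nanargmax(com.mi_z), com.mi_z.shape)
        assert abs(com.phase_freqs[i] - 5.0) <= 1.0
        assert abs(com.amp_freqs[j] - 90.0) <= 10.0
        assert com.mi_z[i, j] > 3.0

    def test_too_few_epochs_rejected(self, coupled_epochs):
        from dataclasses import replace

        small = replace(coupled_epochs, data=coupled_epochs.data[:4])
        with pytest.raises(ValueError):
            comodulogram_z(small)

    def test_trial_mi_z_finite_and_elevated(self, coupled_epochs, rng):
        z = trial_mi_z(coupled_epochs, 5.0, amp_freqs=np.array([90.0]),
                       n_surr=59, rng=rng)
        assert np.isfinite(z).all()
        assert np.mean(z) > 0.5  # per-epoch coupling visible on average


class TestSelectThetaFrequency:
    def _com(self, mi_z):
        mi_z = np.asarray(mi_z, dtype=float)
        return ComodulogramZ(
            mi_z=mi_z, mi_obs=np.abs(mi_z),
            phase_freqs=np.arange(1.0, 11.0), amp_freqs=np.array([90.0]),
            n_surrogates=1,
        )

    def test_single_condition_peak(self):
        z = np.zeros((10, 1))
        z[4] = 5.0  # 5 Hz
        assert select_theta_frequency([self._com(z)]) == 5.0

    def test_pooled_magnitude_across_conditions(self):
        za, zb = np.zeros((10, 1)), np.zeros((10, 1))
        za[3] = 4.0   # 4 Hz
        zb[4] = -6.0  # 5 Hz, larger magnitude
        assert select_theta_frequency([self._com(za), self._com(zb)]) == 5.0

    def test_tie_goes_to_lowest_frequency(self):
        z = np.zeros((10, 1))
        z[3] = z[4] = 2.0
        assert select_theta_frequency([self._com(z)]) == 4.0

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            select_theta_frequency([self._com(np.zeros((10, 1)))], band=(40, 60))


class TestWaveformFeatures:
    def test_sinusoid_symmetric(self):
        t = np.arange(4000) / FS
        f = waveform_features(np.cos(2 * np.pi * 5 * t), FS)
        assert f["s_peak"] == pytest.approx(f["s_trough"], rel=0.05)
        assert abs(f["asym"]) < 0.05

    def test_linearity_of_sharpness_and_amplitude(self):
        t = np.arange(4000) / FS
        x = np.cos(2 * np.pi * 5 * t)
        f1, f2 = waveform_features(x, FS), waveform_features(2 * x, FS)
        assert f2["s_peak"] == pytest.approx(2 * f1["s_peak"], rel=1e-6)
        assert f2["amplitude"] == pytest.approx(2 * f1["amplitude"], rel=1e-3)

    def test_sawtooth_asymmetry_sign(self):
        t = np.arange(4000) / FS
        # slow rise, fast fall: rise time > decay time -> positive asym
        x = signal.sawtooth(2 * np.pi * 5 * t, width=0.9)
        f = waveform_features(x, FS, band=(1.0, 10.0))
        assert f["asym"] > 0.1
        x_rev = signal.sawtooth(2 * np.pi * 5 * t, width=0.1)
        assert waveform_features(x_rev, FS)["asym"] < -0.1

    def test_no_extrema_rejected(self):
        with pytest.raises(ValueError):
            waveform_features(np.linspace(0, 1, 16), FS)

    def test_feature_table_phase_deviation_components(self, coupled_epochs):
        df = waveform_feature_table(coupled_epochs)
        assert len(df) == coupled_epochs.n_epochs
        assert ((df.sin_theta ** 2 + df.cos_theta ** 2) <= 1.0 + 1e-9).all()
        assert (df.s_peak >= 0).all() and (df.s_trough >= 0).all()


class TestAdjustment:
    def _features(self, rng, n):
        return pd.DataFrame({
            "power": rng.gamma(2.0, 1.0, n),
            "sin_theta": rng.uniform(-1, 1, n),
            "cos_theta": rng.uniform(-1, 1, n),
            "s_peak": rng.gamma(2.0, 0.5, n),
            "s_trough": rng.gamma(2.0, 0.5, n),
            "asym": rng.normal(0, 0.2, n),
        })

    def test_power_dependence_detected_and_removed(self, rng):
        df = self._features(rng, 500)
        mi_z = 0.8 * df.power.to_numpy() + rng.normal(0, 1, 500)
        adj = adjust_pac_for_waveform(mi_z, df)
        assert adj.reports["Power"]["p"] < 1e-6
        r = np.corrcoef(adj.adjusted, df.power)[0, 1]
        assert abs(r) < 0.05

    def test_independent_mi_z_leaves_raw_intact(self, rng):
        df = self._features(rng, 300)
        mi_z = rng.normal(0, 1, 300)
        adj = adjust_pac_for_waveform(mi_z, df)
        assert np.corrcoef(adj.adjusted, mi_z)[0, 1] > 0.95

    def test_residuals_orthogonal_to_all_regressors(self, rng):
        df = self._features(rng, 200)
        mi_z = rng.normal(0, 1, 200) + 0.3 * df.s_peak.to_numpy()
        adj = adjust_pac_for_waveform(mi_z, df)
        for col in ("power", "sin_theta", "cos_theta", "s_peak", "s_trough",
                    "asym"):
            r = np.corrcoef(adj.adjusted, df[col])[0, 1]
            assert abs(r) < 1e-10

    def test_constant_feature_dropped_gracefully(self, rng):
        df = self._features(rng, 100)
        df["power"] = 1.0
        with pytest.warns(UserWarning, match="power"):
            adj = adjust_pac_for_waveform(rng.normal(0, 1, 100), df)
        assert "power" in adj.dropped
        assert np.isnan(adj.reports["Power"]["f"])

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            adjust_pac_for_waveform(np.zeros(5), self._features(rng, 5))
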