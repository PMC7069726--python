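"""ITC, circular summaries, Watson-Williams, ERP phase reset."""

import numpy as np
import pytest
from scipy import stats as sps

from thetagaze.preprocess import ContinuousRecording, extract_epochs
from thetagaze.phase_locking import (
    circular_mean_ci,
    erp_power_reset,
    itc,
    itc_contrast_subsampled,
    rayleigh_test,
    watson_williams_f,
    watson_williams_perm,
)


class TestItc:
    def test_identical_phases_give_one(self):
        assert itc(np.zeros((10, 3, 4))).itc == pytest.approx(1.0)

    def test_symmetric_four_phase_zero(self):
        phases = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])[:, None]
        assert itc(phases).itc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_event_rejected(self):
        with pytest.raises(ValueError):
            itc(np.zeros((1, 4)))

    def test_invariant_to_common_rotation(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (40, 5))
        np.testing.assert_allclose(
            itc(ph).itc, itc(ph + 1.234).itc, rtol=1e-12
        )

    def test_uniform_phase_expectation(self, rng):
        vals = [itc(rng.uniform(-np.pi, np.pi, (100, 1))).itc[0]
                for _ in range(300)]
        assert abs(np.mean(vals) - np.sqrt(np.pi) / 2 / 10) < 0.02


class TestSubsampledContrast:
    def test_identical_inputs_near_zero(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (64, 3))
        a, b, diff = itc_contrast_subsampled(ph, ph, n_draws=5, rng=rng)
        assert np.abs(diff).max() < 2 / np.sqrt(64)

    def test_locked_vs_uniform_positive_everywhere(self, rng):
        a = rng.vonmises(0.0, 2.0, (100, 4, 6))
        b = rng.uniform(-np.pi, np.pi, (100, 4, 6))
        _, _, diff = itc_contrast_subsampled(a, b, n_draws=10, rng=rng)
        assert (diff > 0).all()

    def test_bias_removed_for_unequal_n(self, rng):
        diffs, naive = [], []
        for _ in range(200):
            a = rng.uniform(-np.pi, np.pi, (400, 1))
            b = rng.uniform(-np.pi, np.pi, (50, 1))
            _, _, d = itc_contrast_subsampled(a, b, n_draws=10, rng=rng)
            diffs.append(d[0])
            naive.append(itc(a).itc[0] - itc(b).itc[0])
        assert abs(np.mean(diffs)) < 0.015
        assert np.mean(naive) < -0.05  # the bias the subsampling removes

    def test_converges_to_small_n_itc(self, rng):
        a = rng.uniform(-np.pi, np.pi, (400, 1))
        b = rng.vonmises(0, 1.0, (50, 1))
        ia, _, _ = itc_contrast_subsampled(a, b, n_draws=400, rng=rng)
        assert ia.n_events == 50


class TestCircularSummary:
    def test_degenerate_all_equal(self):
        s = circular_mean_ci(np.zeros(3))
        assert s.mean == 0.0 and s.r == pytest.approx(1.0)

    def test_symmetric_sample_mean_zero(self):
        s = circular_mean_ci(np.array([-np.pi / 4, 0.0, np.pi / 4]))
        assert s.mean == pytest.approx(0.0, abs=1e-12)
        assert s.ci95[0] < 0.0 < s.ci95[1]

    def test_coverage_of_von_mises_mean(self, rng):
        cover = 0
        for _ in range(100):
            s = circular_mean_ci(rng.vonmises(np.pi / 2, 2.0, 500))
            d = np.angle(np.exp(1j * (np.pi / 2 - s.mean)))
            cover += (s.ci95[0] - s.mean) <= d <= (s.ci95[1] - s.mean)
        assert 0.88 <= cover / 100 <= 1.0

    def test_near_uniform_flagged_or_bootstrap(self, rng):
        s = circular_mean_ci(rng.uniform(-np.pi, np.pi, 2000), rng=rng)
        assert s.ci_undefined or (s.ci95[1] - s.ci95[0]) > 0.0


class TestRayleigh:
    def test_identical_angles_z_equals_n(self):
        z, p = rayleigh_test(np.full(10, 0.7))
        assert z == pytest.approx(10.0)
        assert p < 1e-3

    def test_power_against_von_mises(self, rng):
        z, p = rayleigh_test(rng.vonmises(0.0, 2.0, 100))
        assert p < 1e-3

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.zeros(4))

    def test_null_p_uniform(self, rng):
        ps = [rayleigh_test(rng.uniform(-np.pi, np.pi, 1000))[1]
              for _ in range(100)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestWatsonWilliams:
    def test_label_swap_leaves_f_unchanged(self, rng):
        a = rng.vonmises(0.0, 2.0, 40)
        b = rng.vonmises(0.5, 2.0, 60)
        assert watson_williams_f(a, b) == pytest.approx(watson_williams_f(b, a))

    def test_detects_opposite_means(self, rng):
        f, z_f, p = watson_williams_perm(
            rng.vonmises(0.0, 2.0, 100), rng.vonmises(np.pi, 2.0, 100),
            n_perm=1000, rng=rng,
        )
        assert p < 0.001 and z_f > 3.0

    def test_null_centered_and_uniform(self, rng):
        ps, zs = [], []
        for _ in range(60):
            f, z_f, p = watson_williams_perm(
                rng.vonmises(0.3, 2.0, 50), rng.vonmises(0.3, 2.0, 50),
                n_perm=200, rng=rng,
            )
            ps.append(p)
            zs.append(z_f)
        assert sps.kstest(ps, "uniform").pvalue > 0.01
        assert abs(np.mean(zs)) < 0.3

    def test_degenerate_identical_angles_rejected(self):
        with pytest.raises(ValueError):
            watson_williams_f(np.zeros(10), np.zeros(10))


class TestErpReset:
    FS = 500.0

    def _epochs(self, data):
        from thetagaze.preprocess import EpochSet

        return EpochSet(data=data, fs=self.FS, window=(-750.0, 750.0),
                        buffer_ms=0.0)

    def _reset_epochs(self, rng, aligned_post, n_ep=30):
        n = 751
        t = (np.arange(n) - 375) / self.FS
        data = np.empty((n_ep, n))
        for k in range(n_ep):
            pre_phase = rng.uniform(0, 2 * np.pi)
            post_phase = 0.0 if aligned_post else rng.uniform(0, 2 * np.pi)
            x = np.where(
                t < 0,
                np.cos(2 * np.pi * 5 * t + pre_phase),
                np.cos(2 * np.pi * 5 * t + post_phase),
            )
            data[k] = x + 0.5 * rng.standard_normal(n)
        return self._epochs(data)

    def test_identical_epochs_erp_equals_epoch(self, rng):
        data = np.tile(rng.standard_normal(751), (12, 1))
        ep = self._epochs(data)
        res = erp_power_reset(ep, n_perm=50, rng=rng)
        assert res.pre_power.min() >= 0.0 and res.post_power.min() >= 0.0

    def test_post_alignment_detected(self, rng):
        res = erp_power_reset(self._reset_epochs(rng, True), n_perm=300,
                              rng=rng)
        i5 = np.argmin(np.abs(res.freqs - 5.0))
        assert res.contrast[i5] > 0.5
        assert any(p < 0.05 and res.freqs[m].min() < 8.0
                   for m, p in zip(res.clusters.masks, res.clusters.p_fwe))

    def test_no_alignment_mostly_clean(self):
        hits = 0
        for s in range(6):
            r = np.random.default_rng(s)
            res = erp_power_reset(self._reset_epochs(r, False), n_perm=200,
                                  rng=r)
            hits += res.clusters.any_significant()
        assert hits <= 2

    def test_window_bounds_checked(self, rng):
        ep = self._reset_epochs(rng, False)
        with pytest.raises(ValueError):
            erp_power_reset(ep, pre_window=(-2000.0, 0.0), rng=rng)
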