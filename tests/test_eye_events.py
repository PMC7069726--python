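"""Gaze parsing, ROI labeling, viewing timecourses."""

import numpy as np
import pandas as pd
import pytest

from thetagaze.eye_events import (
    assign_fixations_to_rois,
    behavioral_sme_timecourse,
    detect_eye_events,
    viewing_timecourse,
    ViewingTimecourse,
)


def _gaze(x, y, pupil=None, fs=500.0):
    n = len(x)
    return pd.DataFrame({
        "time_ms": 1000.0 * np.arange(n) / fs,
        "x_deg": x, "y_deg": y,
        "pupil": np.full(n, 1000.0) if pupil is None else pupil,
    })


class TestDetect:
    def test_constant_gaze_single_fixation(self, rng):
        g = _gaze(np.zeros(500) + rng.normal(0, 0.01, 500),
                  np.zeros(500) + rng.normal(0, 0.01, 500))
        ev = detect_eye_events(g)
        assert list(ev.kind) == ["fixation"]
        assert not ev.excluded.iloc[0]

    def test_all_dropout_single_blink(self):
        g = _gaze(np.zeros(200), np.zeros(200), pupil=np.zeros(200))
        ev = detect_eye_events(g)
        assert list(ev.kind) == ["blink"]

    def test_non_monotonic_time_rejected(self):
        g = _gaze(np.zeros(100), np.zeros(100))
        g.loc[50, "time_ms"] = 0.0
        with pytest.raises(ValueError):
            detect_eye_events(g)

    def test_short_fixation_flagged_excluded(self):
        # 300 ms fixation, saccade, 70 ms fixation, saccade, 300 ms fixation
        def sacc(x0, x1, n):
            tau = np.linspace(0, 1, n)
            return x0 + (x1 - x0) * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))

        x = np.concatenate([
            np.zeros(150), sacc(0, 5, 10), np.full(35, 5.0),
            sacc(5, 10, 10), np.full(150, 10.0),
        ])
        ev = detect_eye_events(_gaze(x, np.zeros_like(x)))
        fix = ev[ev.kind == "fixation"].reset_index(drop=True)
        assert len(fix) == 3
        durs = fix.offset_ms - fix.onset_ms
        assert list(fix.excluded) == [False, True, False]
        assert durs.iloc[1] < 80.0

    def test_blink_absorbs_neighbourhood(self):
        pupil = np.full(500, 1000.0)
        pupil[200:260] = 0.0
        g = _gaze(np.zeros(500), np.zeros(500), pupil=pupil)
        ev = detect_eye_events(g)
        blink = ev[ev.kind == "blink"].iloc[0]
        # dropout 400-520 ms padded by 25 ms each side
        assert blink.onset_ms <= 376.0 and blink.offset_ms >= 544.0
        assert (ev.kind == "saccade").sum() == 0

    def test_partition_no_gaps_no_overlaps(self, quiet_session):
        ev = detect_eye_events(quiet_session["gaze"]).sort_values("onset_ms")
        gaps = ev.onset_ms.to_numpy()[1:] - ev.offset_ms.to_numpy()[:-1]
        assert np.abs(gaps).max() == 0.0

    def test_saccade_recovery_on_synthetic_gaze(self, quiet_session):
        true_sacc = quiet_session["events"]
        true_sacc = true_sacc[(true_sacc.kind == "saccade")
                              & (true_sacc.amplitude_deg >= 1.0)]
        det = detect_eye_events(quiet_session["gaze"])
        det_on = det[det.kind == "saccade"].onset_ms.to_numpy()
        errs = [np.abs(det_on - s).min() for s in true_sacc.onset_ms]
        assert np.mean(np.array(errs) <= 4.0) >= 0.95
        # no detection far from any programmed saccade
        all_true = quiet_session["events"]
        all_on = all_true[all_true.kind == "saccade"].onset_ms.to_numpy()
        false_pos = sum(np.abs(all_on - d).min() > 20.0 for d in det_on)
        assert false_pos == 0


def _trials():
    return pd.DataFrame([{
        "trial": 0, "onset_ms": 0.0, "offset_ms": 4000.0,
        "condition": "Mismatch", "memory": "remembered",
        "roi1_role": "original", "roi1_x": 0.0, "roi1_y": 0.0,
        "roi2_role": "updated", "roi2_x": 12.0, "roi2_y": 0.0,
        "roi3_role": "other", "roi3_x": 6.0, "roi3_y": 10.0,
    }])


def _fix(onset, offset, x, y):
    return pd.DataFrame([{
        "kind": "fixation", "onset_ms": onset, "offset_ms": offset,
        "x": x, "y": y, "excluded": False,
    }])


class TestRoiAssignment:
    @pytest.mark.parametrize("x, y, expected", [
        (0.0, 0.0, "original"),          # dead center
        (12.0, 0.1, "updated"),
        (0.0, 6.1, "none"),              # just outside the 6 deg radius
        (6.0, 0.0, "original"),          # equidistant: priority tie-break
    ])
    def test_nearest_roi_labeling(self, x, y, expected):
        lab = assign_fixations_to_rois(_fix(1000, 1200, x, y), _trials())
        assert lab.roi.iloc[0] == expected

    def test_analysis_window_edges(self):
        early = assign_fixations_to_rois(_fix(100, 300, 0, 0), _trials())
        late = assign_fixations_to_rois(_fix(3300, 3700, 0, 0), _trials())
        mid = assign_fixations_to_rois(_fix(1000, 1300, 0, 0), _trials())
        assert not early.in_analysis_window.iloc[0]
        assert not late.in_analysis_window.iloc[0]
        assert mid.in_analysis_window.iloc[0]

    def test_fixation_outside_trials_excluded(self):
        lab = assign_fixations_to_rois(_fix(9000, 9200, 0, 0), _trials())
        assert lab.trial.iloc[0] == -1 and lab.excluded.iloc[0]


class TestViewingTimecourse:
    def test_full_trial_single_roi(self):
        lab = assign_fixations_to_rois(_fix(0, 4000, 0, 0), _trials())
        tc = viewing_timecourse(lab, _trials(), bin_ms=100.0)
        assert np.allclose(tc.proportion[0, tc.roi_index("original")], 1.0)
        assert np.allclose(tc.proportion[0, tc.roi_index("updated")], 0.0)

    def test_no_fixations_all_zero(self):
        lab = assign_fixations_to_rois(_fix(9000, 9200, 0, 0), _trials())
        tc = viewing_timecourse(lab, _trials(), bin_ms=100.0)
        assert tc.proportion.sum() == 0.0

    def test_half_half_split(self):
        fix = pd.concat([_fix(0, 2000, 0, 0), _fix(2000, 4000, 12, 0)],
                        ignore_index=True)
        lab = assign_fixations_to_rois(fix, _trials())
        tc = viewing_timecourse(lab, _trials(), bin_ms=4000.0)
        assert tc.proportion[0, tc.roi_index("original"), 0] == pytest.approx(0.5)
        assert tc.proportion[0, tc.roi_index("updated"), 0] == pytest.approx(0.5)

    def test_proportions_bounded_and_subadditive(self, quiet_session):
        parsed = detect_eye_events(quiet_session["gaze"])
        lab = assign_fixations_to_rois(parsed, quiet_session["trials"])
        tc = viewing_timecourse(lab, quiet_session["trials"], bin_ms=50.0)
        assert tc.proportion.min() >= 0.0 and tc.proportion.max() <= 1.0
        assert (tc.proportion.sum(axis=1) <= 1.0 + 1e-9).all()


class TestSmeTimecourse:
    def _tc(self, values):
        n_tr, n_bins = values.shape
        prop = np.zeros((n_tr, 1, n_bins))
        prop[:, 0, :] = values
        return ViewingTimecourse(prop, ["updated"], np.arange(n_tr), 50.0)

    def test_identical_classes_no_clusters(self, rng):
        vals = np.tile(np.linspace(0, 1, 30), (20, 1))
        labels = np.array(["remembered"] * 10 + ["forgotten"] * 10)
        res = behavioral_sme_timecourse(self._tc(vals), labels, roi="updated",
                                        n_perm=300, rng=rng)
        assert not res.any_significant()

    def test_injected_difference_detected(self, rng):
        vals = rng.uniform(0, 0.2, (60, 30))
        labels = np.array(["remembered"] * 30 + ["forgotten"] * 30)
        vals[:30, 10:21] += 0.3
        res = behavioral_sme_timecourse(self._tc(vals), labels, roi="updated",
                                        n_perm=500, rng=rng)
        sig = res.significant
        assert sig, "injected viewing difference not detected"
        covered = np.zeros(30, dtype=bool)
        for m in sig:
            covered |= m
        assert covered[10:21].mean() >= 0.8

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            behavioral_sme_timecourse(
                self._tc(np.zeros((4, 10))), np.array(["remembered"] * 4),
                roi="updated", rng=rng,
            )
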