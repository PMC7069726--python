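"""Saccade / fixation / blink parsing, ROI assignment, viewing timecourses.

Gaze samples (500 Hz) are parsed with the standard threshold triplet: a
candidate saccade must jointly exceed velocity (30 deg/s), acceleration
(8000 deg/s^2) and motion (0.15 deg displacement) thresholds.  Velocity and
acceleration are estimated by central differences after a 3-sample median
filter (robust to single-sample tracker noise).  Blinks come from pupil
dropouts and absorb everything within +/-25 ms (eyelid artifacts corrupt
the velocity trace at dropout edges).  Whatever remains below threshold is
a fixation; fixations shorter than 80 ms are kept in the event list but
flagged excluded from analysis.

Every sample belongs to exactly one event after parsing: the three event
kinds partition the record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from . import stats as tg_stats

__all__ = [
    "detect_eye_events",
    "assign_fixations_to_rois",
    "viewing_timecourse",
    "behavioral_sme_timecourse",
    "ViewingTimecourse",
]

ROI_PRIORITY = {"original": 0, "updated": 1, "repeated": 1, "other": 2, "other2": 2}


def detect_eye_events(
    samples: pd.DataFrame,
    motion: float = 0.15,
    velocity: float = 30.0,
    acceleration: float = 8000.0,
    min_fix_ms: float = 80.0,
    blink_pad_ms: float = 25.0,
    onset_floor: float = 10.0,
) -> pd.DataFrame:
    """Parse gaze samples into fixation / saccade / blink events.

    ``samples`` needs columns time_ms, x_deg, y_deg, pupil (pupil <= 0 or
    NaN marks signal loss).  Saccade onsets/offsets are refined by walking
    from the threshold crossing back/forward along the monotone flank of
    the velocity profile (down to ``onset_floor`` deg/s), which recovers
    the true start of the movement to within a sample or two.

    Returns a DataFrame with columns kind, onset_ms, offset_ms, x, y,
    excluded — sorted, non-overlapping, and tiling the record.
    """
    t = samples["time_ms"].to_numpy(dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing with >= 100 ms of data")
    if t[-1] - t[0] < 100.0:
        raise ValueError("need at least 100 ms of samples")
    dt_ms = float(np.median(np.diff(t)))
    fs = 1000.0 / dt_ms
    n = len(t)
    x = samples["x_deg"].to_numpy(dtype=float)
    y = samples["y_deg"].to_numpy(dtype=float)
    pupil = samples["pupil"].to_numpy(dtype=float)

    # blink mask from pupil dropout, padded
    dropout = ~np.isfinite(pupil) | (pupil <= 0)
    pad = int(round(blink_pad_ms / dt_ms))
    blink = dropout.copy()
    if pad > 0 and dropout.any():
        blink = np.convolve(dropout.astype(int), np.ones(2 * pad + 1), mode="same") > 0

    if blink.all():
        return pd.DataFrame([{
            "kind": "blink", "onset_ms": t[0], "offset_ms": t[-1] + dt_ms,
            "x": np.nan, "y": np.nan, "excluded": False,
        }])

    xm = signal.medfilt(x, 3)
    ym = signal.medfilt(y, 3)
    vx = np.gradient(xm, t / 1000.0)
    vy = np.gradient(ym, t / 1000.0)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t / 1000.0)

    sacc_mask = np.zeros(n, dtype=bool)
    cand = (speed > velocity) & ~blink
    for run0, run1 in _runs(cand):
        i0, i1 = run0, run1  # [i0, i1)
        while i0 > 0 and not blink[i0 - 1] and speed[i0 - 1] < speed[i0] \
                and speed[i0 - 1] > onset_floor:
            i0 -= 1
        # the velocity ramp crosses the floor inside the movement: take one
        # extra sample so the marked onset sits at the foot of the profile
        if i0 > 0 and not blink[i0 - 1] and speed[i0 - 1] <= onset_floor:
            i0 -= 1
        while i1 < n and not blink[i1] and speed[i1] < speed[i1 - 1] \
                and speed[i1] > onset_floor:
            i1 += 1
        disp = np.hypot(xm[min(i1, n - 1)] - xm[i0], ym[min(i1, n - 1)] - ym[i0])
        if disp >= motion and np.max(np.abs(accel[i0:i1])) >= acceleration:
            sacc_mask[i0:i1] = True
    sacc_mask &= ~blink

    rows = []
    kind = np.where(blink, 2, np.where(sacc_mask, 1, 0))
    names = {0: "fixation", 1: "saccade", 2: "blink"}
    for i0, i1 in _runs_of_labels(kind):
        k = names[kind[i0]]
        offset = t[i1] if i1 < n else t[-1] + dt_ms
        row = {"kind": k, "onset_ms": t[i0], "offset_ms": offset,
               "x": np.nan, "y": np.nan, "excluded": False}
        if k == "fixation":
            row["x"] = float(np.mean(x[i0:i1]))
            row["y"] = float(np.mean(y[i0:i1]))
            if offset - t[i0] < min_fix_ms:
                row["excluded"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def _runs(mask: np.ndarray):
    """(start, stop) half-open index runs of True."""
    d = np.diff(mask.astype(int), prepend=0, append=0)
    return zip(np.where(d == 1)[0], np.where(d == -1)[0])


def _runs_of_labels(labels: np.ndarray):
    change = np.where(np.diff(labels) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(labels)]])
    return zip(starts, stops)


def assign_fixations_to_rois(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    radius_deg: float = 6.0,
    edge_ms: float = 500.0,
) -> pd.DataFrame:
    """Label fixations with trial, condition, memory, ROI and window flags.

    A fixation belongs to the trial containing its onset; its ROI is the
    nearest of the trial's three circular ROIs whose center lies within
    ``radius_deg``, else "none" (exact distance ties break by role priority:
    original before updated/repeated before other).  ``in_analysis_window``
    is False within ``edge_ms`` of the trial edges (stimulus onset/offset
    transients).  Fixations outside every trial are labeled trial -1 and
    excluded.
    """
    fix = fixations[fixations.kind == "fixation"].copy() \
        if "kind" in fixations else fixations.copy()
    out = []
    for row in fix.itertuples():
        tr = trials[(trials.onset_ms <= row.onset_ms)
                    & (row.onset_ms < trials.offset_ms)]
        rec = row._asdict()
        rec.pop("Index", None)
        if len(tr) == 0:
            rec.update(trial=-1, condition="", memory="", roi="none",
                       in_analysis_window=False, excluded=True)
            out.append(rec)
            continue
        tr = tr.iloc[0]
        best_role, best_d = "none", np.inf
        for j in (1, 2, 3):
            role = tr[f"roi{j}_role"]
            d = float(np.hypot(row.x - tr[f"roi{j}_x"], row.y - tr[f"roi{j}_y"]))
            if d <= radius_deg and (
                d < best_d - 1e-12
                or (abs(d - best_d) <= 1e-12
                    and ROI_PRIORITY.get(role, 9) < ROI_PRIORITY.get(best_role, 9))
            ):
                best_role, best_d = role, d
        rec.update(
            trial=int(tr.trial), condition=tr.condition, memory=tr.memory,
            roi="other" if best_role == "other2" else best_role,
            in_analysis_window=bool(
                row.onset_ms >= tr.onset_ms + edge_ms
                and row.offset_ms <= tr.offset_ms - edge_ms
            ),
        )
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class ViewingTimecourse:
    proportion: np.ndarray   # (n_trials, n_rois, n_bins), in [0, 1]
    rois: list
    trial_ids: np.ndarray
    bin_ms: float

    def roi_index(self, roi: str) -> int:
        return self.rois.index(roi)


def viewing_timecourse(
    labeled: pd.DataFrame,
    trials: pd.DataFrame,
    bin_ms: float = 2.0,
    rois: list | None = None,
) -> ViewingTimecourse:
    """Fraction of each time bin spent fixating each ROI, per trial.

    Bins are relative to trial onset; the common trial length is the
    shortest trial.  Per (trial, bin) the proportions sum to at most 1
    (saccades, blinks and off-ROI gaps take the remainder).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if rois is None:
        rois = ["original", "updated", "repeated", "other", "none"]
    dur = float((trials.offset_ms - trials.onset_ms).min())
    n_bins = int(np.floor(dur / bin_ms))
    prop = np.zeros((len(trials), len(rois), n_bins))
    edges = np.arange(n_bins + 1) * bin_ms
    for ti, tr in enumerate(trials.itertuples()):
        sel = labeled[labeled.trial == tr.trial]
        if "excluded" in sel.columns:
            sel = sel[~sel.excluded.astype(bool)]
        for fx in sel.itertuples():
            if fx.roi not in rois:
                continue
            a = fx.onset_ms - tr.onset_ms
            b = fx.offset_ms - tr.onset_ms
            ri = rois.index(fx.roi)
            lo = np.clip(a, edges[:-1], edges[1:])
            hi = np.clip(b, edges[:-1], edges[1:])
            prop[ti, ri] += np.maximum(hi - lo, 0.0) / bin_ms
    return ViewingTimecourse(
        proportion=np.clip(prop, 0.0, 1.0), rois=list(rois),
        trial_ids=trials.trial.to_numpy(), bin_ms=bin_ms,
    )


def behavioral_sme_timecourse(
    tc: ViewingTimecourse,
    memory_labels: np.ndarray,
    roi: str = "updated",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    tail: str = "two",
) -> tg_stats.ClusterResult:
    """Remembered-vs-forgotten viewing difference, cluster-corrected in time.

    The per-bin statistic is the mean viewing-proportion difference on the
    given ROI; the null shuffles trial memory labels; clusters are
    contiguous time bins.
    """
    if rng is None:
        rng = np.random.default_rng()
    labels = np.asarray(memory_labels) == "remembered"
    if labels.all() or (~labels).all():
        raise ValueError("need both remembered and forgotten trials")
    values = tc.proportion[:, tc.roi_index(roi), :]
    observed, nulls = tg_stats.label_shuffle_nulls(values, labels, n_perm, rng)
    return tg_stats.cluster_from_nulls(observed, nulls, tail=tail)
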