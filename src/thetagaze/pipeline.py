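"""End-to-end orchestration: parse gaze, epoch by fixation class, run the
standard contrasts (retrieval, associative novelty, subsequent memory), and
emit a structured report.

A contrast compares two fixation classes defined by condition x ROI x
memory filters: retrieval pits fixations to the original vs the updated
object-location on Mismatch trials; associative novelty pits fixations to
the updated location on Mismatch trials against the repeated location on
Match trials (restricted to trials whose original location was later
remembered, so novelty is not confounded with forgetting); subsequent
memory splits original-location fixations by later memory outcome.

Each contrast can carry several measures: subsample-matched ITC difference
maps with cluster permutation inference, Watson-Williams phase-angle
comparisons at fixation onset, matched-N modulation-index difference maps
over the comodulogram grid, ERP-based phase-reset tests, and viewing
timecourses.  Every reported p-value is accompanied by its permutation
count, and the whole report is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eye_events, pac, phase_locking, stats as tg_stats
from .preprocess import extract_epochs
from .spectral import default_freqs, morlet_transform

__all__ = [
    "ContrastSpec",
    "standard_contrasts",
    "select_fixations",
    "run_contrast",
    "run_band_comparisons",
    "run_session_report",
]


@dataclass
class ContrastSpec:
    """Two fixation classes plus the measures to contrast them on."""

    name: str
    class_a: dict
    class_b: dict
    measures: tuple = ("itc", "phase_angle")
    window: tuple[float, float] = (-750.0, 750.0)
    band: tuple[float, float] = (4.0, 6.0)
    require_analysis_window: bool = True
    clean_window_ms: float = 0.0      # required clean pre/post margin
    clean_side: str = "post"          # which side the clean window guards
    exclude_after_updated: bool = False  # drop fixations preceded by one to
    #                                      the updated object-location
    phase_time_ms: float = 0.0        # where phase angles are read out
    phase_window: tuple[float, float] | None = None  # optional window readout
    pac_window: tuple[float, float] = (-50.0, 750.0)  # post-fixation coupling


def standard_contrasts() -> list[ContrastSpec]:
    return [
        ContrastSpec(
            "retrieval",
            class_a={"condition": "Mismatch", "roi": "original"},
            class_b={"condition": "Mismatch", "roi": "updated"},
            measures=("itc", "phase_angle"),
        ),
        ContrastSpec(
            "novelty",
            class_a={"condition": "Mismatch", "roi": "updated", "memory": "remembered"},
            class_b={"condition": "Match", "roi": "repeated", "memory": "remembered"},
            measures=("itc", "pac"),
            require_analysis_window=False,   # early fixations are the point
        ),
        ContrastSpec(
            "subsequent_memory",
            class_a={"roi": "original", "memory": "remembered"},
            class_b={"roi": "original", "memory": "forgotten"},
            measures=("itc",),
        ),
    ]


def select_fixations(
    labeled: pd.DataFrame,
    filters: dict,
    require_analysis_window: bool = True,
) -> pd.DataFrame:
    """Apply a condition/roi/memory filter to labeled fixations.

    Always drops parser-excluded fixations (< 80 ms or trial-less).
    """
    sel = labeled[~labeled.excluded.astype(bool)]
    if require_analysis_window and "in_analysis_window" in sel.columns:
        sel = sel[sel.in_analysis_window.astype(bool)]
    for key, val in filters.items():
        sel = sel[sel[key] == val]
    return sel


def apply_clean_window(
    labeled: pd.DataFrame,
    selected: pd.DataFrame,
    window_ms: float,
    side: str = "post",
) -> pd.DataFrame:
    """Restrict to fixations with an uninterrupted window of ``window_ms``.

    A clean *post* window requires the fixation itself to last at least
    ``window_ms``; a clean *pre* window requires the preceding fixation to
    last at least ``window_ms`` and to end within a saccade's reach
    (<= 80 ms) of this fixation's onset.  Only removes events, so analyzed
    counts are monotone non-increasing in ``window_ms``.
    """
    if window_ms <= 0:
        return selected
    if side == "post":
        return selected[selected.offset_ms - selected.onset_ms >= window_ms]
    if side != "pre":
        raise ValueError("clean_side must be 'pre' or 'post'")
    allfix = labeled.sort_values("onset_ms").reset_index(drop=True)
    keep = []
    for row in selected.itertuples():
        prev = allfix[allfix.offset_ms <= row.onset_ms + 1e-9]
        if len(prev) == 0:
            keep.append(False)
            continue
        p = prev.iloc[-1]
        keep.append(
            row.onset_ms - p.offset_ms <= 80.0
            and p.offset_ms - p.onset_ms >= window_ms
        )
    return selected[np.array(keep, dtype=bool)]


def exclude_preceded_by_updated(
    labeled: pd.DataFrame, selected: pd.DataFrame
) -> pd.DataFrame:
    """Drop fixations whose immediately preceding fixation (within the same
    trial) landed on the updated object-location."""
    allfix = labeled.sort_values("onset_ms").reset_index(drop=True)
    keep = []
    for row in selected.itertuples():
        prev = allfix[(allfix.onset_ms < row.onset_ms)
                      & (allfix.trial == row.trial)]
        keep.append(len(prev) == 0 or prev.iloc[-1].roi != "updated")
    return selected[np.array(keep, dtype=bool)]


def _excluded_ledger(labeled: pd.DataFrame, a: pd.DataFrame, b: pd.DataFrame) -> dict:
    return {
        "events_in": int(len(labeled)),
        "parser_excluded": int(labeled.excluded.astype(bool).sum()),
        "class_a": int(len(a)),
        "class_b": int(len(b)),
        "unassigned": int(len(labeled) - len(a) - len(b)
                          - labeled.excluded.astype(bool).sum()),
    }


def run_contrast(
    session: dict,
    spec: ContrastSpec,
    labeled: pd.DataFrame | None = None,
    itc_freqs: np.ndarray | None = None,
    phase_freqs: np.ndarray | None = None,
    amp_freqs: np.ndarray | None = None,
    n_perm: int = 500,
    n_draws: int = 20,
    n_surr: int = 200,
    decim: int = 4,
    alpha: float = 0.05,
    pac_mi_z_maps: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run one contrast on an in-memory session; returns a report fragment.

    ``session`` is the dict produced by :func:`thetagaze.synth.simulate_session`
    or :func:`thetagaze.synth.load_dataset` (keys: recording, gaze, trials).
    If ``labeled`` fixations are not supplied, the gaze record is parsed and
    labeled here.
    """
    if rng is None:
        rng = np.random.default_rng()
    if labeled is None:
        parsed = eye_events.detect_eye_events(session["gaze"])
        labeled = eye_events.assign_fixations_to_rois(parsed, session["trials"])
    a = select_fixations(labeled, spec.class_a, spec.require_analysis_window)
    b = select_fixations(labeled, spec.class_b, spec.require_analysis_window)
    if spec.clean_window_ms > 0:
        a = apply_clean_window(labeled, a, spec.clean_window_ms, spec.clean_side)
        b = apply_clean_window(labeled, b, spec.clean_window_ms, spec.clean_side)
    if spec.exclude_after_updated:
        a = exclude_preceded_by_updated(labeled, a)
        b = exclude_preceded_by_updated(labeled, b)
    for name, cls in (("A", a), ("B", b)):
        if len(cls) < 2:
            raise ValueError(
                f"contrast {spec.name!r}: class {name} empty after filters "
                f"{spec.class_a if name == 'A' else spec.class_b}"
            )

    rec = session["recording"]
    onsets = np.concatenate([a.onset_ms.to_numpy(), b.onset_ms.to_numpy()])
    is_a = np.zeros(len(onsets), dtype=bool)
    is_a[: len(a)] = True
    meta = pd.DataFrame({
        "is_a": is_a,
        "trial": np.concatenate([a.trial.to_numpy(), b.trial.to_numpy()])
        if "trial" in a.columns else -1,
    })
    epochs = extract_epochs(rec, onsets, window=spec.window, events=meta)
    is_a = epochs.events.is_a.to_numpy()
    if is_a.sum() < 2 or (~is_a).sum() < 2:
        raise ValueError(f"contrast {spec.name!r}: too few epochs after epoching")

    out: dict = {
        "name": spec.name,
        "counts": _excluded_ledger(labeled, a, b),
        "n_epochs": {"A": int(is_a.sum()), "B": int((~is_a).sum())},
        "n_perm": n_perm,
        "measures": {},
    }

    if "itc" in spec.measures or "phase_angle" in spec.measures:
        freqs = itc_freqs if itc_freqs is not None else default_freqs(1.0, 10.0, 15)
        tf = morlet_transform(epochs, freqs=freqs)
        phase = tf.phase[:, :, ::decim]
        times = tf.times_ms[::decim]

    trial_ids = (epochs.events.trial.to_numpy()
                 if "trial" in epochs.events.columns else None)
    trial_pure = trial_ids is not None and all(
        len(np.unique(is_a[trial_ids == t])) == 1 for t in np.unique(trial_ids)
    )

    if "itc" in spec.measures:
        # inference: condition-label permutation, blocked at the trial level
        # when condition is a trial property (overlapping within-trial
        # epochs stay together under the null); the N split is preserved,
        # so any count bias is common to observed and null.  Reporting:
        # ITC maps at matched N via random subsampling.
        clusters = tg_stats.cluster_permutation_test(
            [phase], [is_a], n_perm=n_perm, stat="itc_diff", tail="two",
            rng=rng, alpha=alpha,
            groups_per_subject=[trial_ids] if trial_pure else None,
        )
        itc_a, itc_b, diff = phase_locking.itc_contrast_subsampled(
            phase[is_a], phase[~is_a], n_draws=n_draws, rng=rng
        )
        out["measures"]["itc"] = {
            "freqs": freqs.tolist(), "times_ms": times.tolist(),
            "itc_a": itc_a.itc, "itc_b": itc_b.itc, "difference": diff,
            "clusters": clusters, "significant": clusters.any_significant(),
            "p_min": float(clusters.p_fwe.min()) if len(clusters.masks) else 1.0,
            "n_matched": itc_a.n_events,
        }

    if "phase_angle" in spec.measures:
        f_band = (freqs >= spec.band[0]) & (freqs <= spec.band[1])
        fi = int(np.argmax(f_band)) if f_band.any() else int(
            np.argmin(np.abs(freqs - np.mean(spec.band)))
        )
        if spec.phase_window is not None:
            lo, hi = spec.phase_window
            tsel = (times >= lo) & (times <= hi)
            ang = np.angle(np.exp(1j * phase[:, fi, :][:, tsel]).mean(axis=1))
            ti = int(np.argmin(np.abs(times - 0.5 * (lo + hi))))
        else:
            ti = int(np.argmin(np.abs(times - spec.phase_time_ms)))
            ang = phase[:, fi, ti]
        ang_a = ang[is_a]
        ang_b = ang[~is_a]
        f_obs, z_f, p = phase_locking.watson_williams_perm(
            ang_a, ang_b, n_perm=n_perm, rng=rng
        )
        out["measures"]["phase_angle"] = {
            "freq_hz": float(freqs[fi]), "time_ms": float(times[ti]),
            "summary_a": phase_locking.circular_mean_ci(ang_a, rng=rng),
            "summary_b": phase_locking.circular_mean_ci(ang_b, rng=rng),
            "watson_williams_f": f_obs, "z_f": z_f, "p": p, "p_min": p,
            "significant": p < 0.01,
        }

    if "pac" in spec.measures:
        out["measures"]["pac"] = _pac_contrast(
            epochs, is_a, spec,
            phase_freqs if phase_freqs is not None else np.geomspace(1.0, 10.0, 8),
            amp_freqs if amp_freqs is not None else np.arange(80.0, 201.0, 15.0),
            n_perm=n_perm, n_surr=n_surr, n_draws=n_draws, alpha=alpha, rng=rng,
            trial_ids=trial_ids, mi_z_maps=pac_mi_z_maps,
        )

    if "erp_reset" in spec.measures:
        out["measures"]["erp_reset"] = {
            cls: phase_locking.erp_power_reset(
                _subset_epochs(epochs, sel), n_perm=min(n_perm, 500), rng=rng
            )
            for cls, sel in (("A", is_a), ("B", ~is_a))
        }

    return out


def _subset_epochs(epochs, sel):
    from dataclasses import replace

    return replace(
        epochs, data=epochs.data[sel],
        events=None if epochs.events is None
        else epochs.events[sel].reset_index(drop=True),
    )


def _crop_window(epochs, window: tuple[float, float]) -> slice:
    times = epochs.times_ms
    sel = np.where((times >= window[0]) & (times <= window[1]))[0]
    return slice(int(sel[0]), int(sel[-1]) + 1)


def _mi_diag_sums(
    epochs, phase_freqs: np.ndarray, amp_freqs: np.ndarray, n_bins: int = 20,
    time_slice: slice = slice(None),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch phase-binned amplitude sums over the comodulogram grid.

    Returns ``S`` (n_pf, n_af, n_ep, n_bins) and counts ``C`` (n_pf, n_ep,
    n_bins); the MI of any epoch subset is then a cheap reduction, which is
    what makes label-permutation nulls for MI contrasts affordable.
    """
    tf_phase = morlet_transform(epochs, freqs=phase_freqs)
    tf_amp = morlet_transform(epochs, freqs=amp_freqs)
    amp = np.sqrt(tf_amp.power)[:, :, time_slice]
    n_ep = epochs.n_epochs
    s = np.empty((len(phase_freqs), len(amp_freqs), n_ep, n_bins))
    c = np.empty((len(phase_freqs), n_ep, n_bins))
    for pi in range(len(phase_freqs)):
        bins = pac._phase_bins(tf_phase.phase[:, pi, time_slice], n_bins)
        for k in range(n_ep):
            c[pi, k] = np.bincount(bins[k], minlength=n_bins)
            for ai in range(len(amp_freqs)):
                s[pi, ai, k] = np.bincount(
                    bins[k], weights=amp[k, ai], minlength=n_bins
                )
    return s, c


def _mi_maps_for_subset(s, c, subset) -> np.ndarray:
    sums = s[:, :, subset, :].sum(axis=2)              # (pf, af, bins)
    counts = c[:, subset, :].sum(axis=1)[:, None, :]   # (pf, 1, bins)
    return pac._mi_from_sums(sums, np.broadcast_to(counts, sums.shape))


def _pac_contrast(
    epochs, is_a, spec, phase_freqs, amp_freqs, n_perm, n_surr, n_draws,
    alpha, rng, trial_ids=None, mi_z_maps=False,
) -> dict:
    """Matched-N MI difference over the comodulogram grid, cluster-tested,
    plus surrogate-normalized MI_Z maps per class for reporting.

    Coupling is measured in the contrast's PAC window (post-fixation by
    default).  When each trial's fixations all fall in one class — the
    condition is a trial property — the permutation shuffles class labels
    across trials, so within-trial dependence between overlapping fixation
    epochs is preserved under the null; otherwise event labels shuffle.
    """
    win = _crop_window(epochs, spec.pac_window)
    s, c = _mi_diag_sums(epochs, phase_freqs, amp_freqs, time_slice=win)
    idx_a = np.where(is_a)[0]
    idx_b = np.where(~is_a)[0]
    n = min(len(idx_a), len(idx_b))

    def _diff(ia, ib, draws):
        acc = 0.0
        for _ in range(draws):
            sub_a = rng.choice(ia, size=min(n, len(ia)), replace=False)
            sub_b = rng.choice(ib, size=min(n, len(ib)), replace=False)
            acc = acc + (_mi_maps_for_subset(s, c, sub_a)
                         - _mi_maps_for_subset(s, c, sub_b))
        return acc / draws

    observed = _diff(idx_a, idx_b, n_draws)

    trial_pure = False
    if trial_ids is not None:
        trial_pure = all(
            len(np.unique(is_a[trial_ids == t])) == 1 for t in np.unique(trial_ids)
        )
    nulls = np.empty((n_perm,) + observed.shape)
    if trial_pure:
        trials_u = np.unique(trial_ids)
        trial_is_a = np.array(
            [bool(is_a[trial_ids == t][0]) for t in trials_u]
        )
        for i in range(n_perm):
            rng.shuffle(trial_is_a)
            lab = np.isin(trial_ids, trials_u[trial_is_a])
            nulls[i] = _diff(np.where(lab)[0], np.where(~lab)[0], 1)
    else:
        lab = is_a.copy()
        for i in range(n_perm):
            rng.shuffle(lab)
            nulls[i] = _diff(np.where(lab)[0], np.where(~lab)[0], 1)
    clusters = tg_stats.cluster_from_nulls(observed, nulls, tail="two", alpha=alpha)

    out = {
        "phase_freqs": phase_freqs.tolist(), "amp_freqs": amp_freqs.tolist(),
        "mi_difference": observed, "clusters": clusters,
        "significant": clusters.any_significant(),
        "p_min": float(clusters.p_fwe.min()) if len(clusters.masks) else 1.0,
        "n_matched": int(n), "trial_blocked": bool(trial_pure),
    }
    if mi_z_maps:
        for cls, sel in (("A", is_a), ("B", ~is_a)):
            com = pac.comodulogram_z(
                _subset_epochs(epochs, sel), phase_freqs=phase_freqs,
                amp_freqs=amp_freqs, n_surr=n_surr, rng=rng, condition=cls,
                min_epochs=2,
            )
            out[f"mi_z_{cls.lower()}"] = com.mi_z
    return out


def run_band_comparisons(
    epochs,
    bands: dict[str, tuple[float, float]] | None = None,
    amp_freqs: np.ndarray | None = None,
    n_freqs_per_band: int = 3,
    n_surr: int = 200,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> dict:
    """Compare coupling strength between slow-oscillation bands.

    For each band (defaults: low-theta 1-3 Hz, theta 4-6 Hz, fast
    theta/alpha 7-10 Hz) the band statistic per amplitude frequency is the
    maximum MI over the band's phase frequencies; between-band difference
    maps are cluster-tested against surrogate phase permutations shared
    across bands (so a genuinely band-specific coupling survives, identical
    maps give zero difference everywhere).
    """
    if rng is None:
        rng = np.random.default_rng()
    if bands is None:
        bands = {"low_theta": (1.0, 3.0), "theta": (4.0, 6.0),
                 "fast_theta_alpha": (7.0, 10.0)}
    if amp_freqs is None:
        amp_freqs = np.arange(80.0, 201.0, 15.0)

    tf_amp = morlet_transform(epochs, freqs=amp_freqs)
    amp = np.sqrt(tf_amp.power)
    n_ep = epochs.n_epochs
    perms = np.array([rng.permutation(n_ep) for _ in range(n_surr)])
    k_idx = np.arange(n_ep)

    band_obs: dict[str, np.ndarray] = {}
    band_surr: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        pfs = np.linspace(lo, hi, n_freqs_per_band)
        tf_phase = morlet_transform(epochs, freqs=pfs)
        obs = np.full((len(pfs), len(amp_freqs)), -np.inf)
        surr = np.full((n_surr, len(pfs), len(amp_freqs)), -np.inf)
        for pi in range(len(pfs)):
            bins = pac._phase_bins(tf_phase.phase[:, pi, :], pac.N_BINS_DEFAULT)
            n_t = bins.shape[1]
            onehot = np.zeros((n_ep, n_t, pac.N_BINS_DEFAULT))
            np.put_along_axis(onehot, bins[:, :, None], 1.0, axis=2)
            flat = onehot.transpose(1, 0, 2).reshape(n_t, -1)
            counts_total = onehot.sum(axis=(0, 1))
            for ai in range(len(amp_freqs)):
                sp = (amp[:, ai, :] @ flat).reshape(n_ep, n_ep, -1)
                obs[pi, ai] = pac._mi_from_sums(
                    sp[k_idx, k_idx].sum(axis=0), counts_total
                )
                surr_sums = sp[k_idx[None, :], perms].sum(axis=1)
                surr[:, pi, ai] = pac._mi_from_sums(
                    surr_sums, counts_total[None, :]
                )
        band_obs[name] = obs.max(axis=0)
        band_surr[name] = surr.max(axis=1)

    names = list(bands)
    comparisons = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            diff = band_obs[a] - band_obs[b]
            nulls = band_surr[a] - band_surr[b]
            # center the null: surrogate MI carries the same small-sample
            # offset in both bands, the difference null is exchangeable
            clusters = tg_stats.cluster_from_nulls(diff, nulls, tail="two",
                                                   alpha=alpha)
            comparisons[f"{a}_vs_{b}"] = {
                "difference": diff, "clusters": clusters,
                "significant": clusters.any_significant(),
            }
    return {
        "bands": {k: list(v) for k, v in bands.items()},
        "band_max_mi": {k: v for k, v in band_obs.items()},
        "comparisons": comparisons,
    }


def run_session_report(
    session: dict,
    contrasts: list[ContrastSpec] | None = None,
    seed: int = 0,
    n_perm: int = 500,
    alpha: float = 0.05,
    **kwargs,
) -> dict:
    """Parse, label, and run every contrast; return the full report dict.

    Deterministic given ``seed``.  Includes per-contrast event accounting
    and a top-level ``flags`` map naming every significant measure.
    Session-level flags are Bonferroni-corrected across the battery: a
    measure is flagged when its (already FWE-corrected within its own
    search space) p-value beats ``alpha / n_measures``, controlling the
    probability of any false flag across the whole report.
    """
    from . import __version__

    rng = np.random.default_rng(seed)
    if contrasts is None:
        contrasts = standard_contrasts()
    parsed = eye_events.detect_eye_events(session["gaze"])
    labeled = eye_events.assign_fixations_to_rois(parsed, session["trials"])

    report: dict = {
        "software": {"name": "thetagaze", "version": __version__},
        "seed": seed,
        "n_perm": n_perm,
        "alpha": alpha,
        "contrasts": {},
        "flags": {},
        "p_values": {},
    }
    for spec in contrasts:
        frag = run_contrast(
            session, spec, labeled=labeled, n_perm=n_perm, rng=rng, **kwargs
        )
        report["contrasts"][spec.name] = frag
        for mname, m in frag["measures"].items():
            if "p_min" in m:
                report["p_values"][f"{spec.name}.{mname}"] = float(m["p_min"])
    n_tests = max(len(report["p_values"]), 1)
    report["alpha_bonferroni"] = alpha / n_tests
    for key, p in report["p_values"].items():
        report["flags"][key] = bool(p < alpha / n_tests)
    return report
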