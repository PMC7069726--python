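"""Nonparametric cluster permutation inference, proportion tests, effect sizes.

The cluster test controls family-wise error over a time-frequency (or time,
or frequency) search space: a null distribution of the per-bin statistic is
built by permutation, each bin gets its own cluster-forming threshold (the
null 95th percentile one-tailed, 2.5/97.5th two-tailed), supra-threshold
bins are grouped into connected clusters (4-connectivity in 2-D, adjacency
in 1-D), and a cluster is significant when its summed statistic exceeds the
corresponding quantile of the null maximum-cluster-mass distribution.

Permutations for paired designs flip the condition assignment within each
subject (label exchange blocked at the subject level); event-level designs
shuffle event labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "ClusterResult",
    "EffectSize",
    "cluster_from_nulls",
    "cluster_permutation_test",
    "label_shuffle_nulls",
    "binomial_proportion_test",
    "hedges_g_dependent",
]


@dataclass
class ClusterResult:
    """Connected significant clusters with FWE-corrected p-values."""

    observed: np.ndarray                 # per-bin statistic
    masks: list = field(default_factory=list)        # boolean arrays, one per cluster
    masses: np.ndarray = None            # type: ignore[assignment]
    p_fwe: np.ndarray = None             # type: ignore[assignment]
    signs: np.ndarray = None             # +1 / -1 per cluster
    n_perm: int = 0
    tail: str = "two"
    alpha: float = 0.05

    @property
    def significant(self) -> list:
        """Masks of clusters with p_FWE < alpha."""
        return [m for m, p in zip(self.masks, self.p_fwe) if p < self.alpha]

    def any_significant(self) -> bool:
        return len(self.significant) > 0


def _connected_clusters(mask: np.ndarray) -> list[np.ndarray]:
    # default ndimage structure = 4-connectivity in 2-D, adjacency in 1-D
    lab, n = ndimage.label(mask)
    return [lab == i for i in range(1, n + 1)]


def _max_mass(stat: np.ndarray, thr_hi: np.ndarray, thr_lo: np.ndarray | None) -> float:
    best = 0.0
    for m in _connected_clusters(stat >= thr_hi):
        best = max(best, float(stat[m].sum()))
    if thr_lo is not None:
        for m in _connected_clusters(stat <= thr_lo):
            best = max(best, float(-stat[m].sum()))
    return best


def cluster_from_nulls(
    observed: np.ndarray,
    null_stats: np.ndarray,
    tail: str = "two",
    alpha: float = 0.05,
) -> ClusterResult:
    """Cluster inference given an observed statistic map and permutation nulls.

    Parameters
    ----------
    observed : ndarray
        Per-bin statistic, 1-D or 2-D.
    null_stats : ndarray, shape (n_perm, *observed.shape)
        The same statistic computed under each permutation.
    tail : {"one", "two"}
        One-tailed tests look only for positive excursions.
    """
    null_stats = np.asarray(null_stats)
    n_perm = null_stats.shape[0]
    if n_perm < 100:
        import warnings

        warnings.warn(f"only {n_perm} permutations; p-values will be coarse")
    if tail == "one":
        thr_hi = np.percentile(null_stats, 95.0, axis=0)
        thr_lo = None
    elif tail == "two":
        thr_hi = np.percentile(null_stats, 97.5, axis=0)
        thr_lo = np.percentile(null_stats, 2.5, axis=0)
    else:
        raise ValueError("tail must be 'one' or 'two'")

    masks, masses, signs = [], [], []
    for m in _connected_clusters(observed >= thr_hi):
        masks.append(m)
        masses.append(float(observed[m].sum()))
        signs.append(1)
    if thr_lo is not None:
        for m in _connected_clusters(observed <= thr_lo):
            masks.append(m)
            masses.append(float(-observed[m].sum()))
            signs.append(-1)

    null_max = np.array(
        [_max_mass(null_stats[i], thr_hi, thr_lo) for i in range(n_perm)]
    )
    p = np.array(
        [(1 + np.sum(null_max >= mass)) / (n_perm + 1) for mass in masses]
    )
    return ClusterResult(
        observed=observed, masks=masks, masses=np.array(masses), p_fwe=p,
        signs=np.array(signs), n_perm=n_perm, tail=tail, alpha=alpha,
    )


def blocked_label_nulls(
    values_per_subject: list[np.ndarray],
    labels_per_subject: list[np.ndarray],
    n_perm: int,
    rng: np.random.Generator,
    stat: str = "mean_diff",
    groups_per_subject: list[np.ndarray] | None = None,
    n_draws: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted group statistic maps, labels shuffled per block.

    Each subject (block) contributes event-level maps ``values``
    (n_events, *map_shape) with boolean ``labels`` (True = condition A).
    The group statistic is the across-subject mean of the per-subject
    condition difference; the null shuffles condition labels within each
    subject independently — observations never cross subjects.

    When the condition is a property of a coarser unit than the event
    (e.g. the trial a fixation belongs to), pass ``groups_per_subject``:
    labels are then shuffled across groups, keeping each group's events
    together, so dependence between events of one group (overlapping
    epochs) is preserved under the null.

    ``stat``: "mean_diff" (mean(A) - mean(B) per bin) or "itc_diff"
    (values are phase angles; per-subject ITC_A - ITC_B per bin).  ITC is
    biased by the event count, so for "itc_diff" both conditions are
    randomly subsampled to a common N, averaged over the same ``n_draws``
    draws for the observed statistic and for every permutation — equal
    draw counts keep observed and null exchangeable under H0.
    """
    observed = None
    nulls = None
    n_sub = len(values_per_subject)
    if n_sub == 0:
        raise ValueError("need at least one subject block")
    if groups_per_subject is None:
        groups_per_subject = [None] * n_sub
    for values, labels, groups in zip(
        values_per_subject, labels_per_subject, groups_per_subject
    ):
        values = np.asarray(values)
        labels = np.asarray(labels, dtype=bool)
        n_ev = values.shape[0]
        n_a = int(labels.sum())
        if n_a == 0 or n_a == n_ev:
            raise ValueError("each block needs events of both conditions")
        flat = values.reshape(n_ev, -1)
        if groups is not None:
            groups = np.asarray(groups)
            gids = np.unique(groups)
            glab = np.array([bool(labels[groups == g][0]) for g in gids])
            for g in gids:
                if len(np.unique(labels[groups == g])) != 1:
                    raise ValueError(
                        "group-level permutation requires label-pure groups"
                    )

        def _labels_for_row(i: int) -> np.ndarray:
            if i < 0:
                return labels
            if groups is None:
                lab = labels.copy()
                rng.shuffle(lab)
                return lab
            gl = glab.copy()
            rng.shuffle(gl)
            return np.isin(groups, gids[gl])

        if stat == "itc_diff":
            flat_c = np.exp(1j * flat)
            n_min = min(n_a, n_ev - n_a)
            rows = (n_perm + 1) * n_draws
            sel_a = np.zeros((rows, n_ev))
            sel_b = np.zeros((rows, n_ev))
            sizes = np.empty((rows, 1))
            for p in range(n_perm + 1):
                lab = _labels_for_row(-1 if p == 0 else p)
                ia = np.where(lab)[0]
                ib = np.where(~lab)[0]
                m = min(n_min, len(ia), len(ib))
                for d in range(n_draws):
                    i = p * n_draws + d
                    sel_a[i, rng.choice(ia, size=m, replace=False)] = 1.0
                    sel_b[i, rng.choice(ib, size=m, replace=False)] = 1.0
                    sizes[i] = m
            maps = (np.abs(sel_a @ flat_c) - np.abs(sel_b @ flat_c)) / sizes
            maps = maps.reshape(n_perm + 1, n_draws, -1).mean(axis=1)
            maps = maps.reshape((n_perm + 1,) + values.shape[1:])
            obs_map = maps[0]
            null_maps = maps[1:]
        elif stat == "mean_diff":
            total = flat.sum(axis=0)
            sel = np.zeros((n_perm + 1, n_ev))
            sel[0, labels] = 1.0
            for i in range(n_perm):
                sel[i + 1, _labels_for_row(i)] = 1.0
            counts_a = sel.sum(axis=1, keepdims=True)
            sum_a = sel @ flat
            sum_b = total[None, :] - sum_a
            maps = sum_a / counts_a - sum_b / (n_ev - counts_a)
            maps = maps.reshape((n_perm + 1,) + values.shape[1:])
            obs_map = maps[0]
            null_maps = maps[1:]
        else:
            raise ValueError(f"unknown stat {stat!r}")
        observed = obs_map if observed is None else observed + obs_map
        nulls = null_maps if nulls is None else nulls + null_maps
    return observed / n_sub, nulls / n_sub


def cluster_permutation_test(
    values_per_subject: list[np.ndarray],
    labels_per_subject: list[np.ndarray],
    n_perm: int = 1000,
    stat: str = "mean_diff",
    tail: str = "two",
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    groups_per_subject: list[np.ndarray] | None = None,
) -> ClusterResult:
    """Condition contrast with cluster FWE control, blocked at the subject
    level.

    Condition labels of individual events (or of label-pure event groups,
    e.g. trials — see :func:`blocked_label_nulls`) are permuted within each
    subject, never across subjects; the per-bin statistic is the
    across-subject mean condition difference (``stat="mean_diff"``) or ITC
    difference (``stat="itc_diff"``, values being phase maps).
    Single-block input gives the electrode-level test.
    """
    if rng is None:
        rng = np.random.default_rng()
    observed, nulls = blocked_label_nulls(
        values_per_subject, labels_per_subject, n_perm, rng, stat=stat,
        groups_per_subject=groups_per_subject,
    )
    return cluster_from_nulls(observed, nulls, tail=tail, alpha=alpha)


def label_shuffle_nulls(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted mean-difference maps for event-level designs.

    ``values`` is (n_events, *map_shape); ``labels`` a boolean array (True =
    class A).  Returns ``(observed, nulls)`` where the statistic is
    ``mean(A) - mean(B)`` per bin and each null shuffles event labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError("both classes must be non-empty")
    observed = values[labels].mean(axis=0) - values[~labels].mean(axis=0)
    nulls = np.empty((n_perm,) + values.shape[1:])
    lab = labels.copy()
    for i in range(n_perm):
        rng.shuffle(lab)
        nulls[i] = values[lab].mean(axis=0) - values[~lab].mean(axis=0)
    return observed, nulls


def binomial_proportion_test(n_sig: int, n_total: int, p0: float = 0.05) -> float:
    """Upper-tail exact binomial probability of >= ``n_sig`` significant units.

    ``p0`` is the chance rate of a significant electrode under the null
    (0.05 for the per-electrode permutation threshold).  Bonferroni
    multipliers across conditions/time windows are the caller's business.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_sig <= n_total:
        raise ValueError("need 0 <= n_sig <= n_total")
    return float(sps.binom.sf(n_sig - 1, n_total, p0))


@dataclass
class EffectSize:
    hedges_g: float
    n: int
    correction_j: float
    undefined: bool = False


def hedges_g_dependent(x: np.ndarray, y: np.ndarray) -> EffectSize:
    """Hedges' g for dependent samples.

    ``g = J * mean(x - y) / sd(x - y)`` with the small-sample correction
    ``J = 1 - 3 / (4(n - 1) - 1)``.  Degenerate zero-variance differences
    are flagged undefined rather than returning infinity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need paired 1-D samples of equal length n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    if sd == 0:
        if np.all(d == 0):
            return EffectSize(0.0, n, j)  # no effect, no spread
        return EffectSize(np.nan, n, j, undefined=True)
    return EffectSize(float(d.mean() / sd * j), n, j)
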