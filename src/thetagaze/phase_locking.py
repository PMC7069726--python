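"""Inter-trial phase coherence, circular statistics, and phase-reset tests.

ITC at a time-frequency point is the magnitude of the mean unit phasor
across events, ``ITC_ft = |sum_k exp(i*phi_ftk)| / N``: 1 means every event
showed the same oscillatory phase at that moment, while uniform phases give
an expected ITC of about ``sqrt(pi)/(2*sqrt(N))``.  Because that null level
shrinks with N, contrasts between conditions with unequal event counts are
biased; the subsampled contrast repeatedly draws the larger condition down
to the smaller N and averages.

Phase-angle comparisons use the Watson-Williams F (a circular analogue of
the two-sample t-test) whose significance is assessed by permuting group
labels; the standardized ``Z_F = (F_obs - mean(F_null)) / sd(F_null)`` is
reported alongside the exceedance p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats as tg_stats
from .preprocess import EpochSet
from .spectral import multitaper_psd

__all__ = [
    "ITCMap",
    "CircularSummary",
    "PhaseResetResult",
    "itc",
    "itc_contrast_subsampled",
    "circular_mean_ci",
    "rayleigh_test",
    "watson_williams_f",
    "watson_williams_perm",
    "erp_power_reset",
]


@dataclass
class ITCMap:
    itc: np.ndarray          # (..., n_freqs, n_times) or any shape, in [0, 1]
    n_events: int
    condition: str = ""


@dataclass
class CircularSummary:
    mean: float              # radians in (-pi, pi]
    r: float                 # resultant length
    ci95: tuple[float, float]
    n: int
    ci_undefined: bool = False


@dataclass
class PhaseResetResult:
    freqs: np.ndarray
    pre_power: np.ndarray
    post_power: np.ndarray
    contrast: np.ndarray     # log10 post - log10 pre, per frequency
    clusters: "tg_stats.ClusterResult"


def itc(phase: np.ndarray, condition: str = "") -> ITCMap:
    """ITC across the first (event) axis of a phase array."""
    phase = np.asarray(phase)
    n = phase.shape[0]
    if n < 2:
        raise ValueError("ITC needs at least 2 events")
    return ITCMap(
        itc=np.abs(np.exp(1j * phase).mean(axis=0)), n_events=n, condition=condition
    )


def itc_contrast_subsampled(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    n_draws: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[ITCMap, ITCMap, np.ndarray]:
    """ITC difference A - B at matched event counts.

    The larger condition is randomly subsampled (without replacement) to the
    smaller condition's N; ITC is computed per draw and averaged over
    ``n_draws`` draws (``n_draws=1`` gives the cheap single-draw mode).
    """
    if rng is None:
        rng = np.random.default_rng()
    phase_a, phase_b = np.asarray(phase_a), np.asarray(phase_b)
    n_a, n_b = phase_a.shape[0], phase_b.shape[0]
    if min(n_a, n_b) < 2:
        raise ValueError("both conditions need at least 2 events")
    n = min(n_a, n_b)

    def _mean_sub(phase: np.ndarray) -> np.ndarray:
        if phase.shape[0] == n:
            return itc(phase).itc
        acc = 0.0
        for _ in range(n_draws):
            idx = rng.choice(phase.shape[0], size=n, replace=False)
            acc = acc + itc(phase[idx]).itc
        return acc / n_draws

    itc_a = _mean_sub(phase_a)
    itc_b = _mean_sub(phase_b)
    return (
        ITCMap(itc_a, n, "A"), ITCMap(itc_b, n, "B"), itc_a - itc_b,
    )


def _circ_mean_r(angles: np.ndarray) -> tuple[float, float]:
    z = np.exp(1j * np.asarray(angles)).mean()
    return float(np.angle(z)), float(np.abs(z))


def circular_mean_ci(
    angles: np.ndarray,
    rng: np.random.Generator | None = None,
    n_boot: int = 1000,
) -> CircularSummary:
    """Circular mean with a dispersion-based 95% confidence interval.

    Fisher's circular dispersion ``delta = (1 - rho2) / (2 R^2)`` gives the
    circular standard error ``sqrt(delta / n)``; the CI is
    ``mean +/- asin(1.96 * se)``.  When the sample is nearly uniform
    (R < 0.1) the dispersion formula is unstable and a bootstrap CI over the
    resampled circular means is used instead; if even that fails (R ~ 0)
    the CI is flagged undefined.
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n < 3:
        raise ValueError("need at least 3 angles")
    mean, r = _circ_mean_r(angles)
    if r < 1e-6:
        return CircularSummary(mean, r, (np.nan, np.nan), n, ci_undefined=True)
    if r < 0.1:
        if rng is None:
            rng = np.random.default_rng()
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = _circ_mean_r(angles[rng.integers(0, n, size=n)])[0]
        dev = np.angle(np.exp(1j * (boots - mean)))
        lo, hi = np.percentile(dev, [2.5, 97.5])
        return CircularSummary(mean, r, (mean + lo, mean + hi), n)
    rho2 = float(np.abs(np.exp(2j * (angles - mean)).mean()))
    delta = (1.0 - rho2) / (2.0 * r ** 2)
    se = np.sqrt(delta / n)
    arg = 1.959964 * se
    if arg >= 1.0:
        return CircularSummary(mean, r, (np.nan, np.nan), n, ci_undefined=True)
    half = float(np.arcsin(arg))
    return CircularSummary(mean, r, (mean - half, mean + half), n)


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: ``Z = n R^2`` and its p-value."""
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n < 5:
        raise ValueError("Rayleigh test needs n >= 5")
    from pingouin import circ_rayleigh

    z, p = circ_rayleigh(angles)
    return float(z), float(p)


def _kappa_from_r(r: float) -> float:
    # standard maximum-likelihood inversion of the mean resultant length
    r = min(r, 1.0 - 1e-12)
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


def watson_williams_f(angles_a: np.ndarray, angles_b: np.ndarray) -> float:
    """Watson-Williams F statistic for equality of two circular means."""
    a, b = np.asarray(angles_a), np.asarray(angles_b)
    n1, n2 = len(a), len(b)
    n = n1 + n2
    r1 = n1 * _circ_mean_r(a)[1]
    r2 = n2 * _circ_mean_r(b)[1]
    r = n * _circ_mean_r(np.concatenate([a, b]))[1]
    denom = n - (r1 + r2)
    if denom <= 1e-12:
        raise ValueError("degenerate samples (all angles identical)")
    rw = (r1 + r2) / n
    kappa = _kappa_from_r(rw)
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    return float(correction * (n - 2) * (r1 + r2 - r) / denom)


def watson_williams_perm(
    angles_a: np.ndarray,
    angles_b: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Watson-Williams F with permutation significance.

    Returns ``(F, Z_F, p)``: the observed F, its z-score against the
    permutation null (group labels shuffled), and the exceedance p-value.
    """
    if rng is None:
        rng = np.random.default_rng()
    a, b = np.asarray(angles_a, dtype=float), np.asarray(angles_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need n >= 5 per group")
    f_obs = watson_williams_f(a, b)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rng.shuffle(pooled)
        null[i] = watson_williams_f(pooled[:n1], pooled[n1:])
    sd = null.std()
    z_f = float((f_obs - null.mean()) / sd) if sd > 0 else np.nan
    p = float((1 + np.sum(null >= f_obs)) / (n_perm + 1))
    return f_obs, z_f, p


def erp_power_reset(
    epochs: EpochSet,
    pre_window: tuple[float, float] = (-750.0, 50.0),
    post_window: tuple[float, float] = (-50.0, 750.0),
    fmin: float = 1.0,
    fmax: float = 30.0,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
    tail: str = "one",
) -> PhaseResetResult:
    """Phase-reset test: post- vs pre-fixation power of the average ERP.

    A phase reset realigns ongoing oscillations to the fixation, so the
    across-event average (the ERP) gains oscillatory power after the event
    relative to before.  Pre- and post-window multitaper spectra of the ERP
    are contrasted per frequency (log ratio); the null rebuilds the ERP
    after circularly shifting each epoch by a random lag (destroying any
    event-locked alignment while preserving the spectral content), and the
    contrast is cluster-corrected over frequency.
    """
    if rng is None:
        rng = np.random.default_rng()
    if epochs.n_epochs < 10:
        raise ValueError("need at least 10 epochs")
    data = epochs.trimmed()
    times = epochs.times_ms
    for w in (pre_window, post_window):
        if w[0] < times[0] - 1e-9 or w[1] > times[-1] + 1e-9:
            raise ValueError(f"window {w} exceeds epoch bounds")
    pre_sel = (times >= pre_window[0]) & (times <= pre_window[1])
    post_sel = (times >= post_window[0]) & (times <= post_window[1])

    def _contrast(eps: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        erp = eps.mean(axis=0)
        pre = multitaper_psd(erp[pre_sel], epochs.fs, fmin=fmin, fmax=fmax)
        post = multitaper_psd(erp[post_sel], epochs.fs, fmin=fmin, fmax=fmax)
        return pre.freqs, pre.power, post.power, np.log10(post.power) - np.log10(pre.power)

    freqs, pre_p, post_p, obs = _contrast(data)
    n_t = data.shape[1]
    nulls = np.empty((n_perm, len(freqs)))
    for i in range(n_perm):
        shifts = rng.integers(0, n_t, size=data.shape[0])
        rolled = np.empty_like(data)
        for k, s in enumerate(shifts):
            rolled[k] = np.roll(data[k], s)
        nulls[i] = _contrast(rolled)[3]
    clusters = tg_stats.cluster_from_nulls(obs, nulls, tail=tail)
    return PhaseResetResult(freqs, pre_p, post_p, obs, clusters)
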