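"""Theta-gamma phase-amplitude coupling with surrogate normalization.

The modulation index (MI) bins gamma amplitude by theta phase (20 bins of
18 degrees), normalizes the mean-amplitude-per-bin distribution P to sum to
one, and measures its Kullback-Leibler distance from uniform scaled to
[0, 1]: ``MI = D_KL(P, U) / log(N_bins)``.  MI is 0 for a uniform
distribution and 1 when all amplitude concentrates in a single bin.

Because fixation epochs are short, raw MI is noisy and biased; MI_Z
standardizes it against a surrogate distribution built by re-pairing each
epoch's amplitude with the phase series of a randomly permuted epoch
(within condition), preserving everything about both series except their
temporal alignment: ``MI_Z = (MI_obs - mean_surr) / sd_surr``.

Waveform-shape confound control: non-sinusoidal theta (sharp peaks or
troughs, rise/decay asymmetry) can masquerade as coupling, so per-fixation
waveform features are regressed against trial-level MI_Z and the residuals
serve as a shape-adjusted coupling measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochSet
from .spectral import morlet_transform

__all__ = [
    "AmplitudeByPhase",
    "ComodulogramZ",
    "AdjustedPAC",
    "modulation_index",
    "mi_from_distribution",
    "comodulogram_z",
    "pairwise_binned_amplitude",
    "select_theta_frequency",
    "waveform_features",
    "waveform_feature_table",
    "trial_mi_z",
    "adjust_pac_for_waveform",
]

N_BINS_DEFAULT = 20


@dataclass
class AmplitudeByPhase:
    edges: np.ndarray        # n_bins + 1 phase-bin edges in (-pi, pi]
    p: np.ndarray            # normalized mean amplitude per bin, sums to 1
    mi: float                # in [0, 1]
    counts: np.ndarray = None  # type: ignore[assignment]


@dataclass
class ComodulogramZ:
    mi_z: np.ndarray         # (n_phase_freqs, n_amp_freqs)
    mi_obs: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    n_surrogates: int
    condition: str = ""


def mi_from_distribution(p: np.ndarray) -> float:
    """MI of a normalized amplitude-by-phase distribution (0*log0 = 0)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    nz = p > 0
    d_kl = float(np.sum(p[nz] * np.log(p[nz] * n)))
    return d_kl / np.log(n)


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_BINS_DEFAULT
) -> AmplitudeByPhase:
    """Bin amplitude by phase, normalize, and compute MI.

    Empty bins contribute zero to the KL sum; an all-zero amplitude series
    has no distribution to speak of and raises.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    if not np.any(amplitude > 0):
        raise ValueError("amplitude is identically zero")
    idx = _phase_bins(phase, n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    p = means / means.sum()
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return AmplitudeByPhase(edges=edges, p=p, mi=mi_from_distribution(p), counts=counts)


def _phase_bins(phase: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def pairwise_binned_amplitude(
    phase_bins: np.ndarray, amplitude: np.ndarray, n_bins: int = N_BINS_DEFAULT
) -> tuple[np.ndarray, np.ndarray]:
    """All epoch-pair binned amplitude sums, the surrogate workhorse.

    Given per-epoch phase-bin indices (n_epochs, n_times) and amplitudes
    (n_epochs, n_times), returns ``(S, C)`` where ``S[k, j, b]`` is the
    amplitude of epoch ``k`` summed over the samples where epoch ``j``'s
    phase fell in bin ``b``, and ``C[j, b]`` are the per-epoch bin counts.
    Any surrogate pairing of amplitude epochs with permuted phase epochs is
    then a cheap gather over ``S``; total bin counts are permutation
    invariant (every permutation uses each phase epoch exactly once).
    """
    n_ep, n_t = phase_bins.shape
    onehot = np.zeros((n_ep, n_t, n_bins))
    np.put_along_axis(onehot, phase_bins[:, :, None], 1.0, axis=2)
    # S[k, j*b] = amplitude[k] . onehot[j, :, b]
    s = amplitude @ onehot.transpose(1, 0, 2).reshape(n_t, n_ep * n_bins)
    counts = onehot.sum(axis=1)
    return s.reshape(n_ep, n_ep, n_bins), counts


def _mi_from_sums(sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Vectorized MI over leading axes of (..., n_bins) sum/count arrays."""
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    p = means / means.sum(axis=-1, keepdims=True)
    n = p.shape[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p * n), 0.0)
    return terms.sum(axis=-1) / np.log(n)


def comodulogram_z(
    epochs: EpochSet,
    phase_freqs: np.ndarray | None = None,
    amp_freqs: np.ndarray | None = None,
    n_surr: int = 1000,
    rng: np.random.Generator | None = None,
    n_bins: int = N_BINS_DEFAULT,
    wave_number: float = 5.0,
    condition: str = "",
    min_epochs: int = 10,
) -> ComodulogramZ:
    """Surrogate-normalized comodulogram over (phase freq x amplitude freq).

    Observed MI concatenates all epochs of the condition; each surrogate
    re-pairs every amplitude epoch with a randomly permuted phase epoch and
    recomputes MI, giving a null that preserves within-epoch structure.
    Cells with zero surrogate spread are flagged NaN.
    """
    if rng is None:
        rng = np.random.default_rng()
    if phase_freqs is None:
        phase_freqs = np.geomspace(1.0, 10.0, 10)
    if amp_freqs is None:
        amp_freqs = np.arange(80.0, 201.0, 10.0)
    if epochs.n_epochs < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs, got {epochs.n_epochs}")

    tf_phase = morlet_transform(epochs, freqs=phase_freqs, wave_number=wave_number)
    tf_amp = morlet_transform(epochs, freqs=amp_freqs, wave_number=wave_number)
    amp = np.sqrt(tf_amp.power)  # (n_ep, n_af, n_t)
    n_ep = epochs.n_epochs

    perms = np.array([rng.permutation(n_ep) for _ in range(n_surr)])
    k_idx = np.arange(n_ep)
    mi_obs = np.empty((len(phase_freqs), len(amp_freqs)))
    mi_z = np.empty_like(mi_obs)
    for pi in range(len(phase_freqs)):
        bins = _phase_bins(tf_phase.phase[:, pi, :], n_bins)
        n_t = bins.shape[1]
        onehot = np.zeros((n_ep, n_t, n_bins))
        np.put_along_axis(onehot, bins[:, :, None], 1.0, axis=2)
        flat = onehot.transpose(1, 0, 2).reshape(n_t, n_ep * n_bins)
        counts_total = onehot.sum(axis=(0, 1))
        for ai in range(len(amp_freqs)):
            s = (amp[:, ai, :] @ flat).reshape(n_ep, n_ep, n_bins)
            obs = _mi_from_sums(s[k_idx, k_idx].sum(axis=0), counts_total)
            surr_sums = s[k_idx[None, :], perms].sum(axis=1)  # (n_surr, n_bins)
            surr = _mi_from_sums(surr_sums, counts_total[None, :])
            sd = surr.std()
            mi_obs[pi, ai] = obs
            mi_z[pi, ai] = (obs - surr.mean()) / sd if sd > 0 else np.nan
    return ComodulogramZ(
        mi_z=mi_z, mi_obs=mi_obs, phase_freqs=np.asarray(phase_freqs),
        amp_freqs=np.asarray(amp_freqs), n_surrogates=n_surr, condition=condition,
    )


def select_theta_frequency(
    comodulograms: list[ComodulogramZ], band: tuple[float, float] = (4.0, 6.0)
) -> float:
    """Theta frequency with the greatest |MI_Z| in the band, pooled across
    conditions; exact ties go to the lowest frequency."""
    if not comodulograms:
        raise ValueError("no comodulograms given")
    freqs = comodulograms[0].phase_freqs
    for c in comodulograms[1:]:
        if not np.array_equal(c.phase_freqs, freqs):
            raise ValueError("comodulograms must share the phase-frequency grid")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("band outside the frequency grid")
    pooled = np.max(
        [np.nanmax(np.abs(c.mi_z), axis=1) for c in comodulograms], axis=0
    )
    band_vals = pooled[in_band]
    band_freqs = freqs[in_band]
    return float(band_freqs[np.argmax(band_vals)])  # argmax takes first = lowest


def waveform_features(
    epoch: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 10.0),
    sharp_ms: float = 2.0,
) -> dict:
    """Shape features of the theta-filtered waveform of one epoch.

    The epoch is band-passed (4th-order Butterworth, zero-phase), peaks and
    troughs located, and per-epoch averages extracted: peak/trough
    sharpness (mean absolute amplitude change ``sharp_ms`` before and after
    each extremum), rise/decay asymmetry (log of the ratio of trough-to-peak
    rise time over peak-to-trough decay time), analytic amplitude and the
    Hilbert phase at the epoch's reference sample (its midpoint, i.e. the
    fixation onset for symmetric windows).
    """
    x = np.asarray(epoch, dtype=float)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x)
    analytic = signal.hilbert(xf)
    amp_env = np.abs(analytic)
    phase = np.angle(analytic)

    k = max(1, int(round(sharp_ms * fs / 1000.0)))
    peaks, _ = signal.find_peaks(xf)
    troughs, _ = signal.find_peaks(-xf)
    peaks = peaks[(peaks >= k) & (peaks < len(xf) - k)]
    troughs = troughs[(troughs >= k) & (troughs < len(xf) - k)]
    if len(peaks) == 0 or len(troughs) == 0:
        raise ValueError("no extrema found in the filtered waveform")

    def _sharp(idx: np.ndarray) -> float:
        return float(np.mean(
            (np.abs(xf[idx] - xf[idx - k]) + np.abs(xf[idx] - xf[idx + k])) / 2.0
        ))

    ext = np.sort(np.concatenate([peaks, troughs]))
    is_peak = np.isin(ext, peaks)
    rises, decays = [], []
    for i in range(len(ext) - 1):
        dt = (ext[i + 1] - ext[i]) / fs
        if not is_peak[i] and is_peak[i + 1]:
            rises.append(dt)
        elif is_peak[i] and not is_peak[i + 1]:
            decays.append(dt)
    asym = (
        float(np.log(np.mean(rises) / np.mean(decays)))
        if rises and decays else 0.0
    )
    mid = len(x) // 2
    return {
        "power": float(np.mean(amp_env ** 2)),
        "amplitude": float(np.mean(amp_env)),
        "phase": float(phase[mid]),
        "s_peak": _sharp(peaks),
        "s_trough": _sharp(troughs),
        "asym": asym,
    }


def waveform_feature_table(
    epochs: EpochSet,
    band: tuple[float, float] = (1.0, 10.0),
    conditions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-epoch waveform features, with phase deviation split into sin/cos.

    The phase-deviation regressors are ``sin``/``cos`` of each epoch's
    Hilbert phase minus the circular mean phase of its condition (one pooled
    mean if no conditions are given) — the single-trial phase-locking
    estimate, linearized for regression.
    """
    data = epochs.trimmed()
    rows = [waveform_features(data[i], epochs.fs, band=band)
            for i in range(epochs.n_epochs)]
    df = pd.DataFrame(rows)
    if conditions is None:
        conditions = np.zeros(len(df), dtype=int)
    conditions = np.asarray(conditions)
    dev = np.empty(len(df))
    for c in np.unique(conditions):
        sel = conditions == c
        mean_phase = np.angle(np.exp(1j * df.phase[sel].to_numpy()).mean())
        dev[sel] = np.angle(np.exp(1j * (df.phase[sel].to_numpy() - mean_phase)))
    df["sin_theta"] = np.sin(dev)
    df["cos_theta"] = np.cos(dev)
    return df


def trial_mi_z(
    epochs: EpochSet,
    phase_freq: float,
    amp_freqs: np.ndarray | None = None,
    n_surr: int = 200,
    rng: np.random.Generator | None = None,
    n_bins: int = N_BINS_DEFAULT,
    wave_number: float = 5.0,
) -> np.ndarray:
    """Trial-level MI_Z at one theta frequency, gamma-band averaged.

    Each epoch's MI pairs its own phase and (band-mean) gamma amplitude;
    surrogates substitute the phase series of other, randomly drawn epochs.
    """
    if rng is None:
        rng = np.random.default_rng()
    if amp_freqs is None:
        amp_freqs = np.arange(80.0, 201.0, 20.0)
    tf_phase = morlet_transform(epochs, freqs=np.array([phase_freq]),
                                wave_number=wave_number)
    tf_amp = morlet_transform(epochs, freqs=amp_freqs, wave_number=wave_number)
    amp = np.sqrt(tf_amp.power).mean(axis=1)  # (n_ep, n_t)
    bins = _phase_bins(tf_phase.phase[:, 0, :], n_bins)
    n_ep = epochs.n_epochs
    s, counts = pairwise_binned_amplitude(bins, amp, n_bins)
    out = np.empty(n_ep)
    for k in range(n_ep):
        obs = _mi_from_sums(s[k, k], counts[k])
        others = np.delete(np.arange(n_ep), k)
        draw = rng.choice(others, size=min(n_surr, len(others)), replace=n_surr > len(others))
        surr = _mi_from_sums(s[k, draw], counts[draw])
        sd = surr.std()
        out[k] = (obs - surr.mean()) / sd if sd > 0 else np.nan
    return out


@dataclass
class AdjustedPAC:
    raw: np.ndarray
    adjusted: np.ndarray     # residuals of the full model
    reports: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)


DEFAULT_FEATURE_SETS = {
    "Power": ["power"],
    "Sin": ["sin_theta"],
    "Cos": ["cos_theta"],
    "S_peak": ["s_peak"],
    "S_trough": ["s_trough"],
    "Asym": ["asym"],
    "Full": ["power", "sin_theta", "cos_theta", "s_peak", "s_trough", "asym"],
}


def adjust_pac_for_waveform(
    mi_z: np.ndarray,
    features: pd.DataFrame,
    feature_sets: dict[str, list[str]] | None = None,
) -> AdjustedPAC:
    """Regress trial MI_Z on waveform features; residualize the full model.

    One ordinary-least-squares regression per feature set, each reported
    with its overall F test; the adjusted coupling measure is the residual
    of the "Full" model.  Constant or collinear columns are dropped with a
    warning rather than crashing the fit.
    """
    import warnings

    import statsmodels.api as sm

    if feature_sets is None:
        feature_sets = DEFAULT_FEATURE_SETS
    mi_z = np.asarray(mi_z, dtype=float)
    if len(mi_z) < 10:
        raise ValueError("need at least 10 trials")
    if len(mi_z) != len(features):
        raise ValueError("one feature row per trial required")

    usable = {}
    dropped = []
    for col in set(c for cols in feature_sets.values() for c in cols):
        v = features[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or v.std() == 0:
            dropped.append(col)
            warnings.warn(f"feature {col!r} constant or non-finite; dropped")
        else:
            usable[col] = v

    reports = {}
    adjusted = mi_z.copy()
    for name, cols in feature_sets.items():
        cols_u = [c for c in cols if c in usable]
        if not cols_u:
            reports[name] = {"f": np.nan, "p": np.nan, "coefs": {}, "dropped": cols}
            continue
        X = sm.add_constant(np.column_stack([usable[c] for c in cols_u]))
        fit = sm.OLS(mi_z, X).fit()
        reports[name] = {
            "f": float(fit.fvalue), "p": float(fit.f_pvalue),
            "coefs": dict(zip(["const"] + cols_u, map(float, fit.params))),
            "dropped": [c for c in cols if c not in cols_u],
        }
        if name == "Full":
            adjusted = np.asarray(fit.resid)
    return AdjustedPAC(raw=mi_z, adjusted=adjusted, reports=reports, dropped=dropped)
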