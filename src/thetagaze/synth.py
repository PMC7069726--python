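"""Joint LFP + gaze + trial-structure simulator with known ground truth.

The generator emulates the signal structure the analysis chain assumes in a
hippocampal object-location memory task:

* a 1/f-background LFP (Gaussian noise with power spectrum
  ``P(f) = 10**offset * f**-exponent``), plus a theta sinusoid (default 5 Hz)
  whose instantaneous phase is stored exactly, plus a gamma carrier (default
  90 Hz) whose amplitude follows the normalized cosine law
  ``A_g * (1 + d*cos(theta_phase - coupling_phase)) / (1 + d)`` so that
  ``d = 1`` drives the gamma envelope to zero at the anti-preferred phase;
* fixation onsets drawn by thinning a Poisson stream against a von Mises
  density around each condition's preferred theta phase (``kappa = 0`` gives
  uniform phases, large ``kappa`` concentrates onsets at the preferred
  phase) while preserving renewal-like inter-fixation statistics;
* 500 Hz gaze samples whose saccades have raised-cosine velocity profiles
  exceeding the standard detection thresholds (velocity >= 100 deg/s, peak
  acceleration >= 8000 deg/s^2), fixation jitter well below the 0.15 deg
  motion threshold, and blinks emitted as pupil dropouts;
* a trial table (half Match / half Mismatch, three ROI centers on an
  equilateral triangle) with per-trial memory-outcome labels.

Phase convention throughout: 0 rad = theta peak, +/-pi = trough.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0

from .preprocess import ContinuousRecording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_lfp",
    "simulate_fixation_stream",
    "simulate_gaze",
    "simulate_session",
    "make_dataset",
    "load_dataset",
]

@dataclass
class SimulationConfig:
    """Parameters of a synthetic recording session.

    Durations are seconds, frequencies Hz, angles radians, amplitudes in the
    (arbitrary) signal units of the LFP.
    """

    duration_s: float = 120.0
    fs: float = 500.0
    aperiodic_offset: float = 2.0
    aperiodic_exponent: float = 2.0
    theta_freq: float = 5.0
    theta_freq_sd: float = 0.5           # slow frequency wander (OU), Hz
    theta_freq_tau_s: float = 0.5        # OU correlation time
    theta_amp: float = 0.4
    gamma_freq: float = 90.0
    gamma_amp: float = 0.12
    coupling_phase: float = 0.0          # theta phase of maximal gamma amplitude
    coupling_depth: float = 0.0          # in [0, 1]
    coupling_depth_by_condition: dict[str, float] | None = None
    n_trials: int = 24
    fixation_rate: float = 4.0           # accepted fixations per second
    fixation_duration_ms: tuple[float, float] = (90.0, 180.0)
    kappa_by_condition: dict[str, float] = field(
        default_factory=lambda: {"Match": 0.0, "Mismatch": 0.0}
    )
    preferred_phase_by_condition: dict[str, float] = field(
        default_factory=lambda: {"Match": 0.0, "Mismatch": 0.0}
    )
    p_remember: float = 0.5
    p_blink: float = 0.05                # per eligible (long) fixation
    jitter_deg: float = 0.02             # fixation-position noise sd
    roi_distance_deg: float = 12.0       # triangle side between ROI centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.gamma_freq:
            raise ValueError(
                f"fs={self.fs} too low for gamma_freq={self.gamma_freq} "
                "(need fs > 2*gamma_freq)"
            )
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError("coupling_depth must lie in [0, 1]")
        if self.coupling_depth_by_condition is not None:
            for v in self.coupling_depth_by_condition.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("coupling depths must lie in [0, 1]")
        for k in self.kappa_by_condition.values():
            if k < 0:
                raise ValueError("von Mises kappa must be >= 0")
        if not 0.0 <= self.p_remember <= 1.0:
            raise ValueError("p_remember must lie in [0, 1]")
        if self.fixation_duration_ms[0] < 80.0:
            raise ValueError("fixation durations must be >= 80 ms")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["fixation_duration_ms"] = list(self.fixation_duration_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "fixation_duration_ms" in d:
            d["fixation_duration_ms"] = tuple(d["fixation_duration_ms"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    true_theta_phase: np.ndarray        # radians per LFP sample
    true_coupling_phase: float
    true_coupling_depth: float
    fs: float
    trials: pd.DataFrame                # trial, onset_ms, offset_ms, condition, memory, ROI geometry
    true_fixation_phases: np.ndarray = None  # type: ignore[assignment]
    condition_labels: np.ndarray = None      # type: ignore[assignment]
    memory_labels: np.ndarray = None         # per trial

    def phase_at(self, t_ms: np.ndarray | float) -> np.ndarray:
        idx = np.clip(
            np.round(np.asarray(t_ms) * self.fs / 1000.0).astype(int),
            0, len(self.true_theta_phase) - 1,
        )
        return self.true_theta_phase[idx]


def _make_trials(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Contiguous trials tiling the session; half Match, half Mismatch.

    Each trial gets three ROI centers on an equilateral triangle (random
    rotation, side ``roi_distance_deg``).  On Mismatch trials the roles are
    original / updated / other; on Match trials repeated / other / other.
    """
    n = config.n_trials
    dur_ms = 1000.0 * config.duration_s / n
    conditions = np.array(
        ["Match", "Mismatch"] * ((n + 1) // 2), dtype=object
    )[:n]
    rng.shuffle(conditions)
    memory = np.where(
        rng.uniform(size=n) < config.p_remember, "remembered", "forgotten"
    )
    rows = []
    r_circ = config.roi_distance_deg / np.sqrt(3.0)
    for i in range(n):
        rot = rng.uniform(0, 2 * np.pi)
        angles = rot + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        xs, ys = r_circ * np.cos(angles), r_circ * np.sin(angles)
        roles = (
            ["original", "updated", "other"]
            if conditions[i] == "Mismatch"
            else ["repeated", "other", "other2"]
        )
        row = {
            "trial": i,
            "onset_ms": i * dur_ms,
            "offset_ms": (i + 1) * dur_ms,
            "condition": conditions[i],
            "memory": memory[i],
        }
        for j, role in enumerate(roles):
            row[f"roi{j+1}_role"] = role
            row[f"roi{j+1}_x"] = xs[j]
            row[f"roi{j+1}_y"] = ys[j]
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_lfp(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ContinuousRecording, GroundTruth]:
    """Synthesize the LFP channel and its exact ground truth.

    The gamma envelope's coupling depth can vary by trial condition
    (``coupling_depth_by_condition``); otherwise the global
    ``coupling_depth`` applies throughout.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    # 1/f-shaped Gaussian background via spectral shaping of white noise
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    shape = np.zeros_like(freqs)
    shape[1:] = np.sqrt(10.0 ** config.aperiodic_offset
                        * freqs[1:] ** (-config.aperiodic_exponent))
    background = np.fft.irfft(spec * shape, n=n)

    # narrowband theta: instantaneous frequency wanders around theta_freq as
    # an Ornstein-Uhlenbeck process (real hippocampal theta is 4-6 Hz band
    # activity, not a pure tone); the exact phase is stored as ground truth
    phi0 = rng.uniform(-np.pi, np.pi)
    if config.theta_freq_sd > 0:
        from scipy.signal import lfilter

        dt = 1.0 / config.fs
        rho = np.exp(-dt / config.theta_freq_tau_s)
        innov = rng.standard_normal(n) * config.theta_freq_sd * np.sqrt(1 - rho ** 2)
        innov[0] = rng.standard_normal() * config.theta_freq_sd
        dev = lfilter([1.0], [1.0, -rho], innov)
        inst_freq = config.theta_freq + dev
    else:
        inst_freq = np.full(n, config.theta_freq)
    theta_phase = np.angle(np.exp(1j * (
        phi0 + 2 * np.pi * np.cumsum(inst_freq) / config.fs
    )))
    theta = config.theta_amp * np.cos(theta_phase)

    trials = _make_trials(config, rng)
    depth = np.full(n, config.coupling_depth)
    if config.coupling_depth_by_condition is not None:
        for _, tr in trials.iterrows():
            s0 = int(round(tr.onset_ms * config.fs / 1000.0))
            s1 = int(round(tr.offset_ms * config.fs / 1000.0))
            depth[s0:s1] = config.coupling_depth_by_condition[tr.condition]

    psi0 = rng.uniform(-np.pi, np.pi)
    envelope = config.gamma_amp * (
        1.0 + depth * np.cos(theta_phase - config.coupling_phase)
    ) / (1.0 + depth)
    gamma = envelope * np.cos(2 * np.pi * config.gamma_freq * t + psi0)

    rec = ContinuousRecording(
        (background + theta + gamma)[np.newaxis, :], config.fs, ["HIPP1-HIPP2"]
    )
    truth = GroundTruth(
        true_theta_phase=theta_phase,
        true_coupling_phase=config.coupling_phase,
        true_coupling_depth=config.coupling_depth,
        fs=config.fs,
        trials=trials,
        memory_labels=trials.memory.to_numpy(),
    )
    return rec, truth


def _saccade_duration_s(amplitude_deg: float, fs: float) -> float:
    """Main-sequence-like duration, quantized to samples.

    Chosen so a raised-cosine velocity profile exceeds both the 30 deg/s
    velocity and the 8000 deg/s^2 acceleration detection thresholds for any
    amplitude >= ~0.3 deg (peak velocity 2A/T, peak acceleration 2*pi*A/T^2).
    """
    T = float(np.clip(0.014 + 0.0022 * amplitude_deg, 0.014, 0.050))
    return max(4, int(round(T * fs))) / fs

_MAX_SACC_S = 0.050 + 0.008  # scheduling gap: longest saccade + 2 samples


def _roi_positions(trial_row: pd.Series) -> dict[str, tuple[float, float]]:
    return {
        trial_row[f"roi{j}_role"]: (trial_row[f"roi{j}_x"], trial_row[f"roi{j}_y"])
        for j in (1, 2, 3)
    }


def _roi_probs(condition: str) -> dict[str, float]:
    if condition == "Mismatch":
        return {"original": 0.35, "updated": 0.35, "other": 0.15, "none": 0.15}
    return {"repeated": 0.5, "other": 0.175, "other2": 0.175, "none": 0.15}


def _class_param(mapping: dict[str, float], condition: str, roi: str,
                 default: float = 0.0) -> float:
    """Look up a per-class value by 'condition/roi', falling back to the
    condition alone, then to ``default``."""
    return mapping.get(f"{condition}/{roi}", mapping.get(condition, default))


def _draw_position(
    trial_row: pd.Series, role: str, rng: np.random.Generator,
    prev_xy: tuple[float, float] | None,
) -> tuple[float, float]:
    """Gaze point for a fixation with a given ROI role.

    Points land within 2 deg of the role's center (well inside the 6 deg
    assignment radius); 'none' fixations land > 7 deg from every center.
    Consecutive fixations are forced >= 1 deg apart so every programmed
    saccade is parseable.
    """
    centers = _roi_positions(trial_row)
    for _ in range(50):
        if role == "none":
            while True:
                xy = rng.uniform(-16, 16, size=2)
                if all(np.hypot(xy[0] - cx, xy[1] - cy) > 7.0
                       for cx, cy in centers.values()):
                    break
        else:
            cx, cy = centers[role]
            r, a = rng.uniform(0, 2.0), rng.uniform(0, 2 * np.pi)
            xy = (cx + r * np.cos(a), cy + r * np.sin(a))
        if prev_xy is None or np.hypot(xy[0] - prev_xy[0], xy[1] - prev_xy[1]) >= 1.0:
            return float(xy[0]), float(xy[1])
    return float(xy[0]), float(xy[1])  # pragma: no cover


def simulate_fixation_stream(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw fixation / saccade / blink events phase-locked to theta.

    Fixations are laid down sequentially within each trial.  After the
    previous fixation ends (plus a saccade gap) an exponential wait elapses;
    a class with ``kappa = 0`` starts its fixation right there (uniform
    theta phase), while a phase-locked class draws a target phase from
    ``vonMises(mu, kappa)`` and starts at the next instant the theta phase
    passes through it.  The onset phase therefore follows the von Mises law
    exactly while inter-fixation waits stay exponential (plus at most one
    theta period of phase alignment, whose mean half-period cost is folded
    into the wait so the realized rate tracks ``fixation_rate`` until the
    phase-locked regime saturates).  Durations are uniform on
    ``fixation_duration_ms`` (>= 80 ms by construction); the saccade into
    each fixation fills the tail of the preceding gap.  Long fixations may
    carry a blink (pupil dropout).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    d0, d1 = (config.fixation_duration_ms[0] / 1000.0,
              config.fixation_duration_ms[1] / 1000.0)
    mean_dur = 0.5 * (d0 + d1)
    rows: list[dict] = []
    fix_phases, fix_conds = [], []
    prev_xy: tuple[float, float] | None = None
    omega = 2.0 * np.pi * config.theta_freq
    half_period = 0.5 / config.theta_freq

    for _, tr in truth.trials.iterrows():
        roi_p = _roi_probs(tr.condition)
        roles = list(roi_p)
        probs = np.array([roi_p[r] for r in roles])
        probs = probs / probs.sum()

        t0, t1 = tr.onset_ms / 1000.0, tr.offset_ms / 1000.0
        prev_offset = t0 - _MAX_SACC_S
        while True:
            role = roles[rng.choice(len(roles), p=probs)]
            roi = "other" if role == "other2" else role
            kappa = _class_param(config.kappa_by_condition, tr.condition, roi)
            mu = _class_param(config.preferred_phase_by_condition, tr.condition, roi)
            adj_mean = half_period if kappa > 0 else 0.0
            wait_target = max(
                1.0 / config.fixation_rate - mean_dur - _MAX_SACC_S - adj_mean,
                0.015,
            )
            t_base = prev_offset + _MAX_SACC_S + rng.exponential(wait_target)
            if kappa > 0:
                phi_star = rng.vonmises(mu, kappa)
                t_on = t_base + float(
                    np.mod(phi_star - truth.phase_at(1000.0 * t_base), 2 * np.pi)
                ) / omega
                # second Newton step absorbs slow theta-frequency wander
                t_on = t_on + float(np.angle(np.exp(
                    1j * (phi_star - truth.phase_at(1000.0 * t_on))
                ))) / omega
            else:
                t_on = t_base
            if t_on + d0 > t1:
                break
            phase = float(truth.phase_at(1000.0 * t_on))
            dur = rng.uniform(d0, min(d1, t1 - t_on))
            t_cand = t_on
            x, y = _draw_position(tr, role, rng, prev_xy)
            if prev_xy is not None:
                amp = float(np.hypot(x - prev_xy[0], y - prev_xy[1]))
                sdur = _saccade_duration_s(amp, config.fs)
                rows.append({
                    "kind": "saccade",
                    "onset_ms": 1000.0 * (t_cand - sdur),
                    "duration_ms": 1000.0 * sdur,
                    "trial": int(tr.trial), "condition": tr.condition,
                    "roi": "", "memory": tr.memory,
                    "x": x, "y": y, "amplitude_deg": amp, "true_phase": np.nan,
                })
            rows.append({
                "kind": "fixation",
                "onset_ms": 1000.0 * t_cand,
                "duration_ms": 1000.0 * dur,
                "trial": int(tr.trial), "condition": tr.condition,
                "roi": roi, "memory": tr.memory,
                "x": x, "y": y, "amplitude_deg": np.nan, "true_phase": phase,
            })
            if dur >= 0.16 and rng.uniform() < config.p_blink:
                rows.append({
                    "kind": "blink",
                    "onset_ms": 1000.0 * (t_cand + dur / 2 - 0.05),
                    "duration_ms": 100.0,
                    "trial": int(tr.trial), "condition": tr.condition,
                    "roi": "", "memory": tr.memory,
                    "x": x, "y": y, "amplitude_deg": np.nan, "true_phase": np.nan,
                })
            fix_phases.append(phase)
            fix_conds.append(tr.condition)
            prev_xy = (x, y)
            prev_offset = t_cand + dur

    events = pd.DataFrame(rows).sort_values("onset_ms").reset_index(drop=True)
    truth.true_fixation_phases = np.array(fix_phases)
    truth.condition_labels = np.array(fix_conds, dtype=object)
    return events


def simulate_gaze(
    config: SimulationConfig,
    events: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Render 500 Hz gaze samples (time_ms, x_deg, y_deg, pupil) from events.

    Fixations hold their position with Gaussian jitter (sd ``jitter_deg``,
    clipped to +/-0.07 deg, far below the 0.15 deg motion threshold).
    Saccades follow a raised-cosine velocity profile along the straight path
    between fixation positions.  Blinks zero the pupil while the position is
    held (no spurious velocity at dropout edges).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if len(events) == 0:
        raise ValueError("empty event table")
    fixs = events[events.kind == "fixation"].reset_index(drop=True)
    saccs = events[events.kind == "saccade"].reset_index(drop=True)
    blinks = events[events.kind == "blink"].reset_index(drop=True)
    n = int(round(config.duration_s * config.fs))
    t_ms = 1000.0 * np.arange(n) / config.fs

    x = np.empty(n)
    y = np.empty(n)
    # piecewise-constant hold of each fixation position, from the end of the
    # incoming saccade to the start of the outgoing one
    x[:] = fixs.x.iloc[0]
    y[:] = fixs.y.iloc[0]
    for _, fx in fixs.iterrows():
        i0_ = int(round(fx.onset_ms * config.fs / 1000.0))
        x[i0_:] = fx.x
        y[i0_:] = fx.y
    # overwrite saccade intervals with the smooth trajectory
    prev_pos = (fixs.x.iloc[0], fixs.y.iloc[0])
    fix_iter = iter(fixs.itertuples())
    next(fix_iter)
    for sc in saccs.itertuples():
        if sc.onset_ms + sc.duration_ms > t_ms[-1]:
            break
        fx = next(fix_iter)
        s0 = int(round(sc.onset_ms * config.fs / 1000.0))
        s1 = int(round((sc.onset_ms + sc.duration_ms) * config.fs / 1000.0))
        if s1 <= s0 or s0 < 0:
            prev_pos = (fx.x, fx.y)
            continue
        tau = (np.arange(s0, s1 + 1) - s0) / (s1 - s0)
        prog = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)  # integrated raised cosine
        x[s0:s1 + 1] = prev_pos[0] + (fx.x - prev_pos[0]) * prog
        y[s0:s1 + 1] = prev_pos[1] + (fx.y - prev_pos[1]) * prog
        prev_pos = (fx.x, fx.y)

    jit = np.clip(rng.normal(0.0, config.jitter_deg, size=(2, n)), -0.07, 0.07)
    x = x + jit[0]
    y = y + jit[1]

    pupil = 1000.0 + rng.normal(0.0, 5.0, size=n)
    for bl in blinks.itertuples():
        b0 = int(round(bl.onset_ms * config.fs / 1000.0))
        b1 = int(round((bl.onset_ms + bl.duration_ms) * config.fs / 1000.0))
        pupil[max(b0, 0):b1] = 0.0

    return pd.DataFrame({"time_ms": t_ms, "x_deg": x, "y_deg": y, "pupil": pupil})


def simulate_session(config: SimulationConfig) -> dict:
    """Generate a complete in-memory session with one threaded RNG.

    Returns a dict with keys ``recording``, ``truth``, ``events``, ``gaze``,
    ``trials``, ``config``.
    """
    rng = np.random.default_rng(config.seed)
    rec, truth = simulate_lfp(config, rng)
    events = simulate_fixation_stream(config, truth, rng)
    gaze = simulate_gaze(config, events, rng)
    return {
        "recording": rec, "truth": truth, "events": events,
        "gaze": gaze, "trials": truth.trials, "config": config,
    }


_F = "%.12g"


def make_dataset(config: SimulationConfig, out_dir) -> dict:
    """Write a session to disk: HDF5 recording, gaze/events/trials TSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ses = simulate_session(config)
    ses["recording"].to_hdf5(out / "recording.h5")
    import h5py

    with h5py.File(out / "recording.h5", "a") as f:
        f.create_dataset("true_theta_phase", data=ses["truth"].true_theta_phase)
        f.attrs["seed"] = int(config.seed)
    ses["gaze"].to_csv(out / "gaze.tsv", sep="\t", index=False, float_format=_F)
    ses["events"].to_csv(out / "events.tsv", sep="\t", index=False, float_format=_F)
    ses["trials"].to_csv(out / "trials.tsv", sep="\t", index=False, float_format=_F)
    truth = ses["truth"]
    payload = {
        "config": config.to_dict(),
        "true_coupling_phase": truth.true_coupling_phase,
        "true_coupling_depth": truth.true_coupling_depth,
        "true_fixation_phases": [float(v) for v in truth.true_fixation_phases],
        "condition_labels": list(truth.condition_labels),
        "memory_labels": list(truth.memory_labels),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
    return ses


def load_dataset(out_dir) -> dict:
    """Reload a dataset written by :func:`make_dataset`."""
    out = Path(out_dir)
    import h5py

    rec = ContinuousRecording.from_hdf5(out / "recording.h5")
    with h5py.File(out / "recording.h5", "r") as f:
        theta_phase = f["true_theta_phase"][()]
    payload = json.loads((out / "truth.json").read_text())
    config = SimulationConfig.from_dict(payload["config"])
    trials = pd.read_csv(out / "trials.tsv", sep="\t")
    truth = GroundTruth(
        true_theta_phase=theta_phase,
        true_coupling_phase=payload["true_coupling_phase"],
        true_coupling_depth=payload["true_coupling_depth"],
        fs=rec.fs,
        trials=trials,
        true_fixation_phases=np.array(payload["true_fixation_phases"]),
        condition_labels=np.array(payload["condition_labels"], dtype=object),
        memory_labels=np.array(payload["memory_labels"], dtype=object),
    )
    return {
        "recording": rec, "truth": truth,
        "events": pd.read_csv(out / "events.tsv", sep="\t"),
        "gaze": pd.read_csv(out / "gaze.tsv", sep="\t"),
        "trials": trials, "config": config,
    }
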