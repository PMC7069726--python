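"""Referencing, resampling, line-noise filtering and fixation-locked epoching.

Depth-electrode recordings arrive referenced to a clinical contact at 1-2 kHz.
The analysis chain expects a bipolar montage (adjacent-contact differences,
which suppress volume-conducted far-field activity), a 500 Hz sampling rate,
line noise removed with a zero-phase band-stop filter, and epochs cut around
fixation onsets with a generous buffer so that wavelet convolution never sees
an edge.  Everything here is strictly linear and zero-phase: oscillatory
phase, which the downstream phase-locking measures depend on, must not be
distorted by preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "bipolar_reference",
    "notch_filter",
    "resample",
    "extract_epochs",
]


@dataclass
class ContinuousRecording:
    """Multichannel continuous signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Voltage traces in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names.
    excluded : ndarray of bool, shape (n_channels,)
        Exclusion flags (interictal spiking / seizure-onset-zone contacts).
    """

    signal: np.ndarray
    fs: float
    labels: list[str]
    excluded: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if len(self.labels) != self.signal.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.excluded is None:
            self.excluded = np.zeros(self.signal.shape[0], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.signal[self.labels.index(label)]
        except ValueError as err:
            raise KeyError(f"unknown channel label: {label!r}") from err

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal)
            f.attrs["fs"] = float(self.fs)
            f.create_dataset(
                "labels", data=np.array(self.labels, dtype=h5py.string_dtype())
            )
            f.create_dataset("excluded", data=self.excluded)

    @classmethod
    def from_hdf5(cls, path) -> "ContinuousRecording":
        with h5py.File(path, "r") as f:
            return cls(
                signal=f["signal"][()],
                fs=float(f.attrs["fs"]),
                labels=[s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]],
                excluded=f["excluded"][()],
            )


@dataclass
class EpochSet:
    """Fixation-locked epochs from a single channel.

    ``data`` covers ``window`` plus ``buffer_ms`` on each side; the buffer is
    kept through spectral transforms (wavelet edge protection) and trimmed
    afterwards.  ``events`` carries one metadata row per epoch (a
    labeled-fixation record); ``dropped`` records onsets whose buffered
    window left the recording.
    """

    data: np.ndarray  # (n_epochs, n_samples) including buffers
    fs: float
    window: tuple[float, float]  # ms relative to fixation onset
    buffer_ms: float
    events: "object" = None  # pandas DataFrame, one row per epoch
    onsets_ms: np.ndarray = None  # type: ignore[assignment]
    dropped: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_buffer_samples(self) -> int:
        return int(round(self.buffer_ms * self.fs / 1000.0))

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis of the *trimmed* window, ms relative to fixation onset."""
        start, stop = self.window
        n_win = self.data.shape[1] - 2 * self.n_buffer_samples
        return start + 1000.0 * np.arange(n_win) / self.fs

    def trimmed(self) -> np.ndarray:
        """Epoch data with buffers removed: (n_epochs, n_window_samples)."""
        b = self.n_buffer_samples
        return self.data[:, b: self.data.shape[1] - b]


def read_edf(path, preload: bool = True) -> ContinuousRecording:
    """Read a continuous EDF recording into a :class:`ContinuousRecording`."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=preload, verbose=False)
    return ContinuousRecording(
        raw.get_data() * 1e6,  # volts -> microvolts
        float(raw.info["sfreq"]),
        list(raw.ch_names),
    )


def bipolar_reference(
    rec: ContinuousRecording, pairs: list[tuple[str, str]]
) -> ContinuousRecording:
    """Re-reference to a bipolar montage: one channel per (anode, cathode) pair.

    The output channel is ``anode - cathode`` and is flagged excluded if
    either contact was.
    """
    out = np.empty((len(pairs), rec.n_samples))
    labels, excl = [], []
    for i, (anode, cathode) in enumerate(pairs):
        out[i] = rec.channel(anode) - rec.channel(cathode)
        labels.append(f"{anode}-{cathode}")
        excl.append(
            rec.excluded[rec.labels.index(anode)]
            or rec.excluded[rec.labels.index(cathode)]
        )
    return ContinuousRecording(out, rec.fs, labels, np.array(excl))


def notch_filter(
    rec: ContinuousRecording,
    line_freq: float = 60.0,
    order: int = 4,
    width_hz: float = 2.0,
    harmonics: bool = False,
) -> ContinuousRecording:
    """Zero-phase Butterworth band-stop around the line frequency.

    A forward-backward (``filtfilt``) 4th-order Butterworth band-stop,
    ``line_freq ± width_hz``.  With ``harmonics=True`` every integer multiple
    of ``line_freq`` below Nyquist is notched as well.
    """
    nyq = rec.fs / 2.0
    if line_freq >= nyq:
        raise ValueError(f"line_freq {line_freq} Hz >= Nyquist {nyq} Hz")
    freqs = [line_freq]
    if harmonics:
        k = 2
        while k * line_freq < nyq - width_hz:
            freqs.append(k * line_freq)
            k += 1
    out = rec.signal.copy()
    for f0 in freqs:
        sos = signal.butter(
            order, [f0 - width_hz, f0 + width_hz], btype="bandstop", fs=rec.fs,
            output="sos",
        )
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return replace(rec, signal=out)


def resample(rec: ContinuousRecording, fs_target: float = 500.0) -> ContinuousRecording:
    """Polyphase anti-aliased downsampling to ``fs_target``.

    Upsampling is out of scope and raises.  ``fs_target == fs`` is the
    identity.
    """
    if fs_target > rec.fs:
        raise ValueError("upsampling not supported")
    if fs_target == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=-1)
    return replace(rec, signal=out, fs=rec.fs * frac.numerator / frac.denominator)


def extract_epochs(
    rec: ContinuousRecording,
    onsets_ms: np.ndarray,
    channel: str | int = 0,
    window: tuple[float, float] = (-750.0, 750.0),
    buffer_ms: float = 1250.0,
    events=None,
) -> EpochSet:
    """Cut buffered fixation-locked epochs from one channel.

    Each epoch spans ``window`` around its onset plus ``buffer_ms`` of
    padding on each side (retained until after spectral transforms, to keep
    wavelet edge artifacts out of the analysis window).  Onsets whose
    buffered window exits the recording are dropped and listed in
    ``EpochSet.dropped``.
    """
    sig = rec.channel(channel) if isinstance(channel, str) else rec.signal[channel]
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    b = int(round(buffer_ms * rec.fs / 1000.0))
    i0 = int(round(window[0] * rec.fs / 1000.0)) - b
    n_len = int(round((window[1] - window[0]) * rec.fs / 1000.0)) + 2 * b + 1

    rows, kept_idx, dropped = [], [], []
    for k, t in enumerate(onsets_ms):
        s0 = int(round(t * rec.fs / 1000.0)) + i0
        if s0 < 0 or s0 + n_len > rec.n_samples:
            dropped.append((k, float(t), "buffered window outside recording"))
            continue
        rows.append(sig[s0: s0 + n_len])
        kept_idx.append(k)
    if not rows:
        raise ValueError("no epochs survive the buffered-window bounds check")
    meta = None
    if events is not None:
        meta = events.iloc[kept_idx].reset_index(drop=True)
    return EpochSet(
        data=np.array(rows), fs=rec.fs, window=window, buffer_ms=buffer_ms,
        events=meta, onsets_ms=onsets_ms[kept_idx], dropped=dropped,
    )
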