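"""EEG center-frequency trajectories at scan resolution.

The empirical counterpart of the analytic center frequency: each EEG
channel is cut into non-overlapping windows of one repetition time (TR)
aligned to scan onsets, Hann-tapered and Fourier transformed; the power in
the analysis band is renormalized to unit mass per window and its first
moment is the per-scan center frequency.  Because of the normalization the
result is invariant to channel gain, and slow amplitude drifts do not
masquerade as frequency modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EegRecording",
    "CenterFrequencySeries",
    "windowed_spectra",
    "empirical_center_frequency",
    "read_eeg_tsv",
    "read_eeg_edf",
]


@dataclass
class EegRecording:
    """Multichannel EEG: ``samples`` (channels x time, µV), sampling rate
    ``fs`` (Hz), channel ``labels`` and per-channel ``kind``
    ("eeg", "eog" or "ecg")."""

    samples: np.ndarray
    fs: float
    labels: tuple = ()
    kind: tuple = ()

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(np.isnan(self.samples)):
            raise ValueError("EEG contains NaNs; gaps must be declared explicitly")
        c = self.samples.shape[0]
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(c))
        if not self.kind:
            self.kind = tuple("eeg" for _ in range(c))
        if len(self.labels) != c or len(self.kind) != c:
            raise ValueError("labels/kind must match the number of channels")
        bad = set(self.kind) - {"eeg", "eog", "ecg"}
        if bad:
            raise ValueError(f"unknown channel kinds: {bad}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def neural_channels(self) -> np.ndarray:
        return np.array([k == "eeg" for k in self.kind])


@dataclass
class CenterFrequencySeries:
    """Per-channel center frequency (Hz) at scan times."""

    scan_times: np.ndarray
    omega_bar: np.ndarray  # channels x scans
    band: tuple = (1.0, 60.0)
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.omega_bar = np.atleast_2d(np.asarray(self.omega_bar, dtype=float))
        lo, hi = self.band
        finite = self.omega_bar[np.isfinite(self.omega_bar)]
        if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
            raise ValueError("center frequencies outside the analysis band")

    @property
    def n_channels(self) -> int:
        return self.omega_bar.shape[0]

    def to_frame(self):
        import pandas as pd

        labels = self.labels or tuple(f"ch{i}" for i in range(self.n_channels))
        data = {"scan_time_s": self.scan_times}
        for i, l in enumerate(labels):
            data[f"omega_{l}"] = self.omega_bar[i]
        return pd.DataFrame(data)


def windowed_spectra(
    eeg: EegRecording,
    tr: float,
    scan_times: np.ndarray | None = None,
    band: tuple = (1.0, 60.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered FFT power per scan window, band-limited.

    Windows are ``[t, t + TR)`` for each scan onset ``t`` (default onsets
    ``0, TR, 2 TR, ...`` for as many complete windows as the recording
    holds scans), giving a frequency resolution of ``1/TR`` Hz.

    Returns ``(tf_power, freqs)`` with ``tf_power`` of shape
    ``(channels, scans, n_freqs)``.
    """
    n_win = int(round(tr * eeg.fs))
    if scan_times is None:
        n_scans = eeg.samples.shape[1] // n_win
        scan_times = np.arange(n_scans) * tr
    scan_times = np.asarray(scan_times, dtype=float)
    starts = np.round(scan_times * eeg.fs).astype(int)
    over = [i for i, s in enumerate(starts) if s + n_win > eeg.samples.shape[1] or s < 0]
    if over:
        raise ValueError(f"scan windows extend past the recording: scans {over}")
    taper = np.hanning(n_win)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / eeg.fs)
    keep = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    segs = np.stack([eeg.samples[:, s : s + n_win] for s in starts], axis=1)
    spec = np.fft.rfft(segs * taper[None, None, :], axis=-1)
    power = np.abs(spec[..., keep]) ** 2
    return power, freqs[keep]


def empirical_center_frequency(
    tf_power: np.ndarray,
    freqs: np.ndarray,
    scan_times: np.ndarray | None = None,
    labels: tuple = (),
) -> CenterFrequencySeries:
    """First moment of each window's normalized power spectrum.

    Windows with zero total power yield NaN (propagated as missing scans)
    with a warning.  The computation is the same first-moment quadrature
    used for the analytic spectrum.
    """
    tf_power = np.asarray(tf_power, dtype=float)
    if np.any(tf_power < 0):
        raise ValueError("tf_power must be nonnegative")
    total = np.trapezoid(tf_power, freqs, axis=-1)
    zero = total <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} all-zero window(s); center frequency set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.trapezoid(tf_power * freqs, freqs, axis=-1) / np.where(zero, np.nan, total)
    if scan_times is None:
        scan_times = np.arange(tf_power.shape[1], dtype=float)
    return CenterFrequencySeries(
        scan_times=np.asarray(scan_times, dtype=float),
        omega_bar=omega,
        band=(float(freqs[0]), float(freqs[-1])),
        labels=labels,
    )


def read_eeg_tsv(path, sidecar=None) -> EegRecording:
    """Read EEG from TSV (columns = channels) with a JSON sidecar holding
    ``fs``, ``labels`` and ``kind``."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    labels = tuple(meta.get("labels", df.columns.tolist()))
    return EegRecording(
        samples=df[list(labels)].to_numpy().T,
        fs=float(meta["fs"]),
        labels=labels,
        kind=tuple(meta.get("kind", ())),
    )


def read_eeg_edf(path) -> EegRecording:
    """Read EEG from an EDF file (requires the optional mne dependency).

    Channels whose name contains "EOG"/"ECG" (case-insensitive) are
    flagged as artifact channels.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires mne (pip install slowmodes[eeg])") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    kind = tuple(
        "eog" if "eog" in l.lower() else "ecg" if "ecg" in l.lower() else "eeg"
        for l in labels
    )
    return EegRecording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        labels=labels,
        kind=kind,
    )
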