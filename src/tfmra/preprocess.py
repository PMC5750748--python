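"""EEG ingestion, detrending and segmentation.

Reads single- or multi-channel EEG from EDF or delimited text, removes slow
trends with a zero-phase high-pass filter, and cuts one channel into
fixed-length non-overlapping segments ready for time-frequency analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

#: The eight trial classes: resting baseline plus seven ocular/facial-muscle
#: artifact types recorded at a frontal (Fpz) electrode.
CLASSES = (
    "baseline",
    "blink",
    "eye_up",
    "eye_left",
    "eyebrow",
    "head",
    "jaw_clinch",
    "jaw_move",
)


@dataclass
class EegRecording:
    """A multichannel sampled EEG signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        10-20 system labels, one per row of ``samples``.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not found; available: {self.channel_names}"
            ) from None


@dataclass
class Segment:
    """One fixed-length analysis window cut from a single channel."""

    samples: np.ndarray
    fs: float
    window_s: float
    label: str | None = None
    source_channel: str = ""
    participant_id: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        expected = int(round(self.window_s * self.fs))
        if len(self.samples) != expected:
            raise ValueError(
                f"segment has {len(self.samples)} samples, expected "
                f"{expected} (= round({self.window_s} s x {self.fs} Hz))"
            )
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}; classes: {CLASSES}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def read_signal(path: str | Path, format: str | None = None,
                channel: str | int | None = None) -> EegRecording:
    """Read a multichannel EEG recording from an EDF or delimited-text file.

    CSV dialect: rows are channels; the first column may carry the channel
    name; an optional single header row lists channel names.  EDF files are
    read with :mod:`mne` and converted from volts back to microvolts.

    ``channel`` is validated for existence only; channel selection itself is
    deferred to :func:`make_segments`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "csv":
        rec = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'csv')")
    if channel is not None:
        rec.channel_index(channel)  # raises KeyError if absent
    return rec


def _read_edf(path: Path) -> EegRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; store microvolts
    return EegRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _read_csv(path: Path, fs: float = 256.0) -> EegRecording:
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([c.strip() for c in line.split(",")])
    if not rows:
        raise ValueError(f"{path}: empty file")

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    def _check_widths(data_rows: list[list[str]]) -> None:
        widths = {len(r) for r in data_rows}
        if len(widths) != 1:
            raise ValueError(
                f"{path}: inconsistent row lengths {sorted(widths)}")

    names: list[str] | None = None
    # A fully non-numeric first row is a header of channel names (it may be
    # narrower than the data rows: one name per channel row).
    if not any(_numeric(c) for c in rows[0]):
        names = rows[0]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")
        _check_widths(rows)
        data = _parse_matrix(rows, path)
        if data.shape[0] != len(names) and data.shape[1] == len(names):
            # header named columns-as-channels: stored transposed
            data = data.T
        if data.shape[0] != len(names):
            raise ValueError(
                f"{path}: {len(names)} header names but {data.shape[0]} rows"
            )
        return EegRecording(data, fs, names)

    _check_widths(rows)
    # Otherwise rows = channels; first column may be a channel name.
    if not _numeric(rows[0][0]):
        names = [r[0] for r in rows]
        rows = [r[1:] for r in rows]
        data = _parse_matrix(rows, path)
        return EegRecording(data, fs, names)

    data = _parse_matrix(rows, path)
    return EegRecording(data, fs, [f"ch{i}" for i in range(data.shape[0])])


def _parse_matrix(rows: list[list[str]], path: Path) -> np.ndarray:
    try:
        return np.array([[float(c) for c in r] for r in rows])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None


def highpass_filter(rec: EegRecording, cutoff_hz: float = 0.5,
                    order: int = 4) -> EegRecording:
    """Zero-phase Butterworth high-pass to remove DC and slow trends.

    A 4th-order Butterworth applied forward-backward (``filtfilt``), so the
    waveform morphology of transient artifacts is not delayed or skewed.
    """
    nyq = rec.fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rec.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EegRecording(filtered, rec.fs, list(rec.channel_names))


def make_segments(rec: EegRecording, channel: str | int,
                  window_s: float = 1.0) -> list[Segment]:
    """Cut one channel into contiguous non-overlapping windows.

    Returns ``floor(n_samples / (window_s * fs))`` segments in temporal
    order; trailing remainder samples are discarded.
    """
    idx = rec.channel_index(channel)
    seg_len = int(round(window_s * rec.fs))
    if seg_len < 8:
        raise ValueError(f"window of {seg_len} samples is too short (< 8)")
    n_seg = rec.n_samples // seg_len
    if n_seg == 0:
        warnings.warn(
            f"window ({seg_len} samples) longer than recording "
            f"({rec.n_samples} samples); no segments produced",
            stacklevel=2,
        )
        return []
    x = rec.samples[idx]
    name = rec.channel_names[idx]
    return [
        Segment(x[i * seg_len:(i + 1) * seg_len], rec.fs, window_s,
                source_channel=name)
        for i in range(n_seg)
    ]
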