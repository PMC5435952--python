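"""Acquisition-matched EEG preprocessing.

The cleaning chain mirrors a two-electrode (FP1/FP2) frontal acquisition at
1000 Hz: a 0.05–200 Hz band-pass, a 50 Hz mains notch, segmentation into
fixed-length epochs, and peak-amplitude artifact rejection.  All filters are
applied forward-backward (zero phase) so that feature timing is unaffected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecording",
    "Epoch",
    "FilterSpec",
    "band_filter",
    "notch_filter",
    "segment_epochs",
    "reject_artifacts",
    "read_csv_recording",
    "write_csv_recording",
    "read_edf_recording",
]

STATES = ("normal", "fatigue")
STATE_LABELS = {"normal": 0, "fatigue": 1}


@dataclass
class RawRecording:
    """A subject's multichannel EEG session.

    ``data`` is a channels x samples matrix in microvolts; ``state`` labels
    the whole session as ``"normal"`` or ``"fatigue"``.
    """

    subject_id: str
    channels: list[str]
    fs: float
    data: np.ndarray
    state: str

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel count {len(self.channels)} != data rows {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A fixed-length single-channel segment; the unit of feature extraction."""

    subject_id: str
    channel: str
    state: str
    samples: np.ndarray
    fs: float
    epoch_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite samples")

    @property
    def label(self) -> int:
        return STATE_LABELS[self.state]


@dataclass(frozen=True)
class FilterSpec:
    """Cutoffs of the acquisition band and mains notch.

    Defaults follow a 0.05 Hz high-pass, 200 Hz low-pass and 50 Hz notch.
    ``filter_order`` is the Butterworth order of the band-pass (applied
    twice by the zero-phase pass); ``notch_q`` is the notch quality factor
    (centre frequency over -3 dB bandwidth).
    """

    highpass_hz: float = 0.05
    lowpass_hz: float = 200.0
    notch_hz: float = 50.0
    notch_q: float = 30.0
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        if not (0 < self.highpass_hz < self.notch_hz < self.lowpass_hz):
            raise ValueError(
                f"need 0 < highpass ({self.highpass_hz}) < notch ({self.notch_hz})"
                f" < lowpass ({self.lowpass_hz})"
            )
        if self.lowpass_hz >= fs / 2:
            raise ValueError(
                f"low-pass cutoff {self.lowpass_hz} Hz is not below Nyquist {fs / 2} Hz"
            )
        if self.filter_order < 1 or self.notch_q <= 0:
            raise ValueError("filter_order must be >= 1 and notch_q positive")


def band_filter(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase Butterworth band-pass, channel by channel.

    The channel mean is removed before filtering, so the output is free of
    DC regardless of record length relative to the high-pass corner.
    Second-order sections keep the very low 0.05 Hz corner numerically
    stable at kilohertz sampling rates.
    """
    spec.validate(rec.fs)
    sos = signal.butter(
        spec.filter_order,
        [spec.highpass_hz, spec.lowpass_hz],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    demeaned = rec.data - rec.data.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, demeaned, axis=1, padtype="even")
    return replace(rec, data=filtered)


def notch_filter(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase mains notch at ``spec.notch_hz``."""
    spec.validate(rec.fs)
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)
    filtered = signal.filtfilt(b, a, rec.data, axis=1, padtype="even")
    return replace(rec, data=filtered)


def segment_epochs(
    rec: RawRecording,
    epoch_seconds: float = 1.0,
    overlap_fraction: float = 0.0,
) -> list[Epoch]:
    """Cut a recording into fixed-length epochs per channel.

    Windows are ``round(epoch_seconds * fs)`` samples long and advance by
    ``window * (1 - overlap_fraction)`` samples; a trailing partial window
    is dropped.  Returns an empty list (with a warning) if the recording is
    shorter than one window.
    """
    if epoch_seconds <= 0:
        raise ValueError(f"epoch_seconds must be positive, got {epoch_seconds}")
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    window = int(round(epoch_seconds * rec.fs))
    step = max(1, int(round(window * (1 - overlap_fraction))))
    if rec.n_samples < window:
        warnings.warn(
            f"recording of {rec.n_samples} samples is shorter than one epoch ({window})",
            stacklevel=2,
        )
        return []
    starts = range(0, rec.n_samples - window + 1, step)
    epochs = []
    for ch_i, ch in enumerate(rec.channels):
        for epoch_index, start in enumerate(starts):
            epochs.append(
                Epoch(
                    subject_id=rec.subject_id,
                    channel=ch,
                    state=rec.state,
                    samples=rec.data[ch_i, start : start + window].copy(),
                    fs=rec.fs,
                    epoch_index=epoch_index,
                )
            )
    return epochs


def reject_artifacts(
    epochs: list[Epoch], amplitude_uV: float = 100.0
) -> tuple[list[Epoch], int]:
    """Drop epochs whose peak absolute amplitude exceeds ``amplitude_uV``.

    Sample values are never modified; the function returns the kept epochs
    and the number rejected.
    """
    if amplitude_uV <= 0:
        raise ValueError(f"amplitude threshold must be positive, got {amplitude_uV}")
    kept = [ep for ep in epochs if np.max(np.abs(ep.samples)) <= amplitude_uV]
    rejected = len(epochs) - len(kept)
    if rejected:
        logger.info("rejected %d of %d epochs above %.1f uV", rejected, len(epochs), amplitude_uV)
    return kept, rejected


# ---------------------------------------------------------------------------
# I/O

def write_csv_recording(rec: RawRecording, path) -> None:
    """Write a recording as CSV: a time column plus one column per channel."""
    import pandas as pd

    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for i, ch in enumerate(rec.channels):
        df[ch] = rec.data[i]
    df.to_csv(path, index=False)


def read_csv_recording(
    path, subject_id: str, state: str, fs: float | None = None
) -> RawRecording:
    """Read a CSV of microvolt samples (optional ``time`` column, one column
    per channel, header row of channel names).

    If a ``time`` column is present the sampling rate is inferred from it;
    otherwise ``fs`` must be given.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols and cols[0].strip().lower() in ("time", "t", "time_s"):
        t = df[cols[0]].to_numpy(dtype=float)
        if fs is None:
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise ValueError("time column is not increasing; cannot infer fs")
            fs = 1.0 / dt
        channels = cols[1:]
    else:
        if fs is None:
            raise ValueError("CSV has no time column; sampling rate fs is required")
        channels = cols
    data = df[channels].to_numpy(dtype=float).T
    return RawRecording(subject_id=subject_id, channels=list(channels), fs=float(fs),
                        data=data, state=state)


def read_edf_recording(path, subject_id: str, state: str) -> RawRecording:
    """Read a European Data Format (EDF) file via MNE into a RawRecording.

    Channel data are converted to microvolts.  Requires the optional
    ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE stores volts
    return RawRecording(
        subject_id=subject_id,
        channels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=data,
        state=state,
    )
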