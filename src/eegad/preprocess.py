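"""Recording containers, referencing, band-limiting and epoching.

A :class:`Recording` is a channels x samples matrix (µV) with channel
labels, sampling rate, an artifact mask (intervals in seconds to
exclude) and free-form subject metadata. Preprocessing follows the
clinical-EEG convention for resting-state dementia studies:

1. re-reference to the common average of the scalp channels;
2. band-limit to 0.5–60 Hz (equiripple FIR high/low-pass) with a
   49–51 Hz Butterworth notch against powerline interference, all
   applied zero-phase;
3. cut into nonoverlapping fixed-length epochs, dropping any epoch
   that overlaps a marked artifact interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .filters import design_highpass, design_lowpass, notch_filter, zero_phase_fir
from .montage import CHANNELS_1020

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "Epoch",
    "common_average_reference",
    "apply_bandlimit",
    "segment",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
]


@dataclass
class Recording:
    """Multichannel EEG recording (channels x samples, µV)."""

    data: np.ndarray
    fs: float
    labels: Tuple[str, ...]
    artifact_mask: List[Tuple[float, float]] = field(default_factory=list)
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be distinct")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        dur = self.duration
        for s, e in self.artifact_mask:
            if not (0 <= s < e <= dur + 1e-9):
                raise ValueError(f"artifact interval ({s}, {e}) outside [0, {dur}]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass
class Epoch:
    """One nonoverlapping window of a recording; the classification unit."""

    data: np.ndarray
    fs: float
    labels: Tuple[str, ...]
    window_s: float
    t0: float
    subject_id: str = ""
    group: str = ""


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the per-sample mean across channels from every channel.

    The common average reference removes any reference-electrode signal
    shared by all channels; column means of the result are exactly zero.
    """
    if recording.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return replace(recording, data=data)


def apply_bandlimit(recording: Recording) -> Recording:
    """Band-limit to 0.5–60 Hz with a 50 Hz notch, zero-phase.

    Cascade of the 0.5 Hz equiripple FIR high-pass, 60 Hz equiripple
    FIR low-pass and 49–51 Hz Butterworth band-stop; output length
    equals input length.
    """
    fs = recording.fs
    if fs <= 130:
        raise ValueError(
            f"fs={fs} Hz too low for the 0.5-60 Hz band limit with a 65 Hz "
            "stopband edge"
        )
    hp = design_highpass(fs)
    lp = design_lowpass(fs)
    x = zero_phase_fir(recording.data, hp)
    x = zero_phase_fir(x, lp)
    x = notch_filter(x, fs)
    return replace(recording, data=x)


def _overlaps(t0: float, t1: float, mask: Sequence[Tuple[float, float]]) -> bool:
    return any(s < t1 and e > t0 for s, e in mask)


def segment(recording: Recording, window_s: float) -> List[Epoch]:
    """Cut a recording into nonoverlapping epochs of ``window_s`` seconds.

    Epoching starts at t=0; the remainder at the tail is discarded, and
    any candidate epoch that overlaps an artifact-mask interval is
    dropped. A recording shorter than one window yields an empty list.
    """
    if window_s <= 0:
        raise ValueError("window length must be positive")
    n_win = int(round(window_s * recording.fs))
    n_total = recording.n_samples
    epochs: List[Epoch] = []
    meta = recording.meta
    for k in range(n_total // n_win):
        t0 = k * n_win / recording.fs
        t1 = (k + 1) * n_win / recording.fs
        if _overlaps(t0, t1, recording.artifact_mask):
            continue
        epochs.append(
            Epoch(
                data=recording.data[:, k * n_win:(k + 1) * n_win],
                fs=recording.fs,
                labels=recording.labels,
                window_s=window_s,
                t0=t0,
                subject_id=str(meta.get("subject_id", "")),
                group=str(meta.get("group", "")),
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# I/O


def write_recording_csv(recording: Recording, path) -> None:
    """Write a recording as plain CSV: rows = samples, header = labels.

    The sampling rate is stored on a leading ``# fs=`` comment line.
    """
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs}\n")
        fh.write(",".join(recording.labels) + "\n")
        np.savetxt(fh, recording.data.T, delimiter=",", fmt="%.6g")


def read_recording_csv(path, fs: float | None = None, meta: Dict | None = None) -> Recording:
    """Read a plain CSV matrix (rows = samples, header = channel labels).

    ``fs`` overrides any ``# fs=`` comment line; one of the two must be
    present.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        file_fs = None
        if first.startswith("#"):
            if "fs=" in first:
                file_fs = float(first.split("fs=")[1])
            header = fh.readline().strip()
        else:
            header = first
        labels = tuple(h.strip() for h in header.split(","))
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    rate = fs if fs is not None else file_fs
    if rate is None:
        raise ValueError(f"{path}: no sampling rate in file and none provided")
    return Recording(data=data.T, fs=rate, labels=labels, meta=meta or {})


def read_recording_edf(path, meta: Dict | None = None) -> Recording:
    """Read an EDF file, keeping the 19 scalp channels of the montage.

    Channels outside the 10–20 scalp set (A1/A2 earlobes, EOG, ...)
    are dropped with a warning. Requires :mod:`mne`.
    """
    import mne  # deferred: EDF support is optional

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    labels = [ch.strip() for ch in raw.ch_names]
    canon = {ch.lower(): ch for ch in CHANNELS_1020}
    keep, keep_labels = [], []
    for i, lab in enumerate(labels):
        key = lab.lower().replace("eeg", "").replace("-ref", "").strip()
        if key in canon:
            keep.append(i)
            keep_labels.append(canon[key])
    dropped = [lab for i, lab in enumerate(labels) if i not in keep]
    if dropped:
        warnings.warn(f"dropping non-montage channels: {dropped}")
    if not keep:
        raise ValueError(f"{path}: no 10-20 scalp channels found")
    order = sorted(range(len(keep)), key=lambda j: CHANNELS_1020.index(keep_labels[j]))
    data = data[[keep[j] for j in order]]
    labels = tuple(keep_labels[j] for j in order)
    return Recording(data=data, fs=float(raw.info["sfreq"]), labels=labels,
                     meta=meta or {})
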