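"""Audio and label file I/O plus the shared pre-processing primitives.

Recordings of pressurised metered-dose inhaler (pMDI) use are mono RIFF PCM
WAV files (nominally 48 kHz / 16-bit).  Event labels live in plain CSV files
with columns ``start_s,end_s,class`` where the class ids are

    1 = noise, 2 = exhalation, 3 = inhalation, 4 = actuation.

All label times are in seconds, 0-based, over half-open intervals
``[start, end)``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

NOISE, EXHALATION, INHALATION, ACTUATION = 1, 2, 3, 4
CLASS_NAMES = {1: "noise", 2: "exhalation", 3: "inhalation", 4: "actuation"}


class FormatError(ValueError):
    """Raised for unreadable or malformed input files."""


class EmptyInputError(ValueError):
    """Raised when a signal is empty or shorter than one analysis frame."""


@dataclass
class AudioSignal:
    """A sampled waveform with amplitudes normalised to [-1, 1]."""

    samples: np.ndarray
    fs: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.size < 1:
            raise EmptyInputError("empty audio signal")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FrameMatrix:
    """Overlapping analysis frames cut from an :class:`AudioSignal`."""

    frames: np.ndarray           # (n_frames, frame_len)
    frame_len_s: float
    step_s: float
    fs: float
    start_times: np.ndarray      # (n_frames,) seconds

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + self.frame_len_s / 2.0


@dataclass
class LabelTrack:
    """Timed sound-event labels: list of (start_s, end_s, class_id)."""

    entries: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, cls in self.entries:
            if not start < end:
                raise FormatError(f"label interval [{start}, {end}) is empty")
            if cls not in CLASS_NAMES:
                raise FormatError(f"unknown class id {cls}")
        ev = sorted((e for e in self.entries if e[2] != NOISE))
        for (s0, e0, _), (s1, e1, _) in zip(ev, ev[1:]):
            if s1 < e0 - 1e-9:
                raise FormatError(
                    f"overlapping event labels [{s0},{e0}) and [{s1},{e1})")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def load_wav(path: str | Path) -> AudioSignal:
    """Read a RIFF PCM WAV file; stereo input keeps the first channel.

    Integer PCM is scaled to [-1, 1] by the full-scale value of its dtype.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:  # scipy raises assorted ValueError subclasses
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise EmptyInputError(f"zero-length WAV file {path}")
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioSignal(samples=samples, fs=float(fs), source_id=path.stem)


def write_wav(path: str | Path, sig: AudioSignal) -> None:
    """Write as 16-bit PCM, clipping to full scale."""
    x = np.clip(sig.samples, -1.0, 1.0 - 2.0 ** -15)
    data = np.round(x * 32768.0).astype(np.int16)
    wavfile.write(Path(path), int(round(sig.fs)), data)


def bandpass(sig: AudioSignal, lo: float, hi: float, order: int = 4) -> AudioSignal:
    """Zero-phase Butterworth band-pass filter.

    A 4th-order Butterworth is applied forward and backward (``filtfilt``),
    so the passband sees ~8th-order magnitude response and no group delay.
    ``hi`` is clamped to 0.45*fs when it is not representable at this sample
    rate (e.g. the 22 kHz stage-1 band edge on decimated input).
    """
    if lo >= hi:
        raise ValueError(f"bandpass requires lo < hi, got {lo} >= {hi}")
    if lo <= 0:
        raise ValueError("bandpass lower edge must be positive")
    nyq = sig.fs / 2.0
    if hi >= nyq:
        hi_eff = 0.45 * sig.fs
        warnings.warn(
            f"band edge {hi} Hz not representable at fs={sig.fs}; "
            f"clamped to {hi_eff:.0f} Hz")
        hi = hi_eff
        if lo >= hi:
            raise ValueError("band collapsed after clamping upper edge")
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, sig.samples)
    return AudioSignal(filtered, sig.fs, sig.source_id)


def frame_signal(
    sig: AudioSignal,
    frame_len_s: float,
    step_s: float,
    remove_dc: bool = True,
    window: str = "none",
) -> FrameMatrix:
    """Cut a signal into overlapping frames.

    The trailing partial frame is discarded, giving
    ``n_frames = floor((n_samples - frame_len) / step) + 1``.  DC removal
    subtracts each frame's mean before the optional Hanning window.
    """
    if not frame_len_s > step_s > 0:
        raise ValueError("need frame_len_s > step_s > 0")
    frame_len = int(round(frame_len_s * sig.fs))
    step = int(round(step_s * sig.fs))
    n = sig.samples.size
    if n < frame_len:
        raise EmptyInputError(
            f"signal of {n} samples shorter than one {frame_len}-sample frame")
    n_frames = (n - frame_len) // step + 1
    idx = np.arange(frame_len)[None, :] + step * np.arange(n_frames)[:, None]
    frames = sig.samples[idx].astype(np.float64)
    if remove_dc:
        frames -= frames.mean(axis=1, keepdims=True)
    if window == "hanning":
        frames *= np.hanning(frame_len)[None, :]
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    start_times = step * np.arange(n_frames) / sig.fs
    return FrameMatrix(frames, frame_len / sig.fs, step / sig.fs,
                       sig.fs, start_times)


def read_labels(path: str | Path) -> LabelTrack:
    """Read a label CSV with header ``start_s,end_s,class``."""
    entries: list[tuple[float, float, int]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "start_s", "end_s", "class"
        }.issubset(reader.fieldnames):
            raise FormatError(
                f"{path}: expected CSV header start_s,end_s,class")
        for row in reader:
            try:
                entries.append(
                    (float(row["start_s"]), float(row["end_s"]),
                     int(row["class"])))
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: bad row {row}") from exc
    return LabelTrack(entries)


def write_labels(path: str | Path, track: LabelTrack) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "class"])
        for start, end, cls in sorted(track.entries):
            writer.writerow([f"{start:.6f}", f"{end:.6f}", cls])


def labels_to_frames(track: LabelTrack, frames: FrameMatrix) -> np.ndarray:
    """Assign each frame the class covering its midpoint.

    Uncovered frames are noise (class 1).  A midpoint landing exactly on the
    boundary between two adjacent events belongs to the later-starting event
    (half-open interval convention).
    """
    labels = np.full(frames.n_frames, NOISE, dtype=np.int64)
    mids = frames.mid_times
    for start, end, cls in sorted(track.entries):
        covered = (mids >= start - 1e-12) & (mids < end - 1e-12)
        labels[covered] = cls
    return labels


def frames_to_labels(labels: Sequence[int], frames: FrameMatrix) -> LabelTrack:
    """Concatenate maximal same-class frame runs back into a LabelTrack.

    Event times span the first frame's start to the last frame's end.
    Noise runs are not emitted.
    """
    labels = np.asarray(labels)
    entries: list[tuple[float, float, int]] = []
    i = 0
    while i < labels.size:
        j = i
        while j + 1 < labels.size and labels[j + 1] == labels[i]:
            j += 1
        if labels[i] != NOISE:
            start = float(frames.start_times[i])
            end = float(frames.start_times[j] + frames.frame_len_s)
            entries.append((start, end, int(labels[i])))
        i = j + 1
    # clip overlapping tails introduced by frame overlap
    fixed: list[tuple[float, float, int]] = []
    for k, (s, e, c) in enumerate(entries):
        if k + 1 < len(entries):
            e = min(e, entries[k + 1][0])
        if e > s:
            fixed.append((s, e, c))
    return LabelTrack(fixed)
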