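"""Raw recordings -> standardized, labeled 400x2 segments.

Chain per recording: per-sensor resultant acceleration
A_ij = sqrt(ax^2 + ay^2 + az^2), jerk (first difference scaled by the
sampling rate), sliding 1-s RMS, overlapping 400-sample (5 s at 80 Hz)
windows, per-channel z-scoring within each window, and severity
binarization (0/1 -> low, 3/4 -> high, 2 dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import RawRecording

logger = logging.getLogger(__name__)

LOW, HIGH, DROPPED = "low", "high", "dropped"


@dataclass
class PreprocessConfig:
    rms_window_s: float = 1.0
    rms_stride: int = 1
    segment_length: int = 400
    segment_stride: int = 80
    eps: float = 1e-8


@dataclass
class Segment:
    """One standardized 400x2 window with its label and provenance."""

    window: np.ndarray  # (length, 2)
    label: str  # LOW | HIGH
    group_id: str  # parent recording id
    cohort: str
    task: str


def compute_resultant(recording: RawRecording) -> np.ndarray:
    """Per-sensor Euclidean magnitude of the acceleration vector, (n, 2)."""
    s = recording.samples
    if s.ndim != 3 or s.shape[1] != 2:
        raise ValueError("recording must carry two equal-length sensor streams")
    return np.sqrt((s**2).sum(axis=2))


def compute_jerk(resultant: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Forward-difference derivative scaled by fs; output length n-1."""
    resultant = np.asarray(resultant, dtype=float)
    if resultant.shape[0] < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.diff(resultant, axis=0) * sampling_rate


def rms_window(
    series: np.ndarray,
    sampling_rate: float,
    window_s: float = 1.0,
    stride: int = 1,
) -> np.ndarray:
    """Sliding root-mean-square over a trailing window of round(window_s*fs).

    Output length floor((n - w) / stride) + 1 per channel.
    """
    series = np.asarray(series, dtype=float)
    w = int(round(window_s * sampling_rate))
    if series.shape[0] < w:
        raise ValueError("series shorter than one RMS window")
    sq = series**2
    csum = np.concatenate([np.zeros((1,) + sq.shape[1:]), np.cumsum(sq, axis=0)])
    means = (csum[w:] - csum[:-w]) / w
    out = np.sqrt(np.maximum(means, 0.0))
    return out[::stride]


def segment_sequence(
    values: np.ndarray, length: int = 400, stride: int = 80
) -> list[np.ndarray]:
    """Overlapping windows starting at 0, stride, 2*stride, ...

    Returns an empty list (with a logged warning) when the sequence is
    shorter than one window, so short recordings do not abort a cohort.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < length:
        logger.warning(
            "sequence of length %d shorter than window %d; skipped", n, length
        )
        return []
    count = (n - length) // stride + 1
    return [values[i * stride : i * stride + length].copy() for i in range(count)]


def standardize_segment(window: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-channel z-scoring within the window; constant channels -> zeros."""
    window = np.asarray(window, dtype=float)
    mu = window.mean(axis=0, keepdims=True)
    sd = window.std(axis=0, keepdims=True)
    out = np.zeros_like(window)
    ok = sd[0] >= eps
    out[:, ok] = (window[:, ok] - mu[:, ok]) / sd[:, ok]
    return out


def binarize_severity(severity: int) -> str:
    """0/1 -> low, 3/4 -> high, 2 -> dropped (excluded everywhere)."""
    if not (isinstance(severity, (int, np.integer)) and 0 <= severity <= 4):
        raise ValueError("severity must be an integer in 0..4")
    if severity <= 1:
        return LOW
    if severity >= 3:
        return HIGH
    return DROPPED


def preprocess_recording(
    recording: RawRecording, config: PreprocessConfig | None = None
) -> list[Segment]:
    """Full chain on one recording; severity-2 recordings yield no segments."""
    config = config or PreprocessConfig()
    label = binarize_severity(recording.severity)
    if label == DROPPED:
        return []
    resultant = compute_resultant(recording)
    jerk = compute_jerk(resultant, recording.sampling_rate)
    rms = rms_window(
        jerk, recording.sampling_rate, config.rms_window_s, config.rms_stride
    )
    windows = segment_sequence(rms, config.segment_length, config.segment_stride)
    return [
        Segment(
            window=standardize_segment(w, config.eps),
            label=label,
            group_id=recording.recording_id,
            cohort=recording.cohort,
            task=recording.task,
        )
        for w in windows
    ]


# -- segment store ------------------------------------------------------


@dataclass
class SegmentSet:
    """Array-of-segments container: X (n, length, 2) plus an index table."""

    X: np.ndarray
    index: pd.DataFrame  # segment_id, group_id, cohort, task, label

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset_by_groups(self, group_ids) -> "SegmentSet":
        mask = self.index["group_id"].isin(set(group_ids)).to_numpy()
        return SegmentSet(self.X[mask], self.index[mask].reset_index(drop=True))

    def labels(self) -> np.ndarray:
        return (self.index["label"] == HIGH).to_numpy().astype(int)

    def save(self, npz_path, csv_path) -> None:
        np.savez_compressed(npz_path, X=self.X)
        self.index.to_csv(csv_path, index=False)

    @classmethod
    def load(cls, npz_path, csv_path) -> "SegmentSet":
        with np.load(npz_path) as data:
            X = data["X"]
        return cls(X, pd.read_csv(csv_path))


def preprocess_cohort(
    recordings, config: PreprocessConfig | None = None
) -> SegmentSet:
    """Preprocess every recording and stack the surviving segments."""
    config = config or PreprocessConfig()
    windows, rows = [], []
    i = 0
    for rec in recordings:
        for seg in preprocess_recording(rec, config):
            windows.append(seg.window)
            rows.append(
                {
                    "segment_id": f"seg{i:06d}",
                    "group_id": seg.group_id,
                    "cohort": seg.cohort,
                    "task": seg.task,
                    "label": seg.label,
                }
            )
            i += 1
    if windows:
        X = np.stack(windows)
    else:
        X = np.empty((0, config.segment_length, 2))
    return SegmentSet(X, pd.DataFrame(rows, columns=["segment_id", "group_id", "cohort", "task", "label"]))
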