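"""Deterministic sEMG preprocessing.

The chain is: per-channel standardization with a scaler fit on training
data only, rectification (absolute value), non-overlapping 200-sample
windowing, and reshaping of each window into 10 subsequences of
1 x 20 x 12 for the spatiotemporal classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Scaler", "WindowSpec", "fit_scaler", "transform", "window_segment", "tensorize", "untensorize"]

REST_LABEL = 0


@dataclass
class Scaler:
    """Per-channel standardizer followed by rectification."""

    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None


@dataclass(frozen=True)
class WindowSpec:
    """Windowing and tensor layout parameters.

    200-sample non-overlapping windows (~104 ms at 1926 Hz), split into
    10 subsequences of 20 columns; streaming inference re-classifies the
    trailing window every 20 samples (~10 ms).
    """

    window_len: int = 200
    overlap: int = 0
    n_subseq: int = 10
    subseq_cols: int = 20
    stride_inference: int = 20

    def __post_init__(self):
        if self.window_len != self.n_subseq * self.subseq_cols:
            raise ValueError("window_len must equal n_subseq * subseq_cols")
        if self.window_len % self.stride_inference != 0:
            raise ValueError("stride_inference must divide window_len")
        if self.overlap != 0:
            raise ValueError("training windows are non-overlapping")


def fit_scaler(train_segments: Sequence[np.ndarray]) -> Scaler:
    """Fit per-channel mean/sd over all training samples pooled.

    Raises on empty input or any constant channel (sd = 0).
    """
    if not len(train_segments):
        raise ValueError("no training segments")
    data = np.concatenate([np.asarray(s, dtype=np.float64) for s in train_segments])
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0).tolist()
        raise ValueError(f"constant channel(s) {bad}: cannot standardize")
    return Scaler(mean_=mean, sd_=sd)


def transform(segment: np.ndarray, scaler: Scaler) -> np.ndarray:
    """Standardize then rectify: ``|(x - mean) / sd|`` elementwise."""
    if not scaler.fitted:
        raise ValueError("scaler is not fitted")
    x = np.asarray(segment, dtype=np.float32)
    return np.abs((x - scaler.mean_.astype(np.float32)) / scaler.sd_.astype(np.float32))


def window_label(labels: np.ndarray) -> int:
    """Label of one window: majority vote, ties broken toward rest.

    If the rest class ties the most frequent grasp the window is rest
    (conservative for intent detection); a tie between grasps breaks to
    the lower grasp id.
    """
    counts = np.bincount(labels)
    top = counts.max()
    if counts[REST_LABEL] == top:
        return REST_LABEL
    return int(np.argmax(counts))


def window_segment(
    segment: np.ndarray, labels: np.ndarray, spec: WindowSpec = WindowSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a segment into non-overlapping labelled windows.

    Returns ``(windows, window_labels)`` with windows of shape
    (n, window_len, channels); the trailing remainder is dropped.  A
    segment shorter than one window yields empty output with a warning.
    """
    segment = np.asarray(segment)
    labels = np.asarray(labels)
    if len(segment) != len(labels):
        raise ValueError("segment and labels must have equal length")
    n = len(segment) // spec.window_len
    if n == 0:
        warnings.warn(f"segment of {len(segment)} samples is shorter than one window")
        return (
            np.empty((0, spec.window_len, segment.shape[1]), dtype=segment.dtype),
            np.empty(0, dtype=np.int64),
        )
    used = n * spec.window_len
    windows = segment[:used].reshape(n, spec.window_len, segment.shape[1])
    wlabels = np.array(
        [window_label(labels[i * spec.window_len : (i + 1) * spec.window_len]) for i in range(n)],
        dtype=np.int64,
    )
    return windows, wlabels


def tensorize(windows: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Reshape (n, 200, 12) windows to the (n, 10, 1, 20, 12) input tensor.

    Subsequence ``s``, column ``c``, channel ``e`` holds window sample
    ``(20*s + c, e)``; flattening the subsequences in order reproduces
    the original window bit-exactly.
    """
    windows = np.asarray(windows)
    if windows.ndim != 3 or windows.shape[1] != spec.window_len:
        raise ValueError(f"expected (n, {spec.window_len}, channels) windows, got {windows.shape}")
    n, _, ch = windows.shape
    return windows.reshape(n, spec.n_subseq, 1, spec.subseq_cols, ch)


def untensorize(tensor: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Inverse of :func:`tensorize`."""
    tensor = np.asarray(tensor)
    if tensor.ndim != 5 or tensor.shape[1:4] != (spec.n_subseq, 1, spec.subseq_cols):
        raise ValueError(f"expected (n, {spec.n_subseq}, 1, {spec.subseq_cols}, channels), got {tensor.shape}")
    n, _, _, _, ch = tensor.shape
    return tensor.reshape(n, spec.window_len, ch)
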