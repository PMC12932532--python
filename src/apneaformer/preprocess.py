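"""Signal preprocessing: min-max normalization, missing-value imputation,
non-overlapping 30-s windowing, and projection of event-interval
annotations onto a one-second label grid.

Order of operations matters: the min/max are computed over the *non-missing*
values of the array first, then missing samples are set to zero, then the
signal is segmented. Computing the min after imputation would corrupt it.

Conventions: all times are 0-based seconds; intervals are half-open
[start, end). A second ``s`` is labeled positive iff its bin start time lies
inside some annotated event interval, which preserves each event's duration
in whole seconds and never extends it. Events spanning a window boundary
produce positives in both windows, preserving continuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import EventAnnotation, Recording

__all__ = [
    "Window",
    "normalize_minmax",
    "impute_missing",
    "segment",
    "project_event_labels",
    "windows_to_dataset",
    "preprocess_recording",
    "preprocess_cohort",
]


@dataclass
class Window:
    """A 30-s signal segment with 30 per-second binary labels."""

    subject_id: str
    window_index: int
    samples: np.ndarray  # length window_s * fs, values in [0, 1]
    labels: np.ndarray  # length window_s, {0, 1}
    start_time: float  # seconds from recording start


def normalize_minmax(samples: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] over the non-missing values, then set missing
    values to 0. A constant (zero-range) input maps entirely to 0."""
    x = np.asarray(samples, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("cannot normalize an all-missing signal")
    lo = x[finite].min()
    hi = x[finite].max()
    if hi > lo:
        out = (x - lo) / (hi - lo)
    else:
        out = np.zeros_like(x)
    out[~finite] = 0.0
    return out


def impute_missing(samples: np.ndarray) -> np.ndarray:
    """Replace every missing (NaN) sample with zero; leave the rest as is."""
    x = np.array(samples, dtype=float, copy=True)
    x[~np.isfinite(x)] = 0.0
    return x


def project_event_labels(
    events: list[EventAnnotation] | list[tuple[float, float]],
    duration: float,
) -> np.ndarray:
    """Project event intervals onto the one-second grid of a recording.

    Returns a binary vector of ``floor(duration)`` seconds where second
    ``s`` is 1 iff ``s`` (its bin start) lies in some [start, end). For an
    event [a, b) this marks seconds ceil(a) .. ceil(b)-1, so total positives
    per event equal ceil(b) - ceil(a).
    """
    n_seconds = int(math.floor(duration + 1e-9))
    grid = np.zeros(n_seconds, dtype=np.int8)
    for ev in events:
        start, end = (ev.start, ev.end) if isinstance(ev, EventAnnotation) else ev
        if start < 0 or end > duration + 1e-9:
            raise ValueError(f"event [{start}, {end}) outside recording of {duration}s")
        lo = int(math.ceil(start - 1e-9))
        hi = min(int(math.ceil(end - 1e-9)), n_seconds)
        if hi > lo:
            grid[lo:hi] = 1
    return grid


def segment(
    recording: Recording,
    window_s: float = 30.0,
    normalize: bool = True,
    normalize_scope: str = "recording",
) -> list[Window]:
    """Normalize, impute, and cut a recording into non-overlapping windows.

    Produces ``floor(duration / window_s)`` windows; a trailing partial
    window is dropped. Window k covers [k*window_s, (k+1)*window_s) and
    carries one label per second from the recording-wide label grid, so an
    event crossing a window boundary labels seconds in both windows.
    """
    if recording.samples is None:
        raise ValueError("recording has no rendered samples")
    fs = recording.fs
    if fs <= 0 or recording.duration <= 0:
        raise ValueError("fs and duration must be positive")
    win_len = int(round(window_s * fs))
    labels_per_window = int(round(window_s))
    x = np.asarray(recording.samples, dtype=float)
    if normalize and normalize_scope == "recording":
        x = normalize_minmax(x)
    else:
        x = impute_missing(x)
    grid = project_event_labels(recording.events, recording.duration)
    n_windows = len(x) // win_len
    windows = []
    for k in range(n_windows):
        seg = x[k * win_len : (k + 1) * win_len]
        if normalize and normalize_scope == "window":
            seg = normalize_minmax(seg) if np.isfinite(seg).any() else np.zeros_like(seg)
        lab = np.zeros(labels_per_window, dtype=np.int8)
        lo = k * labels_per_window
        avail = grid[lo : lo + labels_per_window]
        lab[: avail.size] = avail
        windows.append(
            Window(
                subject_id=recording.subject_id,
                window_index=k,
                samples=seg,
                labels=lab,
                start_time=k * window_s,
            )
        )
    return windows


def windows_to_dataset(
    windows: list[Window],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into the model tensor contract.

    Returns ``(X, y, subjects, window_indices)`` with X of shape
    (n, sequence_length, 1), y of shape (n, 30). Order is preserved.
    """
    if not windows:
        return (
            np.zeros((0, 0, 1), dtype=np.float32),
            np.zeros((0, 0), dtype=np.int8),
            np.zeros(0, dtype=object),
            np.zeros(0, dtype=int),
        )
    lengths = {len(w.samples) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths in batch: {sorted(lengths)}")
    X = np.stack([w.samples for w in windows]).astype(np.float32)[..., None]
    y = np.stack([w.labels for w in windows]).astype(np.int8)
    subjects = np.array([w.subject_id for w in windows], dtype=object)
    indices = np.array([w.window_index for w in windows], dtype=int)
    return X, y, subjects, indices


def preprocess_recording(
    recording: Recording,
    window_s: float = 30.0,
    normalize_scope: str = "recording",
) -> list[Window]:
    return segment(recording, window_s=window_s, normalize=True,
                   normalize_scope=normalize_scope)


def preprocess_cohort(
    recordings: list[Recording],
    window_s: float = 30.0,
    normalize_scope: str = "recording",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess every recording and stack all windows into one dataset."""
    windows: list[Window] = []
    for rec in recordings:
        windows.extend(
            preprocess_recording(rec, window_s=window_s, normalize_scope=normalize_scope)
        )
    return windows_to_dataset(windows)
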