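"""Recording and dataset persistence.

Recordings are stored either as NPZ (keys ``fs``, ``samples``,
``subject_id``) or as a pair of CSVs: ``<id>_signal.csv`` with columns
``t_s, ecg`` (missing samples as empty fields) and ``<id>_events.csv``
with columns ``start_s, end_s, kind``. Windowed datasets persist as NPZ
with keys ``X`` (n, L, 1), ``y`` (n, 30), ``subject`` (n),
``window_index`` (n).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .synthetic import EventAnnotation, Recording

__all__ = [
    "save_recording", "load_recording", "save_dataset", "load_dataset",
]


def _events_path(directory: str, subject_id: str) -> str:
    return os.path.join(directory, f"{subject_id}_events.csv")


def save_recording(rec: Recording, directory: str, fmt: str = "npz") -> None:
    os.makedirs(directory, exist_ok=True)
    events = pd.DataFrame(
        [(ev.start, ev.end, ev.kind) for ev in rec.events],
        columns=["start_s", "end_s", "kind"],
    )
    events.to_csv(_events_path(directory, rec.subject_id), index=False)
    if rec.samples is None:
        return
    if fmt == "npz":
        np.savez(
            os.path.join(directory, f"{rec.subject_id}.npz"),
            fs=rec.fs, samples=rec.samples, subject_id=rec.subject_id,
        )
    elif fmt == "csv":
        t = np.arange(len(rec.samples)) / rec.fs
        pd.DataFrame({"t_s": t, "ecg": rec.samples}).to_csv(
            os.path.join(directory, f"{rec.subject_id}_signal.csv"),
            index=False,
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _load_events(directory: str, subject_id: str) -> list[EventAnnotation]:
    path = _events_path(directory, subject_id)
    if not os.path.exists(path):
        return []
    df = pd.read_csv(path)
    return [EventAnnotation(start=row.start_s, end=row.end_s, kind=row.kind)
            for row in df.itertuples()]


def load_recording(directory: str, subject_id: str,
                   fs: float | None = None) -> Recording:
    """Load a recording saved by :func:`save_recording` (either format)."""
    npz_path = os.path.join(directory, f"{subject_id}.npz")
    csv_path = os.path.join(directory, f"{subject_id}_signal.csv")
    if os.path.exists(npz_path):
        with np.load(npz_path, allow_pickle=False) as data:
            samples = np.asarray(data["samples"], dtype=float)
            fs = float(data["fs"])
    elif os.path.exists(csv_path):
        df = pd.read_csv(csv_path)
        samples = df["ecg"].to_numpy(dtype=float)  # empty fields -> NaN
        if fs is None:
            dt = np.diff(df["t_s"].to_numpy())
            fs = 1.0 / float(np.median(dt))
    else:
        raise FileNotFoundError(f"no signal file for {subject_id} in {directory}")
    duration = len(samples) / fs
    return Recording(
        subject_id=subject_id, fs=fs, duration=duration,
        events=_load_events(directory, subject_id), samples=samples,
    )


def save_dataset(path: str, X: np.ndarray, y: np.ndarray,
                 subjects: np.ndarray, window_index: np.ndarray) -> None:
    np.savez_compressed(
        path, X=X, y=y,
        subject=np.asarray(subjects, dtype=str),
        window_index=np.asarray(window_index, dtype=int),
    )


def load_dataset(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    with np.load(path, allow_pickle=False) as data:
        return (data["X"], data["y"], data["subject"].astype(object),
                data["window_index"])
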