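"""Plain-text and raw-array I/O for recordings, cohorts, events, results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bursting import BurstEvent
from .exceptions import InvalidParameterError
from .recording import TimeSeriesRecording

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "write_recording_raw",
    "read_recording_raw",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "write_events",
    "write_results",
    "write_report",
]


def write_recording_text(recording: TimeSeriesRecording, path) -> None:
    """Two-column delimited text: time_s, value."""
    data = np.column_stack([recording.times(), recording.samples])
    header = f"time_s\tvalue\t# fs={recording.fs} subject_id={recording.subject_id}"
    np.savetxt(path, data, delimiter="\t", header=header, comments="")


def read_recording_text(path, subject_id: str = "") -> TimeSeriesRecording:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise InvalidParameterError(f"{path}: expected two columns (time_s, value)")
    dt = np.diff(data[:, 0])
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise InvalidParameterError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    return TimeSeriesRecording(samples=data[:, 1], fs=fs, subject_id=subject_id)


def write_recording_raw(recording: TimeSeriesRecording, path) -> None:
    """Little-endian float64 array plus a sidecar JSON header."""
    path = Path(path)
    recording.samples.astype("<f8").tofile(path)
    header = {"fs": recording.fs, "subject_id": recording.subject_id,
              "n_samples": recording.n_samples, "dtype": "<f8"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))


def read_recording_raw(path) -> TimeSeriesRecording:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype=header.get("dtype", "<f8"))
    return TimeSeriesRecording(
        samples=samples, fs=float(header["fs"]), subject_id=header.get("subject_id", "")
    )


def read_recording(path, subject_id: str = "") -> TimeSeriesRecording:
    """Dispatch on extension: .tsv/.txt/.csv text, anything else raw+JSON."""
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt", ".csv"):
        return read_recording_text(path, subject_id=subject_id)
    return read_recording_raw(path)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(events_by_subject: dict[str, list[BurstEvent]], path) -> None:
    """BED-like tab-separated event table."""
    records = [
        {
            "subject_id": sid,
            "onset_s": e.onset_s,
            "offset_s": e.offset_s,
            "peak_amplitude": e.peak_amplitude,
        }
        for sid, events in events_by_subject.items()
        for e in events
    ]
    pd.DataFrame(
        records, columns=["subject_id", "onset_s", "offset_s", "peak_amplitude"]
    ).to_csv(path, sep="\t", index=False)


def write_results(rows: list[dict], path) -> None:
    """Tidy results CSV: outcome, predictor, estimate, ci_low, ci_high, bf10."""
    pd.DataFrame(
        rows, columns=["outcome", "family", "predictor", "estimate", "ci_low", "ci_high", "bf10"]
    ).to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
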