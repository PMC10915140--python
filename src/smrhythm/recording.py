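"""Core time-series container used by every processing stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["TimeSeriesRecording"]


@dataclass
class TimeSeriesRecording:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Signal values in arbitrary source units.
    fs
        Sampling rate in Hz.
    subject_id
        Optional subject identifier carried through the pipeline.
    truth_events
        Optional ground-truth event list of ``(onset_s, offset_s,
        peak_amplitude)`` tuples, populated by the synthetic generator.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    truth_events: list[tuple[float, float, float]] | None = field(default=None)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples contain non-finite values")
        if not (self.fs > 0):
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds starting at 0."""
        return np.arange(self.samples.size) / self.fs
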