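"""Transient mu-beta burst detection and per-subject summaries.

The signal is band-pass filtered (8-30 Hz by default) with a zero-phase FIR
filter, its Hilbert envelope is thresholded at ``k x median(envelope)``, and
each suprathreshold excursion seeds an event whose extent is defined either
by half-max crossings around the excursion peak (default) or by the
threshold crossings themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert

from .exceptions import InsufficientDataError, InvalidParameterError
from .recording import TimeSeriesRecording

__all__ = [
    "BurstSettings",
    "BurstEvent",
    "BurstFeatures",
    "mu_beta_envelope",
    "detect_bursts",
    "summarize_bursts",
]


@dataclass(frozen=True)
class BurstSettings:
    """Detection settings.

    ``threshold_factor`` multiplies the median of the analyzed envelope;
    ``threshold`` (absolute envelope units) overrides the median rule when
    set, for signals whose baseline envelope is degenerate (e.g. noise-free
    synthetic trains where the median is numerically zero).
    """

    band: tuple[float, float] = (8.0, 30.0)
    threshold_factor: float = 2.0
    edge_rule: str = "half_max"  # or "threshold"
    threshold: float | None = None

    def __post_init__(self):
        if self.threshold is None and not (self.threshold_factor > 1):
            raise InvalidParameterError("threshold_factor must exceed 1")
        if not (self.band[0] < self.band[1]):
            raise InvalidParameterError("band low must be below band high")
        if self.edge_rule not in ("half_max", "threshold"):
            raise InvalidParameterError(f"unknown edge_rule '{self.edge_rule}'")


@dataclass(frozen=True)
class BurstEvent:
    onset_s: float
    offset_s: float
    peak_amplitude: float
    peak_time_s: float

    def __post_init__(self):
        if not (self.onset_s < self.offset_s):
            raise InvalidParameterError("onset must precede offset")
        if not (self.onset_s <= self.peak_time_s <= self.offset_s):
            raise InvalidParameterError("peak time must lie within the event")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class BurstFeatures:
    """Per-subject burst summary; medians are NaN when undefined."""

    rate: float  # events per minute
    median_duration_ms: float
    median_interval_ms: float
    median_amplitude: float
    n_events: int
    analyzed_s: float


def mu_beta_envelope(
    recording: TimeSeriesRecording, band: tuple[float, float] = (8.0, 30.0)
) -> TimeSeriesRecording:
    """Hilbert envelope of the band-pass filtered signal.

    Zero-phase FIR band-pass (Hamming design, order = 3 cycles of the band's
    low frequency, applied forward-backward), then analytic-signal
    magnitude.  Output has the same length and sampling rate as the input.
    """
    low, high = band
    if not (recording.fs > 2 * high):
        raise InvalidParameterError(
            f"fs={recording.fs} must exceed twice the band high ({high} Hz)"
        )
    numtaps = int(round(3 * recording.fs / low))
    if numtaps % 2 == 0:
        numtaps += 1
    if recording.n_samples <= 3 * numtaps:
        raise InsufficientDataError(
            f"recording of {recording.n_samples} samples is shorter than "
            f"3x the filter order ({numtaps} taps)"
        )
    taps = firwin(numtaps, [low, high], pass_zero=False, fs=recording.fs, window="hamming")
    filtered = filtfilt(taps, [1.0], recording.samples)
    envelope = np.abs(hilbert(filtered))
    return TimeSeriesRecording(
        samples=envelope,
        fs=recording.fs,
        subject_id=recording.subject_id,
        truth_events=recording.truth_events,
    )


def _excursions(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    diff = np.diff(above.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    return list(zip(starts, ends))


def detect_bursts(
    envelope: TimeSeriesRecording, settings: BurstSettings = BurstSettings()
) -> list[BurstEvent]:
    """Threshold the envelope and return sorted, non-overlapping events.

    The threshold is ``threshold_factor x median`` of the whole analyzed
    envelope (or the absolute override).  With ``edge_rule='half_max'`` an
    event spans from the last upward crossing of half the excursion peak
    before the peak to the first downward crossing after it; spans that
    touch or overlap are merged (peak = max of the merged span).  With
    ``edge_rule='threshold'`` the event is the suprathreshold excursion
    itself.  Onsets are the first sample at/above the edge level; offsets
    are the first sample back below it, so every event spans at least one
    sample.  Events clipped by the recording edge are discarded.
    """
    env = envelope.samples
    if np.any(env < 0):
        raise InvalidParameterError("envelope must be non-negative")
    fs = envelope.fs
    n = env.size
    if settings.threshold is not None:
        thresh = float(settings.threshold)
    else:
        thresh = settings.threshold_factor * float(np.median(env))

    above = env > thresh  # strictly above: constant-zero envelope yields none
    if not above.any():
        return []

    spans: list[tuple[int, int, float, int]] = []  # (start, end, peak, peak_idx)
    for start, end in _excursions(above):
        peak_idx = start + int(np.argmax(env[start : end + 1]))
        peak = float(env[peak_idx])
        if settings.edge_rule == "threshold":
            if start == 0 or end == n - 1:
                continue  # clipped by the recording edge
            spans.append((start, end, peak, peak_idx))
            continue
        half = peak / 2.0
        left = peak_idx
        while left > 0 and env[left - 1] >= half:
            left -= 1
        right = peak_idx
        while right < n - 1 and env[right + 1] >= half:
            right += 1
        if (left == 0 and env[0] >= half) or (right == n - 1 and env[n - 1] >= half):
            continue  # clipped by the recording edge
        spans.append((left, right, peak, peak_idx))

    if settings.edge_rule == "half_max":
        merged: list[list] = []
        for span in sorted(spans):
            if merged and span[0] <= merged[-1][1] + 1:
                prev = merged[-1]
                prev[1] = max(prev[1], span[1])
                if span[2] > prev[2]:
                    prev[2], prev[3] = span[2], span[3]
            else:
                merged.append(list(span))
        spans = [tuple(m) for m in merged]

    events = [
        BurstEvent(
            onset_s=start / fs,
            offset_s=(end + 1) / fs,  # first sample back below the edge level
            peak_amplitude=peak,
            peak_time_s=peak_idx / fs,
        )
        for start, end, peak, peak_idx in sorted(spans)
    ]
    return events


def summarize_bursts(
    events: list[BurstEvent],
    analyzed_s: float,
    segments: list[tuple[float, float]] | None = None,
) -> BurstFeatures:
    """Rate, median duration/interval/amplitude over a list of events.

    Intervals (end of one burst to onset of the next) are only computed
    between consecutive events within the same contiguous segment; pass
    ``segments`` as (start_s, end_s) pairs when the analyzed series is a
    concatenation.  An empty event list yields rate 0 and NaN medians.
    """
    if analyzed_s <= 0:
        raise InvalidParameterError("analyzed_s must be positive")
    n_events = len(events)
    rate = n_events / (analyzed_s / 60.0)
    if n_events == 0:
        return BurstFeatures(0.0, float("nan"), float("nan"), float("nan"), 0, analyzed_s)

    events = sorted(events, key=lambda e: e.onset_s)
    durations = np.array([e.duration_s for e in events])
    amplitudes = np.array([e.peak_amplitude for e in events])

    def segment_of(event):
        if segments is None:
            return 0
        for i, (lo, hi) in enumerate(segments):
            if lo <= event.onset_s and event.offset_s <= hi:
                return i
        return -1  # straddles a boundary; never pairs with a neighbour

    intervals = []
    for prev, nxt in zip(events[:-1], events[1:]):
        if segment_of(prev) == segment_of(nxt) and segment_of(prev) != -1:
            intervals.append(nxt.onset_s - prev.offset_s)

    return BurstFeatures(
        rate=rate,
        median_duration_ms=float(np.median(durations) * 1000.0),
        median_interval_ms=float(np.median(intervals) * 1000.0) if intervals else float("nan"),
        median_amplitude=float(np.median(amplitudes)),
        n_events=n_events,
        analyzed_s=analyzed_s,
    )
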