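"""Shared data model: timestamped signal streams, event/response logs, windowing.

All modalities share a single session clock in seconds. Streams are uniformly
sampled; the time of sample ``i`` is ``start_time + i / sampling_rate``.
Windows are half-open ``[t_start, t_end)`` so that a sample falling exactly at
a stimulus onset is *excluded* from the pre-stimulus window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ARROW_TYPES = ("reliable", "unreliable")
OUTCOMES = ("no_change", "incorrect_change", "correct_change", "normal")
RESPONSE_KEYS = ("U", "N", "I", "C")


class NoSamplesError(ValueError):
    """Raised when a requested window contains no samples of a stream."""


@dataclass
class Window:
    """Half-open time interval ``[t_start, t_end)`` in session seconds."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"empty window: [{self.t_start}, {self.t_end})")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SignalStream:
    """Uniformly sampled single-channel stream on the session clock.

    Parameters
    ----------
    channel_id : str
        Label, e.g. ``"Pz"``, ``"ecg"``, ``"gaze_x"``.
    sampling_rate : float
        Samples per second; must be positive.
    start_time : float
        Session time of the first sample, seconds.
    samples : ndarray
        Signal values (µV for EEG, mV for ECG, px for gaze axes).
    units : str
        Unit label carried through windowing.
    confidence : ndarray, optional
        Per-sample tracker confidence in [0, 1]; gaze streams only.
    """

    channel_id: str
    sampling_rate: float
    start_time: float
    samples: np.ndarray
    units: str = ""
    confidence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.samples.shape:
                raise ValueError("confidence must match samples in length")
            if self.confidence.size and (
                self.confidence.min() < 0 or self.confidence.max() > 1
            ):
                raise ValueError("confidence values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> float:
        """Session time just past the last sample (exclusive)."""
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


def extract_window(stream: SignalStream, window: Window) -> SignalStream:
    """Return the samples of ``stream`` with times in ``[t_start, t_end)``.

    Sampling rate, units and confidence are preserved; ``start_time`` of the
    result is the time of its first retained sample.  Raises
    :class:`NoSamplesError` when the window contains no samples — callers
    flag the trial invalid rather than aborting a run.
    """
    fs = stream.sampling_rate
    # index of first sample with t >= t_start; tolerance absorbs float jitter
    i0 = math.ceil((window.t_start - stream.start_time) * fs - 1e-9)
    i1 = math.ceil((window.t_end - stream.start_time) * fs - 1e-9)
    i0 = max(i0, 0)
    i1 = min(i1, stream.n_samples)
    if i1 <= i0:
        raise NoSamplesError(
            f"no samples of {stream.channel_id!r} in "
            f"[{window.t_start}, {window.t_end})"
        )
    conf = None if stream.confidence is None else stream.confidence[i0:i1]
    return replace(
        stream,
        start_time=stream.start_time + i0 / fs,
        samples=stream.samples[i0:i1].copy(),
        confidence=None if conf is None else conf.copy(),
    )


@dataclass
class Event:
    """One arrow presentation.

    ``outcome`` is ``"normal"`` iff the arrow is reliable; unreliable arrows
    carry one of the three failure outcomes and a 1-based ``trial_index``
    within their period.
    """

    onset: float
    arrow_type: str
    outcome: str
    period: int
    trial_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.arrow_type not in ARROW_TYPES:
            raise ValueError(f"unknown arrow_type {self.arrow_type!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "normal") != (self.arrow_type == "reliable"):
            raise ValueError("outcome 'normal' is reserved for reliable arrows")


@dataclass
class ResponseLog:
    """Button presses as (time, key) with keys U/N/I/C."""

    presses: list = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.presses]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("press times must be non-decreasing")
        for _, key in self.presses:
            if key not in RESPONSE_KEYS:
                raise ValueError(f"unknown key {key!r}")


def validate_events(events: Sequence[Event]) -> None:
    onsets = [e.onset for e in events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("event onsets must be strictly increasing")


# ---------------------------------------------------------------------------
# CSV interfaces (header row required, UTF-8)

def write_stream_csv(path, stream: SignalStream) -> None:
    df = pd.DataFrame({"time_s": stream.times(), "value": stream.samples})
    if stream.confidence is not None:
        df["confidence"] = stream.confidence
    df.to_csv(path, index=False)


def read_stream_csv(path, channel_id: str, sampling_rate: float, units: str = "") -> SignalStream:
    df = _read_csv(path, ["time_s", "value"])
    conf = df["confidence"].to_numpy() if "confidence" in df.columns else None
    return SignalStream(
        channel_id=channel_id,
        sampling_rate=sampling_rate,
        start_time=float(df["time_s"].iloc[0]) if len(df) else 0.0,
        samples=df["value"].to_numpy(),
        units=units,
        confidence=conf,
    )


def write_gaze_csv(path, x: SignalStream, y: SignalStream) -> None:
    df = pd.DataFrame(
        {
            "time_s": x.times(),
            "x_px": x.samples,
            "y_px": y.samples,
            "confidence": x.confidence,
        }
    )
    df.to_csv(path, index=False)


def read_gaze_csv(path, sampling_rate: float):
    df = _read_csv(path, ["time_s", "x_px", "y_px", "confidence"])
    t0 = float(df["time_s"].iloc[0]) if len(df) else 0.0
    conf = df["confidence"].to_numpy()
    x = SignalStream("gaze_x", sampling_rate, t0, df["x_px"].to_numpy(), "px", conf)
    y = SignalStream("gaze_y", sampling_rate, t0, df["y_px"].to_numpy(), "px", conf)
    return x, y


def write_events_csv(path, events: Sequence[Event]) -> None:
    df = pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "arrow_type": [e.arrow_type for e in events],
            "outcome": [e.outcome for e in events],
            "period": [e.period for e in events],
            "trial_index": [e.trial_index if e.trial_index is not None else "" for e in events],
        }
    )
    df.to_csv(path, index=False)


def read_events_csv(path) -> list:
    df = _read_csv(path, ["onset_s", "arrow_type", "outcome", "period", "trial_index"])
    events = []
    for _, row in df.iterrows():
        ti = row["trial_index"]
        ti = None if (pd.isna(ti) or ti == "") else int(ti)
        events.append(
            Event(
                onset=float(row["onset_s"]),
                arrow_type=str(row["arrow_type"]),
                outcome=str(row["outcome"]),
                period=int(row["period"]),
                trial_index=ti,
            )
        )
    validate_events(events)
    return events


def write_responses_csv(path, responses: ResponseLog) -> None:
    df = pd.DataFrame(
        {"time_s": [t for t, _ in responses.presses], "key": [k for _, k in responses.presses]}
    )
    df.to_csv(path, index=False)


def read_responses_csv(path) -> ResponseLog:
    df = _read_csv(path, ["time_s", "key"])
    return ResponseLog([(float(t), str(k)) for t, k in zip(df["time_s"], df["key"])])


def _read_csv(path, required_columns):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV is fatal with a file diagnostic
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
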