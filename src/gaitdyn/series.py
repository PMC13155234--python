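"""Core record types shared across the package.

Axis convention for lumbar accelerometry: column 0 is vertical (V), column 1
anterior-posterior (AP), column 2 mediolateral (ML), all in m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_NAMES = ("a_v", "a_ap", "a_ml")


@dataclass(frozen=True)
class AccelSeries:
    """Uniformly sampled tri-axial acceleration record.

    Parameters
    ----------
    samples : ndarray, shape (T, 3)
        Acceleration in m/s^2, axes ordered V, AP, ML.
    sample_rate : float
        Sampling rate in Hz (128 for the lumbar IMU this package models).
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float = 128.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must be (T, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("AccelSeries needs at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("AccelSeries contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class GroundTruth:
    """Exact stride events of a simulated walking signal.

    ``event_indices`` are sample indices of stride starts (phase origin of the
    base waveform); consecutive events bracket one stride, so there is one
    fewer stride than events.
    """

    event_indices: np.ndarray
    stride_times: np.ndarray
    stride_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        ev = np.asarray(self.event_indices, dtype=int)
        st = np.asarray(self.stride_times, dtype=float)
        if ev.ndim != 1 or np.any(np.diff(ev) <= 0):
            raise ValueError("event_indices must be strictly increasing")
        if len(st) != len(ev) - 1:
            raise ValueError(
                f"expected {len(ev) - 1} stride_times for {len(ev)} events, got {len(st)}"
            )
        object.__setattr__(self, "event_indices", ev)
        object.__setattr__(self, "stride_times", st)
        if self.stride_lengths is not None:
            sl = np.asarray(self.stride_lengths, dtype=float)
            if len(sl) != len(st):
                raise ValueError("stride_lengths must match stride_times in length")
            object.__setattr__(self, "stride_lengths", sl)

    @property
    def n_strides(self) -> int:
        return len(self.stride_times)


@dataclass
class StrideSeries:
    """Ordered per-stride parameters for one participant/condition/leg.

    Stride time in seconds and (optionally) stride length in metres, one entry
    per gait cycle of the given leg. ``leg`` is "left", "right", or
    "combined" for an event-ordered interleaving of the two.
    """

    participant: str
    group: str
    condition: str
    leg: str
    stride_times: np.ndarray
    stride_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.stride_times, dtype=float)
        if st.ndim != 1 or len(st) == 0:
            raise ValueError("stride_times must be a non-empty 1-D sequence")
        if np.any(st <= 0):
            raise ValueError("all stride times must be positive")
        self.stride_times = st
        if self.stride_lengths is not None:
            sl = np.asarray(self.stride_lengths, dtype=float)
            if len(sl) != len(st):
                raise ValueError("stride_lengths must match stride_times in length")
            if np.any(sl <= 0):
                raise ValueError("all stride lengths must be positive")
            self.stride_lengths = sl

    @property
    def n_strides(self) -> int:
        return len(self.stride_times)

    def values(self, measure: str) -> np.ndarray:
        if measure == "stride_time":
            return self.stride_times
        if measure == "stride_length":
            if self.stride_lengths is None:
                raise ValueError("series has no stride lengths")
            return self.stride_lengths
        raise ValueError(f"unknown measure {measure!r}")


def interleave_legs(left: StrideSeries, right: StrideSeries) -> StrideSeries:
    """Combined-leg series: per-leg values interleaved in event order.

    Left and right strides of level walking alternate, so the event-ordered
    combined series is L0, R0, L1, R1, ...
    """
    if (left.participant, left.condition) != (right.participant, right.condition):
        raise ValueError("legs belong to different participant/condition")
    n = min(left.n_strides, right.n_strides)
    times = np.empty(2 * n)
    times[0::2] = left.stride_times[:n]
    times[1::2] = right.stride_times[:n]
    lengths = None
    if left.stride_lengths is not None and right.stride_lengths is not None:
        lengths = np.empty(2 * n)
        lengths[0::2] = left.stride_lengths[:n]
        lengths[1::2] = right.stride_lengths[:n]
    return StrideSeries(
        participant=left.participant,
        group=left.group,
        condition=left.condition,
        leg="combined",
        stride_times=times,
        stride_lengths=lengths,
    )
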