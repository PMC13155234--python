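"""Stride-event segmentation and bout planning.

Stride starts are detected as dominant peaks of the band-passed vertical
lumbar acceleration; bouts are non-overlapping runs of consecutive strides
(8 per bout in the study design this package models) taken earliest-first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .series import AccelSeries


@dataclass(frozen=True)
class BoutPlan:
    """Assignment of detected events to non-overlapping stride bouts.

    Each bout spans ``strides_per_bout + 1`` consecutive events (a run of
    ``strides_per_bout`` strides); ``bout_start_events`` holds the index into
    the event array at which each bout begins.
    """

    n_bouts: int
    strides_per_bout: int
    bout_start_events: np.ndarray

    def bout_events(self, events: np.ndarray, i: int) -> np.ndarray:
        """The strides_per_bout + 1 event sample-indices of bout i."""
        s = int(self.bout_start_events[i])
        return np.asarray(events)[s : s + self.strides_per_bout + 1]


def detect_strides(
    accel: AccelSeries,
    expected_stride_time: float,
    axis: int = 0,
) -> np.ndarray:
    """Peak-based stride-start detection on one acceleration axis.

    The axis (vertical by default; pass axis=1 for the anterior-posterior
    fallback) is band-pass filtered around the stride frequency and strict
    local maxima at least 0.6 expected stride times apart are returned as
    strictly increasing sample indices. A signal with no activity yields an
    empty array; a signal shorter than two expected stride times is an error.
    """
    if expected_stride_time <= 0:
        raise ValueError("expected_stride_time must be positive")
    if accel.duration < 2.0 * expected_stride_time:
        raise ValueError(
            f"signal of {accel.duration:.2f} s is shorter than two expected "
            f"strides ({2 * expected_stride_time:.2f} s)"
        )
    fs = accel.sample_rate
    x = accel.samples[:, axis].astype(float)
    f_stride = 1.0 / expected_stride_time
    low = 0.3 * f_stride
    high = min(5.0 * f_stride, 0.45 * fs)
    sos = sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    spread = float(np.std(xf))
    if spread == 0.0:
        return np.array([], dtype=int)
    min_dist = max(int(round(0.6 * expected_stride_time * fs)), 1)
    peaks, _ = sps.find_peaks(xf, distance=min_dist, prominence=0.5 * spread)
    return peaks.astype(int)


def plan_bouts(
    events,
    n_bouts: int = 11,
    strides_per_bout: int = 8,
) -> BoutPlan:
    """Earliest-first assignment of non-overlapping consecutive-stride bouts.

    Requires ``n_bouts * strides_per_bout + 1`` events; raises with the
    required vs available counts otherwise (mirroring the practical
    constraint that short overground trials may not cover enough strides).
    """
    events = np.asarray(events, dtype=int)
    if n_bouts < 1 or strides_per_bout < 1:
        raise ValueError("n_bouts and strides_per_bout must be positive")
    if np.any(np.diff(events) <= 0):
        raise ValueError("events must be strictly increasing")
    needed = n_bouts * strides_per_bout + 1
    if len(events) < needed:
        raise ValueError(
            f"insufficient strides for {n_bouts} bouts of {strides_per_bout}: "
            f"need {needed} events, have {len(events)}"
        )
    starts = np.arange(n_bouts) * strides_per_bout
    return BoutPlan(
        n_bouts=n_bouts,
        strides_per_bout=strides_per_bout,
        bout_start_events=starts,
    )


def match_events(detected, truth, tolerance: int = 3) -> float:
    """Fraction of ground-truth events matched by a detection within
    +/- tolerance samples (each detection matches at most one truth event)."""
    detected = np.sort(np.asarray(detected, dtype=int))
    truth = np.asarray(truth, dtype=int)
    if len(truth) == 0:
        return 1.0
    used = np.zeros(len(detected), dtype=bool)
    hits = 0
    for ev in truth:
        if len(detected) == 0:
            break
        idx = int(np.argmin(np.abs(detected - ev)))
        if not used[idx] and abs(int(detected[idx]) - int(ev)) <= tolerance:
            used[idx] = True
            hits += 1
    return hits / len(truth)
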