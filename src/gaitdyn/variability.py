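"""Stride-to-stride variability: percent coefficient of variation.

%CV = (sample SD / sample mean) x 100, with the n-1 denominator. Bilateral
averaging follows the convention of forming %CV per leg and averaging the two
("mean" mode); a "pooled" mode (mean of per-leg SDs over mean of per-leg
means) is available because the two orders differ slightly and field usage
varies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import StrideSeries


@dataclass(frozen=True)
class CvResult:
    participant: str
    condition: str
    measure: str
    cv_percent: float
    n_strides: int
    per_leg: tuple[float, float] | None = None


def percent_cv(values) -> float:
    """Percent coefficient of variation of a positive-valued sample.

    Requires at least two values and a positive mean; SD uses ddof=1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("percent_cv needs at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("percent_cv requires a positive mean")
    return float(values.std(ddof=1) / mean * 100.0)


def bilateral_cv(
    left: StrideSeries,
    right: StrideSeries,
    measure: str,
    mode: str = "mean",
) -> CvResult:
    """%CV of a stride measure averaged over the two legs.

    mode="mean"   : arithmetic mean of the per-leg %CVs (default).
    mode="pooled" : mean of the per-leg SDs divided by the mean of the
                    per-leg means, x 100.
    """
    if (left.participant, left.condition) != (right.participant, right.condition):
        raise ValueError("left/right series are from different participant/condition")
    if {left.leg, right.leg} != {"left", "right"}:
        raise ValueError("bilateral_cv needs one left and one right series")
    lv = left.values(measure)
    rv = right.values(measure)
    cv_l = percent_cv(lv)
    cv_r = percent_cv(rv)
    if mode == "mean":
        cv = 0.5 * (cv_l + cv_r)
    elif mode == "pooled":
        sd = 0.5 * (lv.std(ddof=1) + rv.std(ddof=1))
        mean = 0.5 * (lv.mean() + rv.mean())
        cv = float(sd / mean * 100.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CvResult(
        participant=left.participant,
        condition=left.condition,
        measure=measure,
        cv_percent=cv,
        n_strides=len(lv) + len(rv),
        per_leg=(cv_l, cv_r),
    )
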