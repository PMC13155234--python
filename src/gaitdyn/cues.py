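"""Visually cued gait stimulus: stepping-target schedules for a treadmill.

Foot-sized rectangles translate backward at belt speed; a new target arrives
at the stepping line every step period (step_length / belt_speed), with
left/right targets alternating at lateral offsets of +/- step_width / 2.
Coordinates: walking axis positive forward, origin at the treadmill front
edge; cues spawn at the front and move backward (velocity -belt_speed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CueSpec:
    """Participant- and trial-specific cue parameters (SI units)."""

    belt_speed: float  # m/s, matches preferred overground speed
    step_length: float  # m, habitual step length on the treadmill
    step_width: float  # m, habitual step width
    foot_length: float = 0.26
    foot_width: float = 0.10
    duration: float = 180.0  # s, trial length
    margin: float = 0.20  # fractional margin around the foot outline

    def __post_init__(self) -> None:
        for name in ("belt_speed", "step_length", "step_width",
                     "foot_length", "foot_width", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.duration < self.step_length / self.belt_speed:
            raise ValueError("duration shorter than one step period")

    @property
    def step_period(self) -> float:
        return self.step_length / self.belt_speed

    @property
    def target_size(self) -> tuple[float, float]:
        """(length, width) of a stepping target: foot outline plus margin."""
        return (
            self.foot_length * (1.0 + self.margin),
            self.foot_width * (1.0 + self.margin),
        )


def generate_cue_sequence(spec: CueSpec, spawn_x: float = 0.0) -> pd.DataFrame:
    """Deterministic cue schedule for one trial.

    One cue per step period, sides alternating starting with the left foot;
    all cues share velocity -belt_speed along the walking axis. Columns:
    side, x_spawn, y_offset, t_spawn, w, h, v.
    """
    n = int(np.floor(spec.duration / spec.step_period))
    idx = np.arange(n)
    length, width = spec.target_size
    return pd.DataFrame(
        {
            "side": np.where(idx % 2 == 0, "L", "R"),
            "x_spawn": np.full(n, spawn_x),
            "y_offset": np.where(idx % 2 == 0, 1.0, -1.0) * spec.step_width / 2.0,
            "t_spawn": idx * spec.step_period,
            "w": np.full(n, width),
            "h": np.full(n, length),
            "v": np.full(n, -spec.belt_speed),
        }
    )


def arrival_positions(seq: pd.DataFrame, spec: CueSpec, t: float | None = None) -> np.ndarray:
    """Longitudinal cue positions at time t (default: end of the schedule)."""
    if t is None:
        t = float(seq["t_spawn"].iloc[-1])
    return seq["x_spawn"].to_numpy() + seq["v"].to_numpy() * (t - seq["t_spawn"].to_numpy())


def validate_cue_sequence(
    seq: pd.DataFrame, spec: CueSpec, speed_tol: float = 1e-3
) -> list[str]:
    """Consistency checks on a cue schedule; returns a list of violations.

    Checks side alternation, constant step-length spacing of arrival
    positions, and speed match against the belt (relative tolerance 0.1%).
    """
    violations: list[str] = []
    sides = seq["side"].to_numpy()
    for i in range(1, len(sides)):
        if sides[i] == sides[i - 1]:
            violations.append(f"cue {i}: side {sides[i]} does not alternate")
    pos = arrival_positions(seq, spec, t=0.0)
    spacing = np.diff(pos)
    bad = np.flatnonzero(~np.isclose(np.abs(spacing), spec.step_length, rtol=1e-9, atol=1e-9))
    for i in bad:
        violations.append(
            f"cue {i + 1}: longitudinal spacing {abs(spacing[i]):.4f} m != "
            f"step length {spec.step_length:.4f} m"
        )
    v = seq["v"].to_numpy()
    bad_v = np.flatnonzero(np.abs(np.abs(v) - spec.belt_speed) > speed_tol * spec.belt_speed)
    for i in bad_v:
        violations.append(
            f"cue {i}: speed {abs(v[i]):.4f} m/s does not match belt "
            f"{spec.belt_speed:.4f} m/s"
        )
    return violations
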