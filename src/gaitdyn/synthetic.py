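"""Seeded generators for synthetic gait data.

Three layers:

* cohort level — stride-parameter tables with the study's 2-group (young,
  older) x 3-condition (overground, treadmill, visual cues) repeated-measures
  structure, with group- and condition-dependent variability targets;
* signal level — lumbar-like tri-axial acceleration built from a fixed
  harmonic base waveform, time-warped per stride, with controllable
  stride-to-stride amplitude variation and sensor noise, plus exact
  ground-truth stride events;
* reference systems — the Lorenz attractor and phase-shifted sinusoids, used
  to validate the divergence-exponent estimator against systems whose largest
  Lyapunov exponent is independently computable.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import AccelSeries, GroundTruth, StrideSeries, interleave_legs

GROUPS = ("young", "older")
CONDITIONS = ("overground", "treadmill", "visual_cues")
MEASURES = ("stride_time_cv", "stride_length_cv", "lde")

# ---------------------------------------------------------------------------
# Base acceleration waveform
# ---------------------------------------------------------------------------

# Harmonic coefficients of the fixed per-stride base waveform, one row per
# harmonic of the stride cycle: (harmonic k, cosine amp, sine amp), in m/s^2.
# The vertical axis is a cosine series, so its global maximum sits exactly at
# the stride phase origin -- ground-truth events coincide with the dominant
# vertical peak, which is what peak-based stride detection locks onto.
_WAVEFORM = {
    "v": ((1, 1.2, 0.0), (2, 0.6, 0.0), (3, 0.15, 0.0)),
    "ap": ((1, 0.0, 0.8), (2, 0.19, 0.35), (3, 0.0, 0.10)),
    "ml": ((1, 0.67, 0.21), (3, 0.11, 0.17)),
}


def base_waveform(phase: np.ndarray) -> np.ndarray:
    """Evaluate the fixed tri-axial base waveform at stride phase in [0, 1).

    Returns an array of shape (len(phase), 3) ordered V, AP, ML.
    """
    phase = np.asarray(phase, dtype=float)
    out = np.zeros((phase.size, 3))
    for col, axis in enumerate(("v", "ap", "ml")):
        for k, c_amp, s_amp in _WAVEFORM[axis]:
            ang = 2.0 * np.pi * k * phase
            out[:, col] += c_amp * np.cos(ang) + s_amp * np.sin(ang)
    return out


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic 2-group x 3-condition walking cohort.

    ``cv_table`` holds the target percent coefficient of variation of stride
    time and stride length per (group, condition) cell; ``lde_table`` the mean
    short-term divergence exponent (nats/stride) per cell. Participant-level
    heterogeneity enters through random intercepts shared across conditions
    (``*_participant_sd``) plus condition-specific residuals
    (``*_residual_sd``), giving the positive within-subject correlation a
    repeated-measures design needs.
    """

    n_per_group: int = 25
    groups: tuple[str, ...] = GROUPS
    conditions: tuple[str, ...] = CONDITIONS
    stride_time_mean: dict = field(
        default_factory=lambda: {"young": 1.05, "older": 1.10}
    )
    stride_length_mean: dict = field(
        default_factory=lambda: {"young": 1.35, "older": 1.22}
    )
    cv_table: dict = field(default_factory=lambda: _DEFAULT_CV_TABLE.copy())
    lde_table: dict = field(default_factory=lambda: _DEFAULT_LDE_TABLE.copy())
    stride_time_mean_sd: float = 0.07
    stride_length_mean_sd: float = 0.10
    cv_participant_sd: float = 0.45
    cv_residual_sd: float = 0.30
    lde_participant_sd: float = 0.035
    lde_residual_sd: float = 0.020
    n_strides_per_leg: int = 80
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.groups) != 2 or len(self.conditions) != 3:
            raise ValueError("design is 2 groups x 3 conditions")
        for g in self.groups:
            if self.stride_time_mean[g] <= 0 or self.stride_length_mean[g] <= 0:
                raise ValueError("stride parameter means must be positive")
        for g in self.groups:
            for c in self.conditions:
                cell = self.cv_table[(g, c)]
                if cell["stride_time"] < 0 or cell["stride_length"] < 0:
                    raise ValueError("CV targets must be non-negative")
                if self.lde_table[(g, c)] <= 0:
                    raise ValueError("LDE means must be positive")
        for sd in (
            self.stride_time_mean_sd,
            self.stride_length_mean_sd,
            self.cv_participant_sd,
            self.cv_residual_sd,
            self.lde_participant_sd,
            self.lde_residual_sd,
        ):
            if sd < 0:
                raise ValueError("SDs must be non-negative")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 must lie in (-1, 1)")

    @classmethod
    def default(cls, seed: int = 0) -> "CohortSpec":
        return cls(seed=seed)

    def null(self) -> "CohortSpec":
        """Copy of this spec with every cell mean equal (no true effects)."""
        cv = {
            (g, c): {"stride_time": 3.0, "stride_length": 2.5}
            for g in self.groups
            for c in self.conditions
        }
        lde = {(g, c): 0.50 for g in self.groups for c in self.conditions}
        means_t = {g: 1.08 for g in self.groups}
        means_l = {g: 1.30 for g in self.groups}
        return replace(
            self,
            cv_table=cv,
            lde_table=lde,
            stride_time_mean=means_t,
            stride_length_mean=means_l,
        )


# Default cell targets. The published per-cell means are not printed in the
# study this emulates, so the defaults encode its ordering pattern instead:
# stride-time and stride-length %CV essentially equal between groups
# overground, elevated in older adults on the treadmill, and highest for both
# groups under visual cues (with the young group rising only there); the
# divergence exponent higher in older adults in every condition, lowest for
# young adults on the plain treadmill, highest for both under visual cues.
_DEFAULT_CV_TABLE = {
    ("young", "overground"): {"stride_time": 2.30, "stride_length": 2.20},
    ("young", "treadmill"): {"stride_time": 2.40, "stride_length": 2.10},
    ("young", "visual_cues"): {"stride_time": 3.80, "stride_length": 3.20},
    ("older", "overground"): {"stride_time": 2.30, "stride_length": 2.20},
    ("older", "treadmill"): {"stride_time": 3.40, "stride_length": 3.00},
    ("older", "visual_cues"): {"stride_time": 5.00, "stride_length": 4.20},
}

_DEFAULT_LDE_TABLE = {
    ("young", "overground"): 0.48,
    ("young", "treadmill"): 0.42,
    ("young", "visual_cues"): 0.55,
    ("older", "overground"): 0.54,
    ("older", "treadmill"): 0.52,
    ("older", "visual_cues"): 0.65,
}


# ---------------------------------------------------------------------------
# Stride-parameter simulation
# ---------------------------------------------------------------------------


def _draw_strides(
    rng: np.random.Generator, mean: float, sd: float, n: int, ar1: float
) -> np.ndarray:
    """n values from N(mean, sd), optionally AR(1) with unit marginal variance."""
    z = rng.standard_normal(n)
    if ar1 != 0.0:
        out = np.empty(n)
        out[0] = z[0]
        scale = np.sqrt(1.0 - ar1**2)
        for i in range(1, n):
            out[i] = ar1 * out[i - 1] + scale * z[i]
        z = out
    return mean + sd * z


def simulate_stride_pair(
    group: str,
    condition: str,
    n_strides: int,
    spec: CohortSpec,
    seed: int,
    participant: str = "sim",
) -> tuple[StrideSeries, StrideSeries]:
    """Left/right stride-parameter series for one simulated trial.

    The participant-level stride-time and stride-length means are drawn once
    from the between-participant distribution; individual strides are then
    i.i.d. normal (optionally AR(1)) around them with the within-participant
    SD implied by the cell's percent-CV target.
    """
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}")
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if n_strides < 1:
        raise ValueError("n_strides must be positive")
    rng = np.random.default_rng(seed)
    cell = spec.cv_table[(group, condition)]
    mu_t = max(rng.normal(spec.stride_time_mean[group], spec.stride_time_mean_sd), 0.4)
    mu_l = max(
        rng.normal(spec.stride_length_mean[group], spec.stride_length_mean_sd), 0.4
    )
    sd_t = cell["stride_time"] / 100.0 * mu_t
    sd_l = cell["stride_length"] / 100.0 * mu_l
    legs = []
    for leg in ("left", "right"):
        times = _draw_strides(rng, mu_t, sd_t, n_strides, spec.ar1)
        lengths = _draw_strides(rng, mu_l, sd_l, n_strides, spec.ar1)
        legs.append(
            StrideSeries(
                participant=participant,
                group=group,
                condition=condition,
                leg=leg,
                stride_times=np.clip(times, 0.2 * mu_t, None),
                stride_lengths=np.clip(lengths, 0.2 * mu_l, None),
            )
        )
    return legs[0], legs[1]


def simulate_stride_series(
    group: str,
    condition: str,
    n_strides: int,
    spec: CohortSpec,
    seed: int,
    participant: str = "sim",
) -> StrideSeries:
    """Combined-leg stride series: the per-leg series interleaved by event order."""
    left, right = simulate_stride_pair(group, condition, n_strides, spec, seed, participant)
    return interleave_legs(left, right)


@dataclass
class Cohort:
    """A simulated cohort: long measurement table plus raw stride series."""

    spec: CohortSpec
    table: pd.DataFrame  # columns: participant, group, condition, measure, value
    stride_series: dict  # (participant, condition) -> (left, right) StrideSeries

    def wide(self, measure: str) -> pd.DataFrame:
        sub = self.table[self.table["measure"] == measure]
        return sub.pivot_table(
            index=["participant", "group"], columns="condition", values="value"
        ).reset_index()

    def long(self, measure: str) -> pd.DataFrame:
        sub = self.table[self.table["measure"] == measure].copy()
        return sub[["participant", "group", "condition", "value"]].reset_index(drop=True)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full repeated-measures cohort.

    Each of the 2 * n_per_group participants contributes all three conditions.
    Stride-time and stride-length %CV are *measured* from simulated stride
    series through the same estimator real data would pass through
    (per-leg %CV averaged bilaterally); the divergence exponent is drawn at
    measurement level from its cell distribution.
    """
    from .variability import bilateral_cv  # local import to avoid a cycle

    master = np.random.default_rng(spec.seed)
    rows = []
    series: dict = {}
    for g_idx, group in enumerate(spec.groups):
        for p_idx in range(spec.n_per_group):
            pid = f"{group[0].upper()}{p_idx + 1:02d}"
            # participant random intercepts, shared across conditions
            u_cv_t = master.normal(0.0, spec.cv_participant_sd)
            u_cv_l = master.normal(0.0, spec.cv_participant_sd)
            u_lde = master.normal(0.0, spec.lde_participant_sd)
            for condition in spec.conditions:
                cell = spec.cv_table[(group, condition)]
                target_t = max(cell["stride_time"] + u_cv_t
                               + master.normal(0.0, spec.cv_residual_sd), 0.05)
                target_l = max(cell["stride_length"] + u_cv_l
                               + master.normal(0.0, spec.cv_residual_sd), 0.05)
                cell_spec = replace(
                    spec,
                    cv_table={
                        **spec.cv_table,
                        (group, condition): {
                            "stride_time": target_t,
                            "stride_length": target_l,
                        },
                    },
                )
                sub_seed = int(master.integers(0, 2**31 - 1))
                left, right = simulate_stride_pair(
                    group, condition, spec.n_strides_per_leg, cell_spec, sub_seed, pid
                )
                series[(pid, condition)] = (left, right)
                cv_t = bilateral_cv(left, right, "stride_time").cv_percent
                cv_l = bilateral_cv(left, right, "stride_length").cv_percent
                lde_val = max(
                    spec.lde_table[(group, condition)]
                    + u_lde
                    + master.normal(0.0, spec.lde_residual_sd),
                    1e-3,
                )
                for measure, value in (
                    ("stride_time_cv", cv_t),
                    ("stride_length_cv", cv_l),
                    ("lde", lde_val),
                ):
                    rows.append(
                        {
                            "participant": pid,
                            "group": group,
                            "condition": condition,
                            "measure": measure,
                            "value": value,
                        }
                    )
    table = pd.DataFrame(rows)
    return Cohort(spec=spec, table=table, stride_series=series)


# ---------------------------------------------------------------------------
# Acceleration-signal simulation
# ---------------------------------------------------------------------------

#: Preset stride-noise levels (amplitude CV, sensor noise SD in m/s^2,
#: stride-time CV as a fraction), ordered low / medium / high. These bracket
#: the stride-to-stride variation healthy adults show in level walking.
NOISE_LEVELS = {
    "low": (0.02, 0.02, 0.010),
    "medium": (0.06, 0.06, 0.030),
    "high": (0.12, 0.12, 0.050),
}


def simulate_lumbar_accel(
    stride_times,
    amplitude_cv: float = 0.05,
    sensor_noise_sd: float = 0.05,
    sample_rate: float = 128.0,
    seed: int = 0,
) -> tuple[AccelSeries, GroundTruth]:
    """Lumbar-like acceleration from a stride-time sequence.

    Each stride is the fixed harmonic base waveform time-warped to that
    stride's duration, scaled by a per-stride amplitude factor drawn with the
    given coefficient of variation (shared across axes), plus additive white
    sensor noise. The returned ground truth holds the exact stride-start
    samples; the final entry of ``event_indices`` is the exclusive end
    boundary of the last stride.
    """
    stride_times = np.asarray(stride_times, dtype=float)
    if stride_times.size == 0:
        raise ValueError("stride_times is empty")
    if np.any(stride_times <= 0):
        raise ValueError("all stride times must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n_per_stride = np.maximum(np.rint(stride_times * sample_rate).astype(int), 2)
    amps = 1.0 + amplitude_cv * rng.standard_normal(len(stride_times))
    amps = np.clip(amps, 0.1, None)
    chunks = []
    for n_i, a_i in zip(n_per_stride, amps):
        phase = np.arange(n_i) / n_i
        chunks.append(a_i * base_waveform(phase))
    samples = np.concatenate(chunks, axis=0)
    if sensor_noise_sd > 0:
        samples = samples + sensor_noise_sd * rng.standard_normal(samples.shape)
    events = np.concatenate(([0], np.cumsum(n_per_stride)))
    truth = GroundTruth(event_indices=events, stride_times=stride_times)
    return AccelSeries(samples=samples, sample_rate=sample_rate), truth


def simulate_walking_trial(
    n_strides: int,
    mean_stride_time: float = 1.1,
    noise_level: str = "medium",
    sample_rate: float = 128.0,
    seed: int = 0,
) -> tuple[AccelSeries, GroundTruth]:
    """Convenience wrapper: stride-time jitter, amplitude variation and sensor
    noise all scaled together by one named noise level (see NOISE_LEVELS)."""
    try:
        amp_cv, noise_sd, time_cv = NOISE_LEVELS[noise_level]
    except KeyError:
        raise ValueError(f"unknown noise level {noise_level!r}") from None
    rng = np.random.default_rng(seed)
    stride_times = mean_stride_time * (1.0 + time_cv * rng.standard_normal(n_strides))
    stride_times = np.clip(stride_times, 0.5 * mean_stride_time, None)
    return simulate_lumbar_accel(
        stride_times,
        amplitude_cv=amp_cv,
        sensor_noise_sd=noise_sd,
        sample_rate=sample_rate,
        seed=seed + 1,
    )


# ---------------------------------------------------------------------------
# Reference dynamical systems
# ---------------------------------------------------------------------------

LORENZ_DEFAULTS = {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0}


def _lorenz_rhs(x, y, z, sigma, rho, beta):
    return sigma * (y - x), x * (rho - z) - y, x * y - beta * z


def _integrate_lorenz(x, y, z, dt, n_steps, sigma, rho, beta, keep_every=0):
    """Fixed-step RK4. If keep_every > 0, return the subsampled trajectory."""
    out = []
    for i in range(n_steps):
        if keep_every and i % keep_every == 0:
            out.append((x, y, z))
        k1 = _lorenz_rhs(x, y, z, sigma, rho, beta)
        k2 = _lorenz_rhs(
            x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1], z + 0.5 * dt * k1[2],
            sigma, rho, beta,
        )
        k3 = _lorenz_rhs(
            x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1], z + 0.5 * dt * k2[2],
            sigma, rho, beta,
        )
        k4 = _lorenz_rhs(
            x + dt * k3[0], y + dt * k3[1], z + dt * k3[2], sigma, rho, beta
        )
        x += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        z += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    return x, y, z, np.array(out) if keep_every else None


def reference_system(
    name: str,
    params: dict | None = None,
    duration: float = 300.0,
    sample_rate: float = 100.0,
    seed: int = 0,
) -> AccelSeries:
    """Three-channel reference signal with a known largest Lyapunov exponent.

    ``lorenz`` integrates the Lorenz equations (sigma=10, rho=28, beta=8/3 by
    default) with fixed-step RK4, discarding a 10 s transient; its largest
    exponent is ~0.906 nats/s, independently computable with
    :func:`gaitdyn.lyapunov.benettin_lle`. ``sine`` returns three
    phase-shifted sinusoids (largest exponent 0). The seed perturbs the
    initial condition / phases only.
    """
    params = dict(params or {})
    n = int(round(duration * sample_rate))
    if name == "lorenz":
        p = {**LORENZ_DEFAULTS, **params}
        rng = np.random.default_rng(seed)
        x, y, z = 1.0, 1.0, 20.0
        x += 0.1 * rng.standard_normal()
        y += 0.1 * rng.standard_normal()
        dt = 1.0 / (2.0 * sample_rate)  # internal step: half the sample interval
        transient_steps = int(round(10.0 / dt))
        x, y, z, _ = _integrate_lorenz(
            x, y, z, dt, transient_steps, p["sigma"], p["rho"], p["beta"]
        )
        _, _, _, traj = _integrate_lorenz(
            x, y, z, dt, 2 * n, p["sigma"], p["rho"], p["beta"], keep_every=2
        )
        return AccelSeries(samples=traj, sample_rate=sample_rate)
    if name == "sine":
        freq = params.get("frequency", 1.0)
        amp = params.get("amplitude", 1.0)
        rng = np.random.default_rng(seed)
        phase0 = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / sample_rate
        cols = [
            amp * np.sin(2 * np.pi * freq * t + phase0 + shift)
            for shift in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
        ]
        return AccelSeries(samples=np.column_stack(cols), sample_rate=sample_rate)
    raise ValueError(f"unknown reference system {name!r}")
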