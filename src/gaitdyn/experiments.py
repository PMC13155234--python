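"""Methodological experiments on synthetic data.

These are the study-level simulation analyses: robustness of the divergence
exponent to the bout count, monotone response of the estimator to injected
stride noise, type-I error of the ANOVA layer under a null cohort, and
power recovery for a planted interaction. Each is a pure function of its
parameters and seed, shared by the test suite, the analysis scripts, and the
acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import plan_bouts
from .lde import LdeParams, lde_for_trial
from .stats import mixed_anova, paired_t, posthoc_power
from .synthetic import NOISE_LEVELS, CohortSpec, simulate_cohort, simulate_walking_trial


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def bout_robustness(
    n_replicates: int = 20,
    n_participants: int = 16,
    n_strides: int = 135,
    noise_level: str = "medium",
    seed: int = 0,
    params: LdeParams = LdeParams(),
) -> pd.DataFrame:
    """11-bout vs 15-bout divergence exponents, paired t per replicate.

    Each replicate simulates ``n_participants`` walking trials long enough
    for 15 bouts of 8 strides, computes the exponent under both bout plans,
    and runs a paired t-test with Cohen's d. Columns: replicate, t, p, d,
    mean_lde_11, mean_lde_15.
    """
    rows = []
    for rep, rep_seed in enumerate(_spawn_seeds(seed, n_replicates)):
        rng = np.random.default_rng(rep_seed)
        l11, l15 = [], []
        for _ in range(n_participants):
            s = int(rng.integers(0, 2**31 - 1))
            accel, truth = simulate_walking_trial(
                n_strides, noise_level=noise_level, seed=s
            )
            ev = truth.event_indices[:-1]
            l11.append(lde_for_trial(accel, ev, plan_bouts(ev, 11, 8), params).lambda_s)
            l15.append(lde_for_trial(accel, ev, plan_bouts(ev, 15, 8), params).lambda_s)
        t, p, d = paired_t(l11, l15)
        rows.append(
            {
                "replicate": rep,
                "t": t,
                "p": p,
                "d": d,
                "mean_lde_11": float(np.mean(l11)),
                "mean_lde_15": float(np.mean(l15)),
            }
        )
    return pd.DataFrame(rows)


def lde_noise_monotonicity(
    n_replicates: int = 20,
    n_strides: int = 92,
    seed: int = 0,
    levels: tuple[str, ...] = ("low", "medium", "high"),
    params: LdeParams = LdeParams(),
) -> pd.DataFrame:
    """Divergence exponent across increasing stride-noise levels.

    Returns one row per (level, replicate); the seeds are shared across
    levels so replicates are paired.
    """
    rows = []
    for rep, rep_seed in enumerate(_spawn_seeds(seed, n_replicates)):
        for level in levels:
            accel, truth = simulate_walking_trial(
                n_strides, noise_level=level, seed=rep_seed
            )
            ev = truth.event_indices[:-1]
            res = lde_for_trial(accel, ev, plan_bouts(ev, 11, 8), params)
            rows.append({"level": level, "replicate": rep, "lambda_s": res.lambda_s})
    return pd.DataFrame(rows)


def median_lde_by_level(mono: pd.DataFrame, levels=("low", "medium", "high")) -> list[float]:
    return [float(mono[mono["level"] == lv]["lambda_s"].median()) for lv in levels]


def type_i_error(
    n_replicates: int = 500,
    n_per_group: int = 10,
    seed: int = 0,
    measures: tuple[str, ...] = ("stride_time_cv", "stride_length_cv", "lde"),
    gg_policy: str = "auto",
) -> pd.DataFrame:
    """Rejection rates of each ANOVA effect under the null cohort generator.

    The null spec sets every (group, condition) cell mean equal, so any
    rejection is a type-I error. Returns long results: one row per
    (replicate, measure, effect) with the reporting p-value.
    """
    base = CohortSpec(n_per_group=n_per_group).null()
    rows = []
    for rep, rep_seed in enumerate(_spawn_seeds(seed, n_replicates)):
        from dataclasses import replace

        cohort = simulate_cohort(replace(base, seed=rep_seed))
        for measure in measures:
            long = cohort.long(measure)
            res = mixed_anova(long, gg_policy=gg_policy)
            for e in res.effects():
                rows.append(
                    {
                        "replicate": rep,
                        "measure": measure,
                        "effect": e.effect,
                        "p": e.p,
                    }
                )
    return pd.DataFrame(rows)


def rejection_rates(null_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    out = (
        null_results.assign(reject=null_results["p"] < alpha)
        .groupby(["measure", "effect"])["reject"]
        .mean()
        .reset_index(name="rate")
    )
    return out


def power_recovery(
    eta_sq: float = 0.10,
    n_per_group: int = 25,
    corr_rm: float = 0.5,
    n_replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical vs predicted power for a planted group x condition interaction.

    Data are generated from the compound-symmetric mixed model whose
    population partial eta^2 for the interaction equals ``eta_sq`` (via
    f^2 = eta^2 / (1 - eta^2)); the empirical rejection rate of the
    interaction F test is compared to the noncentral-F prediction of
    :func:`gaitdyn.stats.posthoc_power`.
    """
    g, k = 2, 3
    n_total = g * n_per_group
    sigma_total = 1.0
    sigma_u = np.sqrt(corr_rm) * sigma_total
    sigma_e = np.sqrt(1.0 - corr_rm) * sigma_total
    f2 = eta_sq / (1.0 - eta_sq)
    # interaction pattern proportional to the g x k Helmert-like contrast,
    # scaled so sum(ab^2) / (g k) / sigma_total^2 = f^2
    pattern = np.array([[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0]])
    pattern *= np.sqrt(f2 * g * k * sigma_total**2 / np.sum(pattern**2))
    rng_master = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        rng = np.random.default_rng(int(rng_master.integers(0, 2**31 - 1)))
        rows = []
        for gi in range(g):
            for p in range(n_per_group):
                u = rng.normal(0.0, sigma_u)
                for ci in range(k):
                    rows.append(
                        {
                            "participant": f"g{gi}p{p}",
                            "group": f"g{gi}",
                            "condition": f"c{ci}",
                            "value": pattern[gi, ci] + u + rng.normal(0.0, sigma_e),
                        }
                    )
        res = mixed_anova(pd.DataFrame(rows))
        if res.interaction.p < alpha:
            rejections += 1
    empirical = rejections / n_replicates
    predicted = posthoc_power(
        eta_sq, n_total, g, k, corr_rm=corr_rm, alpha=alpha, effect="interaction"
    )
    return {"empirical": empirical, "predicted": predicted, "n_replicates": n_replicates}
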