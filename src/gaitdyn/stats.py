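"""Inference layer: 2 x 3 mixed ANOVA and companions.

One between-subjects factor (age group) crossed with one within-subjects
factor (walking condition), balanced designs only. The decomposition is the
classical split-plot one — subjects nested in groups form the between-error
stratum; the subject x condition residual forms the within-error stratum.
Sphericity is assessed with Mauchly's test on the pooled within-group
covariance, and Greenhouse-Geisser df rescaling is applied to the within
effects when (by default) Mauchly rejects at 0.05.

Also here: Holm-Bonferroni adjustment, condition post hocs (paired t),
per-condition simple main effects (two-sample t), paired t with Cohen's d,
partial eta^2 with the small/medium/large classification, and noncentral-F
post-hoc power for repeated-measures effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass(frozen=True)
class EffectResult:
    effect: str
    ss: float
    df_num: float
    df_den: float
    F: float
    p_uncorrected: float
    gg_epsilon: float | None = None
    p_gg: float | None = None
    mauchly_p: float | None = None
    sphericity_assumed: bool = True
    partial_eta_sq: float = 0.0
    size_class: str = "negligible"

    @property
    def p(self) -> float:
        """Reporting p: Greenhouse-Geisser corrected when applied."""
        return self.p_gg if self.p_gg is not None else self.p_uncorrected


@dataclass(frozen=True)
class AnovaResult:
    group: EffectResult
    condition: EffectResult
    interaction: EffectResult
    ss_subjects_within_group: float
    ss_error_within: float
    grand_mean: float

    def effects(self) -> tuple[EffectResult, EffectResult, EffectResult]:
        return (self.group, self.condition, self.interaction)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects():
            rows.append(
                {
                    "effect": e.effect,
                    "SS": e.ss,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "F": e.F,
                    "p": e.p,
                    "p_uncorrected": e.p_uncorrected,
                    "gg_epsilon": e.gg_epsilon,
                    "partial_eta_sq": e.partial_eta_sq,
                    "size_class": e.size_class,
                }
            )
        return pd.DataFrame(rows)


def _check_long_table(data: pd.DataFrame) -> tuple[pd.DataFrame, list, list]:
    required = {"participant", "group", "condition", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    if data["value"].isna().any():
        raise ValueError("long table contains missing values")
    groups = sorted(data["group"].unique())
    conditions = sorted(data["condition"].unique())
    per_subj = data.groupby("participant")
    for pid, sub in per_subj:
        if sorted(sub["condition"]) != conditions:
            raise ValueError(f"participant {pid} lacks one value per condition")
        if sub["group"].nunique() != 1:
            raise ValueError(f"participant {pid} appears in multiple groups")
    sizes = data.drop_duplicates("participant").groupby("group").size()
    if sizes.nunique() != 1:
        raise ValueError(f"unbalanced design: group sizes {dict(sizes)}")
    if sizes.iloc[0] < 2:
        raise ValueError("need at least 2 participants per group")
    return data, groups, conditions


def _wide_by_group(data: pd.DataFrame, groups, conditions):
    """Per group: (n_g x k) value matrix with a stable participant order."""
    out = {}
    for g in groups:
        sub = data[data["group"] == g]
        wide = sub.pivot(index="participant", columns="condition", values="value")
        out[g] = wide[conditions].to_numpy(dtype=float)
    return out


def _mauchly_gg(wide_by_group: dict, k: int):
    """Mauchly's W (chi-square approximation) and Greenhouse-Geisser epsilon
    from the pooled within-group covariance of the condition vectors."""
    n_total = 0
    pooled = np.zeros((k, k))
    for mat in wide_by_group.values():
        n_g = mat.shape[0]
        centered = mat - mat.mean(axis=0, keepdims=True)
        pooled += centered.T @ centered
        n_total += n_g
    df_pool = n_total - len(wide_by_group)
    s = pooled / df_pool
    # orthonormal contrasts via Helmert basis
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1)
        helmert[i] /= np.linalg.norm(helmert[i])
    t = helmert @ s @ helmert.T
    eigs = np.linalg.eigvalsh(t)
    eigs = np.clip(eigs, 0.0, None)
    p_dim = k - 1
    tr = eigs.sum()
    if tr <= 0:
        return 1.0, 1.0 / p_dim  # fully degenerate: no within-subject variance
    # GG epsilon
    eps = tr**2 / (p_dim * np.sum(eigs**2))
    # Mauchly
    mean_eig = tr / p_dim
    with np.errstate(divide="ignore"):
        w = np.prod(eigs / mean_eig)
    if w <= 0:
        return 0.0, float(eps)
    f_corr = 1.0 - (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim * df_pool)
    chi2 = -f_corr * df_pool * np.log(w)
    df_chi = p_dim * (p_dim + 1) // 2 - 1
    p_mauchly = float(sst.chi2.sf(chi2, df_chi))
    return p_mauchly, float(eps)


def mixed_anova(data: pd.DataFrame, gg_policy: str = "auto") -> AnovaResult:
    """Balanced 2 x 3 (or g x k) mixed ANOVA from a long table.

    ``gg_policy``: "auto" applies the Greenhouse-Geisser correction to the
    within effects only when Mauchly's test rejects at 0.05 (the conditional
    convention), "always" forces it, "never" disables it.
    """
    if gg_policy not in ("auto", "always", "never"):
        raise ValueError(f"unknown gg_policy {gg_policy!r}")
    data, groups, conditions = _check_long_table(data)
    g, k = len(groups), len(conditions)
    wide = _wide_by_group(data, groups, conditions)
    n_g = wide[groups[0]].shape[0]
    n_total = g * n_g

    all_mat = np.vstack([wide[gr] for gr in groups])  # n_total x k
    grand = all_mat.mean()
    if np.allclose(all_mat, grand):
        raise ValueError("all values identical: F is undefined")
    subj_means = all_mat.mean(axis=1)
    group_means = np.array([wide[gr].mean() for gr in groups])
    cond_means = all_mat.mean(axis=0)
    cell_means = np.array([wide[gr].mean(axis=0) for gr in groups])  # g x k

    ss_total = np.sum((all_mat - grand) ** 2)
    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_group = n_g * k * np.sum((group_means - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = n_total * np.sum((cond_means - grand) ** 2)
    ss_inter = n_g * np.sum(
        (cell_means - group_means[:, None] - cond_means[None, :] + grand) ** 2
    )
    ss_err_within = ss_total - ss_between_subj - ss_cond - ss_inter

    df_group, df_subj = g - 1, n_total - g
    df_cond = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err_w = (n_total - g) * (k - 1)

    ms = lambda ss, df: ss / df
    if ss_subj_within <= 0 or ss_err_within <= 0:
        raise ValueError("zero error variance: F is undefined")
    f_group = ms(ss_group, df_group) / ms(ss_subj_within, df_subj)
    f_cond = ms(ss_cond, df_cond) / ms(ss_err_within, df_err_w)
    f_inter = ms(ss_inter, df_inter) / ms(ss_err_within, df_err_w)

    p_mauchly, eps = _mauchly_gg(wide, k)
    apply_gg = {"auto": p_mauchly < 0.05, "always": True, "never": False}[gg_policy]

    def _effect(name, ss, df1, df2, F, ss_err, within):
        p_unc = float(sst.f.sf(F, df1, df2))
        p_gg = None
        e = None
        if within:
            e = eps
            if apply_gg:
                p_gg = float(sst.f.sf(F, df1 * eps, df2 * eps))
        eta = ss / (ss + ss_err)
        return EffectResult(
            effect=name,
            ss=float(ss),
            df_num=df1,
            df_den=df2,
            F=float(F),
            p_uncorrected=p_unc,
            gg_epsilon=e,
            p_gg=p_gg,
            mauchly_p=p_mauchly if within else None,
            sphericity_assumed=not (within and apply_gg),
            partial_eta_sq=float(eta),
            size_class=classify_effect_size(eta),
        )

    return AnovaResult(
        group=_effect("group", ss_group, df_group, df_subj, f_group,
                      ss_subj_within, within=False),
        condition=_effect("condition", ss_cond, df_cond, df_err_w, f_cond,
                          ss_err_within, within=True),
        interaction=_effect("interaction", ss_inter, df_inter, df_err_w, f_inter,
                            ss_err_within, within=True),
        ss_subjects_within_group=float(ss_subj_within),
        ss_error_within=float(ss_err_within),
        grand_mean=float(grand),
    )


def partial_eta_sq(F: float, df_num: float, df_den: float) -> float:
    """Partial eta^2 from an F statistic: F*df1 / (F*df1 + df2).

    Algebraically identical to SS_effect / (SS_effect + SS_error) of the same
    table, and invariant to Greenhouse-Geisser rescaling of both dfs.
    """
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return float(F * df_num / (F * df_num + df_den))


def classify_effect_size(eta_sq: float) -> str:
    """Small/medium/large partial-eta^2 bands at 0.01 / 0.06 / 0.14."""
    if not 0.0 <= eta_sq <= 1.0:
        raise ValueError("eta_sq must lie in [0, 1]")
    if eta_sq >= 0.14:
        return "large"
    if eta_sq >= 0.06:
        return "medium"
    if eta_sq >= 0.01:
        return "small"
    return "negligible"


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def paired_t(a, b) -> tuple[float, float, float]:
    """Two-sided paired t-test with Cohen's d = mean(a-b) / SD(a-b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length sequences (n >= 2)")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0, 0.0
    t, p = sst.ttest_rel(a, b)
    d = diff.mean() / sd
    return float(t), float(p), float(d)


def condition_posthoc(data: pd.DataFrame, per_group: bool = False) -> pd.DataFrame:
    """Pairwise condition comparisons (paired t), Holm-adjusted.

    Default pools both groups into a single condition family (3 pairs);
    ``per_group=True`` additionally tests each pair within each group, with
    Holm applied within each group's family.
    """
    data, groups, conditions = _check_long_table(data)
    frames = [("pooled", data)]
    if per_group:
        frames += [(g, data[data["group"] == g]) for g in groups]
    rows = []
    for label, sub in frames:
        wide = sub.pivot(index="participant", columns="condition", values="value")
        pairs = [
            (conditions[i], conditions[j])
            for i in range(len(conditions))
            for j in range(i + 1, len(conditions))
        ]
        raw = []
        for c1, c2 in pairs:
            t, p, d = paired_t(wide[c1].to_numpy(), wide[c2].to_numpy())
            raw.append((c1, c2, t, p, d))
        adj = holm_adjust([r[3] for r in raw])
        for (c1, c2, t, p, d), pa in zip(raw, adj):
            rows.append(
                {
                    "family": label,
                    "condition_a": c1,
                    "condition_b": c2,
                    "mean_diff": float(
                        wide[c1].mean() - wide[c2].mean()
                    ),
                    "t": t,
                    "p_raw": p,
                    "p_holm": float(pa),
                    "cohens_d": d,
                }
            )
    return pd.DataFrame(rows)


def simple_main_effects(data: pd.DataFrame) -> pd.DataFrame:
    """Group contrast within each condition (two-sample t), Holm-adjusted
    across the condition family."""
    data, groups, conditions = _check_long_table(data)
    if len(groups) != 2:
        raise ValueError("simple main effects implemented for 2 groups")
    g1, g2 = groups
    raw = []
    for c in conditions:
        sub = data[data["condition"] == c]
        a = sub[sub["group"] == g1]["value"].to_numpy()
        b = sub[sub["group"] == g2]["value"].to_numpy()
        t, p = sst.ttest_ind(a, b)
        pooled_sd = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else 0.0
        raw.append((c, float(t), float(p), float(d), a.mean() - b.mean()))
    adj = holm_adjust([r[2] for r in raw])
    return pd.DataFrame(
        [
            {
                "condition": c,
                "group_a": g1,
                "group_b": g2,
                "mean_diff": float(md),
                "t": t,
                "p_raw": p,
                "p_holm": float(pa),
                "cohens_d": d,
            }
            for (c, t, p, d, md), pa in zip(raw, adj)
        ]
    )


def posthoc_power(
    eta_sq: float,
    n_total: int,
    n_groups: int = 2,
    n_measurements: int = 3,
    corr_rm: float = 0.5,
    alpha: float = 0.05,
    effect: str = "interaction",
) -> float:
    """Noncentral-F power for a repeated-measures (within or interaction)
    effect, following the G*Power convention.

    Cohen's f is sqrt(eta^2 / (1 - eta^2)); the noncentrality parameter is
    f^2 * N * m / (1 - rho), where m is the number of repeated measurements
    and rho their assumed correlation.
    """
    if not 0.0 <= eta_sq < 1.0:
        raise ValueError("eta_sq must lie in [0, 1)")
    if not -1.0 < corr_rm < 1.0:
        raise ValueError("corr_rm must lie in (-1, 1)")
    if n_total < n_groups * 2 or n_groups < 2 or n_measurements < 2:
        raise ValueError("invalid design counts")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    f2 = eta_sq / (1.0 - eta_sq)
    lam = f2 * n_total * n_measurements / (1.0 - corr_rm)
    if effect == "interaction":
        df1 = (n_groups - 1) * (n_measurements - 1)
    elif effect == "within":
        df1 = n_measurements - 1
    else:
        raise ValueError(f"unknown effect {effect!r}")
    df2 = (n_total - n_groups) * (n_measurements - 1)
    f_crit = sst.f.isf(alpha, df1, df2)
    return float(sst.ncf.sf(f_crit, df1, df2, lam))
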