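"""Inference layer: ANOVA decomposition, effect sizes, adjustments, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from gaitdyn.stats import (
    classify_effect_size,
    condition_posthoc,
    holm_adjust,
    mixed_anova,
    paired_t,
    partial_eta_sq,
    posthoc_power,
    simple_main_effects,
)


def _long_table(values_by_group):
    """values_by_group: {group: (n_subjects x k) array} -> long DataFrame."""
    rows = []
    for group, mat in values_by_group.items():
        mat = np.asarray(mat, dtype=float)
        for i, row in enumerate(mat):
            for j, v in enumerate(row):
                rows.append(
                    {
                        "participant": f"{group}{i}",
                        "group": group,
                        "condition": f"c{j}",
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)


def _oracle_ss(values_by_group):
    """Definitional cell-means split-plot SS computation.

    Written from the textbook formulas, element by element, independently of
    the vectorized implementation under test.
    """
    groups = list(values_by_group)
    mats = {g: np.asarray(values_by_group[g], float) for g in groups}
    n_g = mats[groups[0]].shape[0]
    k = mats[groups[0]].shape[1]
    all_vals = [mats[g][i, j] for g in groups for i in range(n_g) for j in range(k)]
    grand = sum(all_vals) / len(all_vals)

    ss_group = 0.0
    for g in groups:
        gmean = mats[g].sum() / (n_g * k)
        ss_group += n_g * k * (gmean - grand) ** 2
    ss_subj_within = 0.0
    for g in groups:
        gmean = mats[g].sum() / (n_g * k)
        for i in range(n_g):
            smean = mats[g][i].sum() / k
            ss_subj_within += k * (smean - gmean) ** 2
    ss_cond = 0.0
    for j in range(k):
        cmean = sum(mats[g][i, j] for g in groups for i in range(n_g)) / (
            len(groups) * n_g
        )
        ss_cond += len(groups) * n_g * (cmean - grand) ** 2
    ss_inter = 0.0
    for g in groups:
        gmean = mats[g].sum() / (n_g * k)
        for j in range(k):
            cmean = sum(mats[h][i, j] for h in groups for i in range(n_g)) / (
                len(groups) * n_g
            )
            cell = mats[g][:, j].sum() / n_g
            ss_inter += n_g * (cell - gmean - cmean + grand) ** 2
    ss_err = 0.0
    for g in groups:
        for i in range(n_g):
            smean = mats[g][i].sum() / k
            gmean = mats[g].sum() / (n_g * k)
            for j in range(k):
                cmean = sum(mats[h][x, j] for h in groups for x in range(n_g)) / (
                    len(groups) * n_g
                )
                cell = mats[g][:, j].sum() / n_g
                resid = mats[g][i, j] - smean - cell + gmean
                ss_err += resid**2
    return ss_group, ss_subj_within, ss_cond, ss_inter, ss_err


@pytest.fixture()
def toy_table():
    rng = np.random.default_rng(42)
    return {
        "young": rng.normal(3.0, 1.0, size=(3, 3)),
        "older": rng.normal(4.0, 1.0, size=(3, 3)) + np.array([0.0, 0.5, 1.0]),
    }


class TestMixedAnova:
    def test_ss_match_cell_means_oracle(self, toy_table):
        res = mixed_anova(_long_table(toy_table), gg_policy="never")
        ssg, sss, ssc, ssi, sse = _oracle_ss(toy_table)
        assert res.group.ss == pytest.approx(ssg, abs=1e-10)
        assert res.ss_subjects_within_group == pytest.approx(sss, abs=1e-10)
        assert res.condition.ss == pytest.approx(ssc, abs=1e-10)
        assert res.interaction.ss == pytest.approx(ssi, abs=1e-10)
        assert res.ss_error_within == pytest.approx(sse, abs=1e-10)
        # F ratios from the oracle SS and the design dfs
        f_group = (ssg / 1) / (sss / 4)
        f_cond = (ssc / 2) / (sse / 8)
        assert res.group.F == pytest.approx(f_group, abs=1e-10)
        assert res.condition.F == pytest.approx(f_cond, abs=1e-10)

    def test_matches_pingouin(self, toy_table):
        pg = pytest.importorskip("pingouin")
        df = _long_table(toy_table)
        res = mixed_anova(df, gg_policy="never")
        ref = pg.mixed_anova(
            data=df, dv="value", within="condition", subject="participant",
            between="group", correction=True,
        ).set_index("Source")
        assert res.group.F == pytest.approx(ref.loc["group", "F"])
        assert res.condition.F == pytest.approx(ref.loc["condition", "F"])
        assert res.interaction.F == pytest.approx(ref.loc["Interaction", "F"])
        assert res.group.partial_eta_sq == pytest.approx(ref.loc["group", "np2"])
        assert res.condition.p_uncorrected == pytest.approx(
            ref.loc["condition", "p_unc"]
        )
        # epsilon conventions differ (pingouin does not group-center before
        # pooling), so only the admissible range is compared here; the exact
        # value is pinned by the spherical-covariance construction below
        assert 0.5 <= res.condition.gg_epsilon <= 1.0

    def test_within_stratum_ss_conservation(self, toy_table):
        res = mixed_anova(_long_table(toy_table), gg_policy="never")
        df = _long_table(toy_table)
        wide = df.pivot(index="participant", columns="condition", values="value")
        subj_means = wide.mean(axis=1).to_numpy()
        total_within = float(((wide.to_numpy() - subj_means[:, None]) ** 2).sum())
        parts = res.condition.ss + res.interaction.ss + res.ss_error_within
        assert parts == pytest.approx(total_within, abs=1e-10)

    def test_all_equal_values_rejected(self):
        tab = {"a": np.full((3, 3), 2.0), "b": np.full((3, 3), 2.0)}
        with pytest.raises(ValueError, match="undefined"):
            mixed_anova(_long_table(tab))

    def test_unbalanced_rejected(self):
        tab = _long_table({"a": np.random.default_rng(0).normal(size=(3, 3)),
                           "b": np.random.default_rng(1).normal(size=(4, 3))})
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(tab)

    def test_incomplete_cells_rejected(self):
        tab = _long_table({"a": np.random.default_rng(0).normal(size=(3, 3)),
                           "b": np.random.default_rng(1).normal(size=(3, 3))})
        tab = tab.iloc[:-1]
        with pytest.raises(ValueError, match="per condition"):
            mixed_anova(tab)

    def test_gg_epsilon_one_for_spherical_covariance(self):
        # construct data whose pooled within-group covariance is exactly
        # compound symmetric -> Helmert-transformed covariance proportional
        # to I -> epsilon == 1
        rng = np.random.default_rng(3)
        n, k = 20, 3
        rho, sd = 0.4, 1.0
        target = sd**2 * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        tables = {}
        for g in ("a", "b"):
            z = rng.standard_normal((n, k))
            z -= z.mean(axis=0)
            # empirical whitening, then exact coloring to the CS target
            cov = np.cov(z, rowvar=False)
            z = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
            tables[g] = z @ np.linalg.cholesky(target).T + 5.0
        res = mixed_anova(_long_table(tables), gg_policy="never")
        assert res.condition.gg_epsilon == pytest.approx(1.0, abs=1e-9)
        assert res.condition.mauchly_p == pytest.approx(1.0, abs=1e-6)

    def test_gg_epsilon_bounds(self, toy_table):
        res = mixed_anova(_long_table(toy_table), gg_policy="always")
        assert 0.5 <= res.condition.gg_epsilon <= 1.0
        assert res.condition.p_gg is not None
        assert not res.condition.sphericity_assumed


class TestEffectSizes:
    @pytest.mark.parametrize(
        "f_val, df1, df2, expected",
        [
            (52.937, 1, 48, 0.524),
            (64.316, 2, 96, 0.573),
            (41.565, 1, 48, 0.464),
            (4.524, 2, 96, 0.086),
        ],
    )
    def test_partial_eta_sq_published_values(self, f_val, df1, df2, expected):
        assert round(partial_eta_sq(f_val, df1, df2), 3) == expected

    def test_zero_f_gives_zero(self):
        assert partial_eta_sq(0.0, 2, 96) == 0.0

    def test_two_routes_agree_on_fitted_table(self):
        rng = np.random.default_rng(11)
        tab = {"a": rng.normal(size=(6, 3)), "b": rng.normal(size=(6, 3)) + 1}
        res = mixed_anova(_long_table(tab), gg_policy="never")
        for e, ss_err in (
            (res.group, res.ss_subjects_within_group),
            (res.condition, res.ss_error_within),
            (res.interaction, res.ss_error_within),
        ):
            from_f = partial_eta_sq(e.F, e.df_num, e.df_den)
            from_ss = e.ss / (e.ss + ss_err)
            assert from_f == pytest.approx(from_ss, abs=1e-12)
            assert e.partial_eta_sq == pytest.approx(from_ss, abs=1e-12)

    def test_gg_rescaling_invariance(self):
        eps = 0.71
        assert partial_eta_sq(5.0, 2, 96) == pytest.approx(
            partial_eta_sq(5.0, 2 * eps, 96 * eps), abs=1e-12
        )

    @pytest.mark.parametrize(
        "eta, label",
        [
            (0.0, "negligible"),
            (0.009, "negligible"),
            (0.01, "small"),
            (0.059, "small"),
            (0.06, "medium"),
            (0.086, "medium"),
            (0.135, "medium"),
            (0.14, "large"),
            (0.524, "large"),
        ],
    )
    def test_classification_thresholds(self, eta, label):
        assert classify_effect_size(eta) == label

    def test_classification_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_effect_size(1.2)


class TestHolm:
    def test_hand_oracle(self):
        # sorted: .01*3=.03; max(.03*2,.03)=.06; max(.04*1,.06)=.06
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=10)
        _, ref, _, _ = multipletests(p, method="holm")
        assert holm_adjust(p) == pytest.approx(ref)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 8))
            assert np.all(holm_adjust(p) >= p - 1e-15)


class TestPairedT:
    def test_identical_sequences(self):
        t, p, d = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p, d) == (0.0, 1.0, 0.0)

    def test_hand_oracle(self):
        # diffs (-1, 0, -2): mean -1, sd 1 -> t = -1 / (1/sqrt(3)) = -sqrt(3)
        t, p, d = paired_t([1, 2, 3], [2, 2, 5])
        assert t == pytest.approx(-np.sqrt(3))
        assert d == pytest.approx(-1.0)
        assert p == pytest.approx(2 * sst.t.sf(np.sqrt(3), 2))

    def test_sign_flip_symmetry(self):
        a, b = [1.0, 2.2, 2.9, 4.5], [1.4, 2.0, 3.3, 5.0]
        t1, p1, d1 = paired_t(a, b)
        t2, p2, d2 = paired_t(b, a)
        assert t2 == pytest.approx(-t1)
        assert d2 == pytest.approx(-d1)
        assert p2 == pytest.approx(p1)


class TestPosthocs:
    def _planted(self, vc_boost=2.0, seed=0, n=20):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("young", "older"):
            for i in range(n):
                u = rng.normal(0, 0.5)
                for c in ("overground", "treadmill", "visual_cues"):
                    v = 3.0 + u + rng.normal(0, 0.4)
                    if c == "visual_cues":
                        v += vc_boost
                    rows.append({"participant": f"{g}{i}", "group": g,
                                 "condition": c, "value": v})
        return pd.DataFrame(rows)

    def test_identical_condition_means_not_significant(self):
        df = self._planted(vc_boost=0.0, seed=1)
        out = condition_posthoc(df)
        assert (out["p_holm"] > 0.05).all()

    def test_only_cue_pairs_rejected_with_planted_effect(self):
        df = self._planted(vc_boost=2.0, seed=2)
        out = condition_posthoc(df)
        pooled = out[out["family"] == "pooled"].set_index(["condition_a", "condition_b"])
        assert pooled.loc[("overground", "visual_cues"), "p_holm"] < 0.05
        assert pooled.loc[("treadmill", "visual_cues"), "p_holm"] < 0.05
        assert pooled.loc[("overground", "treadmill"), "p_holm"] > 0.05

    def test_adjusted_monotone(self):
        out = condition_posthoc(self._planted(seed=3))
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()

    def test_simple_main_effects_identical_groups(self):
        df = self._planted(vc_boost=0.0, seed=4)
        out = simple_main_effects(df)
        assert (out["p_holm"] > 0.01).all()

    def test_simple_main_effects_planted_group_gap(self):
        df = self._planted(vc_boost=0.0, seed=5)
        df.loc[(df["group"] == "older") & (df["condition"] != "overground"),
               "value"] += 1.5
        out = simple_main_effects(df).set_index("condition")
        assert out.loc["treadmill", "p_holm"] < 0.05
        assert out.loc["visual_cues", "p_holm"] < 0.05
        assert out.loc["overground", "p_holm"] > 0.05


class TestPower:
    def test_null_limit_equals_alpha(self):
        assert posthoc_power(1e-12, 50) == pytest.approx(0.05, abs=1e-4)

    def test_published_assumption_case_above_80(self):
        power = posthoc_power(0.086, 50, 2, 3, corr_rm=0.5, alpha=0.05)
        assert power >= 0.80

    def test_monotone_in_sample_size(self):
        powers = [posthoc_power(0.05, n) for n in (12, 24, 48, 96)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            posthoc_power(1.2, 50)
        with pytest.raises(ValueError):
            posthoc_power(0.1, 50, corr_rm=1.5)
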