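"""Statistics pipeline: age bins, ANOVA, adjusted means, trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sasscore import (
    adjusted_means,
    anova_by_factor,
    assign_age_group,
    significance_threshold,
    standardized_adjusted_means,
    trend_slope,
)
from sasscore.errors import AnalysisError, IneligibilityError

AGE_LABELS = ("3-5", "6-10", "11-17", ">=18")


def gaussian_table(rng, n_per_group, group_effects, sex_effect=1.0, age_effects=(0.0, 0.5, 1.0, 1.5), noise_sd=1.0):
    """Synthetic analysis table: score = group + sex + age_group + noise."""
    rows = []
    for g, eff in group_effects.items():
        for i in range(n_per_group):
            sex = "male" if rng.random() < 0.5 else "female"
            ai = int(rng.integers(0, 4))
            score = (
                10.0 + eff + (sex_effect if sex == "male" else 0.0)
                + age_effects[ai] + rng.normal(0, noise_sd)
            )
            rows.append({"individual_id": f"{g}{i}", "sex": sex,
                         "age_group": AGE_LABELS[ai], "group": g, "score": score})
    return pd.DataFrame(rows)


def oracle_adjusted_means(df, score, grouping, reference, margins="observed"):
    """Independent LS-means: explicit dummy design solved by normal equations,
    marginal means taken by predicting every cohort row with the group
    forced to each level and averaging the row predictions."""
    groups = sorted(df[grouping].unique())
    sexes = sorted(df["sex"].unique())
    ages = sorted(df["age_group"].unique())

    def row_vec(g, sex, age):
        v = [1.0]
        v += [1.0 if g == lv else 0.0 for lv in groups if lv != reference]
        v += [1.0 if sex == lv else 0.0 for lv in sexes[1:]]
        v += [1.0 if age == lv else 0.0 for lv in ages[1:]]
        return v

    X = np.array([row_vec(r[grouping], r["sex"], r["age_group"]) for _, r in df.iterrows()])
    y = df[score].to_numpy(float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    out = {}
    for g in groups:
        if margins == "observed":
            rows = np.array([row_vec(g, r["sex"], r["age_group"]) for _, r in df.iterrows()])
            L = rows.mean(axis=0)
        else:  # balanced grid over sex x age cells
            rows = np.array([row_vec(g, s, a) for s in sexes for a in ages])
            L = rows.mean(axis=0)
        est = float(L @ beta)
        se = float(np.sqrt(sigma2 * L @ xtx_inv @ L))
        crit = sps.t.ppf(0.975, dof)
        out[g] = (est, est - crit * se, est + crit * se)
    return out


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age, label",
        [(3.0, "3-5"), (5.9, "3-5"), (6.0, "6-10"), (10.99, "6-10"),
         (11.0, "11-17"), (17.99, "11-17"), (18.0, ">=18"), (38.0, ">=18")],
    )
    def test_bins(self, age, label):
        assert assign_age_group(age) == label

    def test_under_three_rejected(self):
        with pytest.raises(IneligibilityError):
            assign_age_group(2.9)


class TestSignificanceThreshold:
    def test_values(self):
        assert round(significance_threshold(15), 4) == 0.0033
        assert significance_threshold(1) == 0.05
        assert significance_threshold(2) == 0.025

    def test_invalid(self):
        with pytest.raises(AnalysisError):
            significance_threshold(0)


class TestAnova:
    def test_zero_within_variance_gives_tiny_p(self):
        df = pd.DataFrame({"f": ["a"] * 5 + ["b"] * 5, "s": [1.0] * 5 + [2.0] * 5})
        res = anova_by_factor(df, "s", "f")
        assert res["p"] < 1e-10

    def test_two_level_anova_equals_squared_t(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "f": ["a"] * 30 + ["b"] * 40,
            "s": np.r_[rng.normal(0, 1, 30), rng.normal(0.4, 1, 40)],
        })
        res = anova_by_factor(df, "s", "f")
        t, p = sps.ttest_ind(df.loc[df.f == "a", "s"], df.loc[df.f == "b", "s"])
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)

    def test_single_level_is_error(self):
        df = pd.DataFrame({"f": ["a"] * 5, "s": range(5)})
        with pytest.raises(AnalysisError):
            anova_by_factor(df, "s", "f")


class TestAdjustedMeans:
    def tiny_fixture(self):
        # 12 rows, full rank (sex not aligned with age group), hand-checkable
        return pd.DataFrame({
            "sex": ["male", "female", "female", "male",
                    "male", "male", "female", "female",
                    "female", "male", "male", "female"],
            "age_group": ["3-5", "6-10", "11-17", ">=18"] * 3,
            "group": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
            "score": [3.0, 5, 4, 6, 8, 7, 9, 10, 12, 11, 14, 13],
        })

    @pytest.mark.parametrize("margins", ["observed", "balanced"])
    def test_matches_normal_equations_oracle(self, margins):
        df = self.tiny_fixture()
        res = adjusted_means(df, "score", "group", reference_group="A", margins=margins)
        oracle = oracle_adjusted_means(df, "score", "group", "A", margins=margins)
        for _, r in res.iterrows():
            est, lo, hi = oracle[r["group"]]
            assert r["estimate"] == pytest.approx(est, rel=1e-11)
            assert r["ci_low"] == pytest.approx(lo, rel=1e-11)
            assert r["ci_high"] == pytest.approx(hi, rel=1e-11)

    def test_balanced_design_collapses_to_raw_means(self):
        # every group has the identical sex x age composition
        rows = []
        base = {"A": 5.0, "B": 9.0}
        for g in ("A", "B"):
            k = 0
            for sex in ("male", "female"):
                for age in AGE_LABELS:
                    rows.append({"sex": sex, "age_group": age, "group": g,
                                 "score": base[g] + k * 0.5})
                    k += 1
        df = pd.DataFrame(rows)
        for margins in ("observed", "balanced"):
            res = adjusted_means(df, "score", "group", margins=margins).set_index("group")
            raw = df.groupby("group")["score"].mean()
            for g in raw.index:
                assert res.loc[g, "estimate"] == pytest.approx(raw[g], abs=1e-10)

    def test_known_effects_recovered_within_ci(self):
        rng = np.random.default_rng(42)
        df = gaussian_table(rng, 500, {"A": 0.0, "B": 3.0, "C": 6.0}, noise_sd=2.0)
        res = adjusted_means(df, "score", "group", reference_group="A").set_index("group")
        for g, truth in (("B", 3.0), ("C", 6.0)):
            assert res.loc[g, "diff_ci_low"] <= truth <= res.loc[g, "diff_ci_high"]
            assert res.loc[g, "diff_vs_reference"] == pytest.approx(truth, abs=0.5)

    def test_constant_shift_invariance(self):
        df = self.tiny_fixture()
        base = adjusted_means(df, "score", "group", reference_group="A")
        shifted = df.assign(score=df["score"] + 100.0)
        res = adjusted_means(shifted, "score", "group", reference_group="A")
        assert np.allclose(res["estimate"], base["estimate"] + 100.0)
        assert np.allclose(res["p_vs_reference"].fillna(-1), base["p_vs_reference"].fillna(-1))

    def test_reference_relabeling_permutes_not_changes(self):
        df = self.tiny_fixture()
        a = adjusted_means(df, "score", "group", reference_group="A").set_index("group")
        b = adjusted_means(df, "score", "group", reference_group="B").set_index("group")
        assert np.allclose(a["estimate"], b["estimate"])
        assert np.isnan(a.loc["A", "p_vs_reference"])
        assert np.isnan(b.loc["B", "p_vs_reference"])

    def test_default_reference_is_least_severe_group(self):
        df = self.tiny_fixture()
        res = adjusted_means(df, "score", "group")
        assert res["reference_group"].iloc[0] == "A"

    def test_confounded_design_raises(self):
        # group perfectly aligned with sex
        df = pd.DataFrame({
            "sex": ["male"] * 4 + ["female"] * 4,
            "age_group": ["3-5", "6-10"] * 4,
            "group": ["A"] * 4 + ["B"] * 4,
            "score": np.arange(8.0),
        })
        with pytest.raises(AnalysisError, match="confounded"):
            adjusted_means(df, "score", "group")

    def test_n_sums_to_cohort(self):
        df = self.tiny_fixture()
        res = adjusted_means(df, "score", "group")
        assert res["n"].sum() == len(df)


class TestStandardizedAdjustedMeans:
    def test_single_group_cohort_is_zero(self):
        rng = np.random.default_rng(0)
        df = gaussian_table(rng, 80, {"A": 0.0})
        mat = standardized_adjusted_means(df, ["score"], "group")
        assert abs(mat.loc["A", "score"]) < 0.05

    def test_one_sd_shift_splits_symmetrically(self):
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame({
            "sex": rng.choice(["male", "female"], 2 * n),
            "age_group": rng.choice(list(AGE_LABELS), 2 * n),
            "group": ["A"] * n + ["B"] * n,
            "cat": np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)],
        })
        mat = standardized_adjusted_means(df, ["cat"], "group")
        a, b = mat.loc["A", "cat"], mat.loc["B", "cat"]
        assert a + b == pytest.approx(0.0, abs=0.05)
        # mixture SD is sqrt(1 + 0.25) so the split lands near +-0.45
        assert b == pytest.approx(0.45, abs=0.1)
        assert a == pytest.approx(-0.45, abs=0.1)

    def test_zero_variance_score_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        df = gaussian_table(rng, 40, {"A": 0.0, "B": 1.0})
        df["flat"] = 2.0
        with pytest.warns(UserWarning, match="flat"):
            mat = standardized_adjusted_means(df, ["score", "flat"], "group")
        assert "flat" not in mat.columns and "score" in mat.columns

    def test_standardization_invariant_to_score_shift(self):
        rng = np.random.default_rng(3)
        df = gaussian_table(rng, 60, {"A": 0.0, "B": 2.0})
        m1 = standardized_adjusted_means(df, ["score"], "group")
        m2 = standardized_adjusted_means(df.assign(score=df.score + 50), ["score"], "group")
        assert np.allclose(m1.to_numpy(), m2.to_numpy())


class TestTrendSlope:
    def test_slope_recovery_within_two_se(self):
        rng = np.random.default_rng(5)
        n = 200
        codon = rng.uniform(1, 733, n)
        df = pd.DataFrame({
            "sex": rng.choice(["male", "female"], n),
            "age_group": rng.choice(list(AGE_LABELS), n),
            "codon_position": codon,
            "total": 15 + 0.02 * codon + rng.normal(0, 3, n),
        })
        tr = trend_slope(df, "total", "codon_position")
        assert abs(tr.slope - 0.02) <= 2 * tr.slope_se
        assert tr.n == n

    def test_constant_score_slope_exactly_zero(self):
        df = pd.DataFrame({
            "sex": ["male"] * 4 + ["female"] * 4,
            "age_group": ["3-5", "6-10", "11-17", ">=18"] * 2,
            "codon_position": np.arange(8.0),
            "total": [5.0] * 8,
        })
        tr = trend_slope(df, "total", "codon_position")
        assert tr.slope == 0.0

    def test_insufficient_rows_is_error(self):
        df = pd.DataFrame({"sex": ["male"], "age_group": ["3-5"],
                           "codon_position": [100.0], "total": [5.0]})
        with pytest.raises(AnalysisError):
            trend_slope(df, "total", "codon_position")

    def test_unadjusted_matches_simple_regression(self):
        rng = np.random.default_rng(9)
        n = 50
        x = rng.uniform(0, 10, n)
        y = 1 + 0.5 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"sex": rng.choice(["male", "female"], n),
                           "age_group": rng.choice(list(AGE_LABELS), n),
                           "x": x, "y": y})
        tr = trend_slope(df, "y", "x", adjusted=False)
        lr = sps.linregress(x, y)
        assert tr.slope == pytest.approx(lr.slope, rel=1e-10)
        assert tr.slope_p == pytest.approx(lr.pvalue, rel=1e-8)
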