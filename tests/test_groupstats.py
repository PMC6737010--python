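import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connseg.groupstats import (
    AGE_BINS,
    age_metric_correlation,
    ancova_effects,
    assign_age_group,
    bonferroni_pairwise,
    cognition_metric_correlations,
    zscore_cognition,
)

from oracles import anova_f_brute, pearson_r_brute


def long_table(groups, covariate=None):
    """groups: dict label -> list of subject values (no within factors)."""
    rows = []
    k = 0
    for g, vals in groups.items():
        for v in vals:
            rows.append(
                {
                    "subject_id": f"s{k}",
                    "age_group": g,
                    "dv": float(v),
                    "scrub_percent": covariate[k] if covariate is not None else 0.0,
                }
            )
            k += 1
    return pd.DataFrame(rows)


class TestAssignAgeGroup:
    @pytest.mark.parametrize(
        "age,expected",
        [(20, "YA"), (34, "YA"), (35, "yMA"), (49, "yMA"), (50, "oMA"),
         (64, "oMA"), (65, "OA"), (80, "OA")],
    )
    def test_bins(self, age, expected):
        assert assign_age_group(age) == expected

    @pytest.mark.parametrize("age", [19, 81, -5])
    def test_out_of_range(self, age):
        with pytest.raises(ValueError, match="outside"):
            assign_age_group(age)

    def test_bins_cover_20_to_80(self):
        edges = sorted(v for pair in AGE_BINS.values() for v in pair)
        assert edges[0] == 20 and edges[-1] == 80


class TestAncovaBetween:
    def test_textbook_two_group_anova(self):
        df = long_table({"A": [1, 2, 3], "B": [4, 5, 6]})
        res = ancova_effects(df, dv="dv", covariate=None)[0]
        assert res.f == pytest.approx(13.5)
        assert res.df == (1.0, 4.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(size=8) for g in ("A", "B", "C")}
        df = long_table({g: v.tolist() for g, v in groups.items()})
        res = ancova_effects(df, dv="dv", covariate=None)[0]
        f, df1, df2 = anova_f_brute(list(groups.values()))
        assert res.f == pytest.approx(f, abs=1e-9)
        assert res.df == (df1, df2)

    def test_identical_groups_null(self):
        df = long_table({"A": [1, 2, 3], "B": [1, 2, 3]})
        res = ancova_effects(df, dv="dv", covariate=None)[0]
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(0.4, 1, size=14)
        df = long_table({"A": a.tolist(), "B": b.tolist()})
        res = ancova_effects(df, dv="dv", covariate=None)[0]
        t, _ = stats.ttest_ind(a, b)
        assert res.f == pytest.approx(t**2, abs=1e-9)

    def test_constant_covariate_dropped_equals_anova(self):
        rng = np.random.default_rng(2)
        groups = {g: rng.normal(size=6).tolist() for g in ("A", "B", "C")}
        df_plain = long_table(groups)
        f_plain = ancova_effects(df_plain, dv="dv", covariate=None)[0].f
        with pytest.warns(UserWarning, match="constant"):
            f_const = ancova_effects(df_plain, dv="dv")[0].f
        assert f_const == pytest.approx(f_plain, abs=1e-9)

    def test_covariate_absorbs_variance(self):
        # dv driven mostly by the covariate: ANCOVA should recover the
        # group effect that plain ANOVA misses
        rng = np.random.default_rng(3)
        n = 40
        cov = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        dv = 3 * cov + np.concatenate([np.zeros(n), np.full(n, 0.8)])
        dv += rng.normal(0, 0.3, 2 * n)
        df = long_table(
            {"A": dv[:n].tolist(), "B": dv[n:].tolist()}, covariate=cov
        )
        p_with = ancova_effects(df, dv="dv")[0].p
        p_without = ancova_effects(df, dv="dv", covariate=None)[0].p
        assert p_with < p_without

    def test_power_with_injected_effect(self):
        # group shift of 1 sd at n = 30/group: reject in >= 90/100 runs
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            groups = {
                "YA": rng.normal(0, 1, 30).tolist(),
                "yMA": rng.normal(0, 1, 30).tolist(),
                "oMA": rng.normal(0, 1, 30).tolist(),
                "OA": rng.normal(1.0, 1, 30).tolist(),
            }
            df = long_table(groups)
            if ancova_effects(df, dv="dv", covariate=None)[0].p < 0.05:
                hits += 1
        assert hits >= 90

    def test_adjusted_means_at_covariate_mean(self):
        rng = np.random.default_rng(4)
        cov = rng.normal(size=12)
        dv = 2 * cov + np.repeat([0.0, 1.0], 6) + rng.normal(0, 0.1, 12)
        df = long_table(
            {"A": dv[:6].tolist(), "B": dv[6:].tolist()}, covariate=cov
        )
        res = ancova_effects(df, dv="dv")[0]
        assert set(res.adjusted_means) == {"A", "B"}
        # adjusted difference should be near the injected 1.0
        assert res.adjusted_means["B"] - res.adjusted_means["A"] == pytest.approx(
            1.0, abs=0.3
        )


class TestAncovaWithin:
    def _paired_design(self, deltas, rng, n=12):
        rows = []
        for i in range(n):
            base = rng.normal()
            for lvl, d in zip(("c1", "c2"), deltas):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "age_group": "A",
                        "w": lvl,
                        "dv": base + d + rng.normal(0, 0.5),
                        "scrub_percent": 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_within_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(5)
        df = self._paired_design((0.0, 0.7), rng)
        res = ancova_effects(df, dv="dv", within=("w",), covariate=None)
        by = {r.effect: r for r in res}
        wide = df.pivot(index="subject_id", columns="w", values="dv")
        t, p = stats.ttest_rel(wide["c1"], wide["c2"])
        assert by["w"].f == pytest.approx(t**2, abs=1e-9)
        assert by["w"].p == pytest.approx(p, abs=1e-12)

    def test_group_by_within_equals_t_on_difference_scores(self):
        rng = np.random.default_rng(6)
        rows = []
        for g, shift in (("A", 0.0), ("B", 0.9)):
            for i in range(10):
                base = rng.normal()
                for lvl, d in (("c1", 0.0), ("c2", shift)):
                    rows.append(
                        {
                            "subject_id": f"{g}{i}",
                            "age_group": g,
                            "w": lvl,
                            "dv": base + d + rng.normal(0, 0.4),
                        }
                    )
        df = pd.DataFrame(rows)
        res = ancova_effects(df, dv="dv", within=("w",), covariate=None)
        by = {r.effect: r for r in res}
        wide = df.pivot(index="subject_id", columns="w", values="dv")
        diff = (wide["c2"] - wide["c1"]).to_frame("d")
        diff["g"] = [s[0] for s in diff.index]
        t, _ = stats.ttest_ind(
            diff.loc[diff.g == "A", "d"], diff.loc[diff.g == "B", "d"]
        )
        assert by["age_group:w"].f == pytest.approx(t**2, abs=1e-9)

    def test_two_within_factors_effect_names_and_dfs(self):
        rng = np.random.default_rng(7)
        rows = []
        for g in ("A", "B"):
            for i in range(6):
                for w1 in ("x", "y"):
                    for w2 in ("p", "q", "r"):
                        rows.append(
                            {
                                "subject_id": f"{g}{i}",
                                "age_group": g,
                                "w1": w1,
                                "w2": w2,
                                "dv": rng.normal(),
                            }
                        )
        df = pd.DataFrame(rows)
        res = ancova_effects(
            df, dv="dv", within=("w1", "w2"), covariate=None
        )
        by = {r.effect: r for r in res}
        assert set(by) == {
            "age_group", "w1", "age_group:w1", "w2", "age_group:w2",
            "w1:w2", "age_group:w1:w2",
        }
        assert by["w1"].df == (1.0, 10.0)
        assert by["w2"].df == (2.0, 20.0)
        assert by["w1:w2"].df == (2.0, 20.0)
        assert by["age_group:w1:w2"].df == (2.0, 20.0)

    def test_missing_cell_errors_with_subject(self):
        rng = np.random.default_rng(8)
        df = self._paired_design((0, 0), rng, n=4)
        df = df.drop(index=df.index[-1])
        with pytest.raises(ValueError, match="s3"):
            ancova_effects(df, dv="dv", within=("w",), covariate=None)

    def test_null_within_effect_calibrated_p(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            df = self._paired_design((0.0, 0.0), rng, n=8)
            res = ancova_effects(df, dv="dv", within=("w",), covariate=None)
            ps.append({r.effect: r for r in res}["w"].p)
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.05


class TestBonferroni:
    def test_multiplication_rule(self):
        # engineered two-group case, m forced to 6
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        res = bonferroni_pairwise(
            np.concatenate([a, b]), ["A"] * 20 + ["B"] * 20, m=6
        )
        row = res.iloc[0]
        assert row["p_adj"] == pytest.approx(min(1.0, 6 * row["p_raw"]))

    def test_cap_at_one(self):
        vals = np.array([1.0, 2.0, 3.0, 1.1, 2.1, 2.9])
        res = bonferroni_pairwise(vals, ["A"] * 3 + ["B"] * 3, m=6)
        assert res.iloc[0]["p_adj"] == 1.0

    def test_four_groups_six_pairs(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=40)
        groups = np.repeat(list("ABCD"), 10)
        res = bonferroni_pairwise(vals, groups)
        assert len(res) == 6

    def test_identical_groups_all_adjusted_one(self):
        vals = np.tile([1.0, 2.0, 3.0], 4)
        groups = np.repeat(list("ABCD"), 3)
        res = bonferroni_pairwise(vals, groups)
        assert (res["p_adj"] == 1.0).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            bonferroni_pairwise([1.0, 2.0, 3.0], ["A", "A", "B"])


class TestCorrelations:
    def test_perfect_line(self):
        ages = np.arange(20, 40)
        r, p = age_metric_correlation(ages, 2 * ages + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self):
        ages = np.arange(20, 40)
        r, _ = age_metric_correlation(ages, -ages)
        assert r == pytest.approx(-1.0)

    def test_five_pair_toy_matches_formula(self):
        x = np.array([21.0, 30.0, 44.0, 58.0, 71.0])
        y = np.array([0.42, 0.40, 0.35, 0.37, 0.30])
        r, _ = age_metric_correlation(x, y)
        assert r == pytest.approx(pearson_r_brute(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            age_metric_correlation([1, 2, 3], [5, 5, 5])

    def test_too_few_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            age_metric_correlation([1, 2], [3, 4])


class TestCognitionCorrelations:
    def _records(self, rng, n=80, beta=1.0):
        ss = rng.uniform(0.2, 0.8, n)
        rec = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "VOCAB": rng.normal(size=n),
                "SPEED": beta * ss + rng.normal(0, 0.1, n),
                "FLUID": rng.normal(size=n),
                "MEM": rng.normal(size=n),
            }
        )
        metrics = pd.DataFrame(
            {"subject_id": rec["subject_id"], "metric": "ss", "value": ss}
        )
        return rec, metrics

    def test_coupled_domain_positive(self):
        rng = np.random.default_rng(12)
        rec, metrics = self._records(rng)
        out = cognition_metric_correlations(rec, metrics)
        speed = out[(out.domain == "SPEED") & (out.metric == "ss")]
        assert speed.iloc[0]["r"] > 0.5
        assert speed.iloc[0]["p"] < 0.01

    def test_uncoupled_domain_small_r(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            rec, metrics = self._records(rng)
            out = cognition_metric_correlations(rec, metrics)
            r = out[(out.domain == "VOCAB") & (out.metric == "ss")].iloc[0]["r"]
            if abs(r) < 3 / np.sqrt(80):
                hits += 1
        assert hits >= 15  # most replicates

    def test_constant_metric_rejected(self):
        rng = np.random.default_rng(13)
        rec, metrics = self._records(rng)
        metrics["value"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            cognition_metric_correlations(rec, metrics)


class TestZscoreCognition:
    def test_reference_mean_maps_to_zero(self):
        ref = pd.DataFrame({"t1": [1.0, 2.0, 3.0]})
        raw = pd.DataFrame({"t1": [2.0]})
        z = zscore_cognition(raw, {"D": ["t1"]}, reference=ref)
        assert z["D"].iloc[0] == pytest.approx(0.0)

    def test_opposite_tasks_average_to_zero(self):
        ref = pd.DataFrame({"t1": [0.0, 2.0], "t2": [0.0, 2.0]})
        raw = pd.DataFrame({"t1": [1 + np.sqrt(2)], "t2": [1 - np.sqrt(2)]})
        z = zscore_cognition(raw, {"D": ["t1", "t2"]}, reference=ref)
        assert z["D"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_by_two_hand_toy(self):
        raw = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [10.0, 20.0, 60.0]})
        z = zscore_cognition(raw, {"D": ["t1", "t2"]})
        # spreadsheet-style expected values
        z1 = (raw.t1 - 2.0) / 1.0
        z2 = (raw.t2 - 30.0) / raw.t2.std(ddof=1)
        expected = (z1 + z2) / 2
        assert np.allclose(z["D"], expected)

    def test_zero_variance_task_rejected(self):
        raw = pd.DataFrame({"t1": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_cognition(raw, {"D": ["t1"]})
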