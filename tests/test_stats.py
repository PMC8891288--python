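"""Statistical battery: correlation, ANOVA, t test, weather, pairwise tests."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from yamcross import (
    anova,
    germination_comparison,
    pearson_correlation,
    pollinator_effect,
    two_sample_t,
    weather_regression,
    weekly_aggregate,
)


class TestPearson:
    def test_exact_linear_relation_gives_r_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = pearson_correlation(x, [2 * v for v in x])
        assert res.r == pytest.approx(1.0)

    def test_four_point_set_matches_brute_force_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        res = pearson_correlation(x, y)
        sx, sy = x - x.mean(), y - y.mean()
        brute_r = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        assert res.r == pytest.approx(brute_r, abs=1e-12)
        t = brute_r * math.sqrt(2 / (1 - brute_r**2))
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 2), abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_null_type_one_error_near_nominal(self, rng):
        # independent x, y: p < .05 should occur in ~5% of replicates
        hits = sum(
            pearson_correlation(rng.normal(size=25),
                                rng.normal(size=25)).p_value < 0.05
            for _ in range(1000))
        assert 30 <= hits <= 72  # 5% +/- ~2.2% (3 sigma at 1,000 reps)


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           "g": ["a"] * 3 + ["b"] * 3})
        table = anova(df, "y", ["g"])
        assert table.loc["g", "F"] == pytest.approx(0.0)

    def test_one_way_matches_brute_force_ss_decomposition(self):
        groups = {"a": [6.0, 8.0, 4.0], "b": [5.0, 4.0, 3.0],
                  "c": [9.0, 7.0, 8.0]}
        df = pd.DataFrame([(g, v) for g, vals in groups.items() for v in vals],
                          columns=["g", "y"])
        table = anova(df, "y", ["g"])
        grand = df["y"].mean()
        ss_b = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_w = sum((x - np.mean(v)) ** 2 for v in groups.values() for x in v)
        assert table.loc["g", "sum_sq"] == pytest.approx(ss_b)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_w)
        f_brute = (ss_b / 2) / (ss_w / 6)
        assert table.loc["g", "F"] == pytest.approx(f_brute)

    def test_two_group_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.8, 1, 15)
        df = pd.DataFrame({"y": np.concatenate([x, y]),
                           "g": ["x"] * 12 + ["y"] * 15})
        f = anova(df, "y", ["g"]).loc["g", "F"]
        t = two_sample_t(x, y).t
        assert f == pytest.approx(t**2)

    def test_injected_factor_detected_in_balanced_two_way(self, rng):
        n = 200
        year = rng.choice(["y1", "y2"], size=n)
        loc = rng.choice(["l1", "l2"], size=n)
        y = rng.normal(size=n) + np.where(loc == "l2", 1.5, 0.0)
        df = pd.DataFrame({"y": y, "year": year, "loc": loc})
        table = anova(df, "y", ["year", "loc"])
        assert table.loc["loc", "p_value"] < 0.001

    def test_aliased_factors_are_an_error(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                           "a": ["p", "p", "q", "q"],
                           "b": ["u", "u", "v", "v"]})
        with pytest.raises(ValueError, match="alias|confound"):
            anova(df, "y", ["a", "b"])

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError):
            anova(df, "y", ["g"])


class TestTwoSampleT:
    def test_identical_samples_give_t_zero_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, x)
        assert res.t == 0.0 and res.p_value == pytest.approx(1.0)

    def test_pooled_t_matches_brute_force_formula(self):
        x = np.array([19.8, 12.7, 13.2, 16.9, 10.6])
        y = np.array([28.2, 26.3, 33.1, 29.9, 23.4])
        res = two_sample_t(x, y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) \
            / (len(x) + len(y) - 2)
        t_brute = (x.mean() - y.mean()) / math.sqrt(sp2 * (1/len(x) + 1/len(y)))
        assert res.t == pytest.approx(t_brute, abs=1e-12)

    def test_shapiro_reported_when_requested(self, rng):
        res = two_sample_t(rng.normal(size=20), rng.normal(size=20),
                           check_normality=True)
        w, p = res.shapiro_x
        assert 0 < w <= 1 and 0 <= p <= 1

    def test_power_against_two_sigma_shift(self, rng):
        hits = sum(
            two_sample_t(rng.normal(0, 1, 30),
                         rng.normal(2, 1, 30)).p_value < 0.01
            for _ in range(200))
        assert hits >= 190  # >= 95% power

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestWeeklyWeather:
    def _daily(self, rain, start="2019-08-05"):
        dates = pd.date_range(start, periods=len(rain))
        return pd.DataFrame({"date": dates, "rainfall": rain,
                             "tmax": [30.0] * len(rain)})

    def test_rainfall_summed_rainy_days_counted(self):
        weekly = weekly_aggregate(self._daily([1.0] * 7), anchor="2019-08-05")
        assert weekly.loc[0, "rainfall"] == 7.0
        assert weekly.loc[0, "rainy_days"] == 7

    def test_half_millimetre_days_are_not_rainy(self):
        weekly = weekly_aggregate(self._daily([0.5] * 7), anchor="2019-08-05")
        assert weekly.loc[0, "rainy_days"] == 0  # strict > 0.5 mm

    def test_temperature_uses_weekly_mean(self):
        weekly = weekly_aggregate(self._daily([0.0] * 14), anchor="2019-08-05")
        assert (weekly["tmax"] == 30.0).all()
        assert list(weekly["week"]) == [1, 2]

    def test_long_gap_flags_week_incomplete(self):
        daily = self._daily([1.0] * 7)
        daily = daily.drop(index=[2, 3, 4])  # 3 consecutive missing days
        weekly = weekly_aggregate(daily, anchor="2019-08-05")
        assert bool(weekly.loc[0, "incomplete"])


class TestWeatherRegression:
    def test_noiseless_linear_function_recovered(self):
        weekly = pd.DataFrame({"rainfall": [10.0, 25, 5, 30, 18, 12, 22],
                               "tmax": [30.0, 31, 29, 33, 32, 28, 30.5]})
        y = 2.0 + 0.5 * weekly["rainfall"] - 1.2 * weekly["tmax"]
        out = weather_regression(y, weekly, ["rainfall", "tmax"]).set_index("term")
        assert out.loc["rainfall", "coef"] == pytest.approx(0.5, abs=1e-8)
        assert out.loc["tmax", "coef"] == pytest.approx(-1.2, abs=1e-8)

    def test_known_slope_recovered_within_three_se(self, rng):
        ok = 0
        for _ in range(100):
            rain = rng.uniform(0, 40, size=20)
            y = 10 + 0.8 * rain + rng.normal(0, 3, size=20)
            out = weather_regression(y, pd.DataFrame({"rainfall": rain}),
                                     ["rainfall"]).set_index("term")
            if abs(out.loc["rainfall", "coef"] - 0.8) \
                    <= 3 * out.loc["rainfall", "std_err"]:
                ok += 1
        assert ok >= 95  # 3-SE coverage ~99.7%

    def test_constant_predictor_is_an_error(self):
        weekly = pd.DataFrame({"rainfall": [5.0] * 8,
                               "tmax": np.arange(8.0)})
        with pytest.raises(ValueError, match="rainfall"):
            weather_regression(np.arange(8.0), weekly, ["rainfall", "tmax"])


class TestPollinatorEffect:
    def _rates(self, shift, rng, n_poll=4, n_comb=6):
        rows = []
        for p in range(n_poll):
            for c in range(n_comb):
                mu = 20.0 + (shift if p == 0 else 0.0)
                rows.append({"pollinator": f"P{p}", "combination": f"C{c}",
                             "crossability_rate": mu + rng.normal(0, 2)})
        return pd.DataFrame(rows)

    def test_identical_outcomes_give_no_significant_pairs(self, rng):
        table, tukey = pollinator_effect(self._rates(0.0, rng))
        assert table.loc["pollinator", "p_value"] > 0.05
        assert not tukey["reject"].any()

    def test_strong_pollinator_is_flagged(self, rng):
        _, tukey = pollinator_effect(self._rates(15.0, rng))
        flagged = tukey[(tukey["group1"] == "P0") | (tukey["group2"] == "P0")]
        assert flagged["reject"].all()

    def test_disjoint_combination_sets_violate_design(self, rng):
        rates = self._rates(0.0, rng)
        rates.loc[rates["pollinator"] == "P0", "combination"] = "Cx"
        with pytest.raises(ValueError, match="common"):
            pollinator_effect(rates)

    def test_tukey_interval_matches_studentized_range_formula(self):
        groups = {"a": [6.0, 8.0, 4.0, 6.0], "b": [5.0, 4.0, 3.0, 4.0],
                  "c": [9.0, 7.0, 8.0, 9.0]}
        rows = [{"pollinator": g, "combination": f"C{i}",
                 "crossability_rate": v}
                for g, vals in groups.items() for i, v in enumerate(vals)]
        _, tukey = pollinator_effect(pd.DataFrame(rows))
        mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
        df_resid = sum(len(v) - 1 for v in groups.values())
        q = sps.studentized_range.ppf(0.95, k=3, df=df_resid)
        half_width = q / math.sqrt(2) * math.sqrt(mse * (1/4 + 1/4))
        row = tukey.iloc[0]
        assert float(row["upper"]) - float(row["lower"]) == pytest.approx(
            2 * half_width, rel=1e-6)


class TestGerminationComparison:
    def _families(self, rates, n=12, sown=50, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for cat, rate in rates.items():
            for _ in range(n):
                rows.append({"cross_category": cat, "seeds_sown": sown,
                             "seeds_germinated": int(rng.binomial(sown, rate))})
        return pd.DataFrame(rows)

    def test_equal_rates_give_no_separation(self, rng):
        table, lsd = germination_comparison(
            self._families({"a": 0.5, "b": 0.5, "c": 0.5}, rng=rng))
        assert table.loc["cross_category", "p_value"] > 0.01
        assert not lsd["significant"].any()

    def test_open_pollinated_advantage_detected(self, rng):
        # 0.61 vs 0.49 at 2,000 seeds per category
        fam = self._families({"open-pollinated": 0.61,
                              "intraspecific supervised": 0.49},
                             n=40, sown=50, rng=rng)
        table, lsd = germination_comparison(fam)
        assert table.loc["cross_category", "p_value"] < 0.001
        assert lsd["significant"].all()

    def test_lsd_threshold_matches_hand_formula(self):
        fam = pd.DataFrame({
            "cross_category": ["a"] * 4 + ["b"] * 4,
            "seeds_sown": [100] * 8,
            "seeds_germinated": [50, 55, 45, 52, 70, 72, 66, 75],
        })
        table, lsd = germination_comparison(fam)
        mse = table.loc["Residual", "mean_sq"]
        tcrit = sps.t.ppf(0.975, table.loc["Residual", "df"])
        assert lsd.loc[0, "lsd"] == pytest.approx(
            tcrit * math.sqrt(mse * (1/4 + 1/4)), abs=1e-10)
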