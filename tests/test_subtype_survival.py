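"""Subtype classifier and the group-comparison / survival statistics."""

import numpy as np
import pandas as pd
import pytest

from mutscape import subtype_survival as ss
from mutscape.synthetic_cohort import simulate_subtype_labels


def expo_frame(aging, hrd):
    n = len(aging)
    return pd.DataFrame(
        {
            "SBS1": np.asarray(aging) * 0.4,
            "SBS5": np.asarray(aging) * 0.6,
            "SBS3": hrd,
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestAssignSubtype:
    def test_hand_tertiles_nine_samples(self):
        out = ss.assign_sbs_subtype(expo_frame(np.arange(1, 10), np.arange(9, 0, -1)))
        assert list(out["aging_tertile"]) == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3
        assert list(out["subtype"]) == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_mapping_is_bijection(self):
        rng = np.random.default_rng(0)
        out = ss.assign_sbs_subtype(expo_frame(rng.random(60), rng.random(60)))
        for row in out.itertuples():
            assert row.subtype == ss.SUBTYPE_MAP[(row.aging_level, row.hrd_level)]
        sizes = out["aging_tertile"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_values_at_cut_point_go_to_lower_tertile(self):
        aging = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        out = ss.assign_sbs_subtype(expo_frame(aging, np.arange(9)))
        assert list(out["aging_tertile"]) == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_proportions_mode_divides_by_total(self):
        expo = expo_frame([10, 20, 30, 40, 50, 60], [3, 5, 1, 6, 2, 4])
        counts = ss.assign_sbs_subtype(expo, mode="counts")
        props = ss.assign_sbs_subtype(expo, mode="proportions")
        assert (props["aging_activity"] <= 1).all()
        assert not counts["aging_activity"].equals(props["aging_activity"])

    def test_all_tied_raises_with_guidance(self):
        with pytest.raises(ValueError, match="degenerate tertiles"):
            ss.assign_sbs_subtype(expo_frame([1] * 9, [1] * 9))


class TestCompareFeatures:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        assert ss.compare_features(x, x) > 0.9

    def test_extreme_rank_separation_exact_p(self):
        assert ss.compare_features([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_power_at_planted_shift(self):
        rng = np.random.default_rng(2)
        hits = sum(
            ss.compare_features(rng.normal(0, 1, 40), rng.normal(1.0, 1, 40)) < 0.05
            for _ in range(50)
        )
        assert hits >= 40  # >= 80% power at a 1 SD shift, n=40 per group

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            ss.compare_features([], [1.0])


class TestSubtypeOdds:
    def test_null_age_effect_or_near_one(self):
        rng = np.random.default_rng(3)
        age = rng.normal(56, 11, 500)
        bmi = rng.normal(31, 6, 500)
        labels = np.where(rng.random(500) < 0.5, 1, 3)
        out = ss.subtype_odds(pd.DataFrame({"subtype": labels, "age": age, "bmi": bmi}))
        row = out[out["covariate"] == "age"].iloc[0]
        assert row.ci_low <= 1.0 <= row.ci_high

    def test_planted_log_odds_recovered(self):
        rng = np.random.default_rng(4)
        age = np.clip(rng.normal(56, 11, 400), 25, 90)
        bmi = np.clip(rng.normal(31, 6.5, 400), 17, 55)
        labels = simulate_subtype_labels(
            age, bmi, -0.115, -0.0749, 0.115 * 56 + 0.0749 * 31, rng
        )
        out = ss.subtype_odds(pd.DataFrame({"subtype": labels, "age": age, "bmi": bmi}))
        row = out[out["covariate"] == "age"].iloc[0]
        assert row.ci_low <= np.exp(-1.15) <= row.ci_high
        assert row.odds_ratio < 1

    def test_single_covariate_matches_contingency_odds_ratio(self):
        # binary age: logistic slope equals the log odds ratio of the 2x2 table
        old = np.array([1] * 100 + [0] * 100)
        labels = np.array([1] * 30 + [3] * 70 + [1] * 60 + [3] * 40)
        df = pd.DataFrame({"subtype": labels, "age": old, "bmi": 0.0})
        out = ss.subtype_odds(df, age_increment=1.0, covariates=("age",))
        table_or = (30 / 70) / (60 / 40)
        assert out.loc[0, "odds_ratio"] == pytest.approx(table_or, rel=1e-4)


class TestKmLogrank:
    def test_no_events_flat_curves_undefined_p(self):
        df = pd.DataFrame({"time": [5, 6, 7, 8], "event": 0, "group": [0, 0, 1, 1]})
        out = ss.km_logrank(df)
        assert out["p"] is None
        for kmf in out["curves"].values():
            assert (kmf.survival_function_.to_numpy() == 1).all()

    def test_hand_computed_fixture(self):
        # events at t=1,2 (A) and t=3,6 (B); censoring at 5 (A) and 4 (B)
        df = pd.DataFrame(
            {
                "time": [1, 2, 5, 3, 4, 6],
                "event": [1, 1, 0, 1, 0, 1],
                "group": ["A", "A", "A", "B", "B", "B"],
            }
        )
        out = ss.km_logrank(df)
        # hand calculation: O_A = 2, E_A = 1/2 + 2/5 + 1/4, V = 1/4 + 6/25 + 3/16
        e_a = 0.5 + 0.4 + 0.25
        v = 0.25 + 0.24 + 0.1875
        assert out["statistic"] == pytest.approx((2 - e_a) ** 2 / v, rel=1e-6)
        km_a = out["curves"]["A"].survival_function_["A"]
        assert km_a.loc[1.0] == pytest.approx(2 / 3)
        assert km_a.loc[2.0] == pytest.approx(1 / 3)
        assert km_a.loc[5.0] == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        times = [3, 5, 8, 11, 14]
        df = pd.DataFrame(
            {
                "time": times * 2,
                "event": [1, 1, 0, 1, 0] * 2,
                "group": ["A"] * 5 + ["B"] * 5,
            }
        )
        assert ss.km_logrank(df)["p"] > 0.95

    def test_nonpositive_times_rejected(self):
        df = pd.DataFrame({"time": [0, 1], "event": [1, 1], "group": [0, 1]})
        with pytest.raises(ValueError):
            ss.km_logrank(df)


class TestCox:
    def test_null_data_hr_near_one(self):
        rng = np.random.default_rng(5)
        n = 400
        df = pd.DataFrame(
            {
                "time": rng.exponential(50, n),
                "event": rng.random(n) < 0.6,
                "group": rng.integers(0, 2, n),
            }
        )
        out = ss.cox_hr(df)
        assert out["ci_low"] <= 1.0 <= out["ci_high"]

    def test_log_likelihood_matches_hand_partial_likelihood(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 0, 1, 1, 0, 1],
                "group": [1, 0, 1, 0, 1, 0],
            }
        )
        out = ss.cox_hr(df)
        beta = np.log(out["hr"])

        def log_pl(b):
            order = df.sort_values("time")
            ll = 0.0
            for i, row in order.iterrows():
                if not row.event:
                    continue
                risk = order[order.time >= row.time]
                ll += b * row.group - np.log(np.exp(b * risk.group).sum())
            return ll

        assert out["model"].log_likelihood_ == pytest.approx(log_pl(beta), rel=1e-6)

    def test_consistency_on_large_exponential_sample(self):
        rng = np.random.default_rng(6)
        n = 2000
        group = rng.integers(0, 2, n)
        lam = 0.01 * np.where(group == 1, 2.0, 1.0)
        t = rng.exponential(1 / lam)
        c = rng.uniform(20, 200, n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int), "group": group}
        )
        out = ss.cox_hr(df)
        assert out["hr"] == pytest.approx(2.0, rel=0.12)

    def test_too_few_events_rejected(self):
        df = pd.DataFrame(
            {"time": [1, 2, 3], "event": [0, 0, 0], "group": [0, 1, 0]}
        )
        with pytest.raises(ValueError):
            ss.cox_hr(df)
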