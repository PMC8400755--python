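"""Propensity weighting, standardized bias and Rubin's balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import selfie_mcda as sm
from conftest import make_cohort


def _bias_oracle(x1, x2, w2=None):
    """Direct formula evaluation: 100 |m1-m2| / sqrt((v1+v2)/2), with
    frequency-normalized weighted moments for the second sample."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    m1, v1 = x1.mean(), x1.var(ddof=1)
    if w2 is None:
        m2, v2 = x2.mean(), x2.var(ddof=1)
    else:
        w = np.asarray(w2, float) * len(w2) / np.sum(w2)
        m2 = np.sum(w * x2) / np.sum(w)
        v2 = np.sum(w * (x2 - m2) ** 2) / (np.sum(w) - 1)
    return 100 * abs(m1 - m2) / np.sqrt((v1 + v2) / 2)


class TestStandardizedBias:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert sm.standardized_bias(x, x) == 0.0

    def test_unit_case(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0, 1, 200_000)
        x2 = rng.normal(1, 1, 200_000)
        assert sm.standardized_bias(x1, x2) == pytest.approx(100.0, abs=1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(2, 1.5, 40), rng.normal(1, 2.0, 30)
        w2 = rng.uniform(0.2, 3.0, 30)
        assert sm.standardized_bias(x1, x2) == pytest.approx(
            _bias_oracle(x1, x2))
        assert sm.standardized_bias(x1, x2, weights_uc=w2) == pytest.approx(
            _bias_oracle(x1, x2, w2))

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=20),
           st.lists(st.floats(-50, 50), min_size=3, max_size=20),
           st.floats(0.1, 5), st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_affine_invariance(self, a, b, scale, shift):
        a, b = np.asarray(a), np.asarray(b)
        if a.var(ddof=1) + b.var(ddof=1) <= 1e-12:
            return
        bias = sm.standardized_bias(a, b)
        assert sm.standardized_bias(b, a) == pytest.approx(bias)
        assert sm.standardized_bias(scale * a + shift, scale * b + shift) \
            == pytest.approx(bias, rel=1e-6, abs=1e-6)

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sm.standardized_bias(np.ones(5), np.ones(4))


class TestFitPropensity:
    def test_att_weight_formula(self, weighted_large):
        arm = weighted_large.cohort.arm_of()
        w, ps = weighted_large.att_weight, weighted_large.propensity
        hcpc = arm.reindex(w.index) == "HCPC"
        assert (w[hcpc] == 1.0).all()
        uc = ~hcpc
        assert np.allclose(w[uc], ps[uc] / (1 - ps[uc]))
        assert np.isfinite(w).all()
        assert ((ps > 0) & (ps < 1)).all()

    def test_no_information_covariates_give_constant_propensity(self):
        rows = []
        for i in range(30):
            arm = "HCPC" if i < 18 else "UC"
            rows.append({"patient_id": f"P{i}", "arm": arm, "time": "T0",
                         "physical_functioning": 5.0,
                         "social_participation": 8.0})
        t = make_cohort(rows)
        w = sm.fit_propensity(t)
        assert np.allclose(w.propensity, 18 / 30, atol=1e-6)
        uc_w = w.att_weight[w.cohort.arm_of() == "UC"]
        assert np.allclose(uc_w, uc_w.iloc[0])

    def test_missing_baseline_outcome_rejected(self, four_patient_cohort):
        df = four_patient_cohort.data
        df["physical_functioning"] = 5.0
        df["social_participation"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            sm.fit_propensity(four_patient_cohort)


class TestRubins:
    @staticmethod
    def _manual_weighted(linear_by_arm, weights_uc=None):
        t = sm.CohortTable(pd.DataFrame(
            [{"patient_id": f"{arm}{i}", "arm": arm, "time": "T0",
              "age_years": 80.0}
             for arm, xs in linear_by_arm.items() for i, _ in enumerate(xs)]))
        idx = [f"{arm}{i}" for arm, xs in linear_by_arm.items()
               for i in range(len(xs))]
        li = pd.Series([x for xs in linear_by_arm.values() for x in xs],
                       index=idx)
        w = pd.Series(1.0, index=idx)
        return sm.WeightedCohort(t, pd.Series(0.5, index=idx), w, li)

    def test_self_vs_self_gives_B0_R1(self):
        xs = [0.1, -0.4, 0.9, 1.3, -2.0]
        wc = self._manual_weighted({"HCPC": xs, "UC": xs})
        B, R = sm.rubins_B_R(wc)
        assert B == 0.0
        assert R == 1.0

    def test_variance_ratio_two_is_borderline(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100_000) * np.sqrt(2)
        b = rng.normal(0, 1, 100_000)
        a, b = a - a.mean(), b - b.mean()
        a *= np.sqrt(2) / a.std(ddof=1)     # exact variances 2 and 1
        b /= b.std(ddof=1)
        wc = self._manual_weighted({"HCPC": list(a[:500]), "UC": list(b[:500])})
        # rescale exactly on the subsample
        li = wc.linear_index.copy()
        arm = wc.cohort.arm_of()
        for lab, target in (("HCPC", 2.0), ("UC", 1.0)):
            mask = arm == lab
            v = li[mask]
            li[mask] = (v - v.mean()) / v.std(ddof=1) * np.sqrt(target)
        wc.linear_index = li
        B, R = sm.rubins_B_R(wc)
        assert R == pytest.approx(2.0, abs=1e-9)

    def test_weighting_improves_balance_on_confounded_cohort(self, weighted_large):
        B_before, _ = sm.rubins_B_R(weighted_large, use_weights=False)
        B_after, R_after = sm.rubins_B_R(weighted_large, use_weights=True)
        assert B_after < B_before
        assert 0.5 < R_after < 2.0

    def test_zero_variance_linear_index_rejected(self):
        wc = self._manual_weighted({"HCPC": [1.0, 1.0], "UC": [0.0, 0.5]})
        with pytest.raises(ValueError, match="variance"):
            sm.rubins_B_R(wc)


class TestBalanceTable:
    def test_hcpc_column_unchanged_by_weighting(self, weighted_large):
        report = sm.balance_table(weighted_large)
        rows = report.rows
        before = rows[rows["stage"] == "before"].set_index("variable")
        after = rows[rows["stage"] == "after"].set_index("variable")
        pd.testing.assert_series_equal(before["mean_hcpc"],
                                       after["mean_hcpc"])

    def test_weighting_reduces_mean_bias(self, weighted_large):
        s = sm.balance_table(weighted_large).summary.set_index("stage")
        assert s.loc["after", "mean_bias"] < s.loc["before", "mean_bias"]
        assert s.loc["after", "rubins_B"] < s.loc["before", "rubins_B"]
        assert s.loc["after", "rubins_B_pass"]

    def test_binary_covariate_cells_match_hand_calculation(self):
        rows = []
        sexes_h = ["male"] * 3 + ["female"] * 7
        sexes_u = ["male"] * 5 + ["female"] * 5
        for i, s in enumerate(sexes_h):
            rows.append({"patient_id": f"H{i}", "arm": "HCPC", "time": "T0",
                         "sex": s})
        for i, s in enumerate(sexes_u):
            rows.append({"patient_id": f"U{i}", "arm": "UC", "time": "T0",
                         "sex": s})
        t = make_cohort(rows)
        idx = [f"H{i}" for i in range(10)] + [f"U{i}" for i in range(10)]
        wc = sm.WeightedCohort(t, pd.Series(0.5, index=idx),
                               pd.Series(1.0, index=idx),
                               pd.Series(np.linspace(-1, 1, 20), index=idx))
        report = sm.balance_table(wc, covariates=["sex"],
                                  include_outcomes=False)
        row = report.rows.query(
            "stage == 'before' and variable == 'sex[male]'").iloc[0]
        assert row["mean_hcpc"] == pytest.approx(0.3)
        assert row["mean_uc"] == pytest.approx(0.5)
        # hand-computed: 100*|0.3-0.5|/sqrt((0.3*0.7/0.9*... ) use ddof=1 vars
        v_h = pd.Series([1]*3 + [0]*7).var(ddof=1)
        v_u = pd.Series([1]*5 + [0]*5).var(ddof=1)
        expected = 100 * 0.2 / np.sqrt((v_h + v_u) / 2)
        assert row["std_bias"] == pytest.approx(expected)

    def test_reweighted_uc_means_approach_hcpc_means(self, weighted_large):
        """Parameter-free ATT balance recovery: with a correctly specified
        propensity model the weighted UC covariate means converge to the
        HCPC means."""
        report = sm.balance_table(weighted_large)
        after = report.rows.query("stage == 'after'").set_index("variable")
        age = after.loc["age_years"]
        assert abs(age["mean_hcpc"] - age["mean_uc"]) < 0.5   # years
        assert age["std_bias"] < 8.0
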