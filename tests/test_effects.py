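"""Random-intercept DiD model: closed-form identities, cross-checks, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import selfie_mcda as sm
from conftest import make_cohort, unit_weighted


def _cell_mean_did(df: pd.DataFrame, outcome: str) -> float:
    cells = df.groupby(["arm", "time"])[outcome].mean()
    return ((cells["HCPC", "T1"] - cells["HCPC", "T0"])
            - (cells["UC", "T1"] - cells["UC", "T0"]))


@pytest.fixture(scope="module")
def balanced_2x2():
    """Complete two-wave cohort, no covariate effects, equal weights."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(30):
        arm = "HCPC" if i < 15 else "UC"
        base = rng.normal(20, 3)
        rows.append({"patient_id": f"P{i}", "arm": arm, "time": "T0",
                     "resilience": float(np.clip(base, 6, 30))})
        change = rng.normal(1.5 if arm == "HCPC" else -0.5, 1)
        rows.append({"patient_id": f"P{i}", "arm": arm, "time": "T1",
                     "resilience": float(np.clip(base + change, 6, 30))})
    return make_cohort(rows)


class TestClosedFormEquivalence:
    def test_beta3_equals_four_cell_mean_did(self, balanced_2x2):
        wc = unit_weighted(balanced_2x2)
        fit = sm.fit_did_model(wc, "resilience", covariates=())
        expected = _cell_mean_did(balanced_2x2.data, "resilience")
        assert fit.beta3 == pytest.approx(expected, abs=1e-8)

    def test_identical_trajectories_give_null_effect(self):
        """Arms built from the same values => beta3 is exactly zero."""
        rows = []
        vals = {"T0": [18.0, 21.0, 24.0], "T1": [19.0, 22.0, 23.0]}
        for a_i, arm in enumerate(["HCPC", "UC"]):
            for i in range(3):
                for t in ("T0", "T1"):
                    rows.append({"patient_id": f"{arm}{i}", "arm": arm,
                                 "time": t, "resilience": vals[t][i]})
        wc = unit_weighted(make_cohort(rows))
        fit = sm.fit_did_model(wc, "resilience", covariates=())
        assert fit.beta3 == pytest.approx(0.0, abs=1e-8)


class TestAgainstMixedLM:
    def test_unit_weight_fit_matches_statsmodels_ml(self):
        """At unit weights the in-package weighted ML must agree with an
        independent mixed-model implementation (ML, random intercept)."""
        cfg = sm.SimulationConfig(
            n_hcpc=150, n_uc=150, seed=4, confounding_strength={},
            attrition_prob={"HCPC": 0.2, "UC": 0.3},
            item_missing_prob=0.0, followup_only_count=0)
        table, _ = sm.simulate_cohort(cfg)
        fit = sm.fit_did_model(unit_weighted(table),
                               "psychological_wellbeing")
        df = table.data.copy()
        df["I"] = (df["arm"] == "HCPC").astype(float)
        df["T"] = (df["time"] == "T1").astype(float)
        ref = smf.mixedlm("psychological_wellbeing ~ I * T + age_years",
                          df, groups=df["patient_id"]).fit(reml=False)
        assert fit.beta3 == pytest.approx(ref.params["I:T"], abs=1e-4)
        assert fit.params["const"] == pytest.approx(ref.params["Intercept"],
                                                    abs=1e-3)
        assert fit.psi_variance == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                                 rel=1e-3)
        assert fit.residual_variance == pytest.approx(float(ref.scale),
                                                      rel=1e-3)
        assert fit.loglik == pytest.approx(float(ref.llf), abs=1e-3)


class TestRecovery:
    def test_beta3_recovers_configured_effect(self):
        """n = 500/arm, no confounding: estimate within 3 robust SE of truth."""
        cfg = sm.SimulationConfig(
            n_hcpc=500, n_uc=500, seed=9, confounding_strength={},
            attrition_prob={"HCPC": 0.1, "UC": 0.1},
            item_missing_prob=0.0, followup_only_count=0)
        table, truth = sm.simulate_cohort(cfg)
        weighted = sm.fit_propensity(table)
        fit = sm.fit_did_model(weighted, "resilience")
        se = float(fit.robust_se["arm_time"])
        assert abs(fit.beta3 - truth.att["resilience"]) < 3 * se

    def test_attrited_patients_keep_baseline_rows(self, study_pipeline):
        table, _, _, weighted = study_pipeline
        fit = sm.fit_did_model(weighted, "resilience")
        n_obs_expected = int(table.data["resilience"].notna().sum())
        assert fit.n_obs == n_obs_expected
        assert fit.n_patients == table.data["patient_id"].nunique()


class TestPrediction:
    def test_anchoring_identity(self, study_pipeline):
        _, _, _, weighted = study_pipeline
        fit = sm.fit_did_model(weighted, "enjoyment_of_life")
        row = sm.predict_performance(fit, weighted)
        assert row.mean_hcpc - row.mean_uc == pytest.approx(fit.beta3,
                                                            abs=1e-12)

    def test_zero_effect_predictions_coincide(self, balanced_2x2):
        wc = unit_weighted(balanced_2x2)
        fit = sm.fit_did_model(wc, "resilience", covariates=())
        fit.params["arm_time"] = 0.0
        row = sm.predict_performance(fit, wc)
        assert row.mean_hcpc == pytest.approx(row.mean_uc, abs=1e-12)

    def test_predictions_track_generator_cell_means(self):
        """Predicted arm means land within 3 SE of the anchored truth."""
        p = sm.DEFAULT_OUTCOME_PARAMS["resilience"]
        cfg = sm.SimulationConfig(
            n_hcpc=800, n_uc=800, seed=13, confounding_strength={},
            attrition_prob={"HCPC": 0.0, "UC": 0.0},
            item_missing_prob=0.0, followup_only_count=0)
        table, truth = sm.simulate_cohort(cfg)
        weighted = sm.fit_propensity(table)
        fit = sm.fit_did_model(weighted, "resilience")
        row = sm.predict_performance(fit, weighted)
        base = table.data[(table.data["arm"] == "HCPC")
                          & (table.data["time"] == "T0")]["resilience"].mean()
        truth_h = base + p.time_trend + p.treatment_effect
        assert row.mean_hcpc == pytest.approx(truth_h, abs=3 * row.se_hcpc + 0.3)
        assert row.mean_uc == pytest.approx(truth_h - p.treatment_effect,
                                            abs=3 * row.se_uc + 0.3)


class TestEffectsTable:
    def test_rows_mirror_fit_fields(self, study_pipeline):
        _, _, _, weighted = study_pipeline
        fits = [sm.fit_did_model(weighted, n)
                for n in ("resilience", "physical_functioning")]
        table = sm.effects_table(fits)
        for fit in fits:
            row = table.loc[fit.outcome_name]
            assert row["diff_in_change"] == fit.beta3
            assert row["change_hcpc"] - row["change_uc"] == pytest.approx(
                fit.beta3, abs=1e-12)
            assert row["ci_lower"] < fit.beta3 < row["ci_upper"]

    def test_improvement_annotation_follows_direction(self):
        specs = sm.outcome_registry()
        table = pd.DataFrame({
            "diff_in_change": [-0.5, -0.5, 0.5],
        }, index=["physical_functioning", "resilience",
                  "psychological_wellbeing"])
        table.index.name = "outcome"
        out = sm.annotate_improvement(table, specs)
        # negative effect improves a higher-is-worse scale, worsens a
        # higher-is-better one
        assert out.loc["physical_functioning", "improvement"] == "HCPC"
        assert out.loc["resilience", "improvement"] == "UC"
        assert out.loc["psychological_wellbeing", "improvement"] == "HCPC"

    def test_singular_outcome_rejected(self, four_patient_cohort):
        wc = unit_weighted(four_patient_cohort)
        with pytest.raises((KeyError, ValueError)):
            sm.fit_did_model(wc, "no_such_outcome")
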