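"""Monte Carlo sensitivity analysis: sampling, degeneracy, dominance, nulls."""

import numpy as np
import pandas as pd
import pytest

import selfie_mcda as sm
from test_mcda import perf_frame


def with_uncertainty(perf: pd.DataFrame, se: float = 0.1,
                     rho: float = 0.0) -> pd.DataFrame:
    out = perf.copy()
    out["se_hcpc"] = se
    out["se_uc"] = se
    out["covariance"] = rho * se * se
    return out


class TestSampleCorrelated:
    def test_zero_covariance_returns_mean_exactly(self):
        mean = np.array([1.0, -2.0, 3.0])
        draws = sm.sample_correlated(mean, np.zeros((3, 3)), 50, rng=0)
        assert (draws == mean).all()

    def test_same_seed_reproduces_draws(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = sm.sample_correlated(np.zeros(2), cov, 1000, rng=7)
        b = sm.sample_correlated(np.zeros(2), cov, 1000, rng=7)
        assert (a == b).all()

    def test_sample_covariance_converges_to_target(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        draws = sm.sample_correlated(np.zeros(2), cov, 100_000, rng=3)
        assert np.allclose(np.cov(draws.T), cov, atol=0.02)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            sm.sample_correlated(np.zeros(3), np.eye(2), 10)

    def test_indefinite_covariance_repaired(self):
        cov = np.array([[1.0, 1.2], [1.2, 1.0]])   # not PSD
        draws = sm.sample_correlated(np.zeros(2), cov, 20_000, rng=5)
        got = np.cov(draws.T)
        assert got[0, 1] > 0.8                      # correlation preserved


@pytest.fixture
def dominant_perf():
    """Programme arm better on every outcome, mixed directions."""
    return with_uncertainty(perf_frame({
        "well": (75.0, 68.0, "higher_better"),
        "adl": (4.5, 6.0, "higher_worse"),
        "joy": (2.9, 2.4, "higher_better"),
    }), se=0.05)


WS = sm.StakeholderWeights(sm.Stakeholder.CUSTOM,
                           {"well": 0.4, "adl": 0.3, "joy": 0.3}, label="w")


class TestRunPsa:
    def test_degenerate_psa_equals_deterministic(self, dominant_perf):
        perf = dominant_perf.copy()
        perf[["se_hcpc", "se_uc", "covariance"]] = 0.0
        res = sm.run_psa(perf, [WS], sm.PsaConfig(n_replications=500, seed=1))
        det = res.deterministic.overall.loc["w"]
        for arm in ("HCPC", "UC"):
            row = res.summary.loc[("w", arm)]
            assert row["mean"] == det[arm]
            assert row["lower"] == row["upper"] == row["mean"]
        assert res.pct_hcpc_better["w"] in (0.0, 100.0)
        assert res.pct_hcpc_better["w"] == 100.0   # HCPC dominant here

    def test_dominant_programme_wins_almost_always(self, dominant_perf):
        res = sm.run_psa(dominant_perf, [WS],
                         sm.PsaConfig(n_replications=10_000, seed=2))
        assert res.pct_hcpc_better["w"] >= 99.0
        assert not res.intervals_overlap["w"]

    def test_identical_arms_split_fifty_fifty(self):
        perf = with_uncertainty(perf_frame({
            "well": (70.0, 70.0, "higher_better"),
            "adl": (5.0, 5.0, "higher_worse"),
        }), se=0.5)
        res = sm.run_psa(perf, [sm.StakeholderWeights(
            sm.Stakeholder.CUSTOM, {"well": 0.6, "adl": 0.4}, label="w")],
            sm.PsaConfig(n_replications=10_000, seed=3))
        se_binom = 100 * 0.5 / np.sqrt(10_000)
        assert abs(res.pct_hcpc_better["w"] - 50.0) < 3 * se_binom + 1e-9
        assert res.intervals_overlap["w"]

    def test_means_converge_to_deterministic_as_uncertainty_shrinks(
            self, dominant_perf):
        det = sm.value_scores(dominant_perf, [WS]).overall.loc["w", "HCPC"]
        gaps = []
        for se in (0.2, 0.02, 0.002):
            perf = with_uncertainty(dominant_perf, se=se)
            res = sm.run_psa(perf, [WS],
                             sm.PsaConfig(n_replications=4000, seed=4))
            gaps.append(abs(res.summary.loc[("w", "HCPC"), "mean"] - det))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 1e-3

    def test_pct_invariant_to_common_rescaling(self, dominant_perf):
        res1 = sm.run_psa(dominant_perf, [WS],
                          sm.PsaConfig(n_replications=2000, seed=5))
        scaled = dominant_perf.copy()
        for col in ("mean_hcpc", "mean_uc", "se_hcpc", "se_uc"):
            scaled[col] *= 3.0
        scaled["covariance"] *= 9.0
        res2 = sm.run_psa(scaled, [WS],
                          sm.PsaConfig(n_replications=2000, seed=5))
        assert res1.pct_hcpc_better["w"] == res2.pct_hcpc_better["w"]

    def test_weight_uncertainty_widens_intervals(self, dominant_perf):
        tight = sm.run_psa(dominant_perf, [WS],
                           sm.PsaConfig(n_replications=4000, seed=6))
        loose = sm.run_psa(dominant_perf, [WS],
                           sm.PsaConfig(n_replications=4000, seed=6,
                                        weight_se=0.05))
        def width(res):
            row = res.summary.loc[("w", "HCPC")]
            return row["upper"] - row["lower"]
        assert width(loose) > width(tight)

    def test_truncates_negative_weight_draws(self, dominant_perf):
        ws = sm.StakeholderWeights(sm.Stakeholder.CUSTOM,
                                   {"well": 0.02, "adl": 0.5, "joy": 0.48},
                                   label="w")
        res = sm.run_psa(dominant_perf, [ws],
                         sm.PsaConfig(n_replications=4000, seed=7,
                                      weight_se=0.05))
        assert res.n_weight_truncated > 0

    def test_impossible_positivity_raises(self):
        perf = with_uncertainty(perf_frame({
            "adl": (0.01, 0.01, "higher_worse")}), se=5.0)
        ws = sm.StakeholderWeights(sm.Stakeholder.CUSTOM, {"adl": 1.0},
                                   label="w")
        with pytest.raises(RuntimeError, match="non-positive"):
            sm.run_psa(perf, [ws], sm.PsaConfig(n_replications=1000, seed=8,
                                                max_resample_rounds=3))


class TestSwingSensitivity:
    def test_swing_equal_to_dce_reproduces_base_analysis(self, dominant_perf):
        dce = sm.value_scores(dominant_perf, [WS])
        swing = sm.swing_sensitivity(dominant_perf, [sm.StakeholderWeights(
            sm.Stakeholder.CUSTOM, dict(WS.weights),
            source=sm.WeightSource.SWING, label="w")])
        pd.testing.assert_frame_equal(dce.overall, swing.overall)

    def test_single_outcome_swing_flips_winner(self):
        # usual care better on autonomy; all swing mass on autonomy
        perf = perf_frame({"autonomy": (21.0, 24.0, "higher_better"),
                           "joy": (2.9, 2.4, "higher_better")})
        swing = sm.swing_sensitivity(perf, [sm.StakeholderWeights(
            sm.Stakeholder.CUSTOM, {"autonomy": 1.0},
            source=sm.WeightSource.SWING, label="w")])
        assert swing.overall.loc["w", "UC"] > swing.overall.loc["w", "HCPC"]

    def test_extended_outcome_set_matches_hand_computation(self):
        rng = np.random.default_rng(10)
        names = [f"o{i}" for i in range(11)]
        h = rng.uniform(1, 10, 11)
        u = rng.uniform(1, 10, 11)
        perf = perf_frame({n: (h[i], u[i], "higher_better")
                           for i, n in enumerate(names)})
        w = rng.uniform(0, 1, 11)
        expected = float(sum(
            w[i] * h[i] / np.hypot(h[i], u[i]) for i in range(11)))
        swing = sm.swing_sensitivity(perf, [sm.StakeholderWeights(
            sm.Stakeholder.CUSTOM, dict(zip(names, w)),
            source=sm.WeightSource.SWING, label="w")])
        assert swing.overall.loc["w", "HCPC"] == pytest.approx(expected)

    def test_missing_programme_specific_rows_rejected(self):
        perf = perf_frame({"joy": (2.9, 2.4, "higher_better")})
        with pytest.raises(KeyError, match="autonomy"):
            sm.swing_sensitivity(perf, [sm.StakeholderWeights(
                sm.Stakeholder.CUSTOM, {"joy": 0.5, "autonomy": 0.5},
                source=sm.WeightSource.SWING, label="w")])
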