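"""Longitudinal mixed-model trajectories, BIC selection, and calibration."""

import numpy as np
import pandas as pd
import pytest

from neonirs import (
    CohortConfig,
    evaluate_test_calibration,
    fit_trajectory,
    select_trajectory_form,
    simulate_cohort,
)

ZERO_SD = {"cbfi": 0.0, "so2": 0.0, "hbt": 0.0}
ZERO_OFFSET = {"cbfi": 0.0, "so2": 0.0, "hbt": 0.0}


def _cohort_df(cfg):
    ds = simulate_cohort(cfg)
    return ds.sessions.merge(ds.truth, on="session_id")


@pytest.fixture(scope="module")
def default_df():
    return _cohort_df(CohortConfig(seed=7))


class TestFitTrajectory:
    def test_mirrored_groups_give_zero_offset(self):
        # both arms are literal copies of the same subjects: the group
        # fixed effects must vanish
        cfg = CohortConfig(n_control=6, n_gmivh=1,
                           gmivh_offset=ZERO_OFFSET, seed=13)
        ds = simulate_cohort(cfg)
        df = ds.sessions.merge(ds.truth, on="session_id")
        ctrl = df[df["group"] == "control"].copy()
        mirror = ctrl.copy()
        mirror["group"] = "gmivh"
        mirror["subject_id"] = mirror["subject_id"] + "_m"
        both = pd.concat([ctrl, mirror], ignore_index=True)
        res = fit_trajectory(both, "cbfi_cm2s")
        tol = 1e-4 * both["cbfi_cm2s"].std()
        assert res.params["group_offset"] == pytest.approx(0.0, abs=tol)
        assert res.params["pma_group_interaction"] == pytest.approx(0.0, abs=tol)

    def test_noise_free_cohort_recovers_slope_exactly(self):
        cfg = CohortConfig(subject_sd=ZERO_SD, session_sd=ZERO_SD, seed=3)
        df = _cohort_df(cfg)
        res = fit_trajectory(df, "cbfi_cm2s")
        assert res.params["pma_slope"] == pytest.approx(
            cfg.control_trajectory["cbfi"][1], rel=1e-9)
        assert res.params["group_offset"] == pytest.approx(
            cfg.gmivh_offset["cbfi"], rel=1e-9)

    def test_shift_equivariance(self, default_df):
        res = fit_trajectory(default_df, "so2")
        shifted = default_df.copy()
        shifted["so2"] = shifted["so2"] + 0.123
        res2 = fit_trajectory(shifted, "so2")
        assert res2.params["intercept"] - res.params["intercept"] == \
            pytest.approx(0.123, abs=1e-5)
        tol = 1e-4 * default_df["so2"].std()
        for k in ("pma_slope", "group_offset", "pma_group_interaction"):
            assert res2.params[k] == pytest.approx(res.params[k], abs=tol)

    def test_window_restriction_applied(self, default_df):
        res = fit_trajectory(default_df, "cbfi_cm2s", window=(30.0, 36.0))
        assert res.n_obs < len(default_df)
        assert res.window == (30.0, 36.0)

    def test_p_values_in_unit_interval(self, default_df):
        res = fit_trajectory(default_df, "cbfi_cm2s")
        assert 0.0 <= res.group_p_value <= 1.0
        assert 0.0 <= res.lrt_p_value <= 1.0
        assert np.isfinite(res.bic)
        assert res.subject_var >= 0 and res.residual_var >= 0

    def test_summary_mentions_key_quantities(self, default_df):
        text = fit_trajectory(default_df, "cbfi_cm2s").summary()
        for token in ("pma_slope", "group_offset", "BIC", "Wald F"):
            assert token in text

    def test_missing_group_errors(self, default_df):
        only_ctrl = default_df[default_df["group"] == "control"]
        with pytest.raises(ValueError, match="group"):
            fit_trajectory(only_ctrl, "cbfi_cm2s")


class TestSelectTrajectoryForm:
    def test_identical_candidates_identical_bic(self, default_df):
        out = select_trajectory_form(
            default_df, "cbfi_cm2s",
            candidate_forms={"a": "value ~ pma_c", "b": "value ~ pma_c"})
        assert out["bic"].iloc[0] == pytest.approx(out["bic"].iloc[1], abs=1e-6)

    def test_ordering_invariant_to_row_shuffle(self, default_df, rng):
        out1 = select_trajectory_form(default_df, "cbfi_cm2s")
        shuffled = default_df.sample(frac=1.0, random_state=99)
        out2 = select_trajectory_form(shuffled, "cbfi_cm2s")
        assert out1["form"].tolist() == out2["form"].tolist()
        assert np.allclose(out1["bic"], out2["bic"], atol=1e-5)

    def test_flat_data_prefers_intercept_only(self):
        # no PMA trend, no group effect: intercept-only should win BIC in
        # a clear majority of replicates
        wins = 0
        n_sims = 20
        base = CohortConfig(
            control_trajectory={"cbfi": (1.3e-8, 0.0), "so2": (0.7, 0.0),
                                "hbt": (40.0, 0.0)},
            gmivh_offset=ZERO_OFFSET, seed=0)
        seeds = np.random.SeedSequence(77).generate_state(n_sims) % (2**31)
        for s in seeds:
            cfg = CohortConfig(**{**base.__dict__, "seed": int(s)})
            out = select_trajectory_form(_cohort_df(cfg), "cbfi_cm2s")
            wins += out["form"].iloc[0] == "intercept"
        assert wins > n_sims / 2

    def test_strong_interaction_prefers_interaction_form(self):
        wins = 0
        n_sims = 20
        base = CohortConfig(seed=0)
        seeds = np.random.SeedSequence(78).generate_state(n_sims) % (2**31)
        for s in seeds:
            cfg = CohortConfig(**{**base.__dict__, "seed": int(s)})
            df = _cohort_df(cfg)
            # inject a strong slope divergence for the hemorrhage arm
            giv = df["group"] == "gmivh"
            df.loc[giv, "cbfi_cm2s"] -= (
                8e-10 * (df.loc[giv, "pma_weeks"] - 27.0))
            out = select_trajectory_form(df, "cbfi_cm2s")
            wins += out["form"].iloc[0] == "pma*group"
        assert wins > n_sims / 2

    def test_needs_two_candidates(self, default_df):
        with pytest.raises(ValueError, match="two candidate"):
            select_trajectory_form(default_df, "cbfi_cm2s",
                                   candidate_forms={"only": "value ~ 1"})


class TestCalibration:
    def test_alpha_zero_never_rejects(self):
        cfg = CohortConfig(gmivh_offset=ZERO_OFFSET, seed=1)
        res = evaluate_test_calibration(cfg, n_reps=60, alpha=0.0, seed=55)
        assert res.rejection_rate == 0.0

    def test_power_exceeds_size_with_large_effect(self):
        null_cfg = CohortConfig(gmivh_offset=ZERO_OFFSET)
        # effect of -2 subject-SD units on CBFi
        eff = -2.0 * null_cfg.subject_sd["cbfi"]
        alt_cfg = CohortConfig(gmivh_offset={"cbfi": eff, "so2": 0.0,
                                             "hbt": 0.0})
        size = evaluate_test_calibration(null_cfg, n_reps=60, seed=91)
        power = evaluate_test_calibration(alt_cfg, n_reps=60, seed=91)
        assert power.rejection_rate > size.rejection_rate

    def test_small_rep_count_warns(self):
        cfg = CohortConfig(gmivh_offset=ZERO_OFFSET, seed=1)
        with pytest.warns(UserWarning, match="n_reps"):
            evaluate_test_calibration(cfg, n_reps=5, alpha=0.05, seed=2)
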