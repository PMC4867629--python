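"""Synthetic-cohort generator: determinism, noise-free collapse, statistics."""

import numpy as np
import pandas as pd
import pytest

from neonirs import (
    AcquisitionGeometry,
    CohortConfig,
    GroundTruth,
    NoiseModel,
    fit_bfi,
    fit_chromophores,
    fit_multidistance,
    simulate_cohort,
    simulate_raw_cohort,
    simulate_raw_session,
    write_cohort,
)

ZERO_SD = {"cbfi": 0.0, "so2": 0.0, "hbt": 0.0}

TRUTH = GroundTruth(hbo_um=28.0, hbr_um=12.0, bfi=1.2e-8, sao2=0.96,
                    hgb=13.5, group="control", pma=33.0)


class TestCohortGeneration:
    def test_same_seed_identical_output(self):
        a = simulate_cohort(CohortConfig(seed=42))
        b = simulate_cohort(CohortConfig(seed=42))
        pd.testing.assert_frame_equal(a.sessions, b.sessions)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortConfig(seed=1))
        b = simulate_cohort(CohortConfig(seed=2))
        assert not a.truth["cbfi_cm2s"].equals(b.truth["cbfi_cm2s"])

    def test_noise_free_sessions_lie_on_trajectory_line(self):
        cfg = CohortConfig(subject_sd=ZERO_SD, session_sd=ZERO_SD, seed=5)
        ds = simulate_cohort(cfg)
        df = ds.sessions.merge(ds.truth, on="session_id")
        ctrl = df[df["group"] == "control"]
        icpt, slope = cfg.control_trajectory["cbfi"]
        expected = icpt + slope * (ctrl["pma_weeks"] - cfg.pma_ref)
        assert np.allclose(ctrl["cbfi_cm2s"], expected, rtol=1e-12)

    def test_monte_carlo_mean_matches_generating_trajectory(self):
        cfg = CohortConfig(n_control=1000, n_gmivh=1, sessions_per_subject=1,
                           pma_range=(34.0, 35.0), seed=11)
        ds = simulate_cohort(cfg)
        df = ds.sessions.merge(ds.truth, on="session_id")
        ctrl = df[df["group"] == "control"]
        icpt, slope = cfg.control_trajectory["cbfi"]
        # generating mean at each session's realised PMA
        gen_mean = icpt + slope * (ctrl["pma_weeks"] - cfg.pma_ref)
        resid = ctrl["cbfi_cm2s"] - gen_mean
        total_sd = np.hypot(cfg.subject_sd["cbfi"], cfg.session_sd["cbfi"])
        se = total_sd / np.sqrt(len(ctrl))
        assert abs(resid.mean()) < 3 * se

    def test_unequal_session_counts(self):
        ds = simulate_cohort(CohortConfig(seed=0))
        counts = ds.sessions.groupby("subject_id").size()
        assert counts.nunique() > 1
        assert (counts >= 1).all()

    def test_zero_group_effect_gives_exchangeable_groups(self):
        from scipy.stats import mannwhitneyu

        cfg = CohortConfig(n_control=60, n_gmivh=60,
                           gmivh_offset={"cbfi": 0.0, "so2": 0.0, "hbt": 0.0},
                           seed=21)
        ds = simulate_cohort(cfg)
        df = ds.sessions.merge(ds.truth, on="session_id")
        subj = df.groupby(["subject_id", "group"])["cbfi_cm2s"].mean().reset_index()
        _, p = mannwhitneyu(subj.loc[subj["group"] == "control", "cbfi_cm2s"],
                            subj.loc[subj["group"] == "gmivh", "cbfi_cm2s"])
        assert p > 0.01

    @pytest.mark.parametrize("bad", [
        dict(n_control=0),
        dict(pma_range=(20.0, 40.0)),
        dict(subject_sd={"cbfi": -1.0, "so2": 0.0, "hbt": 0.0}),
        dict(session_sd={"cbfi": float("nan"), "so2": 0.0, "hbt": 0.0}),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            CohortConfig(**bad)

    def test_truth_invariants(self):
        ds = simulate_cohort(CohortConfig(seed=9))
        t = ds.truth
        assert (t["hbo_um"] >= 0).all() and (t["hbr_um"] >= 0).all()
        assert (t["cbfi_cm2s"] > 0).all()
        assert ds.sessions["sao2_frac"].between(0, 1).all()


class TestRawSignals:
    def test_noiseless_fdnirs_round_trip(self, semi_geom):
        frames, _ = simulate_raw_session(TRUTH, semi_geom,
                                         NoiseModel.noiseless())
        props = fit_multidistance(frames[0], semi_geom)
        true_mua = TRUTH.mua(semi_geom.wavelengths_nm)
        true_musp = TRUTH.musp(semi_geom.wavelengths_nm)
        assert np.allclose(props.mua, true_mua, rtol=1e-8)
        assert np.allclose(props.musp, true_musp, rtol=1e-8)
        state = fit_chromophores(props)
        assert state.hbo == pytest.approx(TRUTH.hbo_um, rel=1e-6)
        assert state.so2 == pytest.approx(TRUTH.so2, abs=1e-6)

    def test_noiseless_dcs_round_trip(self, semi_geom):
        _, curves = simulate_raw_session(TRUTH, semi_geom,
                                         NoiseModel.noiseless())
        mua, musp = TRUTH.optical_properties(
            semi_geom.wavelengths_nm).at_wavelength(semi_geom.dcs_wavelength_nm)
        fit = fit_bfi(curves[0], (mua, musp), geometry=semi_geom.geometry)
        assert fit.bfi == pytest.approx(TRUTH.bfi, rel=1e-3)
        assert fit.beta == pytest.approx(0.5, rel=1e-3)

    def test_noiseless_locations_identical(self, semi_geom):
        frames, curves = simulate_raw_session(TRUTH, semi_geom,
                                              NoiseModel.noiseless())
        assert len(frames) == 3
        for f in frames[1:]:
            assert np.array_equal(f.ac_amplitude, frames[0].ac_amplitude)
        for c in curves[1:]:
            assert np.array_equal(c.g2, curves[0].g2)

    def test_noisy_mua_recovery_within_5pct(self, semi_geom, rng):
        noise = NoiseModel(ac_relative_sd=0.01, phase_sd=0.0, g2_sd=0.0,
                           location_relative_sd=0.0)
        true_mua = TRUTH.mua(semi_geom.wavelengths_nm)
        errs = []
        for _ in range(50):
            frames, _ = simulate_raw_session(TRUTH, semi_geom, noise, rng=rng,
                                             n_locations=1)
            props = fit_multidistance(frames[0], semi_geom)
            errs.append(np.median(np.abs(props.mua - true_mua) / true_mua))
        assert np.median(errs) < 0.05

    def test_raw_cohort_determinism_and_schema(self, semi_geom, tmp_path):
        ds = simulate_cohort(CohortConfig(n_control=2, n_gmivh=2,
                                          sessions_per_subject=2, seed=3))
        noise = NoiseModel(seed=4)
        fd1, dcs1 = simulate_raw_cohort(ds, semi_geom, noise)
        fd2, dcs2 = simulate_raw_cohort(ds, semi_geom, noise)
        pd.testing.assert_frame_equal(fd1, fd2)
        pd.testing.assert_frame_equal(dcs1, dcs2)
        write_cohort(tmp_path, ds, (fd1, dcs1))
        for name in ("sessions.csv", "truth.csv", "fdnirs_raw.csv", "dcs_raw.csv"):
            assert (tmp_path / name).exists()
        cols = pd.read_csv(tmp_path / "fdnirs_raw.csv", nrows=1).columns.tolist()
        assert cols == ["session_id", "location", "wavelength_nm",
                        "distance_cm", "ac_amplitude", "phase_rad"]

    def test_geometry_outside_extinction_domain_errors(self):
        geom = AcquisitionGeometry(wavelengths_nm=(500.0, 600.0, 700.0))
        with pytest.raises(ValueError, match="domain"):
            simulate_raw_session(TRUTH, geom, NoiseModel.noiseless())
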