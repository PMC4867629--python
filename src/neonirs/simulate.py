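"""Synthetic FDNIRS-DCS cohorts: longitudinal physiology plus raw optical signals.

The generator emulates a NICU longitudinal study design: two arms of
extremely preterm neonates (a germinal-matrix hemorrhage arm and a control
arm) measured up to once a week over a postmenstrual-age (PMA) window, with
unequal per-subject session counts.  Each physiological parameter follows a
group-level linear trajectory in PMA plus a per-subject Gaussian random
intercept and a per-session Gaussian residual; the hemorrhage arm carries a
configurable additive deficit (default: cerebral blood-flow index reduced
by 20% of the control mean).  From the latent per-session physiology the
raw-signal layer forward-models multi-distance frequency-domain frames and
DCS autocorrelation curves at three probe locations, with configurable
measurement noise, so the whole inverse pipeline can be exercised without
any real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .extinction import ExtinctionTable, default_extinction_table
from .fdnirs import FdFrame, OpticalProperties, forward_fd
from .dcs import DcsCurve, forward_g2, DEFAULT_TAU_GRID
from .geometry import AcquisitionGeometry

__all__ = [
    "TRAJECTORY_PARAMS",
    "CohortConfig",
    "NoiseModel",
    "GroundTruth",
    "CohortDataset",
    "simulate_cohort",
    "simulate_raw_session",
    "simulate_raw_cohort",
    "write_cohort",
]

TRAJECTORY_PARAMS = ("cbfi", "so2", "hbt")

_SD_FLOORS = {"cbfi": 1e-10, "so2": 1e-3, "hbt": 1.0}
_SD_CEILS = {"so2": 0.999}


def _default_control_trajectory():
    # (value at the reference PMA, slope per week); CBFi in cm^2/s, SO2
    # fraction (flat in PMA), HbT in µM
    return {"cbfi": (1.3e-8, 5e-10), "so2": (0.70, 0.0), "hbt": (40.0, 0.0)}


def _default_gmivh_offset():
    # additive deficit for the hemorrhage arm: -20% of the control CBFi mean
    return {"cbfi": -2.6e-9, "so2": 0.0, "hbt": 0.0}


def _default_subject_sd():
    return {"cbfi": 1.5e-9, "so2": 0.03, "hbt": 3.0}


def _default_session_sd():
    return {"cbfi": 1.0e-9, "so2": 0.02, "hbt": 2.0}


@dataclass
class CohortConfig:
    """Study design and generating parameters for a synthetic cohort.

    Trajectories are parameterised as (value at ``pma_ref``, slope per
    week).  ``sessions_per_subject`` is the target mean number of weekly
    sessions per subject; actual counts vary per subject (random entry,
    discharge and attendance), matching longitudinal designs with unequal
    follow-up.
    """

    n_control: int = 13
    n_gmivh: int = 7
    sessions_per_subject: int = 6
    pma_range: tuple[float, float] = (27.0, 40.0)
    pma_ref: float = 34.0
    control_trajectory: dict = field(default_factory=_default_control_trajectory)
    gmivh_offset: dict = field(default_factory=_default_gmivh_offset)
    subject_sd: dict = field(default_factory=_default_subject_sd)
    session_sd: dict = field(default_factory=_default_session_sd)
    sao2_range: tuple[float, float] = (0.90, 1.00)
    hgb_range: tuple[float, float] = (10.0, 17.0)
    musp_ref_mean: float = 8.0
    musp_ref_sd: float = 0.5
    scatter_power_mean: float = 1.0
    scatter_power_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 1 or self.n_gmivh < 1 or self.sessions_per_subject < 1:
            raise ValueError("subject and session counts must be >= 1")
        lo, hi = self.pma_range
        if not (24.0 <= lo < hi <= 44.0):
            raise ValueError("pma_range must be an increasing interval within [24, 44] weeks")
        for name, d in (("subject_sd", self.subject_sd),
                        ("session_sd", self.session_sd)):
            for p in TRAJECTORY_PARAMS:
                v = d.get(p, 0.0)
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"{name}[{p!r}] must be finite and >= 0")
        for d in (self.control_trajectory, self.gmivh_offset):
            for v in d.values():
                if not np.all(np.isfinite(np.asarray(v, dtype=float))):
                    raise ValueError("trajectory parameters must be finite")


@dataclass
class NoiseModel:
    """Measurement-noise settings for the raw-signal layer.

    ``ac_relative_sd`` multiplies AC amplitudes by (1 + N(0, sd)),
    ``phase_sd`` adds radians to phases, ``g2_sd`` adds per-lag noise to
    autocorrelation curves, and ``location_relative_sd`` jitters the latent
    physiology between the three probe locations (exchangeable replicates).
    With every SD at zero the simulated signals equal the forward models
    exactly.
    """

    ac_relative_sd: float = 0.01
    phase_sd: float = 0.005
    g2_sd: float = 0.005
    location_relative_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("ac_relative_sd", "phase_sd", "g2_sd", "location_relative_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(ac_relative_sd=0.0, phase_sd=0.0, g2_sd=0.0,
                   location_relative_sd=0.0)


@dataclass
class GroundTruth:
    """Latent per-session physiology behind one simulated measurement."""

    hbo_um: float
    hbr_um: float
    bfi: float
    sao2: float
    hgb: float
    group: str
    pma: float
    musp_ref: float = 8.0
    scatter_power: float = 1.0
    musp_ref_wavelength_nm: float = 785.0

    def __post_init__(self):
        if self.hbo_um < 0 or self.hbr_um < 0:
            raise ValueError("hemoglobin concentrations must be non-negative")
        if not 0.0 <= self.sao2 <= 1.0:
            raise ValueError("SaO2 must be a fraction in [0, 1]")
        if self.bfi <= 0:
            raise ValueError("BFi must be positive")

    @property
    def hbt_um(self) -> float:
        return self.hbo_um + self.hbr_um

    @property
    def so2(self) -> float:
        return self.hbo_um / self.hbt_um

    @property
    def cmro2i(self) -> float:
        return self.bfi * self.hgb * (self.sao2 - self.so2)

    def musp(self, wavelengths_nm) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        return self.musp_ref * (wl / self.musp_ref_wavelength_nm) ** (-self.scatter_power)

    def mua(self, wavelengths_nm, table: ExtinctionTable | None = None,
            water_fraction: float = 0.0) -> np.ndarray:
        table = table or default_extinction_table()
        return table.mua_from_concentrations(wavelengths_nm, self.hbo_um,
                                             self.hbr_um, water_fraction)

    def optical_properties(self, wavelengths_nm,
                           table: ExtinctionTable | None = None) -> OpticalProperties:
        wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        return OpticalProperties(mua=self.mua(wl, table), musp=self.musp(wl),
                                 wavelengths_nm=wl)


@dataclass
class CohortDataset:
    """A simulated cohort: session metadata plus per-session latent truth."""

    sessions: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    def session_truth(self, session_id: str) -> GroundTruth:
        meta = self.sessions.set_index("session_id").loc[session_id]
        t = self.truth.set_index("session_id").loc[session_id]
        return GroundTruth(
            hbo_um=float(t["hbo_um"]), hbr_um=float(t["hbr_um"]),
            bfi=float(t["cbfi_cm2s"]), sao2=float(meta["sao2_frac"]),
            hgb=float(meta["hgb_g_dl"]), group=str(meta["group"]),
            pma=float(meta["pma_weeks"]), musp_ref=float(t["musp_ref"]),
            scatter_power=float(t["scatter_power"]),
        )

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)


def _trajectory_value(config, param, group, pma, subject_effect, resid):
    intercept, slope = config.control_trajectory[param]
    value = intercept + slope * (pma - config.pma_ref)
    if group == "gmivh":
        value += config.gmivh_offset.get(param, 0.0)
    value += subject_effect + resid
    lo = _SD_FLOORS.get(param, 0.0)
    hi = _SD_CEILS.get(param, np.inf)
    return float(np.clip(value, lo, hi))


def simulate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw one cohort: subjects, session schedule, and latent physiology.

    Identical configs (including ``seed``) produce byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.pma_range
    n_weeks = int(np.floor(hi - lo)) + 1

    meta_rows, truth_rows = [], []
    groups = ["control"] * config.n_control + ["gmivh"] * config.n_gmivh
    for i, group in enumerate(groups):
        sid = f"S{i:03d}"
        musp_ref = max(float(rng.normal(config.musp_ref_mean, config.musp_ref_sd)), 4.0)
        b = max(float(rng.normal(config.scatter_power_mean, config.scatter_power_sd)), 0.2)
        subj_fx = {p: float(rng.normal(0.0, config.subject_sd.get(p, 0.0)))
                   for p in TRAJECTORY_PARAMS}

        # weekly schedule: random entry, random discharge, random attendance
        entry = int(rng.integers(0, min(3, n_weeks)))
        discharge = int(rng.integers(min(entry + 3, n_weeks - 1), n_weeks))
        candidates = np.arange(entry, discharge + 1)
        p_attend = min(1.0, config.sessions_per_subject / max(len(candidates), 1))
        attend = rng.random(len(candidates)) < p_attend
        if not attend.any():
            attend[0] = True
        weeks = candidates[attend]

        for j, week in enumerate(weeks):
            pma = float(lo + week + rng.uniform(0.0, 1.0))
            if pma > hi:
                pma = hi
            sess = f"{sid}_V{j:02d}"
            resid = {p: float(rng.normal(0.0, config.session_sd.get(p, 0.0)))
                     for p in TRAJECTORY_PARAMS}
            cbfi = _trajectory_value(config, "cbfi", group, pma,
                                     subj_fx["cbfi"], resid["cbfi"])
            so2 = _trajectory_value(config, "so2", group, pma,
                                    subj_fx["so2"], resid["so2"])
            hbt = _trajectory_value(config, "hbt", group, pma,
                                    subj_fx["hbt"], resid["hbt"])
            sao2 = float(rng.uniform(*config.sao2_range))
            hgb = float(rng.uniform(*config.hgb_range))
            meta_rows.append(dict(subject_id=sid, session_id=sess, group=group,
                                  pma_weeks=pma, sao2_frac=sao2, hgb_g_dl=hgb))
            truth_rows.append(dict(
                session_id=sess, so2=so2, cbfi_cm2s=cbfi, hbt_um=hbt,
                hbo_um=so2 * hbt, hbr_um=(1.0 - so2) * hbt,
                cmro2i=cbfi * hgb * (sao2 - so2),
                musp_ref=musp_ref, scatter_power=b,
            ))
    return CohortDataset(sessions=pd.DataFrame(meta_rows),
                         truth=pd.DataFrame(truth_rows), config=config)


def _jittered(truth: GroundTruth, rel: float, rng) -> GroundTruth:
    """Location-level replicate: small multiplicative jitter on the latent state."""
    if rel == 0.0:
        return truth
    f = lambda: float(np.exp(rng.normal(0.0, rel)))
    return replace(truth, hbo_um=truth.hbo_um * f(), hbr_um=truth.hbr_um * f(),
                   bfi=truth.bfi * f())


def simulate_raw_session(truth: GroundTruth, acq: AcquisitionGeometry,
                         noise: NoiseModel, rng=None, n_locations: int = 3,
                         tau_grid: np.ndarray | None = None,
                         table: ExtinctionTable | None = None,
                         ) -> tuple[list[FdFrame], list[DcsCurve]]:
    """Forward-model raw optical signals for one session.

    Returns one frequency-domain frame and one DCS curve per probe
    location.  Noise structure follows :class:`NoiseModel`; a zero noise
    model reproduces the forward models exactly at every location.
    """
    if len(acq.distances_cm) < 3 or len(acq.wavelengths_nm) < 2:
        raise ValueError("need >= 3 distances and >= 2 wavelengths")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    table = table or default_extinction_table()
    tau = DEFAULT_TAU_GRID if tau_grid is None else tau_grid

    frames, curves = [], []
    for k in range(n_locations):
        loc = f"loc{k}"
        t = _jittered(truth, noise.location_relative_sd, rng)
        props = t.optical_properties(acq.wavelengths_nm, table)
        frame = forward_fd(props, acq, location=loc)
        ac = frame.ac_amplitude
        ph = frame.phase
        if noise.ac_relative_sd > 0:
            ac = ac * (1.0 + rng.normal(0.0, noise.ac_relative_sd, ac.shape))
            ac = np.clip(ac, 1e-300, None)
        if noise.phase_sd > 0:
            ph = ph + rng.normal(0.0, noise.phase_sd, ph.shape)
        frames.append(FdFrame(ac_amplitude=ac, phase=ph, location=loc))

        mua_dcs, musp_dcs = props.at_wavelength(acq.dcs_wavelength_nm)
        curve = forward_g2((mua_dcs, musp_dcs), t.bfi, beta=0.5,
                           distance_cm=acq.dcs_distance_cm, tau=tau,
                           wavelength_nm=acq.dcs_wavelength_nm,
                           refractive_index=acq.refractive_index,
                           geometry=acq.geometry, location=loc)
        g2 = curve.g2
        if noise.g2_sd > 0:
            g2 = g2 + rng.normal(0.0, noise.g2_sd, g2.shape)
        curves.append(DcsCurve(tau=curve.tau, g2=g2,
                               distance_cm=curve.distance_cm,
                               wavelength_nm=curve.wavelength_nm, location=loc))
    return frames, curves


def simulate_raw_cohort(dataset: CohortDataset, acq: AcquisitionGeometry,
                        noise: NoiseModel, n_locations: int = 3,
                        tau_grid: np.ndarray | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw signals for every session of a cohort, in tidy long format.

    Returns (fdnirs_raw, dcs_raw) dataframes matching the on-disk schema of
    :func:`write_cohort`.
    """
    rng = np.random.default_rng(noise.seed)
    wl = np.asarray(acq.wavelengths_nm)
    r = np.asarray(acq.distances_cm)
    fd_rows, dcs_rows = [], []
    for sess in dataset.sessions["session_id"]:
        truth = dataset.session_truth(sess)
        frames, curves = simulate_raw_session(truth, acq, noise, rng=rng,
                                              n_locations=n_locations,
                                              tau_grid=tau_grid)
        for frame in frames:
            for i, w in enumerate(wl):
                for j, d in enumerate(r):
                    fd_rows.append((sess, frame.location, w, d,
                                    frame.ac_amplitude[i, j], frame.phase[i, j]))
        for curve in curves:
            for t, g in zip(curve.tau, curve.g2):
                dcs_rows.append((sess, curve.location, t, g))
    fdnirs_raw = pd.DataFrame(fd_rows, columns=[
        "session_id", "location", "wavelength_nm", "distance_cm",
        "ac_amplitude", "phase_rad"])
    dcs_raw = pd.DataFrame(dcs_rows, columns=["session_id", "location",
                                              "tau_s", "g2"])
    return fdnirs_raw, dcs_raw


def write_cohort(outdir, dataset: CohortDataset,
                 raw: tuple[pd.DataFrame, pd.DataFrame] | None = None) -> None:
    """Write sessions.csv, truth.csv and optionally the raw-signal CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.sessions.to_csv(outdir / "sessions.csv", index=False)
    dataset.truth.to_csv(outdir / "truth.csv", index=False)
    if raw is not None:
        fdnirs_raw, dcs_raw = raw
        fdnirs_raw.to_csv(outdir / "fdnirs_raw.csv", index=False)
        dcs_raw.to_csv(outdir / "dcs_raw.csv", index=False)
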