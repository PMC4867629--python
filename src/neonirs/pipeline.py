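"""Session-level pipeline: quality screening, CMRO2i, and aggregation.

Each bedside session yields, per probe location, a hemoglobin state (from
the frequency-domain inversion) and a flow fit (from DCS).  Measurements
failing quality assessment are excluded; the survivors are combined into a
single session record: repeats are averaged within location, the cerebral
oxygen-metabolism index

    CMRO2i = CBFi * HGB * (SaO2 - SO2)

is computed per location with the session's arterial saturation and blood
hemoglobin, and SO2, CBFi and CMRO2i are then averaged across passing
locations to represent the frontal region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fdnirs import MultiDistanceModel, FdFrame, fit_chromophores
from .dcs import DcsCurve, G2Model, FlatCurveError
from .geometry import AcquisitionGeometry

__all__ = ["QaThresholds", "QaReport", "SessionRecord", "assess_quality",
           "compute_cmro2i", "aggregate_session", "run_pipeline"]


@dataclass(frozen=True)
class QaThresholds:
    """Data-quality acceptance thresholds for one measurement.

    Defaults are deliberately conservative and fully configurable: the
    slope regressions of a clean multi-distance frame are essentially
    perfect lines, so R^2 >= 0.98 rejects frames with coupling artifacts;
    the spectral residual bounds chromophore-model mismatch; the beta
    window and convergence flag reject unusable correlation curves.
    """

    min_r2_ac: float = 0.98
    min_r2_phase: float = 0.98
    max_spectral_residual: float = 0.10
    beta_range: tuple[float, float] = (0.1, 0.6)
    min_g2_intercept: float = 1.05
    require_convergence: bool = True

    def __post_init__(self):
        for name in ("min_r2_ac", "min_r2_phase", "max_spectral_residual"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        lo, hi = self.beta_range
        if not lo < hi:
            raise ValueError("beta_range must satisfy low < high")


@dataclass
class QaReport:
    """Per-criterion pass/fail for one (session, location) measurement."""

    checks: dict
    passed: bool
    reasons: list = field(default_factory=list)


def assess_quality(r2_ac, r2_phase, spectral_residual, flow_fit,
                   thresholds: QaThresholds = QaThresholds(),
                   g2_intercept: float | None = None) -> QaReport:
    """Screen one measurement against the quality thresholds.

    ``r2_ac``/``r2_phase`` may be scalars or per-wavelength arrays, in
    which case the median across wavelengths is screened.  ``flow_fit``
    needs ``beta`` and ``converged`` attributes (or may be None, which
    fails the flow criteria).  Missing diagnostics fail the corresponding
    criterion with a logged reason rather than raising.
    """
    checks = {}

    def _median(x):
        if x is None:
            return math.nan
        return float(np.median(np.atleast_1d(np.asarray(x, dtype=float))))

    m_ac, m_ph = _median(r2_ac), _median(r2_phase)
    checks["ac_linearity"] = bool(m_ac >= thresholds.min_r2_ac)
    checks["phase_linearity"] = bool(m_ph >= thresholds.min_r2_phase)
    sr = math.nan if spectral_residual is None else float(spectral_residual)
    checks["spectral_residual"] = bool(sr <= thresholds.max_spectral_residual)

    lo, hi = thresholds.beta_range
    if flow_fit is None:
        checks["beta_range"] = False
        checks["convergence"] = False
    else:
        checks["beta_range"] = bool(lo <= flow_fit.beta <= hi)
        checks["convergence"] = (bool(flow_fit.converged)
                                 if thresholds.require_convergence else True)
    if g2_intercept is not None:
        checks["g2_intercept"] = bool(g2_intercept >= thresholds.min_g2_intercept)

    reasons = [name for name, ok in checks.items() if not ok]
    return QaReport(checks=checks, passed=not reasons, reasons=reasons)


def compute_cmro2i(cbfi: float, hgb: float, sao2: float, so2: float) -> float:
    """Cerebral oxygen-metabolism index, CBFi * HGB * (SaO2 - SO2).

    Exactly multilinear in each argument.  A negative value (SO2 above
    SaO2) is returned as-is — downstream QA flags it but does not clamp.
    """
    vals = (cbfi, hgb, sao2, so2)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite input to CMRO2i: {vals}")
    if cbfi < 0:
        raise ValueError("CBFi must be non-negative")
    if not (0.0 <= sao2 <= 1.0 and 0.0 <= so2 <= 1.0):
        raise ValueError("saturations must be fractions in [0, 1]")
    if hgb <= 0:
        raise ValueError("blood hemoglobin must be positive")
    return cbfi * hgb * (sao2 - so2)


@dataclass
class SessionRecord:
    """One session's aggregated outputs with its clinical metadata."""

    subject_id: str
    session_id: str
    group: str
    pma: float
    sao2: float
    hgb: float
    so2: float
    cbfi: float
    cmro2i: float
    n_locations_passed: int
    location_so2: dict = field(default_factory=dict)
    location_cbfi: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def aggregate_session(location_results, metadata) -> SessionRecord | None:
    """Combine QA-passing location measurements into one session record.

    ``location_results`` is an iterable of dicts with keys ``location``,
    ``so2``, ``cbfi`` and ``passed`` (repeats at the same location allowed;
    they are averaged first).  ``metadata`` needs subject_id, session_id,
    group, pma_weeks, sao2_frac, hgb_g_dl.  Returns None when no location
    passes (session excluded downstream).
    """
    rows = pd.DataFrame(list(location_results))
    if rows.empty or "passed" not in rows:
        return None
    passing = rows[rows["passed"].astype(bool)]
    if passing.empty:
        return None
    # within-location repeats first, then across locations
    per_loc = passing.groupby("location")[["so2", "cbfi"]].mean()

    sao2 = float(metadata["sao2_frac"])
    hgb = float(metadata["hgb_g_dl"])
    warnings = []
    cmro2 = {}
    for loc, row in per_loc.iterrows():
        cmro2[loc] = compute_cmro2i(float(row["cbfi"]), hgb, sao2, float(row["so2"]))
        if row["so2"] > sao2:
            warnings.append(f"{loc}: SO2 exceeds SaO2; negative CMRO2i retained")

    return SessionRecord(
        subject_id=str(metadata["subject_id"]),
        session_id=str(metadata["session_id"]),
        group=str(metadata["group"]),
        pma=float(metadata["pma_weeks"]),
        sao2=sao2, hgb=hgb,
        so2=float(per_loc["so2"].mean()),
        cbfi=float(per_loc["cbfi"].mean()),
        cmro2i=float(np.mean(list(cmro2.values()))),
        n_locations_passed=int(per_loc.shape[0]),
        location_so2=per_loc["so2"].to_dict(),
        location_cbfi=per_loc["cbfi"].to_dict(),
        warnings=warnings,
    )


def _fit_location_optics(sub: pd.DataFrame, geom: AcquisitionGeometry):
    """Rebuild an FdFrame from tidy rows and invert it."""
    wl = np.sort(sub["wavelength_nm"].unique())
    r = np.sort(sub["distance_cm"].unique())
    piv_ac = sub.pivot_table(index="wavelength_nm", columns="distance_cm",
                             values="ac_amplitude").loc[wl, r].to_numpy()
    piv_ph = sub.pivot_table(index="wavelength_nm", columns="distance_cm",
                             values="phase_rad").loc[wl, r].to_numpy()
    geom_here = AcquisitionGeometry(
        distances_cm=tuple(r), wavelengths_nm=tuple(wl),
        modulation_frequency_hz=geom.modulation_frequency_hz,
        refractive_index=geom.refractive_index, geometry=geom.geometry,
        dcs_wavelength_nm=geom.dcs_wavelength_nm,
        dcs_distance_cm=geom.dcs_distance_cm)
    frame = FdFrame(ac_amplitude=piv_ac, phase=piv_ph)
    return MultiDistanceModel(frame, geom_here).fit()


def run_pipeline(indir, outdir, geom: AcquisitionGeometry | None = None,
                 thresholds: QaThresholds = QaThresholds(),
                 water_fraction: float = 0.0) -> pd.DataFrame:
    """Run raw CSVs through inversion, flow fitting, QA and aggregation.

    Reads ``fdnirs_raw.csv``, ``dcs_raw.csv`` and ``sessions.csv`` from
    ``indir``; writes ``optical_properties.csv``, ``hemodynamics.csv``,
    ``flow_fits.csv``, ``session_results.csv`` and ``qa_log.txt`` to
    ``outdir``; returns the session-results table.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = geom or AcquisitionGeometry()
    fdnirs_raw = pd.read_csv(indir / "fdnirs_raw.csv")
    dcs_raw = pd.read_csv(indir / "dcs_raw.csv")
    sessions = pd.read_csv(indir / "sessions.csv")

    optics_rows, hemo_rows, flow_rows = [], [], []
    qa_log = []
    per_session_locs: dict[str, list] = {}

    for (sess, loc), sub in fdnirs_raw.groupby(["session_id", "location"]):
        entry = dict(session_id=sess, location=loc)
        try:
            props = _fit_location_optics(sub, geom)
        except Exception as exc:  # degenerate frame: log and skip
            qa_log.append(f"{sess}\t{loc}\tinversion_failed\t{exc}")
            per_session_locs.setdefault(sess, []).append(
                dict(location=loc, so2=np.nan, cbfi=np.nan, passed=False))
            continue
        hemo = fit_chromophores(props, water_fraction=water_fraction)
        for i, w in enumerate(props.wavelengths_nm):
            optics_rows.append(dict(session_id=sess, location=loc,
                                    wavelength_nm=w, mua_percm=props.mua[i],
                                    musp_percm=props.musp[i],
                                    r2_ac=props.r2_ac[i],
                                    r2_phase=props.r2_phase[i]))
        hemo_rows.append(dict(session_id=sess, location=loc, hbo_um=hemo.hbo,
                              hbr_um=hemo.hbr, hbt_um=hemo.hbt, so2=hemo.so2,
                              spectral_residual=hemo.spectral_residual))

        curve_rows = dcs_raw[(dcs_raw["session_id"] == sess)
                             & (dcs_raw["location"] == loc)]
        flow = None
        g2_intercept = None
        if not curve_rows.empty:
            curve = DcsCurve(tau=curve_rows["tau_s"].to_numpy(),
                             g2=curve_rows["g2"].to_numpy(),
                             distance_cm=geom.dcs_distance_cm,
                             wavelength_nm=geom.dcs_wavelength_nm, location=loc)
            g2_intercept = curve.intercept
            try:
                flow = G2Model(curve, props, geom.refractive_index,
                               geom.geometry).fit()
            except FlatCurveError as exc:
                qa_log.append(f"{sess}\t{loc}\tflat_g2\t{exc}")
        if flow is not None:
            flow_rows.append(dict(session_id=sess, location=loc,
                                  bfi_cm2s=flow.bfi, beta=flow.beta,
                                  residual=flow.residual,
                                  converged=flow.converged))

        report = assess_quality(props.r2_ac, props.r2_phase,
                                hemo.spectral_residual, flow, thresholds,
                                g2_intercept=g2_intercept)
        if not report.passed:
            qa_log.append(f"{sess}\t{loc}\tqa_fail\t{','.join(report.reasons)}")
        per_session_locs.setdefault(sess, []).append(dict(
            location=loc, so2=hemo.so2,
            cbfi=flow.bfi if flow is not None else np.nan,
            passed=report.passed))

    records = []
    for _, meta in sessions.iterrows():
        locs = per_session_locs.get(meta["session_id"], [])
        rec = aggregate_session(locs, meta)
        if rec is None:
            qa_log.append(f"{meta['session_id']}\t-\tsession_excluded\t"
                          "no location passed QA")
            continue
        records.append(dict(subject_id=rec.subject_id, session_id=rec.session_id,
                            group=rec.group, pma_weeks=rec.pma, so2=rec.so2,
                            cbfi_cm2s=rec.cbfi, cmro2i=rec.cmro2i,
                            n_locations_passed=rec.n_locations_passed))

    pd.DataFrame(optics_rows).to_csv(outdir / "optical_properties.csv", index=False)
    pd.DataFrame(hemo_rows).to_csv(outdir / "hemodynamics.csv", index=False)
    pd.DataFrame(flow_rows).to_csv(outdir / "flow_fits.csv", index=False)
    results = pd.DataFrame(records)
    results.to_csv(outdir / "session_results.csv", index=False)
    (outdir / "qa_log.txt").write_text("\n".join(qa_log) + ("\n" if qa_log else ""))
    return results
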