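"""Diffuse correlation spectroscopy: correlation-diffusion forward model and
nonlinear fitting of measured g2(tau) curves for a blood-flow index.

The normalized field autocorrelation g1(tau) of coherent light multiply
scattered by moving red blood cells obeys the correlation-diffusion
equation; for Brownian scatterer dynamics (mean-square displacement linear
in lag) the decay wavenumber is

    K(tau)^2 = 3 mu_a mu_s' + 6 mu_s'^2 k0^2 * BFi * tau,   k0 = 2 pi n / lambda

and the measured intensity autocorrelation follows the Siegert relation
g2(tau) = 1 + beta |g1(tau)|^2, with beta set by the detection optics.
The blood-flow index BFi (cm^2/s) is the effective Brownian diffusion
coefficient of the moving scatterers and serves as the CBFi measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .fdnirs import OpticalProperties, boundary_offsets
from .geometry import AcquisitionGeometry

__all__ = ["DcsCurve", "FlowFit", "G2Model", "forward_g2", "fit_bfi",
           "FlatCurveError", "DEFAULT_TAU_GRID"]

# log-spaced lag grid mirroring a multi-tau hardware correlator
DEFAULT_TAU_GRID = np.geomspace(1e-7, 1e-2, 64)

BFI_BOUNDS = (1e-10, 1e-6)
BETA_MAX = 0.6


class FlatCurveError(ValueError):
    """The autocorrelation shows no usable decay."""


@dataclass
class DcsCurve:
    """A measured (or simulated) intensity autocorrelation curve."""

    tau: np.ndarray
    g2: np.ndarray
    distance_cm: float = 2.0
    wavelength_nm: float = 785.0
    location: str = "loc0"

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.ndim != 1 or self.tau.shape != self.g2.shape:
            raise ValueError("tau and g2 must be matching 1-D arrays")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau grid must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g2)):
            raise ValueError("g2 must be finite")

    @property
    def intercept(self) -> float:
        """Empirical early-lag g2 intercept (mean of the three earliest lags)."""
        return float(np.mean(self.g2[:3]))


@dataclass
class FlowFit:
    """Result of fitting one g2 curve: blood-flow index and coherence factor."""

    bfi: float
    beta: float
    residual: float
    converged: bool

    def __post_init__(self):
        if self.converged and self.bfi <= 0:
            raise ValueError("fitted BFi must be positive")


def _decay_wavenumber(mua, musp, k0, bfi, tau):
    return np.sqrt(3.0 * mua * musp + 6.0 * musp**2 * k0**2 * bfi * tau)


def g1_model(tau, mua, musp, bfi, distance_cm, wavelength_nm,
             refractive_index=1.4, geometry="semi_infinite"):
    """Normalized field autocorrelation g1(tau); g1(0) = 1 by construction."""
    k0 = 2.0 * np.pi * refractive_index / (wavelength_nm * 1e-7)
    tau = np.asarray(tau, dtype=float)
    K = _decay_wavenumber(mua, musp, k0, bfi, tau)
    K0 = np.sqrt(3.0 * mua * musp)
    r = distance_cm
    if geometry == "infinite":
        return np.exp(-(K - K0) * r)
    z0, zb = boundary_offsets(mua, musp, refractive_index)
    z0, zb = float(z0), float(zb)
    r1 = np.hypot(r, z0)
    r2 = np.hypot(r, z0 + 2.0 * zb)

    def fluence(q):
        return np.exp(-q * r1) / r1 - np.exp(-q * r2) / r2

    return fluence(K) / fluence(K0)


def forward_g2(props: OpticalProperties | tuple[float, float], bfi: float,
               beta: float, distance_cm: float = 2.0,
               tau: np.ndarray | None = None, wavelength_nm: float = 785.0,
               refractive_index: float = 1.4, geometry: str = "semi_infinite",
               location: str = "loc0") -> DcsCurve:
    """Forward-model a DCS intensity autocorrelation curve.

    ``props`` is either an :class:`OpticalProperties` with a wavelength axis
    (interpolated at the DCS wavelength) or a plain (mua, musp) pair in 1/cm.
    """
    if bfi <= 0:
        raise ValueError("BFi must be positive")
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    if isinstance(props, OpticalProperties):
        mua, musp = props.at_wavelength(wavelength_nm)
    else:
        mua, musp = float(props[0]), float(props[1])
    if not 0.0 < mua < musp:
        raise ValueError("need 0 < mua < musp at the DCS wavelength")
    if tau is None:
        tau = DEFAULT_TAU_GRID
    g1 = g1_model(tau, mua, musp, bfi, distance_cm, wavelength_nm,
                  refractive_index, geometry)
    return DcsCurve(tau=np.asarray(tau, float), g2=1.0 + beta * np.abs(g1) ** 2,
                    distance_cm=distance_cm, wavelength_nm=wavelength_nm,
                    location=location)


class G2Model:
    """Nonlinear least-squares fit of a g2 curve for (BFi, beta).

    The optimisation runs in (log10 BFi, beta) with box bounds
    BFi in [1e-10, 1e-6] cm^2/s and beta in (0, 0.6].  beta is initialised
    from the empirical early-lag intercept minus one; BFi from a coarse
    log-grid search, which makes the subsequent trust-region refinement
    robust over the full physiological decade.
    """

    def __init__(self, curve: DcsCurve,
                 props: OpticalProperties | tuple[float, float],
                 refractive_index: float = 1.4,
                 geometry: str = "semi_infinite"):
        if curve.tau.size < 20:
            raise ValueError("need at least 20 lags spanning the decay")
        if isinstance(props, OpticalProperties):
            mua, musp = props.at_wavelength(curve.wavelength_nm)
        else:
            mua, musp = float(props[0]), float(props[1])
        self.curve = curve
        self.mua = mua
        self.musp = musp
        self.refractive_index = refractive_index
        self.geometry = geometry

    def _predict(self, bfi, beta):
        g1 = g1_model(self.curve.tau, self.mua, self.musp, bfi,
                      self.curve.distance_cm, self.curve.wavelength_nm,
                      self.refractive_index, self.geometry)
        return 1.0 + beta * g1**2

    def fit(self) -> FlowFit:
        g2 = self.curve.g2
        decay = self.curve.intercept - float(np.mean(g2[-3:]))
        if decay < 1e-4:
            raise FlatCurveError("g2 curve shows no decay; cannot fit a flow index")

        beta0 = float(np.clip(self.curve.intercept - 1.0, 0.05, BETA_MAX))
        grid = np.geomspace(*BFI_BOUNDS, 33)
        sse = [np.sum((self._predict(b, beta0) - g2) ** 2) for b in grid]
        bfi0 = float(grid[int(np.argmin(sse))])

        def residuals(x):
            return self._predict(10.0 ** x[0], x[1]) - g2

        lo = [np.log10(BFI_BOUNDS[0]), 1e-4]
        hi = [np.log10(BFI_BOUNDS[1]), BETA_MAX]
        sol = optimize.least_squares(
            residuals, x0=[np.log10(bfi0), beta0], bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        bfi = float(10.0 ** sol.x[0])
        beta = float(sol.x[1])
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        return FlowFit(bfi=bfi, beta=beta, residual=rms,
                       converged=bool(sol.success))


def fit_bfi(curve: DcsCurve, props, refractive_index: float = 1.4,
            geometry: str = "semi_infinite") -> FlowFit:
    """Fit one autocorrelation curve for (BFi, beta)."""
    return G2Model(curve, props, refractive_index, geometry).fit()
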