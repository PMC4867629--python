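"""Acquisition geometry for multi-distance frequency-domain NIRS and DCS."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionGeometry", "SPEED_OF_LIGHT_CM_S"]

SPEED_OF_LIGHT_CM_S = 2.99792458e10

DEFAULT_DISTANCES_CM = (1.0, 1.5, 2.0, 2.5)
DEFAULT_WAVELENGTHS_NM = (660.0, 690.0, 705.0, 730.0, 760.0, 785.0, 808.0, 830.0)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Source-detector layout and modulation settings of the instrument.

    The defaults mirror a frequency-domain oximeter with eight laser
    wavelengths spanning 660-830 nm and four source-detector separations
    spanning 1-2.5 cm, modulated at 110 MHz, probing tissue of refractive
    index 1.4.  ``geometry`` selects the diffusion-theory boundary model:
    ``"infinite"`` (exact slope linearity, used for exact round trips) or
    ``"semi_infinite"`` (extrapolated-boundary image source, the realistic
    default for analysis of reflectance data).
    """

    distances_cm: tuple[float, ...] = DEFAULT_DISTANCES_CM
    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    modulation_frequency_hz: float = 110e6
    refractive_index: float = 1.4
    geometry: str = "semi_infinite"
    dcs_wavelength_nm: float = 785.0
    dcs_distance_cm: float = 2.0

    def __post_init__(self):
        r = np.asarray(self.distances_cm, dtype=float)
        if r.ndim != 1 or r.size < 2:
            raise ValueError("need at least two source-detector distances")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("distances must be positive and strictly increasing")
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.size < 1 or np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")
        if self.modulation_frequency_hz <= 0:
            raise ValueError("modulation frequency must be positive")
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if self.geometry not in ("infinite", "semi_infinite"):
            raise ValueError("geometry must be 'infinite' or 'semi_infinite'")
        object.__setattr__(self, "distances_cm", tuple(float(x) for x in r))
        object.__setattr__(self, "wavelengths_nm", tuple(float(x) for x in wl))

    @property
    def omega(self) -> float:
        """Angular modulation frequency (rad/s)."""
        return 2.0 * np.pi * self.modulation_frequency_hz

    @property
    def speed_in_tissue(self) -> float:
        """Speed of light in tissue (cm/s)."""
        return SPEED_OF_LIGHT_CM_S / self.refractive_index

    @property
    def distance_exponent(self) -> int:
        """Power p of r in the linearised slope variable ln(r^p * AC)."""
        return 1 if self.geometry == "infinite" else 2
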