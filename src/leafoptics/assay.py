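"""Pre-model laboratory computations.

Two steps that precede any radiative-transfer work: correcting raw
integrating-sphere measurements for the reference panel and the black
background, and converting a chlorophyll-corrected anthocyanin absorbance
reading into an area-based concentration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .absorption import SpectralGrid
from .plate import SpectraPair

__all__ = [
    "RawSpectralMeasurement",
    "AnthocyaninAssay",
    "correct_measured_spectra",
    "anthocyanin_content",
]

logger = logging.getLogger(__name__)

# two disks from a 0.97 cm diameter cork borer
DEFAULT_DISK_AREA_CM2 = 2.0 * math.pi * (0.97 / 2.0) ** 2


@dataclass
class RawSpectralMeasurement:
    """Raw integrating-sphere spectra: sample, reference panel and black background.

    Sensor artifacts slightly above 1 are tolerated on input (and logged);
    a black-background reflectance at or above 1 is unphysical and rejected
    because the correction divides by 1 − R_black.
    """

    grid: SpectralGrid
    r_sensor: np.ndarray
    t_sensor: np.ndarray
    r_reference: np.ndarray
    r_black: np.ndarray

    def __post_init__(self) -> None:
        shape = self.grid.wavelengths.shape
        for name in ("r_sensor", "t_sensor", "r_reference", "r_black"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must match the grid shape")
            if np.any(arr < 0) or np.any(arr > 1.05):
                raise ValueError(f"{name} has values outside [0, 1.05]")
            if np.any(arr > 1.0):
                logger.warning("%s exceeds 1 at %d wavelengths (sensor artifact)",
                               name, int(np.sum(arr > 1.0)))
            setattr(self, name, arr)
        if np.any(self.r_black >= 1.0):
            raise ValueError("black-background reflectance must be < 1 everywhere")


def correct_measured_spectra(raw: RawSpectralMeasurement) -> SpectraPair:
    """Reference-panel and black-background correction of raw DHR/DHT.

    T = T_sen · R_refer / (1 − R_black);
    R = R_sen − R_black · R_refer / (1 − R_black).

    Outputs are clipped into the physical range (each to [0, 1], and the
    pair rescaled where R + T marginally exceeds 1); every clip event is
    logged with its wavelength count.
    """
    denom = 1.0 - raw.r_black
    t = raw.t_sensor * raw.r_reference / denom
    r = raw.r_sensor - raw.r_black * raw.r_reference / denom

    n_clip = int(np.sum((r < 0) | (r > 1) | (t < 0) | (t > 1)))
    r = np.clip(r, 0.0, 1.0)
    t = np.clip(t, 0.0, 1.0)
    s = r + t
    over = s > 1.0
    if np.any(over):
        r = np.where(over, r / s, r)
        t = np.where(over, t / s, t)
        n_clip += int(np.sum(over))
    if n_clip:
        logger.warning("spectra correction clipped values at %d wavelength points", n_clip)
    return SpectraPair(grid=raw.grid, reflectance=r, transmittance=t)


@dataclass(frozen=True)
class AnthocyaninAssay:
    """Absorbance readings and geometry of one anthocyanin extraction.

    ``molar_absorbance`` is interpreted as a molar absorptivity in
    L·mol⁻¹·cm⁻¹ (default 30000) and ``molar_mass`` as the molar mass of
    the reference anthocyanin, cyanidin-3-glucoside (449.2 g/mol) unless
    configured otherwise.
    """

    a530: float
    a657: float
    extract_volume_ml: float
    disk_area_cm2: float = DEFAULT_DISK_AREA_CM2
    molar_absorbance: float = 30000.0
    path_length_cm: float = 1.0
    molar_mass: float = 449.2

    def __post_init__(self) -> None:
        if self.a530 < 0 or self.a657 < 0:
            raise ValueError("absorbances must be >= 0")
        if self.extract_volume_ml <= 0:
            raise ValueError("extract volume must be > 0")
        if self.disk_area_cm2 <= 0:
            raise ValueError("disk area must be > 0")
        if self.molar_absorbance <= 0 or self.path_length_cm <= 0 or self.molar_mass <= 0:
            raise ValueError("molar absorbance, path length and molar mass must be > 0")


def anthocyanin_content(assay: AnthocyaninAssay) -> float:
    """Anthocyanin concentration in µg/cm² from corrected absorbance.

    The chlorophyll overlap at 530 nm is removed with AA = A530 − 0.25·A657;
    Beer–Lambert gives the molarity, which the extract volume, molar mass
    and sampled leaf-disk area convert to mass per leaf area. A negative AA
    is floored at zero with a warning.
    """
    aa = assay.a530 - 0.25 * assay.a657
    if aa < 0:
        logger.warning("corrected absorbance AA=%.4f < 0; floored at 0", aa)
        aa = 0.0
    molarity = aa / (assay.molar_absorbance * assay.path_length_cm)  # mol/L
    grams = molarity * (assay.extract_volume_ml / 1000.0) * assay.molar_mass
    return grams * 1e6 / assay.disk_area_cm2
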