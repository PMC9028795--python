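"""In vivo pigment specific absorption coefficients from pseudo-Voigt peaks.

Each pigment's specific absorption coefficient ``K_i(λ)`` (cm²/µg) is a sum
of modified Gauss–Lorentz (pseudo-Voigt) peaks sharing position, height and
full width at half maximum between the Gaussian and Lorentzian components:

    K_ij(λ) = v·h·exp(−4·ln2·((p−λ)/w)²) + (1−v)·h / (1 + 4·((p−λ)/w)²)

where ``v`` is the Gauss ratio, ``h`` the peak height, ``w`` the FWHM and
``p`` the in vivo peak position, i.e. the organic-solution position shifted
by the spectral displacement Δλ (the polarity effect of the leaf interior).

The total per-layer leaf absorption combines the four pigment coefficients
with their area concentrations (µg/cm²), the leaf structure index N and a
baseline absorption K0 of non-pigment photosensitive material:

    k(λ) = (K_Chla·C_Chla + K_Chlb·C_Chlb + K_Cars·C_Cars + K_Ants·C_Ants)/N + K0(λ)
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

FOUR_LN2 = 4.0 * np.log(2.0)

__all__ = [
    "Pigment",
    "SpectralGrid",
    "PeakParameter",
    "PigmentCoefficientSet",
    "PigmentConcentrations",
    "glf_peak",
    "pigment_coefficient",
    "total_absorption",
    "default_parameters",
    "measure_peak",
    "measure_fwhm",
]


class Pigment(str, enum.Enum):
    """The four retrievable leaf pigment pools."""

    CHLA = "Chla"
    CHLB = "Chlb"
    CARS = "Cars"
    ANTS = "Ants"


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength grid in nm.

    The default grid spans 400–800 nm inclusive at 1 nm (401 points), the
    visible/red-edge window where the four pigments absorb.
    """

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("invalid grid: need a non-empty 1-D wavelength array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("invalid grid: wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls) -> "SpectralGrid":
        return cls(np.arange(400.0, 801.0, 1.0))

    @classmethod
    def from_spec(cls, spec: str) -> "SpectralGrid":
        """Build a grid from a ``start:stop:step`` string, stop inclusive."""
        start, stop, step = (float(x) for x in spec.split(":"))
        return cls(np.arange(start, stop + 0.5 * step, step))

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def __hash__(self) -> int:
        return hash((self.wavelengths.size, float(self.wavelengths[0]), float(self.wavelengths[-1])))


@dataclass(frozen=True)
class PeakParameter:
    """One pseudo-Voigt absorption peak of pigment ``pigment``, index ``j``.

    ``solution_position`` is the peak wavelength measured in organic solvent;
    ``displacement`` shifts it to the in vivo leaf environment. Where a
    calibrated in vivo position is known directly it may be pinned with
    ``invivo_position``, which then takes precedence over the sum (the two
    routes disagree by a few nm for some published chlorophyll b peaks).
    ``raf`` is the reported range-of-absorption-feature interval, carried as
    metadata only.
    """

    pigment: Pigment
    peak_index: int
    gauss_ratio: float
    height: float
    fwhm: float
    solution_position: float
    displacement: float
    invivo_position: float | None = None
    raf: str | None = None

    def __post_init__(self) -> None:
        if self.peak_index < 1:
            raise ValueError("peak_index must be >= 1")
        if not 0.0 <= self.gauss_ratio <= 1.0:
            raise ValueError(f"gauss_ratio must lie in [0, 1], got {self.gauss_ratio}")
        if self.height <= 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")

    @property
    def position(self) -> float:
        """Effective in vivo peak position (nm)."""
        if self.invivo_position is not None:
            return self.invivo_position
        return self.solution_position + self.displacement

    def to_dict(self) -> dict:
        d = {
            "pigment": self.pigment.value,
            "j": self.peak_index,
            "v": self.gauss_ratio,
            "h": self.height,
            "w": self.fwhm,
            "A_p": self.solution_position,
            "delta": self.displacement,
        }
        if self.invivo_position is not None:
            d["p_invivo"] = self.invivo_position
        if self.raf is not None:
            d["raf"] = self.raf
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PeakParameter":
        try:
            pigment = Pigment(d["pigment"])
        except ValueError as exc:
            raise ValueError(f"unknown pigment name {d.get('pigment')!r}") from exc
        return cls(
            pigment=pigment,
            peak_index=int(d["j"]),
            gauss_ratio=float(d["v"]),
            height=float(d["h"]),
            fwhm=float(d["w"]),
            solution_position=float(d["A_p"]),
            displacement=float(d["delta"]),
            invivo_position=float(d["p_invivo"]) if "p_invivo" in d else None,
            raf=d.get("raf"),
        )


@dataclass(frozen=True)
class PigmentConcentrations:
    """Area-based pigment concentrations, µg/cm²."""

    c_chla: float = 0.0
    c_chlb: float = 0.0
    c_cars: float = 0.0
    c_ants: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_chla", "c_chlb", "c_cars", "c_ants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.c_chla, self.c_chlb, self.c_cars, self.c_ants])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "PigmentConcentrations":
        return cls(*(float(x) for x in a))


def glf_peak(peak: PeakParameter, grid: SpectralGrid) -> np.ndarray:
    """Evaluate one pseudo-Voigt peak on the grid (cm²/µg).

    The maximum equals ``peak.height`` at the in vivo position and both
    mixture components fall to half maximum at ``± fwhm/2``.
    """
    x = (peak.position - grid.wavelengths) / peak.fwhm
    gauss = np.exp(-FOUR_LN2 * x * x)
    lorentz = 1.0 / (1.0 + 4.0 * x * x)
    return peak.height * (peak.gauss_ratio * gauss + (1.0 - peak.gauss_ratio) * lorentz)


def pigment_coefficient(peaks: Sequence[PeakParameter], grid: SpectralGrid) -> np.ndarray:
    """Sum the peaks of a single pigment into its coefficient spectrum K_i(λ)."""
    if not peaks:
        raise ValueError("need at least one peak")
    pigments = {p.pigment for p in peaks}
    if len(pigments) > 1:
        raise ValueError(f"peaks belong to multiple pigments: {sorted(p.value for p in pigments)}")
    out = np.zeros(len(grid))
    for p in peaks:
        out += glf_peak(p, grid)
    return out


@dataclass
class PigmentCoefficientSet:
    """The four specific absorption coefficient spectra plus baseline K0."""

    peaks: list[PeakParameter]
    grid: SpectralGrid = field(default_factory=SpectralGrid.default)
    baseline: np.ndarray | None = None  # K0(λ); None means zero
    name: str | None = None

    def __post_init__(self) -> None:
        present = {p.pigment for p in self.peaks}
        missing = [p.value for p in Pigment if p not in present]
        if missing:
            raise ValueError(f"every pigment needs at least one peak; missing: {missing}")
        seen = set()
        for p in self.peaks:
            key = (p.pigment, p.peak_index)
            if key in seen:
                raise ValueError(f"duplicate peak ({p.pigment.value}, j={p.peak_index})")
            seen.add(key)
        lo, hi = self.grid.wavelengths[0], self.grid.wavelengths[-1]
        for p in self.peaks:
            if not lo <= p.position <= hi:
                raise ValueError(
                    f"in vivo position {p.position} nm of {p.pigment.value} j={p.peak_index} "
                    f"lies outside the grid [{lo}, {hi}]"
                )
        if self.baseline is not None:
            b = np.asarray(self.baseline, dtype=float)
            if b.shape != self.grid.wavelengths.shape:
                raise ValueError("baseline K0 must live on the same grid")
            if np.any(b < 0):
                raise ValueError("baseline K0 must be nonnegative")
            self.baseline = b

    def peaks_for(self, pigment: Pigment) -> list[PeakParameter]:
        return [p for p in self.peaks if p.pigment == pigment]

    def coefficient(self, pigment: Pigment) -> np.ndarray:
        return pigment_coefficient(self.peaks_for(pigment), self.grid)

    def coefficient_matrix(self) -> np.ndarray:
        """(n_wavelengths, 4) matrix of K spectra, pigment order Chla/Chlb/Cars/Ants."""
        return np.column_stack([self.coefficient(p) for p in Pigment])

    @property
    def k0(self) -> np.ndarray:
        if self.baseline is None:
            return np.zeros(len(self.grid))
        return self.baseline

    def to_dict(self) -> dict:
        d: dict = {"peaks": [p.to_dict() for p in self.peaks]}
        if self.name:
            d["name"] = self.name
        d["grid"] = {
            "start": float(self.grid.wavelengths[0]),
            "stop": float(self.grid.wavelengths[-1]),
            "step": float(self.grid.wavelengths[1] - self.grid.wavelengths[0]),
        }
        if self.baseline is not None:
            d["baseline"] = [float(x) for x in self.baseline]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PigmentCoefficientSet":
        if "grid" in d:
            g = d["grid"]
            grid = SpectralGrid.from_spec(f"{g['start']}:{g['stop']}:{g['step']}")
        else:
            grid = SpectralGrid.default()
        baseline = np.asarray(d["baseline"], dtype=float) if "baseline" in d else None
        return cls(
            peaks=[PeakParameter.from_dict(p) for p in d["peaks"]],
            grid=grid,
            baseline=baseline,
            name=d.get("name"),
        )


def total_absorption(
    coeffs: PigmentCoefficientSet,
    conc: PigmentConcentrations,
    n_layers: float,
) -> np.ndarray:
    """Per-layer leaf absorption k(λ): pigment term scaled by 1/N plus K0."""
    if n_layers <= 0:
        raise ValueError(f"structure index N must be > 0, got {n_layers}")
    pigment_term = coeffs.coefficient_matrix() @ conc.as_array()
    return pigment_term / n_layers + coeffs.k0


def measure_peak(values: np.ndarray, grid: SpectralGrid) -> tuple[float, float]:
    """Numerically locate a spectrum's maximum: (wavelength, value)."""
    i = int(np.argmax(values))
    return float(grid.wavelengths[i]), float(values[i])


def measure_fwhm(values: np.ndarray, grid: SpectralGrid) -> float:
    """Full width at half maximum from the two half-maximum crossings.

    Crossing wavelengths are located by linear interpolation between grid
    points, so sub-grid-step precision is obtained on any sampling.
    """
    wl = grid.wavelengths
    i_max = int(np.argmax(values))
    half = values[i_max] / 2.0

    def crossing(lo_side: bool) -> float:
        idx = range(i_max, 0, -1) if lo_side else range(i_max, len(wl) - 1)
        for i in idx:
            j = i - 1 if lo_side else i + 1
            if (values[i] - half) * (values[j] - half) <= 0 and values[j] <= half:
                f = (values[i] - half) / (values[i] - values[j])
                return float(wl[i] + f * (wl[j] - wl[i]))
        raise ValueError("half-maximum crossing not found inside the grid")

    return crossing(False) - crossing(True)


def default_parameters(grid: SpectralGrid | None = None) -> PigmentCoefficientSet:
    """The shipped calibrated parameter set (9 peaks: Chla 4, Chlb 3, Cars 1, Ants 1).

    Loaded from the packaged JSON file; baseline K0 defaults to zero and can
    be replaced on the returned object.
    """
    text = resources.files("leafoptics.data").joinpath("pigment_peaks_default.json").read_text()
    cs = PigmentCoefficientSet.from_dict(json.loads(text))
    if grid is not None and grid != cs.grid:
        cs = PigmentCoefficientSet(peaks=cs.peaks, grid=grid, name=cs.name)
    return cs
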