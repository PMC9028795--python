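"""Synthetic leaf datasets emulating the statistical envelope of real leaves.

The generator draws pigment concentrations uniformly (or log-uniformly)
within published per-pigment ranges, honors a configurable Chlb/Chla ratio
interval, assigns each leaf a structure index, runs the forward plate model
and adds independent Gaussian spectral noise. Everything is reproducible
from a single seed, so every other module can be tested without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .absorption import PigmentCoefficientSet, PigmentConcentrations
from .calibration import CalibrationDataset
from .plate import (
    LeafSample,
    LeafStructure,
    PlateConfig,
    RefractiveIndexSpectrum,
    SpectraPair,
    forward_model,
)

__all__ = ["SyntheticLeafConfig", "simulate_dataset"]

# published concentration envelopes (µg/cm²) of a 59-leaf multi-species campaign
DEFAULT_RANGES = {
    "chla": (0.04, 94.53),
    "chlb": (0.05, 47.49),
    "cars": (0.24, 44.55),
    "ants": (0.01, 47.22),
}


@dataclass(frozen=True)
class SyntheticLeafConfig:
    """Sampling envelope for the synthetic dataset generator.

    Defaults reproduce the study conditions the model was built for:
    per-pigment ranges of the multi-species campaign, Chlb/Chla ratio in
    [0.4, 1.09], structure index in [1, 3] and additive spectral noise with
    standard deviation 0.005 on both R and T.
    """

    n_samples: int = 59
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    chlb_to_chla: tuple[float, float] = (0.4, 1.09)
    n_range: tuple[float, float] = (1.0, 3.0)
    noise_sd: float = 0.005
    seed: int = 0
    log_uniform: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, (lo, hi) in self.ranges.items():
            if not 0 <= lo < hi:
                raise ValueError(f"range for {name} must be positive and ordered")
        if not 0 < self.chlb_to_chla[0] <= self.chlb_to_chla[1]:
            raise ValueError("ratio range must be positive and ordered")
        if not 1.0 <= self.n_range[0] <= self.n_range[1]:
            raise ValueError("N range must be ordered and >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # feasibility of the ratio constraint against both chlorophyll ranges
        a_lo, a_hi = self.ranges["chla"]
        b_lo, b_hi = self.ranges["chlb"]
        r_lo, r_hi = self.chlb_to_chla
        if b_lo / r_lo > a_hi or b_hi / r_hi < a_lo:
            raise ValueError(
                "infeasible ratio constraint: no Chla value keeps Chlb inside its range"
            )


def _draw(rng: np.random.Generator, lo: float, hi: float, log_uniform: bool) -> float:
    if log_uniform:
        lo = max(lo, 1e-6)
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def simulate_dataset(
    config: SyntheticLeafConfig,
    coeffs: PigmentCoefficientSet,
    m_la: RefractiveIndexSpectrum,
    plate_config: PlateConfig = PlateConfig(),
) -> CalibrationDataset:
    """Generate ``n_samples`` synthetic leaves with noisy forward spectra.

    The Chlb/Chla ratio is drawn first; Chla is then drawn on the
    subinterval of its range that keeps Chlb inside its own range, so both
    per-pigment envelopes and the ratio invariant hold without clipping.
    Noisy spectra are clipped to [0, 1] and renormalized where R + T would
    exceed 1. All samples are tagged ``calibration``; use
    :func:`leafoptics.calibration.split_dataset` to re-split.
    """
    rng = np.random.default_rng(config.seed)
    a_lo, a_hi = config.ranges["chla"]
    b_lo, b_hi = config.ranges["chlb"]
    samples = []
    for i in range(config.n_samples):
        ratio = rng.uniform(*config.chlb_to_chla)
        lo = max(a_lo, b_lo / ratio)
        hi = min(a_hi, b_hi / ratio)
        if lo > hi:
            raise ValueError(
                f"infeasible ratio constraint: ratio {ratio:.3f} leaves no feasible Chla"
            )
        chla = _draw(rng, lo, hi, config.log_uniform)
        chlb = ratio * chla
        cars = _draw(rng, *config.ranges["cars"], config.log_uniform)
        ants = _draw(rng, *config.ranges["ants"], config.log_uniform)
        n_layers = float(rng.uniform(*config.n_range))

        sample = LeafSample(
            concentrations=PigmentConcentrations(chla, chlb, cars, ants),
            structure=LeafStructure(n_layers),
            sample_id=f"syn_{i:04d}",
        )
        clean = forward_model(sample, coeffs, m_la, plate_config)
        r = clean.reflectance
        t = clean.transmittance
        if config.noise_sd > 0:
            r = r + rng.normal(0.0, config.noise_sd, size=r.shape)
            t = t + rng.normal(0.0, config.noise_sd, size=t.shape)
            r = np.clip(r, 0.0, 1.0)
            t = np.clip(t, 0.0, 1.0)
            s = r + t
            over = s > 1.0
            r = np.where(over, r / s, r)
            t = np.where(over, t / s, t)
        sample.spectra = SpectraPair(grid=coeffs.grid, reflectance=r, transmittance=t)
        samples.append(sample)

    return CalibrationDataset(samples=samples, roles=["calibration"] * len(samples))
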