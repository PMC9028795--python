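"""Model recalibration from paired spectra + pigment datasets.

Given leaves with measured reflectance/transmittance and known pigment
concentrations, re-fit the pseudo-Voigt peak parameters (Gauss ratio,
height, FWHM, spectral displacement per peak), optionally a nonnegative
baseline absorption K0 and the per-wavelength refractive index, by
minimizing the pooled spectral merit function. The procedure alternates:

  (a) estimate each sample's structure index N on the NIR window;
  (b) fit all peak parameters (+ K0 knots) jointly by bounded
      least squares across the calibration samples;
  (c) optionally refine m_la wavelength by wavelength (bounded scalar
      search, then a short moving-average smooth);

until the merit improvement falls below tolerance. Displacements are kept
in a small band around the organic-solution peak positions, which anchors
each peak to its physical origin and prevents the overlapping-band fit from
degenerating into an unconstrained spectral decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .absorption import (
    PeakParameter,
    Pigment,
    PigmentCoefficientSet,
    SpectralGrid,
)
from .plate import (
    LeafSample,
    PlateConfig,
    RefractiveIndexSpectrum,
    SpectraPair,
    _forward_rt,
)
from .retrieval import estimate_structure_index, merit

__all__ = [
    "CalibrationDataset",
    "CalibratedModel",
    "CalibrationConfig",
    "split_dataset",
    "calibrate_model",
    "count_free_parameters",
]

_PIGMENT_NAMES = [p.value for p in Pigment]


@dataclass
class CalibrationDataset:
    """Leaf samples tagged as calibration or validation members."""

    samples: list[LeafSample]
    roles: list[str]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.roles):
            raise ValueError("one role per sample required")
        for role in self.roles:
            if role not in ("calibration", "validation"):
                raise ValueError(f"unknown role {role!r}")
        grids = set()
        for i, (sample, role) in enumerate(zip(self.samples, self.roles)):
            sid = sample.sample_id or f"sample_{i}"
            if role != "calibration":
                continue
            if sample.spectra is None:
                raise ValueError(f"calibration sample {sid!r} has no measured spectra")
            conc = sample.concentrations.as_array()
            if not np.all(np.isfinite(conc)):
                missing = [n for n, v in zip(_PIGMENT_NAMES, conc) if not np.isfinite(v)]
                raise ValueError(
                    f"calibration sample {sid!r} is missing concentrations: {missing}"
                )
            grids.add(sample.spectra.grid)
        if len(grids) > 1:
            raise ValueError("all calibration spectra must share one grid")

    def calibration_samples(self) -> list[LeafSample]:
        return [s for s, r in zip(self.samples, self.roles) if r == "calibration"]

    def validation_samples(self) -> list[LeafSample]:
        return [s for s, r in zip(self.samples, self.roles) if r == "validation"]


@dataclass
class CalibratedModel:
    coeffs: PigmentCoefficientSet
    m_la: RefractiveIndexSpectrum
    n_layers: list[float]
    merit_history: list[float]
    converged: bool


@dataclass(frozen=True)
class CalibrationConfig:
    """Bounds and loop controls for :func:`calibrate_model`.

    Displacement is bounded at ±45 nm: wide enough to admit the largest
    in vivo shift seen in practice (~39 nm for carotenoids) while keeping
    every peak tied to its solvent position.
    """

    delta_bound: float = 45.0
    w_bounds: tuple[float, float] = (10.0, 250.0)
    h_max: float = 2.0
    fit_k0: bool = False
    k0_n_knots: int = 9
    k0_max: float = 0.5
    fit_mla: bool = False
    mla_bounds: tuple[float, float] = (1.2, 1.6)
    mla_smooth_window: int = 11
    max_outer: int = 5
    tol: float = 1e-8
    incidence_deg: float = 40.0


def count_free_parameters(coeffs) -> int:
    """Number of free calibration parameters: 4 (v, h, w, Δλ) per peak."""
    if isinstance(coeffs, PigmentCoefficientSet):
        peaks: Iterable[PeakParameter] = coeffs.peaks
    else:
        peaks = list(coeffs)
    return 4 * sum(1 for _ in peaks)


def split_dataset(
    samples: Sequence[LeafSample],
    n_calibration: int | None = None,
    seed: int = 0,
    tolerance: float = 0.10,
    max_tries: int = 2000,
) -> CalibrationDataset:
    """Deterministic stratified calibration/validation split.

    Random seeded shuffles are screened until both subsets represent the
    full set per pigment: each subset mean within ``tolerance`` (relative)
    of the full-set mean, and each subset range bracketing the full-set
    mean. Raises naming the offending pigment when no such split exists.
    """
    samples = list(samples)
    if len(samples) < 4:
        raise ValueError(f"need at least 4 samples to split, got {len(samples)}")
    if n_calibration is None:
        n_calibration = (len(samples) + 1) // 2
    if not 2 <= n_calibration <= len(samples) - 2:
        raise ValueError("each subset needs at least 2 samples")

    conc = np.array([s.concentrations.as_array() for s in samples])  # (S, 4)
    full_mean = conc.mean(axis=0)
    rng = np.random.default_rng(seed)
    eps = 1e-12
    worst_pigment = None
    for _ in range(max_tries):
        order = rng.permutation(len(samples))
        cal_idx = np.sort(order[:n_calibration])
        val_idx = np.sort(order[n_calibration:])
        ok = True
        for idx in (cal_idx, val_idx):
            sub = conc[idx]
            mean_ok = np.abs(sub.mean(axis=0) - full_mean) <= tolerance * full_mean + eps
            bracket_ok = (sub.min(axis=0) <= full_mean + eps) & (
                sub.max(axis=0) >= full_mean - eps
            )
            good = mean_ok & bracket_ok
            if not np.all(good):
                worst_pigment = _PIGMENT_NAMES[int(np.argmin(good))]
                ok = False
                break
        if ok:
            roles = ["validation"] * len(samples)
            for i in cal_idx:
                roles[i] = "calibration"
            return CalibrationDataset(samples=samples, roles=roles)
    raise ValueError(
        f"no representative split found in {max_tries} tries; "
        f"stratification fails for pigment {worst_pigment}"
    )


def _pack(peaks: list[PeakParameter]) -> np.ndarray:
    return np.concatenate(
        [[p.gauss_ratio, p.height, p.fwhm, p.displacement] for p in peaks]
    )


def _unpack(
    x: np.ndarray, template: list[PeakParameter], grid: SpectralGrid
) -> list[PeakParameter]:
    peaks = []
    lo, hi = grid.wavelengths[0], grid.wavelengths[-1]
    for i, p in enumerate(template):
        v, h, w, d = x[4 * i : 4 * i + 4]
        pos = min(max(p.solution_position + d, lo), hi)
        peaks.append(
            PeakParameter(
                pigment=p.pigment,
                peak_index=p.peak_index,
                gauss_ratio=float(min(max(v, 0.0), 1.0)),
                height=float(max(h, 1e-9)),
                fwhm=float(max(w, 1e-6)),
                solution_position=p.solution_position,
                displacement=float(pos - p.solution_position),
                raf=p.raf,
            )
        )
    return peaks


def _dataset_merit(
    samples: list[LeafSample],
    n_layers: list[float],
    coeffs: PigmentCoefficientSet,
    m_la: RefractiveIndexSpectrum,
    incidence_deg: float,
) -> float:
    total = 0.0
    kmat = coeffs.coefficient_matrix()
    k0 = coeffs.k0
    for s, nl in zip(samples, n_layers):
        k = (kmat @ s.concentrations.as_array()) / nl + k0
        pair = _forward_rt(k, m_la.values, nl, incidence_deg, coeffs.grid)
        total += merit(s.spectra, pair)
    return total


def calibrate_model(
    dataset: CalibrationDataset,
    init: PigmentCoefficientSet,
    config: CalibrationConfig = CalibrationConfig(),
) -> CalibratedModel:
    """Re-fit peak parameters (and optionally K0, m_la) on a calibration set.

    Returns the best model found; ``converged`` is False when the outer
    loop exhausted ``max_outer`` iterations while still improving more than
    the tolerance. The merit history is nonincreasing by construction
    (every accepted step is an improvement over the previous model).
    """
    samples = dataset.calibration_samples()
    if not samples:
        raise ValueError("dataset has no calibration samples")
    grid = init.grid
    m_la = RefractiveIndexSpectrum(grid=grid, values=_initial_mla(init, dataset))
    template = list(init.peaks)
    obs = [
        np.concatenate([s.spectra.reflectance, s.spectra.transmittance]) for s in samples
    ]

    # fitted displacements always measure from the solution position, so any
    # pinned in vivo positions in the init are folded into the start value
    x_peaks = np.concatenate(
        [
            [p.gauss_ratio, p.height, p.fwhm, p.position - p.solution_position]
            for p in template
        ]
    )
    n_peaks = len(template)
    lo = np.tile([0.0, 1e-6, config.w_bounds[0], -config.delta_bound], n_peaks)
    hi = np.tile([1.0, config.h_max, config.w_bounds[1], config.delta_bound], n_peaks)

    knots = np.linspace(grid.wavelengths[0], grid.wavelengths[-1], config.k0_n_knots)
    if config.fit_k0:
        k0_init = np.interp(knots, grid.wavelengths, init.k0)
        x_peaks = np.concatenate([x_peaks, k0_init])
        lo = np.concatenate([lo, np.zeros(config.k0_n_knots)])
        hi = np.concatenate([hi, np.full(config.k0_n_knots, config.k0_max)])

    def build(x: np.ndarray) -> PigmentCoefficientSet:
        peaks = _unpack(x[: 4 * n_peaks], template, grid)
        baseline = (
            np.interp(grid.wavelengths, knots, x[4 * n_peaks :]) if config.fit_k0 else init.baseline
        )
        return PigmentCoefficientSet(peaks=peaks, grid=grid, baseline=baseline, name=init.name)

    def residuals(x: np.ndarray, n_layers: list[float]) -> np.ndarray:
        cs = build(x)
        kmat = cs.coefficient_matrix()
        k0 = cs.k0
        out = []
        for s, nl, o in zip(samples, n_layers, obs):
            k = (kmat @ s.concentrations.as_array()) / nl + k0
            pair = _forward_rt(k, m_la.values, nl, config.incidence_deg, grid)
            out.append(np.concatenate([pair.reflectance, pair.transmittance]) - o)
        return np.concatenate(out)

    best_x = np.clip(x_peaks, lo, hi)
    coeffs = build(best_x)
    n_layers = [
        estimate_structure_index(s.spectra, coeffs, m_la).n_layers for s in samples
    ]
    best_merit = _dataset_merit(samples, n_layers, coeffs, m_la, config.incidence_deg)
    history = [best_merit]
    converged = False

    for _ in range(config.max_outer):
        # (a) refresh per-sample structure indices under the current model
        n_new = [estimate_structure_index(s.spectra, coeffs, m_la).n_layers for s in samples]
        m_new = _dataset_merit(samples, n_new, coeffs, m_la, config.incidence_deg)
        if m_new <= best_merit:
            n_layers, best_merit = n_new, m_new

        # (b) joint peak (+K0) fit
        res = least_squares(
            residuals,
            x0=best_x,
            args=(n_layers,),
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=400,
        )
        cand = build(res.x)
        m_fit = _dataset_merit(samples, n_layers, cand, m_la, config.incidence_deg)
        if m_fit <= best_merit:
            best_x, coeffs, best_merit = res.x, cand, m_fit

        # (c) per-wavelength refractive-index refinement
        if config.fit_mla:
            m_la_new = _refine_mla(samples, n_layers, coeffs, m_la, config)
            m_ref = _dataset_merit(samples, n_layers, coeffs, m_la_new, config.incidence_deg)
            if m_ref <= best_merit:
                m_la, best_merit = m_la_new, m_ref

        improvement = history[-1] - best_merit
        history.append(best_merit)
        if improvement < config.tol:
            converged = True
            break

    return CalibratedModel(
        coeffs=coeffs,
        m_la=m_la,
        n_layers=n_layers,
        merit_history=history,
        converged=converged,
    )


def _initial_mla(init: PigmentCoefficientSet, dataset: CalibrationDataset) -> np.ndarray:
    from .plate import synthetic_refractive_index

    return synthetic_refractive_index(init.grid).values


def _refine_mla(
    samples: list[LeafSample],
    n_layers: list[float],
    coeffs: PigmentCoefficientSet,
    m_la: RefractiveIndexSpectrum,
    config: CalibrationConfig,
) -> RefractiveIndexSpectrum:
    """Bounded scalar search for m_la at each wavelength, then smooth."""
    grid = coeffs.grid
    kmat = coeffs.coefficient_matrix()
    k0 = coeffs.k0
    ks = np.array(
        [(kmat @ s.concentrations.as_array()) / nl + k0 for s, nl in zip(samples, n_layers)]
    )  # (S, L)
    robs = np.array([s.spectra.reflectance for s in samples])
    tobs = np.array([s.spectra.transmittance for s in samples])
    nls = np.array(n_layers)

    new_vals = m_la.values.copy()
    one_grid = SpectralGrid(np.array([grid.wavelengths[0], grid.wavelengths[0] + 1.0]))
    for i in range(len(grid)):
        kcol = ks[:, i]

        def obj(nv: float) -> float:
            total = 0.0
            for s_idx in range(len(samples)):
                pair = _forward_rt(
                    np.full(2, kcol[s_idx]),
                    np.full(2, nv),
                    nls[s_idx],
                    config.incidence_deg,
                    one_grid,
                )
                total += (pair.reflectance[0] - robs[s_idx, i]) ** 2 + (
                    pair.transmittance[0] - tobs[s_idx, i]
                ) ** 2
            return total

        res = minimize_scalar(
            obj, bounds=config.mla_bounds, method="bounded", options={"xatol": 1e-5}
        )
        new_vals[i] = res.x

    w = max(int(config.mla_smooth_window) | 1, 1)
    if w > 1:
        kernel = np.ones(w) / w
        padded = np.pad(new_vals, w // 2, mode="edge")
        new_vals = np.convolve(padded, kernel, mode="valid")
    new_vals = np.clip(new_vals, config.mla_bounds[0] + 1e-9, config.mla_bounds[1] - 1e-9)
    return RefractiveIndexSpectrum(grid=grid, values=new_vals)
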