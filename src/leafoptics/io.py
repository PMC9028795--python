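"""File formats: spectra CSV, parameter JSON/YAML, refractive-index CSV,
dataset manifests and provenance records.

All files are UTF-8; wavelengths are physical nanometres and reflectance/
transmittance are fractions in [0, 1]. Spectra on grids other than the
target are resampled by linear interpolation (logged).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .absorption import PigmentCoefficientSet, PigmentConcentrations, SpectralGrid, default_parameters
from .calibration import CalibrationDataset
from .plate import LeafSample, LeafStructure, RefractiveIndexSpectrum, SpectraPair

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_parameters",
    "write_parameters",
    "read_refractive_index",
    "write_refractive_index",
    "export_coefficients",
    "read_dataset",
    "write_dataset",
    "write_provenance",
]

logger = logging.getLogger(__name__)

SPECTRA_COLUMNS = ["wavelength_nm", "reflectance", "transmittance"]


def _resample(wl: np.ndarray, values: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    return np.interp(grid.wavelengths, wl, values)


def read_spectra(path, grid: SpectralGrid | None = None) -> SpectraPair:
    """Read a spectra CSV (wavelength_nm, reflectance, transmittance).

    Values outside [−0.01, 1.01] are rejected naming the offending row;
    tiny sensor undershoot/overshoot inside that band is clipped. Inputs on
    a different grid are linearly resampled onto ``grid`` (default
    400–800 nm at 1 nm) with a logged note.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        bad = int(np.argmin(np.diff(wl))) + 1
        raise ValueError(f"{path}: wavelengths not strictly increasing at row {bad}")
    for col in ("reflectance", "transmittance"):
        v = df[col].to_numpy(dtype=float)
        bad = np.where((v < -0.01) | (v > 1.01))[0]
        if bad.size:
            raise ValueError(
                f"{path}: {col} value {v[bad[0]]} outside [-0.01, 1.01] at row {bad[0]}"
            )
    r = np.clip(df["reflectance"].to_numpy(dtype=float), 0.0, 1.0)
    t = np.clip(df["transmittance"].to_numpy(dtype=float), 0.0, 1.0)

    grid = grid or SpectralGrid.default()
    if wl.shape != grid.wavelengths.shape or not np.allclose(wl, grid.wavelengths):
        logger.info("%s: resampling %d-point spectra onto the %d-point target grid",
                    path, wl.size, len(grid))
        r = _resample(wl, r, grid)
        t = _resample(wl, t, grid)
    return SpectraPair(grid=grid, reflectance=r, transmittance=t)


def write_spectra(pair: SpectraPair, path) -> None:
    df = pd.DataFrame(
        {
            "wavelength_nm": pair.grid.wavelengths,
            "reflectance": pair.reflectance,
            "transmittance": pair.transmittance,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_parameters(path) -> PigmentCoefficientSet:
    """Load a peak-parameter file (JSON or YAML by extension).

    The shipped calibrated default is reachable by the name
    ``"table6-default"`` without any file on disk.
    """
    if str(path) == "table6-default":
        return default_parameters()
    p = Path(path)
    text = p.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if p.suffix.lower() in (".yml", ".yaml") else json.loads(text)
    return PigmentCoefficientSet.from_dict(data)


def write_parameters(coeffs: PigmentCoefficientSet, path) -> None:
    p = Path(path)
    d = coeffs.to_dict()
    if p.suffix.lower() in (".yml", ".yaml"):
        p.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
    else:
        p.write_text(json.dumps(d, indent=2), encoding="utf-8")


def read_refractive_index(path, grid: SpectralGrid | None = None) -> RefractiveIndexSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "m_la"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    v = df["m_la"].to_numpy(dtype=float)
    grid = grid or SpectralGrid.default()
    if wl.shape != grid.wavelengths.shape or not np.allclose(wl, grid.wavelengths):
        v = _resample(wl, v, grid)
    return RefractiveIndexSpectrum(grid=grid, values=v)


def write_refractive_index(m_la: RefractiveIndexSpectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": m_la.grid.wavelengths, "m_la": m_la.values}).to_csv(
        path, index=False, float_format="%.12g"
    )


def export_coefficients(coeffs: PigmentCoefficientSet, path) -> None:
    """Write the four coefficient spectra plus K0 as a CSV table."""
    mat = coeffs.coefficient_matrix()
    pd.DataFrame(
        {
            "wavelength_nm": coeffs.grid.wavelengths,
            "K_Chla": mat[:, 0],
            "K_Chlb": mat[:, 1],
            "K_Cars": mat[:, 2],
            "K_Ants": mat[:, 3],
            "K0": coeffs.k0,
        }
    ).to_csv(path, index=False, float_format="%.12g")


MANIFEST_COLUMNS = [
    "sample_id", "role", "c_chla", "c_chlb", "c_cars", "c_ants", "n_est", "spectra_path",
]


def write_dataset(dataset: CalibrationDataset, out_dir) -> Path:
    """Write a dataset as a manifest CSV plus per-sample spectra CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample, role in zip(dataset.samples, dataset.roles):
        sid = sample.sample_id or f"sample_{len(rows):04d}"
        spath = f"{sid}.csv"
        if sample.spectra is not None:
            write_spectra(sample.spectra, out / spath)
        c = sample.concentrations
        rows.append(
            {
                "sample_id": sid,
                "role": role,
                "c_chla": c.c_chla,
                "c_chlb": c.c_chlb,
                "c_cars": c.c_cars,
                "c_ants": c.c_ants,
                "n_est": sample.structure.n_layers,
                "spectra_path": spath if sample.spectra is not None else "",
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path, grid: SpectralGrid | None = None) -> CalibrationDataset:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest_path}: missing manifest columns {missing}")
    base = manifest_path.parent
    samples, roles = [], []
    for _, row in df.iterrows():
        spectra = None
        if isinstance(row["spectra_path"], str) and row["spectra_path"]:
            spectra = read_spectra(base / row["spectra_path"], grid=grid)
        samples.append(
            LeafSample(
                concentrations=PigmentConcentrations(
                    float(row["c_chla"]), float(row["c_chlb"]),
                    float(row["c_cars"]), float(row["c_ants"]),
                ),
                structure=LeafStructure(float(row["n_est"])),
                spectra=spectra,
                sample_id=str(row["sample_id"]),
            )
        )
        roles.append(str(row["role"]))
    return CalibrationDataset(samples=samples, roles=roles)


def write_provenance(out_dir, command: str, inputs: dict, seed: int | None = None) -> Path:
    """Write a machine-readable run record next to the outputs."""
    from . import __version__

    record = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": seed,
        "version": __version__,
    }
    record["config_hash"] = hashlib.sha256(
        json.dumps(record, sort_keys=True).encode()
    ).hexdigest()[:16]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "provenance.json"
    path.write_text(json.dumps(record, indent=2), encoding="utf-8")
    return path
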