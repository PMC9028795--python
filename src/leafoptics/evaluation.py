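"""Evaluation metrics for spectra and retrieved concentrations.

RMSE, BIAS, SEC (bias-corrected standard error of the residuals, n−1
denominator) and CV (SEC as a percentage of the measured mean). Residuals
are taken as predicted − measured. The three error measures obey the
decomposition RMSE² = BIAS² + SEC²·(n−1)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvaluationMetrics", "metrics", "spectral_error_profile"]


@dataclass(frozen=True)
class EvaluationMetrics:
    rmse: float
    bias: float
    sec: float
    cv_percent: float
    cv_defined: bool = True


def metrics(measured, predicted) -> EvaluationMetrics:
    """Compute RMSE/BIAS/SEC/CV for paired vectors (residual = predicted − measured)."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ValueError("measured and predicted must be 1-D vectors of equal length")
    n = m.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    d = p - m
    rmse = float(np.sqrt(np.mean(d**2)))
    bias = float(np.mean(d))
    sec = float(np.sqrt(np.sum((d - bias) ** 2) / (n - 1)))
    mean_m = float(np.mean(m))
    if mean_m == 0.0:
        return EvaluationMetrics(rmse, bias, sec, float("nan"), cv_defined=False)
    return EvaluationMetrics(rmse, bias, sec, 100.0 * sec / mean_m)


def spectral_error_profile(measured_pairs, modeled_pairs) -> pd.DataFrame:
    """Per-wavelength RMSE/BIAS/SEC across samples, for R and T separately.

    Returns a DataFrame indexed by wavelength_nm with columns
    ``{rmse,bias,sec}_{r,t}``.
    """
    measured_pairs = list(measured_pairs)
    modeled_pairs = list(modeled_pairs)
    if len(measured_pairs) != len(modeled_pairs):
        raise ValueError("need one modeled pair per measured pair")
    if len(measured_pairs) < 2:
        raise ValueError("need at least 2 samples for a per-wavelength profile")
    grid = measured_pairs[0].grid
    for pair in measured_pairs + modeled_pairs:
        if pair.grid != grid:
            raise ValueError("all spectra must share one grid")

    out = {}
    for tag, attr in (("r", "reflectance"), ("t", "transmittance")):
        mea = np.array([getattr(p, attr) for p in measured_pairs])  # (S, L)
        mod = np.array([getattr(p, attr) for p in modeled_pairs])
        d = mod - mea
        n = d.shape[0]
        out[f"rmse_{tag}"] = np.sqrt(np.mean(d**2, axis=0))
        out[f"bias_{tag}"] = np.mean(d, axis=0)
        out[f"sec_{tag}"] = np.sqrt(np.sum((d - d.mean(axis=0)) ** 2, axis=0) / (n - 1))
    return pd.DataFrame(out, index=pd.Index(grid.wavelengths, name="wavelength_nm"))
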