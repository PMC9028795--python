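"""Independent reference computations used to check the implementation.

Everything here is written from the physical definitions only (Fresnel
coefficients, Beer–Lambert slant paths, photon bookkeeping, naive peak
summation) and deliberately shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def glf_value(v, h, w, p, lam):
    """Naive pseudo-Voigt evaluation at a single wavelength."""
    g = math.exp(-4.0 * math.log(2.0) * ((p - lam) / w) ** 2)
    l = 1.0 / (1.0 + 4.0 * ((p - lam) / w) ** 2)
    return v * h * g + (1.0 - v) * h * l


def fresnel_reflectance_external(theta, n):
    """Unpolarized Fresnel reflectance, air -> dielectric of index n."""
    theta = np.asarray(theta, dtype=float)
    ci = np.cos(theta)
    s = np.sin(theta) / n
    ct = np.sqrt(1.0 - s * s)
    rs = ((ci - n * ct) / (ci + n * ct)) ** 2
    rp = ((n * ci - ct) / (n * ci + ct)) ** 2
    return 0.5 * (rs + rp)


def fresnel_reflectance_internal(theta, n):
    """Unpolarized Fresnel reflectance, dielectric n -> air (1 beyond TIR)."""
    theta = np.asarray(theta, dtype=float)
    s = n * np.sin(theta)
    tir = s >= 1.0
    s = np.where(tir, 0.0, s)  # placeholder, overwritten below
    ci = np.cos(theta)
    ct = np.sqrt(1.0 - s * s)
    rs = ((n * ci - ct) / (n * ci + ct)) ** 2
    rp = ((ci - n * ct) / (ci + n * ct)) ** 2
    return np.where(tir, 1.0, 0.5 * (rs + rp))


def tav_quadrature(alpha_deg, n):
    """Cone-averaged Fresnel transmissivity by adaptive quadrature."""
    a = math.radians(alpha_deg)
    num = quad(
        lambda th: (1.0 - fresnel_reflectance_external(th, n)) * math.sin(th) * math.cos(th),
        0.0,
        a,
        limit=200,
    )[0]
    den = 0.5 * math.sin(a) ** 2
    return num / den


def diffuse_transmission_quadrature(k):
    """∫₀¹ 2·μ·e^(−k/μ) dμ — isotropic-flux transmission through one layer."""
    if k == 0.0:
        return 1.0
    return quad(lambda mu: 2.0 * mu * math.exp(-k / mu), 0.0, 1.0, limit=200)[0]


def mc_single_plate(n, tau_abs, incidence_deg, n_photons, rng):
    """Monte-Carlo photon tracing of one absorbing plate.

    Photons enter within the incidence cone (density ∝ sinθ·cosθ), refract
    or reflect at the top per the Fresnel coefficients, survive each layer
    traversal with probability ``tau_abs`` (the flux inside is diffuse, so
    each arrival at an interface draws a fresh diffuse angle, with total
    internal reflection beyond the critical angle), and are tallied as
    reflected or transmitted on exit. Returns (R, T, se) with ``se`` a
    binomial standard error for one tally.
    """
    u = rng.uniform(0.0, math.sin(math.radians(incidence_deg)) ** 2, n_photons)
    theta = np.arcsin(np.sqrt(u))
    refl_ext = fresnel_reflectance_external(theta, n)
    reflected = rng.random(n_photons) < refl_ext

    n_reflected = int(np.sum(reflected))
    n_transmitted = 0
    alive = np.full(n_photons, True)
    alive[reflected] = False
    going_down = np.full(n_photons, True)

    for _ in range(10_000):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        # traverse one layer
        survive = rng.random(idx.size) < tau_abs
        alive[idx[~survive]] = False
        idx = idx[survive]
        if idx.size == 0:
            continue
        # diffuse arrival angle at the far interface
        theta_i = np.arcsin(np.sqrt(rng.uniform(0.0, 1.0, idx.size)))
        r_int = fresnel_reflectance_internal(theta_i, n)
        exits = rng.random(idx.size) < (1.0 - r_int)
        out = idx[exits]
        n_transmitted += int(np.sum(going_down[out]))
        n_reflected += int(np.sum(~going_down[out]))
        alive[out] = False
        going_down[idx[~exits]] = ~going_down[idx[~exits]]

    r_hat = n_reflected / n_photons
    t_hat = n_transmitted / n_photons
    se = math.sqrt(max(r_hat * (1 - r_hat), t_hat * (1 - t_hat)) / n_photons)
    return r_hat, t_hat, se


def stack_by_adding(r1, t1, n_layers):
    """Integer-N stack via repeated adding of one symmetric layer."""
    r, t = r1, t1
    for _ in range(n_layers - 1):
        denom = 1.0 - r * r1
        t_new = t * t1 / denom
        r_new = r + t * t * r1 / denom
        r, t = r_new, t_new
    return r, t


def naive_metrics(measured, predicted):
    """Loop-based RMSE/BIAS/SEC/CV recomputation."""
    n = len(measured)
    d = [p - m for m, p in zip(measured, predicted)]
    rmse = math.sqrt(sum(x * x for x in d) / n)
    bias = sum(d) / n
    sec = math.sqrt(sum((x - bias) ** 2 for x in d) / (n - 1))
    mean_m = sum(measured) / n
    cv = 100.0 * sec / mean_m if mean_m != 0 else float("nan")
    return rmse, bias, sec, cv
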