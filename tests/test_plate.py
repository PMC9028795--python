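"""Plate radiative transfer: interfaces, single plate, Stokes stack, forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafoptics import (
    LeafSample,
    LeafStructure,
    PigmentCoefficientSet,
    PigmentConcentrations,
    SpectralGrid,
    default_parameters,
    diffuse_plate_transmission,
    forward_model,
    interface_transmissivity,
    single_plate_rt,
    stack_rt,
    synthetic_refractive_index,
)
from leafoptics.absorption import Pigment, glf_peak
from oracles import (
    diffuse_transmission_quadrature,
    mc_single_plate,
    stack_by_adding,
    tav_quadrature,
)


class TestInterfaceTransmissivity:
    def test_vacuum_interface_is_transparent(self):
        assert interface_transmissivity(40.0, 1.0) == 1.0
        assert interface_transmissivity(90.0, 1.0) == 1.0

    @pytest.mark.parametrize("angle", [15.0, 40.0, 60.0, 90.0])
    @pytest.mark.parametrize("n", [1.2, 1.45, 1.6])
    def test_matches_fresnel_quadrature(self, angle, n):
        assert interface_transmissivity(angle, n) == pytest.approx(
            tav_quadrature(angle, n), abs=1e-9
        )

    def test_narrow_cone_transmits_more(self):
        for n in (1.3, 1.5):
            assert interface_transmissivity(40.0, n) >= interface_transmissivity(90.0, n)

    @pytest.mark.parametrize("angle", [0.0, -10.0, 91.0])
    def test_invalid_angle_rejected(self, angle):
        with pytest.raises(ValueError, match="angle"):
            interface_transmissivity(angle, 1.4)


class TestDiffusePlateTransmission:
    def test_no_absorption(self):
        assert diffuse_plate_transmission(0.0) == 1.0

    @pytest.mark.parametrize("k", [0.05, 0.3, 1.0, 3.0])
    def test_matches_slant_path_quadrature(self, k):
        assert diffuse_plate_transmission(k) == pytest.approx(
            diffuse_transmission_quadrature(k), abs=1e-10
        )

    def test_strictly_decreasing_to_zero(self):
        ks = np.linspace(0.0, 50.0, 400)
        tau = diffuse_plate_transmission(ks)
        assert np.all(np.diff(tau) < 1e-15)
        assert tau[-1] < 1e-12

    def test_negative_absorption_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            diffuse_plate_transmission(-0.1)


class TestSinglePlate:
    def test_conservation_without_absorption(self):
        for n in (1.2, 1.45, 1.7):
            r, t = single_plate_rt(n, 1.0, 40.0)
            assert r + t == pytest.approx(1.0, abs=1e-12)

    def test_no_interfaces_means_bare_absorber(self):
        r, t = single_plate_rt(1.0, 0.83, 40.0)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(0.83, abs=1e-12)

    def test_matches_photon_tracing(self):
        rng = np.random.default_rng(2024)
        r_mod, t_mod = single_plate_rt(1.45, 0.9, 40.0)
        r_mc, t_mc, se = mc_single_plate(1.45, 0.9, 40.0, 200_000, rng)
        assert abs(r_mod - r_mc) < 3 * se
        assert abs(t_mod - t_mc) < 3 * se


class TestStack:
    def test_single_layer_identity(self):
        r, t = stack_rt(0.12, 0.55, 1.0)
        assert (r, t) == pytest.approx((0.12, 0.55), abs=1e-12)

    @pytest.mark.parametrize("n_layers", [2, 3, 5])
    def test_integer_layers_match_adding_recursion(self, n_layers):
        r1, t1 = 0.08, 0.6
        r_exp, t_exp = stack_by_adding(r1, t1, n_layers)
        r, t = stack_rt(r1, t1, float(n_layers))
        assert r == pytest.approx(r_exp, rel=1e-10)
        assert t == pytest.approx(t_exp, rel=1e-10)

    def test_monotone_in_layer_count(self):
        ns = np.linspace(1.0, 4.0, 61)
        rs = np.array([stack_rt(0.1, 0.5, n)[0] for n in ns])
        ts = np.array([stack_rt(0.1, 0.5, n)[1] for n in ns])
        assert np.all(np.diff(rs) >= -1e-12)
        assert np.all(np.diff(ts) <= 1e-12)

    def test_continuous_in_real_layer_count(self):
        ns = np.linspace(1.0, 4.0, 3001)
        for r1, t1 in [(0.05, 0.9), (0.2, 0.3), (0.4, 0.59)]:
            vals = np.array([stack_rt(r1, t1, n) for n in ns])
            jumps = np.abs(np.diff(vals, axis=0)).max()
            assert jumps < 5e-3

    def test_conserving_degenerate_layer(self):
        r, t = stack_rt(0.3, 0.7, 2.5)
        assert r + t == pytest.approx(1.0, abs=1e-12)
        assert t == pytest.approx(0.7 / (0.7 + 0.3 * 2.5), rel=1e-12)


class TestForwardModel:
    def test_conservation_with_zero_pigments(self, coeffs, m_la):
        sample = LeafSample(PigmentConcentrations(), LeafStructure(2.0))
        pair = forward_model(sample, coeffs, m_la)
        np.testing.assert_allclose(
            pair.reflectance + pair.transmittance, 1.0, atol=1e-12
        )

    @settings(max_examples=15, derandomize=True)
    @given(
        chla=st.floats(0.0, 90.0),
        ants=st.floats(0.0, 45.0),
        n_layers=st.floats(1.0, 3.5),
    )
    def test_energy_never_created(self, chla, ants, n_layers):
        coeffs = default_parameters()
        m_la = synthetic_refractive_index(coeffs.grid)
        sample = LeafSample(
            PigmentConcentrations(chla, 0.4 * chla, 5.0, ants), LeafStructure(n_layers)
        )
        pair = forward_model(sample, coeffs, m_la)
        assert np.all(pair.reflectance + pair.transmittance <= 1.0 + 1e-9)
        assert np.all(pair.reflectance >= 0) and np.all(pair.transmittance >= 0)

    def test_anthocyanin_absorbs_green_not_nir(self, coeffs, grid, m_la):
        base = LeafSample(PigmentConcentrations(30, 10, 8, 2), LeafStructure(1.5))
        rich = LeafSample(PigmentConcentrations(30, 10, 8, 12), LeafStructure(1.5))
        p0 = forward_model(base, coeffs, m_la)
        p1 = forward_model(rich, coeffs, m_la)
        i544 = np.searchsorted(grid.wavelengths, 544.0)
        assert p1.transmittance[i544] < p0.transmittance[i544] - 1e-3
        # strong relative effect in the green, weak in the NIR
        rel_544 = 1.0 - p1.transmittance[i544] / p0.transmittance[i544]
        rel_800 = 1.0 - p1.transmittance[-1] / p0.transmittance[-1]
        assert rel_544 > 0.5 and rel_800 < 0.1
        # the NIR response is explained by the peak's Lorentzian far tail:
        # first-order sensitivity oracle dT/dk at 800 nm by central difference
        from leafoptics.absorption import total_absorption
        from leafoptics.plate import _forward_rt

        ants_peak = coeffs.peaks_for(Pigment.ANTS)[0]
        tail = glf_peak(ants_peak, grid)[-1]
        assert tail < 3e-3  # small but not numerically zero
        dk = tail * 10.0 / 1.5
        k_base = total_absorption(coeffs, base.concentrations, 1.5)
        h = dk / 2  # derivative at the midpoint absorbs the curvature over dk
        t_hi = _forward_rt(k_base + dk / 2 + h, m_la.values, 1.5, 40.0, grid).transmittance[-1]
        t_lo = _forward_rt(k_base + dk / 2 - h, m_la.values, 1.5, 40.0, grid).transmittance[-1]
        predicted = (t_lo - t_hi) / (2 * h) * dk
        actual = p0.transmittance[-1] - p1.transmittance[-1]
        assert actual == pytest.approx(predicted, rel=0.05)

    def test_more_layers_scatter_more_in_nir(self, coeffs, m_la):
        conc = PigmentConcentrations(30, 10, 8, 2)
        r_thin = forward_model(LeafSample(conc, LeafStructure(1.5)), coeffs, m_la)
        r_thick = forward_model(LeafSample(conc, LeafStructure(2.5)), coeffs, m_la)
        assert r_thick.reflectance[-1] > r_thin.reflectance[-1]

    def test_grid_mismatch_rejected(self, coeffs):
        short = SpectralGrid(np.arange(400.0, 701.0))
        m_short = synthetic_refractive_index(short)
        sample = LeafSample(PigmentConcentrations(), LeafStructure(1.5))
        with pytest.raises(ValueError, match="grid"):
            forward_model(sample, coeffs, m_short)

    def test_wavelength_order_independence(self, coeffs, m_la):
        """Each wavelength's R/T depends only on that wavelength's inputs."""
        sample = LeafSample(PigmentConcentrations(30, 10, 8, 2), LeafStructure(1.5))
        full = forward_model(sample, coeffs, m_la)
        sub = SpectralGrid(coeffs.grid.wavelengths[::25])
        coeffs_sub = PigmentCoefficientSet(peaks=coeffs.peaks, grid=sub, name=coeffs.name)
        m_sub = synthetic_refractive_index(sub)
        pair_sub = forward_model(sample, coeffs_sub, m_sub)
        np.testing.assert_allclose(pair_sub.reflectance, full.reflectance[::25], atol=1e-12)
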