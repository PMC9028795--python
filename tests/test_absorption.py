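"""Pseudo-Voigt peaks, pigment coefficients and the total absorption k(λ)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafoptics import (
    PeakParameter,
    Pigment,
    PigmentCoefficientSet,
    PigmentConcentrations,
    SpectralGrid,
    default_parameters,
    glf_peak,
    measure_fwhm,
    measure_peak,
    pigment_coefficient,
    total_absorption,
)
from oracles import glf_value

CARS_PEAK = PeakParameter(Pigment.CARS, 1, 0.5, 0.067, 56, 443, 39)


def eval_at(peak, wavelength):
    """Evaluate one peak at one exact wavelength via a tiny ad-hoc grid."""
    g = SpectralGrid(np.array([wavelength, wavelength + 1.0]))
    return glf_peak(peak, g)[0]


class TestGlfPeak:
    def test_peak_value_at_maximum(self):
        assert eval_at(CARS_PEAK, 482.0) == pytest.approx(0.067, abs=1e-15)

    @pytest.mark.parametrize("v", [0.0, 0.37, 0.5, 1.0])
    def test_half_maximum_at_half_width(self, v):
        peak = PeakParameter(Pigment.ANTS, 1, v, 0.2, 80.0, 500.0, 0.0)
        for lam in (500.0 - 40.0, 500.0 + 40.0):
            assert eval_at(peak, lam) == pytest.approx(0.1, rel=1e-12)

    def test_pure_gaussian_at_one_width(self):
        peak = PeakParameter(Pigment.CHLA, 1, 1.0, 0.5, 30.0, 600.0, 0.0)
        assert eval_at(peak, 630.0) == pytest.approx(0.5 / 16.0, rel=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            SpectralGrid(np.array([]))

    def test_matches_naive_evaluation_everywhere(self, coeffs, grid):
        for p in coeffs.peaks:
            spectrum = glf_peak(p, grid)
            naive = [
                glf_value(p.gauss_ratio, p.height, p.fwhm, p.position, lam)
                for lam in grid.wavelengths
            ]
            np.testing.assert_allclose(spectrum, naive, atol=1e-12)


class TestPigmentCoefficient:
    def test_ants_argmax(self, coeffs, grid):
        pos, _ = measure_peak(coeffs.coefficient(Pigment.ANTS), grid)
        assert pos == 544.0

    def test_single_peak_identity(self, grid):
        assert np.array_equal(
            pigment_coefficient([CARS_PEAK], grid), glf_peak(CARS_PEAK, grid)
        )

    def test_chla_exceeds_first_component_at_419(self, coeffs, grid):
        k_chla = coeffs.coefficient(Pigment.CHLA)
        i = np.searchsorted(grid.wavelengths, 419.0)
        # j=1 contributes exactly its height there; the other tails are positive
        assert k_chla[i] >= 0.153

    def test_mixed_pigments_rejected(self, grid):
        other = PeakParameter(Pigment.ANTS, 1, 0.45, 0.099, 100, 530, 14)
        with pytest.raises(ValueError, match="multiple pigments"):
            pigment_coefficient([CARS_PEAK, other], grid)

    def test_equals_brute_force_summation(self, coeffs, grid):
        for pig in Pigment:
            peaks = coeffs.peaks_for(pig)
            brute = np.array(
                [
                    sum(
                        glf_value(p.gauss_ratio, p.height, p.fwhm, p.position, lam)
                        for p in peaks
                    )
                    for lam in grid.wavelengths
                ]
            )
            np.testing.assert_allclose(coeffs.coefficient(pig), brute, atol=1e-12)


class TestShippedPeakAnatomy:
    """Numeric maxima and widths of every shipped peak match their parameters."""

    def test_argmax_matches_position(self, coeffs, grid):
        for p in coeffs.peaks:
            pos, val = measure_peak(glf_peak(p, grid), grid)
            assert abs(pos - p.position) <= 0.5, (p.pigment, p.peak_index)
            assert val == pytest.approx(p.height, rel=1e-9)

    def test_numeric_fwhm_matches_width(self, coeffs):
        # extended grid: the blue chlorophyll-a peak's left half-maximum
        # crossing sits just below 400 nm
        wide = SpectralGrid(np.arange(300.0, 901.0, 1.0))
        for p in coeffs.peaks:
            fwhm = measure_fwhm(glf_peak(p, wide), wide)
            assert abs(fwhm - p.fwhm) <= 1.0, (p.pigment, p.peak_index)


class TestTotalAbsorption:
    def test_zero_concentrations_zero_baseline(self, coeffs):
        k = total_absorption(coeffs, PigmentConcentrations(), 1.5)
        np.testing.assert_array_equal(k, 0.0)

    def test_doubling_concentrations_doubles_k(self, coeffs):
        c1 = PigmentConcentrations(30, 10, 8, 2)
        c2 = PigmentConcentrations(60, 20, 16, 4)
        np.testing.assert_allclose(
            total_absorption(coeffs, c2, 1.5),
            2.0 * total_absorption(coeffs, c1, 1.5),
            rtol=1e-12,
        )

    def test_value_at_679_matches_per_peak_oracle(self, coeffs, grid):
        conc = PigmentConcentrations(30, 10, 8, 2)
        k = total_absorption(coeffs, conc, 1.5)
        i = np.searchsorted(grid.wavelengths, 679.0)
        weights = dict(zip(Pigment, conc.as_array()))
        expected = (
            sum(
                weights[p.pigment]
                * glf_value(p.gauss_ratio, p.height, p.fwhm, p.position, 679.0)
                for p in coeffs.peaks
            )
            / 1.5
        )
        assert k[i] == pytest.approx(expected, rel=1e-12)

    def test_invalid_structure_index(self, coeffs):
        with pytest.raises(ValueError, match="N"):
            total_absorption(coeffs, PigmentConcentrations(), 0.0)

    @settings(max_examples=25, derandomize=True)
    @given(
        scale=st.floats(0.1, 5.0),
        n1=st.floats(1.0, 4.0),
        n2=st.floats(1.0, 4.0),
    )
    def test_linearity_and_n_scaling(self, scale, n1, n2):
        coeffs = default_parameters()
        base = PigmentConcentrations(12.0, 6.0, 4.0, 1.5)
        scaled = PigmentConcentrations(*(scale * base.as_array()))
        k_base = total_absorption(coeffs, base, n1)
        np.testing.assert_allclose(
            total_absorption(coeffs, scaled, n1), scale * k_base, rtol=1e-10
        )
        np.testing.assert_allclose(
            total_absorption(coeffs, base, n2), k_base * n1 / n2, rtol=1e-10
        )

    def test_baseline_unaffected_by_n(self, coeffs, grid):
        k0 = np.full(len(grid), 0.03)
        with_k0 = PigmentCoefficientSet(peaks=coeffs.peaks, grid=grid, baseline=k0)
        conc = PigmentConcentrations(10, 5, 3, 1)
        k1 = total_absorption(with_k0, conc, 1.0)
        k2 = total_absorption(with_k0, conc, 2.0)
        np.testing.assert_allclose(k1 - k0, 2.0 * (k2 - k0), rtol=1e-12)


class TestDefaultParameters:
    def test_peak_counts(self, coeffs):
        counts = {pig: len(coeffs.peaks_for(pig)) for pig in Pigment}
        assert counts == {Pigment.CHLA: 4, Pigment.CHLB: 3, Pigment.CARS: 1, Pigment.ANTS: 1}

    def test_chla_first_peak_position(self, coeffs):
        p = coeffs.peaks_for(Pigment.CHLA)[0]
        assert p.solution_position == 432 and p.displacement == -13
        assert p.position == 419

    def test_serialization_round_trip(self, coeffs):
        restored = PigmentCoefficientSet.from_dict(coeffs.to_dict())
        assert restored.peaks == coeffs.peaks
        assert restored.grid == coeffs.grid
        assert restored.name == coeffs.name
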