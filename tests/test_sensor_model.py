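"""Fabry-Perot sensor model: fringe shape, bias optimization, thickness
tolerance, frequency response, NEP statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fpscan.sensor_model import (
    FPSensorSpec,
    frequency_response,
    itf_reflectance,
    lognormal_mode_fwhm_params,
    optimum_bias,
    sample_nep_map,
    thickness_tolerance,
)

SPEC = FPSensorSpec()        # 26.6 um sensor: F=76.6, V=0.78, FSR=26.6 nm


class TestITF:
    def test_periodic_in_fsr_to_machine_precision(self):
        wl = np.linspace(1540.0, 1560.0, 501)
        np.testing.assert_allclose(
            itf_reflectance(SPEC, wl),
            itf_reflectance(SPEC, wl + SPEC.fsr_nm),
            rtol=0, atol=1e-12,
        )

    def test_bounded_and_fringe_depth_matches_visibility(self):
        wl = np.linspace(1530.0, 1570.0, 20001)
        r = itf_reflectance(SPEC, wl)
        assert np.all((0 <= r) & (r <= 1))
        assert r.max() == pytest.approx(1.0, abs=1e-3)
        assert r.min() == pytest.approx(1.0 - SPEC.visibility, abs=1e-6)

    def test_resonance_is_extremum(self):
        eps = 1e-5
        r0 = itf_reflectance(SPEC, SPEC.resonance_wavelength_nm)
        assert itf_reflectance(SPEC, SPEC.resonance_wavelength_nm + eps) >= r0
        assert itf_reflectance(SPEC, SPEC.resonance_wavelength_nm - eps) >= r0

    def test_fringe_fwhm_by_bisection(self):
        # F = 76.6, FSR = 26.6 nm -> FWHM = FSR/F = 0.347 nm (the stated
        # ITF width is "> 0.35 nm" at its rounding)
        from scipy.optimize import brentq

        half = 1.0 - SPEC.visibility / 2.0
        lo = SPEC.resonance_wavelength_nm

        def f(wl):
            return itf_reflectance(SPEC, wl) - half

        right = brentq(f, lo, lo + SPEC.fsr_nm / 2)
        left = brentq(f, lo - SPEC.fsr_nm / 2, lo)
        fwhm = right - left
        assert fwhm == pytest.approx(26.6 / 76.6, rel=1e-3)
        assert fwhm == pytest.approx(0.347, abs=5e-3)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            FPSensorSpec(visibility=1.5)
        with pytest.raises(ValueError):
            FPSensorSpec(finesse=0.5)
        with pytest.raises(ValueError):
            FPSensorSpec(fsr_nm=-1)


class TestOptimumBias:
    def test_positive_slope_between_resonance_and_half_maximum(self):
        lb = optimum_bias(SPEC)
        assert lb > SPEC.resonance_wavelength_nm
        # half-maximum flank position
        half_width = SPEC.fringe_fwhm_nm / 2
        assert lb < SPEC.resonance_wavelength_nm + half_width
        eps = 1e-6
        slope = (
            itf_reflectance(SPEC, lb + eps) - itf_reflectance(SPEC, lb - eps)
        ) / (2 * eps)
        assert slope > 0

    def test_flat_itf_raises(self):
        with pytest.raises(ValueError, match="no fringe"):
            optimum_bias(FPSensorSpec(visibility=1e-15))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        spec = FPSensorSpec(
            finesse=float(rng.uniform(20, 120)),
            visibility=float(rng.uniform(0.3, 1.0)),
            fsr_nm=float(rng.uniform(15, 40)),
        )
        lb = optimum_bias(spec)
        grid = np.arange(
            spec.resonance_wavelength_nm,
            spec.resonance_wavelength_nm + spec.fsr_nm / 2,
            1e-4,
        )
        r = itf_reflectance(spec, grid)
        slope = np.gradient(r, grid)
        brute = grid[np.argmax(np.abs(slope))]
        assert lb == pytest.approx(brute, abs=2e-4)

    def test_sensitivity_parity_within_bias_tolerance(self):
        # a bias-wavelength spread < 0.08 nm across the beam array, with
        # the laser centred in the band (worst detuning +-0.04 nm on a
        # ~0.35 nm fringe), keeps |dR/dlambda| within ~90% of its peak
        spec = FPSensorSpec(finesse=76.6, fsr_nm=26.6)
        assert spec.fringe_fwhm_nm == pytest.approx(0.347, abs=5e-3)
        lb = optimum_bias(spec)
        eps = 1e-6

        def slope(wl):
            return abs(
                itf_reflectance(spec, wl + eps) - itf_reflectance(spec, wl - eps)
            ) / (2 * eps)

        ratio = min(slope(lb + 0.04), slope(lb - 0.04)) / slope(lb)
        assert ratio >= 0.85


class TestThicknessTolerance:
    def test_printed_multibeam_requirement(self):
        # l = 25 um, lambda_b = 1550 nm, dlambda_b = 0.08 nm -> 1.29 nm,
        # inside the dl < 1.3 nm uniformity requirement
        dl = thickness_tolerance(25.0, 1550.0, 0.08)
        assert dl == pytest.approx(1.29, abs=0.005)
        assert dl < 1.3

    @given(
        l=st.floats(1.0, 100.0),
        lb=st.floats(1400.0, 1700.0),
        dlb=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_bilinear_in_l_and_dlambda(self, l, lb, dlb):
        base = thickness_tolerance(l, lb, dlb)
        assert thickness_tolerance(2 * l, lb, dlb) == pytest.approx(2 * base)
        assert thickness_tolerance(l, lb, 2 * dlb) == pytest.approx(2 * base)
        assert thickness_tolerance(l, 2 * lb, dlb) == pytest.approx(base / 2)

    def test_zero_spread_gives_zero(self):
        assert thickness_tolerance(25.0, 1550.0, 0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            thickness_tolerance(25.0, 0.0, 0.08)
        with pytest.raises(ValueError):
            thickness_tolerance(-1.0, 1550.0, 0.08)


class TestFrequencyResponse:
    def test_passband_and_minus_3db_calibration(self):
        spec = FPSensorSpec(spacer_thickness_um=24.6, f3db_mhz=35.0)
        assert frequency_response(spec, 0.1) == pytest.approx(1.0, abs=1e-3)
        assert frequency_response(spec, 35.0) == pytest.approx(
            1.0 / np.sqrt(2.0), abs=1e-9
        )

    def test_monotone_decreasing_to_first_null(self):
        f = np.linspace(0.0, 35.0 / 0.443 * 0.99, 400)
        r = frequency_response(FPSensorSpec(f3db_mhz=35.0), f)
        assert np.all(np.diff(r) <= 1e-12)
        spec = FPSensorSpec(f3db_mhz=35.0)
        assert frequency_response(spec, 70.0) < frequency_response(spec, 35.0)


class TestNEPMap:
    def test_mode_and_fwhm_recovered_on_scan_size_grid(self):
        # 34,560-point scan grid; modal NEP 0.2 kPa, FWHM 0.25 kPa
        nep = sample_nep_map(192, 180, 0.2, 0.25, seed=1)
        assert nep.shape == (192, 180)
        assert np.all(nep > 0)
        hist, edges = np.histogram(nep, bins=np.arange(0.0, 1.5, 0.02))
        centres = 0.5 * (edges[:-1] + edges[1:])
        mode_est = centres[np.argmax(hist)]
        assert abs(mode_est - 0.2) / 0.2 < 0.10
        # FWHM from half-max crossings of the histogram
        half = hist.max() / 2
        above = np.flatnonzero(hist >= half)
        fwhm_est = centres[above[-1]] - centres[above[0]] + 0.02
        assert abs(fwhm_est - 0.25) / 0.25 < 0.15

    def test_parameterization_closed_form(self):
        scale, sigma = lognormal_mode_fwhm_params(0.2, 0.25)
        mode = scale * np.exp(-sigma**2)
        assert mode == pytest.approx(0.2, rel=1e-12)
        c = np.sqrt(2 * np.log(2))
        fwhm = mode * 2 * np.sinh(sigma * c)
        assert fwhm == pytest.approx(0.25, rel=1e-12)

    def test_degenerate_fwhm_limit_and_determinism(self):
        tight = sample_nep_map(64, 64, 0.2, 1e-6, seed=0)
        assert np.allclose(tight, 0.2, atol=1e-5)
        a = sample_nep_map(32, 32, 0.2, 0.25, seed=7)
        b = sample_nep_map(32, 32, 0.2, 0.25, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sample_nep_map(8, 8, -0.1, 0.25)
        with pytest.raises(ValueError):
            sample_nep_map(8, 8, 0.2, 0.0)
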