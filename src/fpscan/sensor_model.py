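"""Fabry-Perot ultrasound sensor model.

The acoustically sensitive element of the scanner is a thin polymer
Fabry-Perot interferometer (FPI).  An incident acoustic wave modulates the
optical thickness of the polymer spacer and hence the optical power
reflected from the cavity.  The sensor is interrogated at a *bias
wavelength* on the steep flank of an interferometer fringe, where the
derivative of the interferometer transfer function (ITF) -- reflected
power versus wavelength -- is largest and acoustic sensitivity maximal.

This module provides:

* an Airy-fringe model of the ITF parameterized by finesse, visibility and
  free spectral range (FSR);
* bias-wavelength optimization (peak-|dR/dlambda| search);
* the spacer-thickness uniformity tolerance ``dl = l * dlambda_b / lambda_b``
  required for a shared bias wavelength across a multibeam array;
* a sinc-magnitude acoustic frequency response calibrated to a stated
  -3 dB frequency;
* a log-normal spatial noise-equivalent-pressure (NEP) model
  parameterized by its histogram mode and FWHM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "FPSensorSpec",
    "itf_reflectance",
    "optimum_bias",
    "thickness_tolerance",
    "frequency_response",
    "sample_nep_map",
    "lognormal_mode_fwhm_params",
]


@dataclass(frozen=True)
class FPSensorSpec:
    """Optical and acoustic parameters of a Fabry-Perot ultrasound sensor.

    Parameters
    ----------
    spacer_thickness_um:
        Polymer spacer thickness ``l`` in micrometres.
    finesse:
        Reflectivity finesse ``F`` = FSR / fringe FWHM (dimensionless, > 1).
    visibility:
        Fringe visibility ``V`` in (0, 1]: fractional modulation depth of
        the reflected power across a fringe.
    fsr_nm:
        Free spectral range in nanometres.
    bias_wavelength_nm:
        Operating (interrogation) wavelength in nm.  May be ``None``; use
        :func:`optimum_bias` to compute the sensitivity-optimal value.
    resonance_wavelength_nm:
        Wavelength of the fringe reflectance minimum that anchors the ITF
        model.  Defaults to 1550 nm (centre of the interrogation band).
    f3db_mhz:
        Acoustic -3 dB frequency in MHz.
    nep_mode_kpa, nep_fwhm_kpa:
        Mode and FWHM of the spatial NEP distribution in kPa (over the
        20 MHz measurement band).
    band_lo_mhz, band_hi_mhz:
        Effective signal band applied in post-processing.
    refractive_index:
        Spacer refractive index; 1.66 (Parylene C near-IR) by default.
        Used only to derive the FSR from the spacer thickness when
        ``fsr_nm`` is not given explicitly.
    """

    spacer_thickness_um: float = 26.6
    finesse: float = 76.6
    visibility: float = 0.78
    fsr_nm: float = 26.6
    bias_wavelength_nm: float | None = 1550.0
    resonance_wavelength_nm: float = 1550.0
    f3db_mhz: float = 31.5
    nep_mode_kpa: float = 0.2
    nep_fwhm_kpa: float = 0.25
    band_lo_mhz: float = 0.05
    band_hi_mhz: float = 20.0
    refractive_index: float = 1.66

    def __post_init__(self) -> None:
        if self.spacer_thickness_um <= 0:
            raise ValueError("spacer thickness must be positive")
        if self.finesse <= 1:
            raise ValueError("finesse must exceed 1")
        if not 0 < self.visibility <= 1:
            raise ValueError("visibility must lie in (0, 1]")
        if self.fsr_nm <= 0:
            raise ValueError("FSR must be positive")
        if self.nep_mode_kpa <= 0 or self.nep_fwhm_kpa <= 0:
            raise ValueError("NEP mode and FWHM must be positive")

    @property
    def fringe_fwhm_nm(self) -> float:
        """Fringe full width at half maximum, FSR / finesse."""
        return self.fsr_nm / self.finesse

    @property
    def coefficient_of_finesse(self) -> float:
        """Airy coefficient of finesse, (2 F / pi)^2."""
        return (2.0 * self.finesse / math.pi) ** 2

    def with_bias(self, bias_nm: float) -> "FPSensorSpec":
        return replace(self, bias_wavelength_nm=bias_nm)


def itf_reflectance(spec: FPSensorSpec, wavelength_nm: np.ndarray | float):
    """Reflected-power fraction of the FP cavity at ``wavelength_nm``.

    The ITF is modelled as an Airy dip on a unit background, scaled by the
    fringe visibility::

        R(lambda) = 1 - V / (1 + F_c sin^2(pi (lambda - lambda_res) / FSR))

    with ``F_c = (2 F / pi)^2`` the coefficient of finesse.  The phase is
    linearized in wavelength so the model is exactly FSR-periodic, which
    is an excellent approximation over the few-FSR neighbourhood of the
    bias point where the sensor operates.  The fringe FWHM equals
    FSR / F to first order in 1/F.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    phase = np.pi * (wl - spec.resonance_wavelength_nm) / spec.fsr_nm
    airy = 1.0 / (1.0 + spec.coefficient_of_finesse * np.sin(phase) ** 2)
    out = 1.0 - spec.visibility * airy
    if np.isscalar(wavelength_nm):
        return float(out)
    return out


def _itf_derivative(spec: FPSensorSpec, wavelength_nm: np.ndarray | float):
    """Analytic dR/dlambda (per nm) of the Airy ITF model."""
    wl = np.asarray(wavelength_nm, dtype=float)
    fc = spec.coefficient_of_finesse
    phase = np.pi * (wl - spec.resonance_wavelength_nm) / spec.fsr_nm
    s, c = np.sin(phase), np.cos(phase)
    denom = (1.0 + fc * s**2) ** 2
    return spec.visibility * fc * 2.0 * s * c * (np.pi / spec.fsr_nm) / denom


def optimum_bias(spec: FPSensorSpec, refine_tol_nm: float = 1e-9) -> float:
    """Bias wavelength maximizing acoustic sensitivity |dR/dlambda|.

    Searches one free spectral range centred on the anchor resonance and
    refines the maximum of the ITF derivative by bounded scalar
    minimization.  Two symmetric solutions of opposite derivative sign
    exist per fringe; by convention the positive-slope flank (wavelength
    above the resonance minimum) is returned.

    Raises
    ------
    ValueError
        If the ITF is degenerate (visibility ~ 0, no fringe).
    """
    if spec.visibility < 1e-12:
        raise ValueError("no fringe: degenerate flat ITF (V = 0)")
    lo = spec.resonance_wavelength_nm
    hi = spec.resonance_wavelength_nm + 0.5 * spec.fsr_nm
    # coarse grid then bounded refinement of the positive-slope flank
    grid = np.linspace(lo, hi, 4001)
    d = _itf_derivative(spec, grid)
    i = int(np.argmax(d))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda wl: -_itf_derivative(spec, wl),
        bounds=(a, b),
        method="bounded",
        options={"xatol": refine_tol_nm},
    )
    return float(res.x)


def thickness_tolerance(l_um: float, bias_nm: float, dbias_nm: float) -> float:
    """Spacer thickness uniformity dl (nm) for a bias-wavelength spread.

    For all beams of a multibeam interrogation array to share a single
    bias wavelength, the spacer thickness may vary by at most
    ``dl = l * dlambda_b / lambda_b`` over the array footprint, where
    ``l`` is the spacer thickness and ``dlambda_b`` the tolerable bias
    wavelength variation.

    Parameters are ``l`` in um and wavelengths in nm; the result is in nm.
    """
    if l_um <= 0:
        raise ValueError("spacer thickness must be positive")
    if bias_nm <= 0:
        raise ValueError("bias wavelength must be positive")
    if dbias_nm < 0:
        raise ValueError("bias wavelength spread must be non-negative")
    return (l_um * 1e3) * dbias_nm / bias_nm


# fractional frequency x0 where sin(pi x)/(pi x) = 1/sqrt(2); the sinc
# response is calibrated so the -3 dB point lands exactly on f3db.
_SINC_3DB_ARG = brentq(lambda x: np.sinc(x) - 1.0 / math.sqrt(2.0), 0.1, 0.6)


def frequency_response(spec: FPSensorSpec, f_mhz: np.ndarray | float):
    """Normalized acoustic frequency response amplitude of the sensor.

    The finite spacer thickness averages the acoustic pressure through the
    film, giving a sinc-magnitude response.  The response is calibrated
    per sensor so that the amplitude at ``spec.f3db_mhz`` is exactly
    1/sqrt(2); this absorbs unmodelled details (overcoat loading, mirror
    stack) into the single stated -3 dB figure.
    """
    f = np.asarray(f_mhz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    amp = np.abs(np.sinc(_SINC_3DB_ARG * f / spec.f3db_mhz))
    if np.isscalar(f_mhz):
        return float(amp)
    return amp


def lognormal_mode_fwhm_params(mode: float, fwhm: float) -> tuple[float, float]:
    """(scale, sigma) of a log-normal with given density mode and FWHM.

    For ``X = s * exp(sigma * Z)`` the density mode is ``s * exp(-sigma^2)``
    and FWHM/mode = ``2 sinh(sigma * sqrt(2 ln 2))``, giving the closed
    form ``sigma = asinh(FWHM / (2 mode)) / sqrt(2 ln 2)``.
    """
    if mode <= 0 or fwhm <= 0:
        raise ValueError("mode and fwhm must be positive")
    c = math.sqrt(2.0 * math.log(2.0))
    sigma = math.asinh(fwhm / (2.0 * mode)) / c
    scale = mode * math.exp(sigma**2)
    return scale, sigma


def sample_nep_map(
    nx: int, ny: int, mode_kpa: float, fwhm_kpa: float, seed: int | None = None
) -> np.ndarray:
    """Sample a spatial NEP map (kPa) over an ``(nx, ny)`` scan grid.

    NEP varies across the sensor aperture because of residual spacer
    thickness non-uniformity.  The measured distribution is a skewed,
    strictly positive unimodal histogram; it is modelled log-normal with
    the requested density mode and FWHM (closed-form parameterization,
    see :func:`lognormal_mode_fwhm_params`).
    """
    scale, sigma = lognormal_mode_fwhm_params(mode_kpa, fwhm_kpa)
    rng = np.random.default_rng(seed)
    return scale * np.exp(sigma * rng.standard_normal((nx, ny)))
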