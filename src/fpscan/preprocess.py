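"""A-line conditioning before reconstruction.

Bandpass filtering (zero-phase Butterworth), Fourier spatial upsampling
of the detection grid, autofocus sound-speed estimation by maximizing a
sharpness metric of trial reconstructions, and post-reconstruction
exponential depth attenuation correction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, resample, sosfiltfilt

from .phantom import PressureVolume
from .forward_model import SensorTimeSeries

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "spatial_upsample",
    "autofocus_sound_speed",
    "attenuation_correction",
    "brenner_sharpness",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults for the preprocessing stage.

    ``band_hi_mhz`` is raised to 30 MHz in the high-resolution scan mode;
    the attenuation exponent ``mu`` (combined first-order optical +
    acoustic decay) lies in the 100-150 1/m range.
    """

    band_lo_mhz: float = 0.05
    band_hi_mhz: float = 20.0
    spatial_factor: int = 2
    mu_per_m: float = 120.0
    c_search_m_s: tuple[float, float] = (1350.0, 1700.0)

    def __post_init__(self) -> None:
        if not 0 < self.band_lo_mhz < self.band_hi_mhz:
            raise ValueError("require 0 < band_lo < band_hi")
        if self.spatial_factor not in (1, 2, 3):
            raise ValueError("spatial_factor must be 1, 2 or 3")
        if self.mu_per_m < 0:
            raise ValueError("mu must be non-negative")


def bandpass(
    data: SensorTimeSeries, band_lo_mhz: float = 0.05, band_hi_mhz: float = 20.0
) -> SensorTimeSeries:
    """Zero-phase 4th-order Butterworth bandpass along the time axis."""
    f_nyq_mhz = 1e3 / (2.0 * data.dt_ns)
    if not 0 < band_lo_mhz < band_hi_mhz:
        raise ValueError("require 0 < band_lo < band_hi")
    if band_hi_mhz >= f_nyq_mhz:
        raise ValueError(
            f"band_hi {band_hi_mhz} MHz must lie below Nyquist {f_nyq_mhz} MHz"
        )
    sos = butter(
        4, [band_lo_mhz / f_nyq_mhz, band_hi_mhz / f_nyq_mhz], btype="band",
        output="sos",
    )
    return dataclasses.replace(data, p=sosfiltfilt(sos, data.p, axis=2))


def spatial_upsample(data: SensorTimeSeries, factor: int) -> SensorTimeSeries:
    """Interpolate the detection grid onto a ``factor`` x finer pitch.

    Periodic-sinc (Fourier zero-padding) interpolation; original samples
    are reproduced exactly at their nodes.  Requires a fully sampled
    grid -- subsampled acquisitions go through the variational
    reconstruction instead, which handles the mask in the data term.
    """
    if factor not in (1, 2, 3):
        raise ValueError("factor must be 1, 2 or 3")
    if not data.fully_sampled:
        raise ValueError(
            "spatial_upsample requires a full grid; reconstruct subsampled "
            "data with recon_cs.reconstruct_tv"
        )
    if factor == 1:
        return data.copy()
    nx, ny, _ = data.p.shape
    up = resample(data.p, factor * nx, axis=0)
    up = resample(up, factor * ny, axis=1)
    return dataclasses.replace(
        data,
        p=up,
        dx_um=data.dx_um / factor,
        dy_um=data.dy_um / factor,
        mask=np.ones((factor * nx, factor * ny), dtype=bool),
    )


def brenner_sharpness(vol: np.ndarray) -> float:
    """Brenner gradient of the volume's depth-axis envelope magnitude."""
    env = np.abs(vol)
    d = env[:, :, 2:] - env[:, :, :-2]
    return float(np.sum(d * d))


def autofocus_sound_speed(
    data: SensorTimeSeries,
    c_range_m_s: tuple[float, float] = (1350.0, 1700.0),
    coarse_step_m_s: float = 25.0,
    metric=brenner_sharpness,
    nz: int | None = None,
) -> float:
    """Estimate tissue sound speed by autofocus.

    Reconstructs the volume over a coarse grid of candidate speeds,
    scores each with a sharpness ``metric`` (Brenner gradient of the
    envelope by default), then refines the best candidate by
    golden-section search over the bracketing interval.  On feature-less
    (pure noise) data the metric is flat; a warning is emitted and the
    range midpoint returned.
    """
    from .recon_kspace import ReconConfig, reconstruct_kspace

    c_lo, c_hi = c_range_m_s
    cs = np.arange(c_lo, c_hi + 0.5 * coarse_step_m_s, coarse_step_m_s)

    def score(c: float) -> float:
        cfg = ReconConfig(c_m_s=float(c), post_interp=1)
        vol = reconstruct_kspace(data, cfg, nz=nz)
        return metric(vol.p0)

    scores = np.array([score(c) for c in cs])
    spread = scores.max() - scores.min()
    if spread <= 1e-6 * abs(scores.max()):
        warnings.warn("autofocus metric is flat; returning range midpoint")
        return 0.5 * (c_lo + c_hi)
    i = int(np.argmax(scores))
    a = cs[max(i - 1, 0)]
    b = cs[min(i + 1, cs.size - 1)]
    # golden-section refinement on the bracketing interval
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = score(x1), score(x2)
    while b - a > 1.0:                       # 1 m/s refinement tolerance
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = score(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = score(x1)
    return float(0.5 * (a + b))


def attenuation_correction(vol: PressureVolume, mu_per_m: float = 120.0) -> PressureVolume:
    """First-order depth attenuation correction.

    Multiplies each voxel by exp(mu * z) with z the depth below the
    sensor plane in metres, compensating the combined optical fluence
    and acoustic attenuation decay.  Exactly inverted by the negative
    exponent.
    """
    if mu_per_m < 0:
        raise ValueError("mu must be non-negative")
    gain = np.exp(mu_per_m * vol.z_coords_um * 1e-6)
    return dataclasses.replace(vol, p0=vol.p0 * gain[None, None, :])
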