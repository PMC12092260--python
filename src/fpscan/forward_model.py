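"""Homogeneous-medium planar acoustic forward model and exact adjoint.

An initial pressure distribution p0(x, y, z) released at t = 0 in a
homogeneous free-field medium propagates as

    p(r, t) = IFFT3[ P0(k) cos(c |k| t) ](r),

and the planar sensor records p at z = 0.  The operator is realized
spectrally: the 3D FFT of p0 is folded over +-kz (cosine propagation is
even in kz), each (kx, ky, kz) mode is assigned its temporal frequency
omega = c sqrt(kx^2 + ky^2 + kz^2) by linear interpolation onto the
regular FFT frequency grid of a zero-padded time axis, and inverse FFTs
over (omega -> t) and (kx, ky -> x, y) yield the time series.  The
time axis is padded to twice the requested length so the acausal mirror
of the cosine propagator (which wraps to the end of the periodic window)
is cropped away.

Because every step is a (sparse or unitary-scaled) linear map, the exact
numerical adjoint is the reversed chain of transposes; the adjoint
identity <A x, y> = <x, A^T y> holds to machine precision, which is the
foundation the iterative variational reconstruction rests on.

All propagating modes are real (omega = c|k| always); modes whose
frequency exceeds the temporal Nyquist of the sampled window cannot be
represented and are dropped (not aliased).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantom import PressureVolume
from .units import c_um_per_ns

__all__ = [
    "SensorTimeSeries",
    "PlanarOperator",
    "forward_planar",
    "adjoint_planar",
    "apply_sensor_bandwidth",
]


@dataclass
class SensorTimeSeries:
    """Pressure time series p(x, y, t) on the planar detection grid.

    ``p`` is indexed [x, y, t] (kPa); ``mask`` flags measured A-lines.
    """

    p: np.ndarray
    dx_um: float
    dy_um: float
    dt_ns: float
    mask: np.ndarray | None = None
    c_m_s: float = 1500.0

    def __post_init__(self) -> None:
        if self.dt_ns <= 0:
            raise ValueError("dt must be positive")
        if self.p.ndim != 3:
            raise ValueError("p must be indexed [x, y, t]")
        if self.mask is None:
            self.mask = np.ones(self.p.shape[:2], dtype=bool)
        if self.mask.shape != self.p.shape[:2]:
            raise ValueError("mask shape must equal the spatial grid shape")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("pressure data must be finite")

    @property
    def nt(self) -> int:
        return self.p.shape[2]

    @property
    def fully_sampled(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "SensorTimeSeries":
        return dataclasses.replace(self, p=self.p.copy(), mask=self.mask.copy())


def _keys_cubic(f: np.ndarray) -> tuple[np.ndarray, ...]:
    """Keys cubic-convolution interpolation weights (a = -1/2) for a
    fractional position ``f`` in [0, 1), taps at offsets -1, 0, 1, 2."""
    f2, f3 = f * f, f * f * f
    return (
        -0.5 * f + f2 - 0.5 * f3,
        1.0 - 2.5 * f2 + 1.5 * f3,
        0.5 * f + 2.0 * f2 - 1.5 * f3,
        -0.5 * f2 + 0.5 * f3,
    )


class PlanarOperator:
    """Matched forward/adjoint pair A, A^T for a fixed geometry.

    Maps a p0 volume of shape ``vol_shape`` with voxel ``voxel_um`` onto
    sensor time series of ``nt`` samples at ``dt_ns`` for sound speed
    ``c_m_s``.  The lateral grid of the volume and the sensor coincide.
    """

    def __init__(
        self,
        vol_shape: tuple[int, int, int],
        voxel_um: tuple[float, float, float],
        dt_ns: float,
        nt: int,
        c_m_s: float,
    ):
        self.vol_shape = tuple(vol_shape)
        self.voxel_um = tuple(float(v) for v in voxel_um)
        self.dt_ns = float(dt_ns)
        self.nt = int(nt)
        self.c_m_s = float(c_m_s)
        nx, ny, nz = self.vol_shape
        dx, dy, dz = self.voxel_um
        c = c_um_per_ns(c_m_s)                      # um/ns
        self.ntp = 4 * self.nt
        # the volume is zero-padded axially so the acausal mirror of the
        # cosine propagator (a periodic copy below the sensor plane)
        # arrives after the cropped time window
        self.nzp = 2 * nz
        self.nzh = self.nzp // 2 + 1

        kx = 2.0 * np.pi * np.fft.fftfreq(nx, dx)   # rad/um
        ky = 2.0 * np.pi * np.fft.fftfreq(ny, dy)
        kz = 2.0 * np.pi * np.arange(self.nzh) / (self.nzp * dz)
        kpar2 = kx[:, None] ** 2 + ky[None, :] ** 2
        dom = 2.0 * np.pi / (self.ntp * self.dt_ns)

        # Every axial mode radiates a single temporal frequency
        # omega = c|k|; it is scattered onto the two neighbouring bins of
        # the regular frequency grid with linearly interpolated,
        # phase-rotated weights.  The rotation references the centre of
        # the time window t_c so the two-bin surrogate reproduces
        # cos(omega t) accurately across the cropped window instead of
        # beating against it; the 4x temporal padding keeps the residual
        # phase mismatch at the window edges below pi/8.
        omega = c * np.sqrt(kpar2[:, :, None] + kz[None, None, :] ** 2)
        b = omega / dom
        i0 = np.floor(b).astype(np.int64)
        frac = b - i0
        half = 0.5 / self.nzp                        # 1/nzp ifft norm, cos split
        t_c = 0.5 * self.nt * self.dt_ns

        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        chan = (ix * ny + iy)[:, :, None]            # lateral channel index
        cols = chan * self.nzh + np.arange(self.nzh)[None, None, :]
        rows, ccols, vals = [], [], []
        representable = b <= self.ntp // 2           # modes beyond temporal
        for off, wk in zip((-1, 0, 1, 2), _keys_cubic(frac)):  # Nyquist dropped
            bin_idx = i0 + off
            valid = representable & (bin_idx >= 0) & (bin_idx <= self.ntp // 2)
            w = half * wk * np.exp(1j * (frac - off) * dom * t_c)
            for mirrored in (False, True):
                r = (self.ntp - bin_idx) % self.ntp if mirrored else bin_idx
                rows.append((chan * self.ntp + r)[valid])
                ccols.append(cols[valid])
                vals.append((np.conj(w) if mirrored else w)[valid])
        self._B = sp.csr_matrix(
            (
                np.concatenate(vals),
                (np.concatenate(rows), np.concatenate(ccols)),
            ),
            shape=(nx * ny * self.ntp, nx * ny * self.nzh),
        )
        self._BH = self._B.conjugate().transpose().tocsr()

    # -- kz folding (cosine propagation is even in kz) -------------------

    def _fold(self, P0: np.ndarray) -> np.ndarray:
        nzp = self.nzp
        S = np.empty(P0.shape[:2] + (self.nzh,), dtype=complex)
        S[..., 0] = P0[..., 0]
        S[..., 1:self.nzh - 1] = (
            P0[..., 1:self.nzh - 1] + P0[..., :-(self.nzh - 1):-1]
        )
        S[..., nzp // 2] = P0[..., nzp // 2]
        return S

    def _unfold(self, S: np.ndarray) -> np.ndarray:
        nx, ny, _ = self.vol_shape
        P0 = np.zeros((nx, ny, self.nzp), dtype=complex)
        P0[..., 0] = S[..., 0]
        P0[..., 1:self.nzh - 1] = S[..., 1:self.nzh - 1]
        P0[..., :-(self.nzh - 1):-1] = S[..., 1:self.nzh - 1]
        P0[..., self.nzp // 2] = S[..., self.nzp // 2]
        return P0

    # -- operator application --------------------------------------------

    def forward(self, p0: np.ndarray) -> np.ndarray:
        """A: p0 volume -> (nx, ny, nt) sensor time series."""
        if p0.shape != self.vol_shape:
            raise ValueError(f"expected volume shape {self.vol_shape}")
        nx, ny, nz = self.vol_shape
        pz = np.zeros((nx, ny, self.nzp), dtype=p0.dtype)
        pz[..., :nz] = p0
        S = self._fold(np.fft.fftn(pz))
        H = (self._B @ S.ravel()).reshape(nx, ny, self.ntp)
        q = np.fft.ifft(H, axis=2) * self.ntp
        return np.real(np.fft.ifft2(q[..., : self.nt], axes=(0, 1)))

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """A^T: (nx, ny, nt) time series -> p0 volume (exact transpose)."""
        nx, ny, nz = self.vol_shape
        if y.shape != (nx, ny, self.nt):
            raise ValueError(f"expected data shape {(nx, ny, self.nt)}")
        Y = np.fft.fft2(y, axes=(0, 1)) / (nx * ny)
        Yp = np.zeros((nx, ny, self.ntp), dtype=complex)
        Yp[..., : self.nt] = Y
        H = np.fft.fft(Yp, axis=2)
        S = (self._BH @ H.ravel()).reshape(nx, ny, self.nzh)
        P0 = self._unfold(S)
        vol = np.real(np.fft.ifftn(P0) * (nx * ny * self.nzp))
        return vol[..., :nz]


def forward_planar(
    p0: PressureVolume, c_m_s: float, dt_ns: float, nt: int
) -> SensorTimeSeries:
    """Simulate planar sensor data from an initial pressure volume.

    The temporal window must cover the deepest source:
    ``nt * dt * c >= max source depth``.
    """
    nz = p0.shape[2]
    occupied = np.flatnonzero(np.any(p0.p0 != 0, axis=(0, 1)))
    max_depth_um = occupied[-1] * p0.dz_um if occupied.size else 0.0
    window_um = nt * dt_ns * c_um_per_ns(c_m_s)
    if window_um < max_depth_um:
        need = int(np.ceil(max_depth_um / (dt_ns * c_um_per_ns(c_m_s))))
        raise ValueError(
            f"temporal window too short: nt={nt} covers {window_um:.0f} um "
            f"but sources extend to {max_depth_um:.0f} um; need nt >= {need}"
        )
    # spectral validity: the padded axis places a mirror copy of each
    # source at 2 nz dz - z; the window must end before it arrives
    wrap_um = 2 * nz * p0.dz_um - max_depth_um
    if window_um > wrap_um:
        limit = int(np.floor(wrap_um / (dt_ns * c_um_per_ns(c_m_s))))
        raise ValueError(
            f"temporal window nt={nt} extends into the axial wrap-around "
            f"(first mirror arrival at {wrap_um:.0f} um); use nt <= {limit} "
            f"or a deeper volume"
        )
    op = PlanarOperator(p0.shape, (p0.dx_um, p0.dy_um, p0.dz_um), dt_ns, nt, c_m_s)
    data = op.forward(p0.p0)
    return SensorTimeSeries(
        p=data, dx_um=p0.dx_um, dy_um=p0.dy_um, dt_ns=dt_ns, c_m_s=c_m_s
    )


def adjoint_planar(
    data: SensorTimeSeries,
    c_m_s: float,
    volume_shape: tuple[int, int, int],
    dz_um: float | None = None,
) -> PressureVolume:
    """Exact adjoint of :func:`forward_planar` composed with the mask
    projection (unmeasured A-lines are zero-filled)."""
    nx, ny, _ = data.p.shape
    if volume_shape[:2] != (nx, ny):
        raise ValueError("volume lateral shape must match the data grid")
    dz = dz_um if dz_um is not None else c_um_per_ns(c_m_s) * data.dt_ns
    op = PlanarOperator(
        volume_shape, (data.dx_um, data.dy_um, dz), data.dt_ns, data.nt, c_m_s
    )
    y = np.where(data.mask[:, :, None], data.p, 0.0)
    vol = op.adjoint(y)
    return PressureVolume(vol, data.dx_um, data.dy_um, dz)


def apply_sensor_bandwidth(data: SensorTimeSeries, spec) -> SensorTimeSeries:
    """Filter every A-line by the sensor's acoustic frequency response.

    Applies the sinc-magnitude spacer response (see
    :func:`fpscan.sensor_model.frequency_response`) together with a
    second-order 50 kHz high-pass magnitude, as a zero-phase spectral
    multiplication.  Requires the sampling to resolve the sensor band
    (Nyquist > f3db).
    """
    from .sensor_model import frequency_response

    f_nyq_mhz = 1e3 / (2.0 * data.dt_ns)
    if spec.f3db_mhz >= f_nyq_mhz:
        raise ValueError(
            f"Nyquist {f_nyq_mhz:.1f} MHz does not resolve sensor "
            f"f3db {spec.f3db_mhz:.1f} MHz"
        )
    nt = data.nt
    f_mhz = np.fft.rfftfreq(nt, data.dt_ns) * 1e3
    resp = frequency_response(spec, f_mhz)
    x = (f_mhz / spec.band_lo_mhz) ** 2
    resp = resp * (x / np.sqrt(1.0 + x * x))        # 50 kHz low-frequency cut
    spec_t = np.fft.rfft(data.p, axis=2) * resp
    return dataclasses.replace(data, p=np.fft.irfft(spec_t, n=nt, axis=2))
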