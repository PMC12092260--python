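"""Planar forward operator: adjoint identity, arrival kinematics,
spherical-source waveform oracle, sensor bandwidth filtering."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from fpscan.forward_model import (
    PlanarOperator,
    SensorTimeSeries,
    adjoint_planar,
    apply_sensor_bandwidth,
    forward_planar,
)
from fpscan.phantom import PressureVolume, point_line_targets
from fpscan.sensor_model import FPSensorSpec

C = 1500.0
DT = 100.0 / 3.0        # 33.33 ns -> dz = c dt = 50 um


class TestAdjoint:
    def test_dot_product_identity(self, rng):
        op = PlanarOperator((16, 16, 24), (100.0, 100.0, 50.0), DT, 48, C)
        for _ in range(5):
            x = rng.standard_normal((16, 16, 24))
            y = rng.standard_normal((16, 16, 48))
            lhs = float(np.sum(op.forward(x) * y))
            rhs = float(np.sum(x * op.adjoint(y)))
            assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), abs(rhs))

    def test_adjoint_linearity(self, rng):
        op = PlanarOperator((8, 8, 16), (100.0, 100.0, 50.0), DT, 32, C)
        y = rng.standard_normal((8, 8, 32))
        a = op.adjoint(3.0 * y)
        b = 3.0 * op.adjoint(y)
        assert np.max(np.abs(a - b)) < 1e-12 * np.max(np.abs(b))

    def test_masked_adjoint_zero_fills(self, rng):
        data = SensorTimeSeries(
            p=rng.standard_normal((8, 8, 32)), dx_um=100.0, dy_um=100.0,
            dt_ns=DT, c_m_s=C,
        )
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        data.mask = mask
        full = adjoint_planar(data, C, (8, 8, 16))
        zeroed = data.copy()
        zeroed.p[~mask] = 0.0
        zeroed.mask = np.ones((8, 8), dtype=bool)
        ref = adjoint_planar(zeroed, C, (8, 8, 16))
        np.testing.assert_allclose(full.p0, ref.p0, atol=1e-12)

    def test_adjoint_of_point_data_peaks_at_source(self):
        # time-of-flight backprojection: A^T applied to clean point data
        # concentrates at the true source voxel
        pv = point_line_targets((32, 32, 64), (100.0, 100.0, 50.0),
                                points_um=[(1600.0, 1600.0, 1500.0)])
        data = forward_planar(pv, C, DT, 64)
        bp = adjoint_planar(data, C, (32, 32, 64))
        ix, iy, iz = np.unravel_index(np.argmax(bp.p0), bp.p0.shape)
        assert (ix, iy) == (16, 16)
        assert abs(iz - 30) <= 1


class TestKinematics:
    def test_on_axis_arrival_time(self):
        # source at 5 mm depth, c = 1500 m/s: t = z/c = 3.33 us
        pv = point_line_targets((64, 64, 128), (100.0, 100.0, 50.0),
                                points_um=[(3200.0, 3200.0, 5000.0)])
        data = forward_planar(pv, C, DT, 128)
        peak = np.argmax(np.abs(data.p[32, 32]))
        assert abs(peak - 100) <= 1

    def test_off_axis_euclidean_arrival(self):
        pv = point_line_targets((64, 64, 128), (100.0, 100.0, 50.0),
                                points_um=[(3200.0, 3200.0, 5000.0)])
        data = forward_planar(pv, C, DT, 128)
        expect = np.hypot(3000.0, 5000.0) / (1.5 * DT)
        peak = np.argmax(np.abs(data.p[62, 32]))
        assert abs(peak - expect) <= 1.5

    def test_causality_no_signal_before_first_arrival(self):
        # band-limited ball source (a bare single-voxel delta is
        # dominated by super-Nyquist content and its truncation ringing)
        x = np.arange(32)[:, None, None]
        y = np.arange(32)[None, :, None]
        z = np.arange(96)[None, None, :]
        ball = np.exp(-(((x - 16) / 2.5) ** 2 + ((y - 16) / 2.5) ** 2
                        + ((z - 60) / 2.5) ** 2))
        pv = PressureVolume(ball, 100.0, 100.0, 50.0)
        data = forward_planar(pv, C, DT, 96)
        tr = data.p[16, 16]
        early = np.abs(tr[:48]).max()        # arrival at sample 60
        assert early < 0.02 * np.abs(tr).max()

    def test_linearity_of_superposition(self):
        a = point_line_targets((16, 16, 48), (100.0, 100.0, 50.0),
                               points_um=[(400.0, 400.0, 1000.0)])
        b = point_line_targets((16, 16, 48), (100.0, 100.0, 50.0),
                               points_um=[(1200.0, 800.0, 2000.0)])
        both = PressureVolume(a.p0 + b.p0, 100.0, 100.0, 50.0)
        da = forward_planar(a, C, DT, 48)
        db = forward_planar(b, C, DT, 48)
        dboth = forward_planar(both, C, DT, 48)
        np.testing.assert_allclose(dboth.p, da.p + db.p, atol=1e-10)

    def test_window_too_short_names_required_nt(self):
        pv = point_line_targets((16, 16, 64), (100.0, 100.0, 50.0),
                                points_um=[(400.0, 400.0, 3000.0)])
        with pytest.raises(ValueError, match="need nt >= 60"):
            forward_planar(pv, C, DT, 32)

    def test_window_into_wrap_around_rejected(self):
        pv = point_line_targets((16, 16, 64), (100.0, 100.0, 50.0),
                                points_um=[(400.0, 400.0, 3000.0)])
        # mirror of the 3 mm source sits at 2*3.2 - 3.0 = 3.4 mm
        with pytest.raises(ValueError, match="wrap-around"):
            forward_planar(pv, C, DT, 80)


class TestSphericalSourceOracle:
    def test_n_wave_matches_closed_form(self):
        # uniform (soft-edged) sphere, radius 0.3 mm at 4 mm depth: the
        # on-axis pressure is the N-wave p = (d - ct) f(|d - ct|) / 2d,
        # with f the radial amplitude profile; compared after identical
        # band-limiting, within 5% L2
        cc = C * 1e-3
        dt, dx = 15.0, 30.0
        dz = cc * dt
        nx, d_um, a_um = 128, 4000.0, 300.0
        nz = int((d_um + 700.0) / dz)
        x = (np.arange(nx) - nx // 2)[:, None, None] * dx
        y = (np.arange(nx) - nx // 2)[None, :, None] * dx
        z = np.arange(nz)[None, None, :] * dz
        r = np.sqrt(x**2 + y**2 + (z - d_um) ** 2)
        h = 2.0 * max(dx, dz)
        p0 = np.clip((a_um + h / 2 - r) / h, 0.0, 1.0)
        nt = int((d_um + a_um) / (cc * dt)) + 10
        data = forward_planar(PressureVolume(p0, dx, dx, dz), C, dt, nt)
        tr = data.p[nx // 2, nx // 2]
        t = np.arange(nt) * dt
        rad = np.abs(d_um - cc * t)
        f = np.clip((a_um + h / 2 - rad) / h, 0.0, 1.0)
        exact = (d_um - cc * t) * f / (2 * d_um)
        ny_mhz = 0.5 / dt * 1e3
        sos = butter(4, [0.05 / ny_mhz, 10.0 / ny_mhz], btype="band",
                     output="sos")
        a = sosfiltfilt(sos, tr)
        b = sosfiltfilt(sos, exact)
        err = np.linalg.norm(a - b) / np.linalg.norm(b)
        assert err < 0.05


class TestSensorBandwidth:
    SPEC = FPSensorSpec(spacer_thickness_um=24.6, f3db_mhz=35.0)

    @staticmethod
    def _impulse(nt=512, dt=10.0):
        p = np.zeros((4, 4, nt))
        p[:, :, nt // 2] = 1.0
        return SensorTimeSeries(p=p, dx_um=100.0, dy_um=100.0, dt_ns=dt)

    def test_impulse_spectrum_minus_3db_at_f3db(self):
        out = apply_sensor_bandwidth(self._impulse(), self.SPEC)
        spec = np.abs(np.fft.rfft(out.p[0, 0]))
        f_mhz = np.fft.rfftfreq(512, 10.0) * 1e3
        i35 = np.argmin(np.abs(f_mhz - 35.0))
        ref = spec[np.argmin(np.abs(f_mhz - 5.0))]   # in-band reference
        assert spec[i35] / ref == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_zero_in_zero_out_and_multiplicativity(self):
        d = self._impulse()
        zeros = SensorTimeSeries(p=np.zeros_like(d.p), dx_um=100.0,
                                 dy_um=100.0, dt_ns=10.0)
        assert not apply_sensor_bandwidth(zeros, self.SPEC).p.any()
        once = apply_sensor_bandwidth(d, self.SPEC)
        twice = apply_sensor_bandwidth(once, self.SPEC)
        spec1 = np.fft.rfft(once.p[0, 0])
        spec2 = np.fft.rfft(twice.p[0, 0])
        spec0 = np.fft.rfft(d.p[0, 0])
        np.testing.assert_allclose(
            spec2 * spec0, spec1**2, atol=1e-10
        )

    def test_nyquist_violation_rejected(self):
        d = self._impulse(dt=16.67)          # Nyquist 30 MHz < 35 MHz
        with pytest.raises(ValueError, match="Nyquist"):
            apply_sensor_bandwidth(d, self.SPEC)
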