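"""Synthetic phantoms: rasterization fidelity, layered scenes, dynamics,
noise injection."""

import numpy as np
import pytest

from fpscan.forward_model import SensorTimeSeries
from fpscan.phantom import (
    BranchingParams,
    PressureVolume,
    VesselTree,
    add_sensor_noise,
    layered_skin_phantom,
    occlusion_reperfusion_sequence,
    point_line_targets,
    pulsatile_radius,
    vessel_tree_phantom,
)


class TestVesselTree:
    def test_straight_tube_tortuosity_is_one(self):
        tree = VesselTree(
            [np.array([[100.0, 500.0, 500.0], [900.0, 500.0, 500.0]])],
            [50.0], [10.0],
        )
        assert tree.tortuosity(0) == pytest.approx(1.0)

    def test_rasterized_volume_matches_cylinder_formula(self):
        # single unbranched tube, no junction overlap: integrated
        # coverage should match pi r^2 L within 10%
        t = np.linspace(0, 1, 40)
        pts = np.stack(
            [400 + 3200 * t, 1200 + 800 * np.sin(2 * np.pi * t), 2000 + 600 * t],
            axis=1,
        )
        tree = VesselTree([pts], [150.0], [1.0])
        from fpscan.phantom import _rasterize_tubes

        vol = _rasterize_tubes((80, 80, 80), (50.0, 50.0, 50.0), tree)
        measured = vol.sum() * 50.0**3
        assert measured == pytest.approx(tree.analytic_volume_um3(), rel=0.10)

    def test_deterministic_under_seed(self):
        a, _ = vessel_tree_phantom((32, 32, 64), 50.0, (0.5, 2.8), seed=4)
        b, _ = vessel_tree_phantom((32, 32, 64), 50.0, (0.5, 2.8), seed=4)
        np.testing.assert_array_equal(a.p0, b.p0)

    def test_linear_in_amplitude(self):
        bp1 = BranchingParams(amplitude_kpa=10.0)
        bp2 = BranchingParams(amplitude_kpa=20.0)
        a, _ = vessel_tree_phantom((32, 32, 64), 50.0, (0.5, 2.8),
                                   branching=bp1, seed=4)
        b, _ = vessel_tree_phantom((32, 32, 64), 50.0, (0.5, 2.8),
                                   branching=bp2, seed=4)
        np.testing.assert_allclose(b.p0, 2 * a.p0, atol=1e-12)

    def test_nonnegative_and_ground_truth_returned(self):
        pv, tree = vessel_tree_phantom((32, 32, 64), 50.0, (0.5, 2.8), seed=1)
        assert np.all(pv.p0 >= 0)
        assert len(tree.segments) == len(tree.radii_um)
        assert tree.total_length_um() > 0

    def test_volume_too_small_for_radius(self):
        with pytest.raises(ValueError, match="too small"):
            vessel_tree_phantom(
                (8, 8, 8), 20.0, (0.05, 0.1),
                branching=BranchingParams(root_radius_um=500.0),
            )


class TestLayeredSkin:
    def test_slab_thickness_in_voxel_planes(self):
        pv, _, slab = layered_skin_phantom(
            (32, 32, 64), 50.0, epidermis_thickness_um=200.0,
            surface_depth_um=400.0, depth_range_mm=(0.8, 2.8), seed=2,
        )
        planes = np.flatnonzero(slab.any(axis=(0, 1)))
        assert planes.size == 4                      # 200 um / 50 um
        assert planes[0] == 8                        # 400 um down
        assert np.all(pv.p0[:, :, 8:12] >= 5.0)

    def test_zero_amplitude_slab_is_pure_vessel_phantom(self):
        a, _, _ = layered_skin_phantom(
            (32, 32, 64), 50.0, epidermis_amplitude_kpa=0.0,
            depth_range_mm=(0.8, 2.8), seed=2,
        )
        b, _ = vessel_tree_phantom((32, 32, 64), 50.0, (0.8, 2.8), seed=2)
        np.testing.assert_array_equal(a.p0, b.p0)

    def test_too_thin_slab_rejected(self):
        with pytest.raises(ValueError):
            layered_skin_phantom((32, 32, 64), 50.0, epidermis_thickness_um=10.0)


class TestPointLineTargets:
    def test_single_point_is_single_voxel(self):
        pv = point_line_targets((32, 32, 128), 50.0,
                                points_um=[(800.0, 800.0, 5000.0)])
        assert np.count_nonzero(pv.p0) == 1
        assert pv.p0[16, 16, 100] == 1.0

    def test_superposition_linearity(self):
        p1 = point_line_targets((16, 16, 32), 50.0, points_um=[(200, 200, 400)])
        p2 = point_line_targets((16, 16, 32), 50.0, points_um=[(600, 600, 800)])
        both = point_line_targets(
            (16, 16, 32), 50.0, points_um=[(200, 200, 400), (600, 600, 800)]
        )
        np.testing.assert_array_equal(both.p0, p1.p0 + p2.p0)

    def test_line_grid_spans_requested_depths(self):
        depths = [1000.0, 4000.0, 8000.0, 12000.0]
        lines = [((400.0, 200.0, z), (400.0, 3000.0, z)) for z in depths]
        pv = point_line_targets((64, 64, 256), 50.0, lines_um=lines)
        occupied = np.flatnonzero(pv.p0.any(axis=(0, 1))) * 50.0
        for z in depths:
            assert np.any(np.abs(occupied - z) <= 50.0)

    def test_out_of_volume_target_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            point_line_targets((16, 16, 16), 50.0, points_um=[(0, 0, 5000.0)])


class TestOcclusionReperfusion:
    @pytest.fixture
    def scene(self):
        base = PressureVolume(np.zeros((16, 16, 32)), 50, 50, 50)
        labels = np.zeros((16, 16, 32), dtype=int)
        labels[:, :, 4:6] = 1          # epidermis
        labels[2:6, 2:6, 10:14] = 2    # digital artery
        labels[8:12, 2:6, 14:18] = 3   # vein 1
        labels[8:12, 8:12, 18:22] = 4  # vein 2
        base.p0[labels > 0] = 10.0
        return base, labels

    def test_epidermis_constant_vessels_ramp_in_onset_order(self, scene):
        base, labels = scene
        onsets = {2: 5.0, 3: 5.8, 4: 6.6}
        frames, times = occlusion_reperfusion_sequence(
            base, labels, t_occlusion_end_s=5.0, onsets_s=onsets,
            ramp_s=2.5, fps=10.0, duration_s=12.0, constant_labels=(1,),
        )
        epi = np.array([f.p0[labels == 1].mean() for f in frames])
        assert np.ptp(epi) == 0.0
        # each vascular ROI attains >= 95% of baseline within its ramp
        for lab, onset in onsets.items():
            series = np.array([f.p0[labels == lab].mean() for f in frames])
            after = series[times >= onset + 2.5]
            assert np.all(after >= 0.95 * 10.0)
            before = series[times < 5.0]
            assert np.all(before <= 0.21 * 10.0)
        # 50%-crossing order follows the onsets (arterial first)
        crossings = {
            lab: times[
                np.argmax(
                    np.array([f.p0[labels == lab].mean() for f in frames])
                    > 5.0
                )
            ]
            for lab in onsets
        }
        assert crossings[2] < crossings[3] < crossings[4]

    def test_onset_before_occlusion_end_rejected(self, scene):
        base, labels = scene
        with pytest.raises(ValueError, match="precedes"):
            occlusion_reperfusion_sequence(
                base, labels, t_occlusion_end_s=5.0, onsets_s={2: 4.0}
            )


class TestSensorNoise:
    @staticmethod
    def _series(nx=8, ny=8, nt=10000, dt=16.67):
        return SensorTimeSeries(
            p=np.zeros((nx, ny, nt)), dx_um=108.0, dy_um=108.0, dt_ns=dt
        )

    def test_zero_nep_leaves_data_unchanged(self):
        d = self._series()
        out = add_sensor_noise(d, np.zeros((8, 8)), seed=0)
        np.testing.assert_array_equal(out.p, d.p)

    def test_in_band_rms_matches_nep(self):
        # NEP is defined over a 20 MHz measurement band
        d = self._series()
        nep = np.full((8, 8), 0.2)
        out = add_sensor_noise(d, nep, seed=1)
        spec = np.fft.rfft(out.p, axis=2)
        f_mhz = np.fft.rfftfreq(d.nt, d.dt_ns) * 1e3
        in_band = f_mhz <= 20.0
        # Parseval: band RMS from the in-band spectral power
        band_rms = np.sqrt(
            (np.abs(spec[:, :, in_band]) ** 2).sum(axis=2) / d.nt**2 * 2
        )
        assert np.allclose(band_rms, 0.2, rtol=0.05)

    def test_doubling_nep_halves_snr(self):
        d = self._series(nt=2000)
        a = add_sensor_noise(d, np.full((8, 8), 0.2), seed=3)
        b = add_sensor_noise(d, np.full((8, 8), 0.4), seed=3)
        np.testing.assert_allclose(b.p, 2 * a.p, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        d = self._series()
        with pytest.raises(ValueError, match="does not match"):
            add_sensor_noise(d, np.zeros((4, 4)), seed=0)


def test_pulsatile_radius_modulation():
    t = np.linspace(0, 2, 400)
    r = pulsatile_radius(500.0, t, freq_hz=70 / 60, epsilon=0.05)
    assert r.max() == pytest.approx(525.0, rel=1e-3)
    assert r.min() == pytest.approx(475.0, rel=1e-3)
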