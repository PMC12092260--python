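"""Synthetic initial-pressure phantoms.

Numerical stand-ins for the scenes the scanner images in vivo: branching
vessel trees embedded in a layered skin-like volume (a superficial
absorbing epidermal slab above dermal/subdermal vasculature), point and
line targets for resolution probing, and time-varying sequences
(occlusion--reperfusion ROI dynamics, pulsatile vessels).  Phantom
amplitudes are initial pressures p0 in kPa directly; optical fluence and
acoustic attenuation are deliberately not modelled.

Every generator is deterministic under a seed and returns the analytic
ground truth (centrelines, radii, ROI schedules) alongside the voxel
grid, so downstream quantitation can be tested against closed-form
oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PressureVolume",
    "VesselTree",
    "BranchingParams",
    "vessel_tree_phantom",
    "layered_skin_phantom",
    "point_line_targets",
    "occlusion_reperfusion_sequence",
    "pulsatile_radius",
    "add_sensor_noise",
]


@dataclass
class PressureVolume:
    """Initial pressure p0(x, y, z) on a regular voxel grid.

    ``p0`` is indexed [x, y, z] with z the depth axis (z = 0 at the
    sensor plane); spacings are in um, pressures in kPa.
    """

    p0: np.ndarray
    dx_um: float
    dy_um: float
    dz_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.dx_um, self.dy_um, self.dz_um) <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.p0.ndim != 3:
            raise ValueError("p0 must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.p0.shape

    @property
    def z_coords_um(self) -> np.ndarray:
        return self.origin_um[2] + np.arange(self.p0.shape[2]) * self.dz_um

    def copy(self) -> "PressureVolume":
        return dataclasses.replace(self, p0=self.p0.copy())


@dataclass
class VesselTree:
    """Ground-truth vessel geometry: per-segment centreline polylines
    (um coordinates), radii and initial-pressure amplitudes."""

    segments: list[np.ndarray]
    radii_um: list[float]
    amplitudes_kpa: list[float]

    def __post_init__(self) -> None:
        for seg, r in zip(self.segments, self.radii_um):
            if seg.shape[0] < 2:
                raise ValueError("polylines need at least 2 points")
            if r <= 0:
                raise ValueError("radii must be positive")

    def segment_length_um(self, i: int) -> float:
        d = np.diff(self.segments[i], axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    def total_length_um(self) -> float:
        return sum(self.segment_length_um(i) for i in range(len(self.segments)))

    def analytic_volume_um3(self) -> float:
        """Sum of cylinder volumes pi r^2 L over segments (ignores joints)."""
        return sum(
            np.pi * r**2 * self.segment_length_um(i)
            for i, r in enumerate(self.radii_um)
        )

    def tortuosity(self, i: int) -> float:
        """Arc length over endpoint chord for segment ``i``."""
        seg = self.segments[i]
        chord = float(np.linalg.norm(seg[-1] - seg[0]))
        if chord == 0:
            raise ValueError("coincident endpoints: tortuosity undefined")
        return self.segment_length_um(i) / chord


@dataclass(frozen=True)
class BranchingParams:
    """Recursive binary branching model parameters."""

    root_radius_um: float = 150.0
    radius_decay: float = 0.79          # ~Murray's law 2^(-1/3)
    n_levels: int = 3
    step_um: float = 250.0
    steps_per_segment: tuple[int, int] = (8, 16)
    curvature_sigma_rad: float = 0.15   # direction jitter per step
    branch_angle_rad: float = 0.5
    amplitude_kpa: float = 10.0


def _rasterize_tubes(
    shape: tuple[int, int, int],
    voxel_um: tuple[float, float, float],
    tree: VesselTree,
) -> np.ndarray:
    """Anti-aliased tube rasterization.

    Voxel value = amplitude * coverage, where coverage ramps linearly
    from 1 to 0 over a one-voxel band around the tube surface (soft
    edge), evaluated from the exact distance of the voxel centre to the
    centreline.  Overlapping tubes combine by maximum so junctions do
    not exceed the segment amplitude; scaling all amplitudes by a common
    factor scales the volume linearly.
    """
    vol = np.zeros(shape)
    dx, dy, dz = voxel_um
    h = float(np.mean(voxel_um))        # soft-edge width
    spacing = np.array(voxel_um)
    for seg, radius, amp in zip(tree.segments, tree.radii_um, tree.amplitudes_kpa):
        for a, b in zip(seg[:-1], seg[1:]):
            lo = np.minimum(a, b) - (radius + h)
            hi = np.maximum(a, b) + (radius + h)
            i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
            i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, shape)
            if np.any(i0 >= i1):
                continue
            xs = (np.arange(i0[0], i1[0]) * dx)[:, None, None]
            ys = (np.arange(i0[1], i1[1]) * dy)[None, :, None]
            zs = (np.arange(i0[2], i1[2]) * dz)[None, None, :]
            ab = b - a
            L2 = float(ab @ ab)
            if L2 == 0:
                continue
            # projection parameter of each voxel centre onto the segment
            t = ((xs - a[0]) * ab[0] + (ys - a[1]) * ab[1] + (zs - a[2]) * ab[2]) / L2
            t = np.clip(t, 0.0, 1.0)
            d2 = (
                (xs - (a[0] + t * ab[0])) ** 2
                + (ys - (a[1] + t * ab[1])) ** 2
                + (zs - (a[2] + t * ab[2])) ** 2
            )
            cov = np.clip((radius + 0.5 * h - np.sqrt(d2)) / h, 0.0, 1.0)
            sub = vol[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
            np.maximum(sub, amp * cov, out=sub)
    return vol


def _grow_tree(
    shape, voxel_um, depth_range_um, n_roots, params: BranchingParams, rng
) -> VesselTree:
    dx, dy, dz = voxel_um
    extent = np.array([shape[0] * dx, shape[1] * dy, shape[2] * dz])
    z_lo, z_hi = depth_range_um
    z_hi = min(z_hi, extent[2] - 2 * dz)
    segments, radii, amps = [], [], []

    def random_unit(bias: np.ndarray) -> np.ndarray:
        v = bias + 0.6 * rng.standard_normal(3)
        return v / np.linalg.norm(v)

    def grow(start, direction, radius, level):
        if level > params.n_levels or radius < 2 * min(voxel_um):
            return
        n_steps = rng.integers(*params.steps_per_segment)
        pts = [start.copy()]
        d = direction.copy()
        for _ in range(n_steps):
            # smooth random curvature: jitter the heading, renormalize
            d = d + params.curvature_sigma_rad * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            nxt = pts[-1] + params.step_um * d
            # reflect off lateral walls and the depth band
            for ax, (lo, hi) in enumerate(
                [(dx, extent[0] - 2 * dx), (dy, extent[1] - 2 * dy), (z_lo, z_hi)]
            ):
                if nxt[ax] < lo or nxt[ax] > hi:
                    d[ax] = -d[ax]
                    nxt[ax] = np.clip(nxt[ax], lo, hi)
            pts.append(nxt)
        seg = np.asarray(pts)
        segments.append(seg)
        radii.append(radius)
        amps.append(params.amplitude_kpa)
        if level < params.n_levels:
            end = seg[-1]
            d_end = seg[-1] - seg[-2]
            d_end /= np.linalg.norm(d_end)
            for sign in (+1, -1):
                # rotate heading by +-branch_angle in a random plane
                perp = np.cross(d_end, random_unit(d_end))
                if np.linalg.norm(perp) < 1e-9:
                    perp = np.array([0.0, 0.0, 1.0])
                perp /= np.linalg.norm(perp)
                ang = sign * params.branch_angle_rad * (0.7 + 0.6 * rng.random())
                child = np.cos(ang) * d_end + np.sin(ang) * perp
                grow(end, child, radius * params.radius_decay, level + 1)

    for _ in range(n_roots):
        start = np.array(
            [
                rng.uniform(0.15, 0.85) * extent[0],
                rng.uniform(0.15, 0.85) * extent[1],
                rng.uniform(z_lo, 0.5 * (z_lo + z_hi)),
            ]
        )
        heading = random_unit(np.array([1.0, 0.2, 0.3]))
        grow(start, heading, params.root_radius_um, 1)
    return VesselTree(segments, radii, amps)


def vessel_tree_phantom(
    volume_shape: tuple[int, int, int],
    voxel_um: float | tuple[float, float, float],
    depth_range_mm: tuple[float, float] = (0.5, 15.0),
    n_roots: int = 2,
    branching: BranchingParams | None = None,
    seed: int | None = None,
) -> tuple[PressureVolume, VesselTree]:
    """Random branching vessel tree rasterized into a voxel grid.

    Returns both the :class:`PressureVolume` and the generating
    :class:`VesselTree` ground truth.  Deterministic under ``seed``.
    """
    if np.isscalar(voxel_um):
        voxel_um = (float(voxel_um),) * 3
    if min(voxel_um) <= 0:
        raise ValueError("voxel size must be positive")
    branching = branching or BranchingParams()
    min_dim_um = min(s * v for s, v in zip(volume_shape, voxel_um))
    if 2 * branching.root_radius_um > min_dim_um:
        raise ValueError("volume too small for the requested root radius")
    depth_lo = depth_range_mm[0] * 1e3
    depth_hi = depth_range_mm[1] * 1e3
    if depth_lo >= volume_shape[2] * voxel_um[2]:
        raise ValueError("depth range lies outside the volume")
    rng = np.random.default_rng(seed)
    tree = _grow_tree(volume_shape, voxel_um, (depth_lo, depth_hi), n_roots,
                      branching, rng)
    vol = _rasterize_tubes(volume_shape, voxel_um, tree)
    pv = PressureVolume(vol, *voxel_um)
    return pv, tree


def layered_skin_phantom(
    volume_shape: tuple[int, int, int],
    voxel_um: float | tuple[float, float, float],
    epidermis_thickness_um: float = 200.0,
    epidermis_amplitude_kpa: float = 5.0,
    surface_depth_um: float = 400.0,
    depth_range_mm: tuple[float, float] = (0.5, 15.0),
    n_roots: int = 2,
    branching: BranchingParams | None = None,
    seed: int | None = None,
) -> tuple[PressureVolume, VesselTree, np.ndarray]:
    """Layered skin-like scene: superficial absorbing slab + vessel tree.

    The epidermal slab (melanin contrast, predominantly avascular) is a
    uniform layer of the stated thickness starting at ``surface_depth_um``
    below the sensor plane; the vessel tree occupies the depth band below
    it.  Returns (volume, tree ground truth, boolean epidermis mask).
    """
    if np.isscalar(voxel_um):
        voxel_um = (float(voxel_um),) * 3
    if epidermis_thickness_um < voxel_um[2]:
        raise ValueError("epidermis thinner than one voxel plane")
    pv, tree = vessel_tree_phantom(
        volume_shape, voxel_um, depth_range_mm, n_roots, branching, seed
    )
    z0 = int(round(surface_depth_um / voxel_um[2]))
    n_planes = int(round(epidermis_thickness_um / voxel_um[2]))
    slab = np.zeros(volume_shape, dtype=bool)
    slab[:, :, z0:z0 + n_planes] = True
    pv.p0[slab] = np.maximum(pv.p0[slab], epidermis_amplitude_kpa)
    return pv, tree, slab


def point_line_targets(
    volume_shape: tuple[int, int, int],
    voxel_um: float | tuple[float, float, float],
    points_um: list[tuple[float, float, float]] = (),
    lines_um: list[tuple[tuple, tuple]] = (),
    amplitude_kpa: float = 1.0,
    line_radius_um: float | None = None,
) -> PressureVolume:
    """Delta (single-voxel) and thin-line targets for PSF/resolution tests.

    Point contributions add linearly; a point exactly on a grid node
    occupies exactly one voxel.
    """
    if np.isscalar(voxel_um):
        voxel_um = (float(voxel_um),) * 3
    vol = np.zeros(volume_shape)
    spacing = np.array(voxel_um)
    for p in points_um:
        idx = np.round(np.asarray(p, dtype=float) / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= volume_shape):
            raise ValueError(f"target {p} um lies outside the volume")
        vol[tuple(idx)] += amplitude_kpa
    if lines_um:
        r = line_radius_um if line_radius_um is not None else 0.5 * min(voxel_um)
        tree = VesselTree(
            [np.array([a, b], dtype=float) for a, b in lines_um],
            [r] * len(lines_um),
            [amplitude_kpa] * len(lines_um),
        )
        for a, b in lines_um:
            for p in (a, b):
                if np.any(np.asarray(p) < 0) or np.any(
                    np.asarray(p) / spacing >= volume_shape
                ):
                    raise ValueError(f"line endpoint {p} um outside the volume")
        vol += _rasterize_tubes(volume_shape, voxel_um, tree)
    return PressureVolume(vol, *voxel_um)


def _reperfusion_factor(t, onset_s, ramp_s, occluded_factor):
    """Smoothstep ramp from the occluded level back to baseline."""
    u = np.clip((t - onset_s) / ramp_s, 0.0, 1.0)
    s = u * u * (3.0 - 2.0 * u)
    return occluded_factor + (1.0 - occluded_factor) * s


def occlusion_reperfusion_sequence(
    base: PressureVolume,
    roi_labels: np.ndarray,
    t_occlusion_end_s: float,
    onsets_s: dict[int, float],
    ramp_s: float = 2.5,
    fps: float = 16.7,
    duration_s: float = 12.0,
    occluded_factor: float = 0.2,
    constant_labels: tuple[int, ...] = (),
) -> tuple[list[PressureVolume], np.ndarray]:
    """Time-varying cuff occlusion / reperfusion scene.

    Vascular ROIs (integer labels with an entry in ``onsets_s``) sit at
    ``occluded_factor`` of baseline while the cuff is inflated, then ramp
    smoothly back to baseline starting at their individual onset times --
    arterial supply first, downstream veins later.  Labels listed in
    ``constant_labels`` (the epidermis, whose melanin contrast is
    non-vascular) and the unlabelled background stay constant.

    Returns (frames, frame_times_s).
    """
    if ramp_s <= 0:
        raise ValueError("ramp must be positive")
    for label, onset in onsets_s.items():
        if onset < t_occlusion_end_s:
            raise ValueError(
                f"ROI {label} onset {onset}s precedes occlusion end "
                f"{t_occlusion_end_s}s"
            )
    if roi_labels.shape != base.p0.shape:
        raise ValueError("roi_labels shape must match the volume")
    times = np.arange(int(round(duration_s * fps))) / fps
    frames = []
    for t in times:
        scale = np.ones_like(base.p0)
        for label, onset in onsets_s.items():
            scale[roi_labels == label] = _reperfusion_factor(
                t, onset, ramp_s, occluded_factor
            )
        frames.append(dataclasses.replace(base, p0=base.p0 * scale))
    return frames, times


def pulsatile_radius(
    r0_um: float, t_s: np.ndarray | float, freq_hz: float, epsilon: float = 0.05
) -> np.ndarray | float:
    """Sinusoidal arterial radius modulation r(t) = r0 (1 + eps sin 2pi f t)."""
    return r0_um * (1.0 + epsilon * np.sin(2.0 * np.pi * freq_hz * np.asarray(t_s)))


def add_sensor_noise(data, nep_map_kpa: np.ndarray, seed: int | None = None,
                     measurement_band_mhz: float = 20.0):
    """Add per-channel Gaussian noise matching a spatial NEP map.

    The NEP is defined as the RMS noise within the stated measurement
    band (20 MHz).  White Gaussian noise over the full sampled band is
    scaled so that its in-band RMS equals each channel's NEP: for a
    Nyquist frequency ``f_N >= band``, the total noise standard deviation
    is ``NEP * sqrt(f_N / band)``.

    ``data`` is a :class:`~fpscan.forward_model.SensorTimeSeries`; a new
    instance is returned.
    """
    if nep_map_kpa.shape != data.p.shape[:2]:
        raise ValueError(
            f"nep_map shape {nep_map_kpa.shape} does not match scan grid "
            f"{data.p.shape[:2]}"
        )
    f_nyq_mhz = 1.0 / (2.0 * data.dt_ns) * 1e3
    boost = np.sqrt(max(f_nyq_mhz / measurement_band_mhz, 1.0))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(data.p.shape) * (
        nep_map_kpa[:, :, None] * boost
    )
    return dataclasses.replace(data, p=data.p + noise)
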