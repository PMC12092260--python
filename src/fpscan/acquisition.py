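"""Multibeam scan patterns and acquisition timing.

The planar sensor is read out by scanning an array of ``N = rows x cols``
focused interrogation beams across its surface, one step per excitation
laser pulse, so the A-line rate is ``N x PRF``.  The beam pitch (324 um)
is an integer multiple of the detection-grid step (108 or 54 um), so each
beam cell is tiled by an integer number of sub-steps and a full raster
covers every grid node exactly once.  Randomized non-overlapping scan
orders permute the pulse positions (the rigid beam array is never split),
which is what makes compressed-sensing subsampling and sliding-window
dynamic imaging possible: any prefix or window of the acquisition order
is a spatially quasi-uniform random subset of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BeamArrayLayout",
    "ScanPattern",
    "AcquisitionTiming",
    "aline_rate",
    "scan_time",
    "raster_scan_pattern",
    "random_scan_pattern",
    "subsample_mask",
    "frame_schedule_2d",
    "sliding_window_frames",
]


@dataclass(frozen=True)
class BeamArrayLayout:
    """Geometry of the focused interrogation beam array."""

    rows: int = 4
    cols: int = 16
    pitch_um: float = 324.0
    spot_diameter_um: float = 49.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("beam array must have at least one beam")
        if self.pitch_um <= 0:
            raise ValueError("beam pitch must be positive")

    @property
    def n_beams(self) -> int:
        return self.rows * self.cols

    @property
    def footprint_um2(self) -> float:
        """Rectangular area occupied by the beam array."""
        return (self.cols * self.pitch_um) * (self.rows * self.pitch_um)


@dataclass
class ScanPattern:
    """Ordered interrogation positions over a regular detection grid.

    ``positions[order[i]]`` is the i-th A-line acquired; ``aline_times``
    and ``mask`` are indexed in *acquisition* order.  A-lines acquired on
    the same laser pulse share a timestamp.
    """

    nx: int
    ny: int
    dx_um: float
    dy_um: float
    positions: np.ndarray          # (n, 2) grid-node coordinates, um
    order: np.ndarray              # (n,) permutation of node indices
    aline_times_s: np.ndarray      # (n,) acquisition time per A-line
    mask: np.ndarray               # (n,) bool, in acquisition order
    n_beams: int = 1
    prf_hz: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of node indices")
        if np.any(np.diff(self.aline_times_s) < 0):
            raise ValueError("aline_times must be non-decreasing")

    @property
    def n_alines(self) -> int:
        return int(self.positions.shape[0])

    @property
    def scan_time_s(self) -> float:
        """Duration of the (possibly subsampled) acquisition."""
        n_kept = int(self.mask.sum())
        return n_kept / aline_rate(self.n_beams, self.prf_hz)

    def node_mask_2d(self) -> np.ndarray:
        """Boolean (nx, ny) map of measured grid nodes."""
        m = np.zeros((self.nx, self.ny), dtype=bool)
        kept = self.order[self.mask]
        ix = np.round(self.positions[kept, 0] / self.dx_um).astype(int)
        iy = np.round(self.positions[kept, 1] / self.dy_um).astype(int)
        m[ix, iy] = True
        return m


@dataclass(frozen=True)
class AcquisitionTiming:
    """PRF-limited acquisition timing summary."""

    prf_hz: float
    n_beams: int
    efficiency: float = 1.0

    @property
    def aline_rate_hz(self) -> float:
        return aline_rate(self.n_beams, self.prf_hz, self.efficiency)

    def scan_time_s(self, n_alines: int) -> float:
        return scan_time(n_alines, self.aline_rate_hz)


def aline_rate(n_beams: int, prf_hz: float, efficiency: float = 1.0) -> float:
    """A-line rate eta * N * PRF (A-lines per second).

    ``efficiency`` (eta in (0, 1]) is an explicit dead-time factor; it
    defaults to 1 and is never applied silently.
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if prf_hz <= 0:
        raise ValueError("PRF must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must lie in (0, 1]")
    return efficiency * n_beams * prf_hz


def scan_time(n_alines: int, aline_rate_hz: float) -> float:
    """Total scan time T = n_alines / A-line rate (seconds)."""
    if aline_rate_hz <= 0:
        raise ValueError("aline_rate must be positive")
    return n_alines / aline_rate_hz


def _tiling(nx: int, ny: int, dx_um: float, dy_um: float, layout: BeamArrayLayout):
    """Integer tiling of the detection grid by the rigid beam array.

    The beam pitch must be an integer multiple ``s`` of the grid step on
    each axis; each beam then rasters an s x s cell of sub-steps
    (row-major sub-step order), and the array footprint is stepped across
    the grid to cover it without overlap.
    """
    sx = layout.pitch_um / dx_um
    sy = layout.pitch_um / dy_um
    if abs(sx - round(sx)) > 1e-9 or abs(sy - round(sy)) > 1e-9:
        raise ValueError(
            f"beam pitch {layout.pitch_um} um must be an integer multiple of "
            f"the grid step (dx={dx_um}, dy={dy_um} um)"
        )
    sx, sy = int(round(sx)), int(round(sy))
    cell_x = layout.cols * sx   # grid nodes per array placement, x
    cell_y = layout.rows * sy
    if nx % cell_x or ny % cell_y:
        raise ValueError(
            f"grid ({nx} x {ny}) must be divisible by the array coverage "
            f"({cell_x} x {cell_y} nodes = cols*pitch/dx x rows*pitch/dy)"
        )
    return sx, sy, cell_x, cell_y


def _pulse_positions(nx, ny, dx_um, dy_um, layout):
    """Node indices measured by each laser pulse, raster pulse order.

    Returns an (n_pulses, N) int array of flat node indices (ix * ny + iy).
    """
    sx, sy, cell_x, cell_y = _tiling(nx, ny, dx_um, dy_um, layout)
    px, py = nx // cell_x, ny // cell_y
    bx = np.arange(layout.cols) * sx          # beam column offsets (nodes)
    by = np.arange(layout.rows) * sy
    pulses = []
    for gy in range(py):                      # array placements, slow axis
        for gx in range(px):
            for uy in range(sy):              # sub-steps, row-major
                for ux in range(sx):
                    ix = gx * cell_x + bx[:, None] + ux   # (cols, 1)
                    iy = gy * cell_y + by[None, :] + uy   # (1, rows)
                    pulses.append((ix * ny + iy).ravel())
    return np.asarray(pulses)


def _pattern_from_pulses(nx, ny, dx_um, dy_um, layout, prf_hz, pulse_nodes, seed):
    n_pulses, n_beams = pulse_nodes.shape
    order = pulse_nodes.ravel()
    xs = (order // ny) * dx_um
    ys = (order % ny) * dy_um
    positions = np.empty((nx * ny, 2))
    positions[order, 0] = xs
    positions[order, 1] = ys
    times = np.repeat(np.arange(n_pulses) / prf_hz, n_beams)
    return ScanPattern(
        nx=nx, ny=ny, dx_um=dx_um, dy_um=dy_um,
        positions=positions, order=order, aline_times_s=times,
        mask=np.ones(nx * ny, dtype=bool),
        n_beams=layout.n_beams, prf_hz=prf_hz, seed=seed,
    )


def raster_scan_pattern(
    nx: int, ny: int, dx_um: float, dy_um: float,
    layout: BeamArrayLayout | None = None, prf_hz: float = 100.0,
) -> ScanPattern:
    """Deterministic raster scan covering every grid node exactly once."""
    layout = layout or BeamArrayLayout()
    pulses = _pulse_positions(nx, ny, dx_um, dy_um, layout)
    return _pattern_from_pulses(nx, ny, dx_um, dy_um, layout, prf_hz, pulses, None)


def random_scan_pattern(
    nx: int, ny: int, dx_um: float, dy_um: float,
    layout: BeamArrayLayout | None = None, prf_hz: float = 100.0,
    seed: int | None = None,
) -> ScanPattern:
    """Non-overlapping random scan: pulse positions visited in uniformly
    random order, beams within a pulse rigid.  Covers the identical node
    set as the raster pattern."""
    layout = layout or BeamArrayLayout()
    pulses = _pulse_positions(nx, ny, dx_um, dy_um, layout)
    rng = np.random.default_rng(seed)
    pulses = pulses[rng.permutation(pulses.shape[0])]
    return _pattern_from_pulses(nx, ny, dx_um, dy_um, layout, prf_hz, pulses, seed)


def subsample_mask(pattern: ScanPattern, fraction: float) -> ScanPattern:
    """Keep only the earliest-acquired ``fraction`` of A-lines.

    This mirrors how subsampled data sets are formed in practice: the
    first 12.5/25/50% of the recorded data are extracted from the fully
    sampled acquisition, so the scan time scales by the same fraction.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = int(round(fraction * pattern.n_alines))
    mask = np.zeros(pattern.n_alines, dtype=bool)
    mask[:n_keep] = True
    return replace(pattern, mask=mask)


def frame_schedule_2d(
    line_length_mm: float, step_um: float,
    layout: BeamArrayLayout | None = None, prf_hz: float = 200.0,
) -> tuple[float, float]:
    """(frame_time_s, fps) for the 2D video-rate line-scan mode.

    The beam array's long axis is aligned with the scan line; one frame
    comprises ``(line_length / step) * rows`` A-lines acquired at
    ``N * PRF``.  The frame rate is floored to one decimal.
    """
    layout = layout or BeamArrayLayout()
    if step_um > line_length_mm * 1e3:
        raise ValueError("step exceeds line length")
    n_steps = line_length_mm * 1e3 / step_um
    if abs(n_steps - round(n_steps)) > 0.05 * n_steps:
        raise ValueError("line length must be an integral number of steps")
    n_steps = int(round(n_steps))
    n_alines = n_steps * layout.rows
    frame_time = n_alines / aline_rate(layout.n_beams, prf_hz)
    fps = np.floor(10.0 / frame_time) / 10.0
    return frame_time, float(fps)


def sliding_window_frames(
    n_total_alines: int, window: int, advance_fraction: float
) -> list[tuple[int, int]]:
    """Sliding-window frame index ranges over a continuous acquisition.

    The window advances by ``round(advance_fraction * window)`` A-lines
    per frame; each frame reuses the remainder of the previous window, so
    the refresh frame rate is ``aline_rate / advance``.  Final windows are
    truncated at the end of the data, giving ``n_total / advance`` frames.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 < advance_fraction <= 1:
        raise ValueError("advance_fraction must lie in (0, 1]")
    if window > n_total_alines:
        raise ValueError("window exceeds total A-line count")
    advance = int(round(advance_fraction * window))
    frames = []
    start = 0
    while start < n_total_alines:
        frames.append((start, min(start + window, n_total_alines)))
        start += advance
    return frames
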