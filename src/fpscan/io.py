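"""File formats, rendering and provenance.

One HDF5 container ("scan file", schema v1) holds all pipeline
intermediates -- sensor time series, scan pattern, pressure volumes --
with units encoded in attribute names.  TIFF and NIfTI are export-only.
Maximum intensity projections (greyscale and depth-to-colour) follow the
display conventions of planar PAT: linear intensity scale, hue encoding
the depth of the maximizing voxel.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .acquisition import ScanPattern
from .forward_model import SensorTimeSeries
from .phantom import PressureVolume

__all__ = [
    "SCHEMA_VERSION",
    "RenderSpec",
    "save_scan_file",
    "load_scan_file",
    "mip",
    "depth_colour_mip",
    "export_tiff",
    "export_nifti",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RenderSpec:
    """Projection request for MIP rendering.

    ``axis`` names the projection plane; slab bounds are in mm along the
    projected-out axis (None = full thickness).  Intensity mapping is
    always linear from black (0) to white (1).
    """

    axis: str = "x-y"
    slab_mm: tuple[float, float] | None = None
    mode: str = "greyscale"

    def __post_init__(self) -> None:
        if self.axis not in ("x-y", "x-z", "y-z"):
            raise ValueError("axis must be one of x-y, x-z, y-z")
        if self.mode not in ("greyscale", "depth-to-colour"):
            raise ValueError("mode must be greyscale or depth-to-colour")


def _content_hash(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def save_scan_file(
    path,
    sensor: SensorTimeSeries | None = None,
    pattern: ScanPattern | None = None,
    p0: PressureVolume | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a schema-v1 scan file."""
    import h5py

    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        if seed is not None:
            meta.attrs["seed"] = seed
        if config is not None:
            meta.attrs["config_json"] = json.dumps(config, sort_keys=True)
        hashes = []
        if sensor is not None:
            g = f.create_group("sensor")
            g.create_dataset("p", data=sensor.p)
            g.create_dataset("mask", data=sensor.mask)
            g.attrs["dx_um"] = sensor.dx_um
            g.attrs["dy_um"] = sensor.dy_um
            g.attrs["dt_ns"] = sensor.dt_ns
            g.attrs["c_hint_m_s"] = sensor.c_m_s
            hashes.append(_content_hash(sensor.p))
        if pattern is not None:
            g = f.create_group("scan")
            g.create_dataset("positions", data=pattern.positions)
            g.create_dataset("order", data=pattern.order)
            g.create_dataset("mask", data=pattern.mask)
            g.create_dataset("aline_times", data=pattern.aline_times_s)
            g.attrs["nx"] = pattern.nx
            g.attrs["ny"] = pattern.ny
            g.attrs["dx_um"] = pattern.dx_um
            g.attrs["dy_um"] = pattern.dy_um
            g.attrs["prf_hz"] = pattern.prf_hz
            g.attrs["n_beams"] = pattern.n_beams
            if pattern.seed is not None:
                g.attrs["seed"] = pattern.seed
            hashes.append(_content_hash(pattern.order))
        if p0 is not None:
            g = f.create_group("p0")
            g.create_dataset("p0", data=p0.p0)
            g.attrs["dx_um"] = p0.dx_um
            g.attrs["dy_um"] = p0.dy_um
            g.attrs["dz_um"] = p0.dz_um
            g.attrs["origin_um"] = p0.origin_um
            hashes.append(_content_hash(p0.p0))
        meta.attrs["content_hash"] = "-".join(hashes)


def load_scan_file(path) -> dict:
    """Read a schema-v1 scan file back into pipeline objects.

    Returns a dict with any of the keys ``sensor``, ``pattern``, ``p0``,
    ``config``, ``seed``.  Unknown schema versions are refused.
    """
    import h5py

    out: dict = {}
    with h5py.File(path, "r") as f:
        version = int(f["meta"].attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported scan-file schema version {version} "
                f"(this build reads version {SCHEMA_VERSION})"
            )
        if "config_json" in f["meta"].attrs:
            out["config"] = json.loads(f["meta"].attrs["config_json"])
        if "seed" in f["meta"].attrs:
            out["seed"] = int(f["meta"].attrs["seed"])
        if "sensor" in f:
            g = f["sensor"]
            out["sensor"] = SensorTimeSeries(
                p=g["p"][()],
                dx_um=float(g.attrs["dx_um"]),
                dy_um=float(g.attrs["dy_um"]),
                dt_ns=float(g.attrs["dt_ns"]),
                mask=g["mask"][()],
                c_m_s=float(g.attrs["c_hint_m_s"]),
            )
        if "scan" in f:
            g = f["scan"]
            out["pattern"] = ScanPattern(
                nx=int(g.attrs["nx"]),
                ny=int(g.attrs["ny"]),
                dx_um=float(g.attrs["dx_um"]),
                dy_um=float(g.attrs["dy_um"]),
                positions=g["positions"][()],
                order=g["order"][()],
                aline_times_s=g["aline_times"][()],
                mask=g["mask"][()],
                n_beams=int(g.attrs["n_beams"]),
                prf_hz=float(g.attrs["prf_hz"]),
                seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
            )
        if "p0" in f:
            g = f["p0"]
            out["p0"] = PressureVolume(
                p0=g["p0"][()],
                dx_um=float(g.attrs["dx_um"]),
                dy_um=float(g.attrs["dy_um"]),
                dz_um=float(g.attrs["dz_um"]),
                origin_um=tuple(g.attrs["origin_um"]),
            )
    return out


_AXIS_OF = {"x-y": 2, "x-z": 1, "y-z": 0}


def _slab_slices(vol: PressureVolume, spec: RenderSpec):
    proj_ax = _AXIS_OF[spec.axis]
    sl = [slice(None)] * 3
    if spec.slab_mm is not None:
        spacing = (vol.dx_um, vol.dy_um, vol.dz_um)[proj_ax]
        lo = int(np.floor(spec.slab_mm[0] * 1e3 / spacing))
        hi = int(np.ceil(spec.slab_mm[1] * 1e3 / spacing))
        if hi <= lo or lo >= vol.p0.shape[proj_ax]:
            raise ValueError("empty slab")
        sl[proj_ax] = slice(max(lo, 0), hi)
    return tuple(sl), proj_ax


def mip(vol: PressureVolume, spec: RenderSpec | None = None) -> np.ndarray:
    """Maximum intensity projection within the requested slab."""
    spec = spec or RenderSpec()
    sl, proj_ax = _slab_slices(vol, spec)
    return vol.p0[sl].max(axis=proj_ax)


def depth_colour_mip(
    vol: PressureVolume, spec: RenderSpec | None = None, colormap: str = "viridis"
) -> np.ndarray:
    """Depth-to-colour encoded MIP (RGB).

    Hue encodes the depth of the maximizing voxel along the projection
    axis; value (brightness) encodes its intensity on a linear scale.
    The intensity channel equals the greyscale MIP.
    """
    import matplotlib

    spec = spec or RenderSpec(mode="depth-to-colour")
    sl, proj_ax = _slab_slices(vol, spec)
    sub = vol.p0[sl]
    intensity = sub.max(axis=proj_ax)
    depth_idx = sub.argmax(axis=proj_ax)
    n = max(sub.shape[proj_ax] - 1, 1)
    rgb = matplotlib.colormaps[colormap](depth_idx / n)[..., :3]
    vmax = intensity.max()
    scale = intensity / vmax if vmax > 0 else intensity
    return rgb * scale[..., None]


def export_tiff(path, vol: PressureVolume) -> None:
    """Write the volume as a multi-page TIFF (one x-y page per depth)."""
    import tifffile

    pages = np.moveaxis(vol.p0, 2, 0).astype(np.float32)
    tifffile.imwrite(
        path, pages,
        resolution=(1e4 / vol.dx_um, 1e4 / vol.dy_um),  # pixels per cm
        metadata={"spacing_um": vol.dz_um},
    )


def export_nifti(path, vol: PressureVolume) -> None:
    """Write the volume as NIfTI-1 with mm voxel spacing."""
    import nibabel as nib

    affine = np.diag([vol.dx_um * 1e-3, vol.dy_um * 1e-3, vol.dz_um * 1e-3, 1.0])
    nib.save(nib.Nifti1Image(vol.p0.astype(np.float32), affine), path)
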