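"""Image quantitation: CNR, vessel density, suprathreshold counts,
tortuosity, ROI time courses.

Definitions follow the conventions of photoacoustic vascular imaging:

* **CNR** (dB): the background scalar is the mean of the per-depth-plane
  mean intensities; the contrast is the peak over depth of the
  (background-subtracted) plane means; the noise is the RMS intensity
  within a caller-supplied feature-free ROI; CNR = 20 log10(contrast /
  noise) (amplitude convention).
* **V_s** (%): resolvable-vessel density -- the vasculature is segmented
  by intensity K-means clustering (no explicit threshold), reduced to a
  3D medial-axis skeleton, and V_s is the skeleton voxel count as a
  percentage of the image volume.
* **V_I**: subresolution vascular contrast -- the number of voxels above
  background within a volume of interest.
* **Tortuosity index**: vessel arc length over the straight-line
  distance between its endpoints (>= 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import PressureVolume

__all__ = [
    "QuantMetrics",
    "cnr",
    "vessel_density_vs",
    "vascular_signal_vi",
    "tortuosity_index",
    "roi_timecourse",
]


@dataclass
class QuantMetrics:
    """Bundle of vascular image metrics."""

    cnr_db: float | None = None
    v_s_percent: float | None = None
    v_i_count: int | None = None
    tortuosity: float | None = None

    def __post_init__(self) -> None:
        if self.v_s_percent is not None and not 0 <= self.v_s_percent <= 100:
            raise ValueError("V_s is a percentage")
        if self.v_i_count is not None and self.v_i_count < 0:
            raise ValueError("V_I is a count")
        if self.tortuosity is not None and self.tortuosity < 1:
            raise ValueError("tortuosity index is >= 1")


def _as_array(vol) -> np.ndarray:
    return vol.p0 if isinstance(vol, PressureVolume) else np.asarray(vol, float)


def _background_scalar(x: np.ndarray) -> float:
    """Mean over depth of the per-(x, y)-plane mean intensities."""
    return float(x.mean(axis=(0, 1)).mean())


def cnr(vol, noise_roi, contrast_roi=None) -> float:
    """Contrast-to-noise ratio in dB.

    ``noise_roi`` indexes a sub-volume devoid of image features (boolean
    mask or tuple of slices).  Contrast is the peak over depth of the
    background-subtracted plane-mean intensity, computed over
    ``contrast_roi`` when given (the common anatomical ROI of a
    comparison series) or the whole volume otherwise; noise is the RMS
    within the noise ROI; the result is 20 log10(contrast / noise).
    """
    x = _as_array(vol)
    region = x[contrast_roi] if contrast_roi is not None else x
    plane_means = region.mean(axis=(0, 1))
    background = float(plane_means.mean())
    contrast = float((plane_means - background).max())
    noise_vals = x[noise_roi]
    if noise_vals.size == 0:
        raise ValueError("empty noise ROI")
    noise_rms = float(np.sqrt(np.mean(noise_vals**2)))
    if noise_rms == 0:
        raise ValueError("degenerate noise ROI: zero RMS")
    return 20.0 * np.log10(contrast / noise_rms)


def vessel_density_vs(
    vol, k_clusters: int = 2, n_foreground: int = 1, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Vessel density V_s (%) and the 3D skeleton it is counted from.

    Segments the vasculature by K-means clustering of voxel intensities
    (foreground = the ``n_foreground`` clusters of highest mean), thins
    the binary segmentation to a 3D medial-axis skeleton, and reports
    skeleton voxels as a percentage of the image volume.
    """
    from sklearn.cluster import KMeans
    from skimage.morphology import skeletonize

    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    x = _as_array(vol)
    flat = x.reshape(-1, 1)
    if np.ptp(flat) == 0:
        warnings.warn("constant volume: no clusters, V_s = 0")
        return 0.0, np.zeros_like(x, dtype=bool)
    km = KMeans(n_clusters=k_clusters, n_init=3, random_state=seed)
    labels = km.fit_predict(flat).reshape(x.shape)
    order = np.argsort(km.cluster_centers_.ravel())
    fg = np.isin(labels, order[-n_foreground:])
    skel = skeletonize(fg)
    v_s = 100.0 * float(skel.sum()) / skel.size
    return v_s, skel


def vascular_signal_vi(
    vol, roi, threshold: float | None = None, noise_rms: float = 0.0,
    k_sigma: float = 2.0,
) -> int:
    """Suprathreshold voxel count V_I within a volume of interest.

    By default the threshold is the image background scalar plus
    ``k_sigma`` times a supplied noise RMS; pass ``threshold`` to
    override the rule entirely.
    """
    x = _as_array(vol)
    roi_vals = x[roi]
    if roi_vals.size == 0:
        raise ValueError("empty ROI")
    if threshold is None:
        threshold = _background_scalar(x) + k_sigma * noise_rms
    return int(np.count_nonzero(roi_vals > threshold))


def tortuosity_index(centreline_um: np.ndarray) -> float:
    """Vessel arc length divided by the endpoint chord length.

    ``centreline_um`` is an (n, d) polyline, n >= 2.  Invariant under
    rigid motions; equals 1 for a straight segment.
    """
    pts = np.asarray(centreline_um, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("centreline needs at least 2 points")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0:
        raise ValueError("coincident endpoints: tortuosity undefined")
    arc = float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())
    return arc / chord


def roi_timecourse(frames, rois: dict) -> dict:
    """Per-ROI mean-intensity time series over a frame sequence.

    ``rois`` maps names to boolean masks or slice tuples; the result
    maps each name to a series of length ``len(frames)``.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    out = {}
    for name, roi in rois.items():
        series = []
        for fr in frames:
            vals = _as_array(fr)[roi]
            if vals.size == 0:
                raise ValueError(f"empty ROI {name!r}")
            series.append(float(vals.mean()))
        out[name] = np.asarray(series)
    return out
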