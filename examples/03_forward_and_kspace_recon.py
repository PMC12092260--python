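"""Simulate a vessel scene and reconstruct it spectrally.

Generates a layered skin phantom (epidermal slab + branching vessels),
propagates it to the sensor plane, adds NEP noise, band-filters, and
inverts with the one-step k-space mapping.  Prints the fidelity of the
round trip and renders a maximum intensity projection.
"""

import numpy as np

from fpscan import phantom, preprocess
from fpscan.forward_model import forward_planar
from fpscan.io import RenderSpec, mip
from fpscan.recon_kspace import ReconConfig, reconstruct_kspace
from fpscan.sensor_model import sample_nep_map

c, dt, nz = 1500.0, 100.0 / 3.0, 96
pv, tree, slab = phantom.layered_skin_phantom(
    (48, 48, nz), 50.0, depth_range_mm=(0.8, 4.3), seed=7
)
print(f"phantom: {len(tree.segments)} vessel segments, "
      f"total length {tree.total_length_um() / 1e3:.1f} mm")

data = forward_planar(pv, c, dt, nz)
nep = sample_nep_map(48, 48, 0.2, 0.25, seed=8)
data = phantom.add_sensor_noise(data, nep, seed=9)
data = preprocess.bandpass(data, 0.05, 12.0)

rec = reconstruct_kspace(data, ReconConfig(c_m_s=c), nz=nz)
a = pv.p0.ravel() - pv.p0.mean()
b = rec.p0.ravel() - rec.p0.mean()
ncc = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
print(f"reconstruction NCC against ground truth: {ncc:.3f}")
# < 1 because vessels carry content outside the planar acceptance cone
# and the noise floor remains; the vasculature itself is well resolved.

img = mip(rec, RenderSpec(axis="x-y"))
print(f"x-y MIP: {img.shape}, peak {img.max():.1f} kPa at "
      f"{np.unravel_index(img.argmax(), img.shape)}")
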