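"""Occlusion-reperfusion dynamics and vascular quantitation.

Builds a labelled scene (epidermis, digital artery, two venous ROIs),
simulates cuff occlusion followed by staggered reperfusion, recovers the
onset ordering from ROI time courses, and computes the morphometric
metrics (vessel density, tortuosity) on a synthetic tree.
"""

import numpy as np

from fpscan import phantom, quant
from fpscan.studies import dynamics_study

dyn = dynamics_study()
print("ROI 50%-recovery crossings (s):",
      {k: round(v, 2) for k, v in dyn["crossings"].items()})
print(f"epidermis coefficient of variation: {dyn['epidermis_cv']:.4f}")
# arterial inflow resumes first (DA), the downstream venous ROIs follow;
# the melanin-dominated epidermis stays constant throughout.

pv, tree = phantom.vessel_tree_phantom((48, 48, 96), 50.0,
                                       depth_range_mm=(0.8, 4.3), seed=7)
v_s, skel = quant.vessel_density_vs(pv)
print(f"vessel density V_s = {v_s:.2f}% ({int(skel.sum())} skeleton voxels)")

torts = [tree.tortuosity(i) for i in range(len(tree.segments))]
print(f"segment tortuosity: min {min(torts):.3f}, max {max(torts):.3f} "
      "(1.0 = straight)")
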