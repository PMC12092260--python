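"""2D video-rate imaging of a pulsating artery.

Simulates the 33 fps line-scan mode: a 1 mm artery at 3.5 mm depth
pulsates at 70 beats/minute with 5% radius modulation; each frame is
beamformed across the 4 elevation rows of the notional 1.5D array and
reconstructed in-plane, and the minor axis is tracked over time.
"""

import numpy as np

from fpscan.studies import pulsatile_study

out = pulsatile_study(epsilon=0.05, n_frames=30)
dia = out["diameters_mm"]
print(f"tracked minor axis over {dia.size} frames: "
      f"mean {np.nanmean(dia):.2f} mm, "
      f"range {np.nanmin(dia):.2f}-{np.nanmax(dia):.2f} mm")
print(f"recovered relative modulation: {100 * out['epsilon_hat']:.1f}% "
      "(ground truth 5%)")
print(f"dominant frequency: {60 * out['f_peak_hz']:.0f} beats/min "
      f"(ground truth {60 * out['f_true_hz']:.0f}, "
      f"resolution {60 * out['df_hz']:.0f})")
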