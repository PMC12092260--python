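"""Multibeam acquisition timing: scan rates, subsampling, dynamic modes.

Reproduces the scanner's headline timing arithmetic: a 64-beam array at
100 Hz delivers 6,400 A-lines/s, a full 192 x 180 scan takes 5.4 s, and
sliding-window readout of a continuous 12 s random scan yields 200
frames at a 16.7 fps refresh rate.
"""

from fpscan import acquisition
from fpscan.acquisition import BeamArrayLayout

layout = BeamArrayLayout()                # 4 x 16 beams, 324 um pitch
rate = acquisition.aline_rate(layout.n_beams, 100.0)
print(f"A-line rate at 100 Hz PRF: {rate:,.0f} A-lines/s")
print(f"A-line rate at 1 kHz PRF:  "
      f"{acquisition.aline_rate(layout.n_beams, 1000.0):,.0f} A-lines/s")

pattern = acquisition.raster_scan_pattern(192, 180, 108.0, 108.0, layout,
                                          prf_hz=100.0)
print(f"full scan: {pattern.n_alines:,} detection points, "
      f"T = {pattern.scan_time_s:.1f} s")

for frac in (0.5, 0.25, 0.125):
    sub = acquisition.subsample_mask(pattern, frac)
    print(f"  first {frac:>5.1%} of the data -> T = {sub.scan_time_s:.2f} s")
# these subsets are what the variational reconstruction recovers images
# from in the compressed-sensing mode.

frame_time, fps = acquisition.frame_schedule_2d(15.55, 162.0, layout, 200.0)
print(f"2D line-scan mode: {frame_time * 1e3:.0f} ms/frame, {fps:.0f} fps")

frames = acquisition.sliding_window_frames(153600, 7680, 0.1)
refresh = acquisition.aline_rate(64, 200.0) / round(0.1 * 7680)
print(f"sliding window: {len(frames)} frames, refresh rate {refresh:.1f} fps")
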