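"""Compute the time-warping marker d_w between analytic T waves.

Builds raised-cosine T waves whose widths follow a potassium excursion,
warps each against the end-of-dialysis reference, and prints the signed
marker: positive d_w = the wave is narrower than the reference = higher
potassium, in milliseconds of average absolute time warping.
"""

import numpy as np

from kwarp import MeanWarpedTWave, warp_pair


def cosine_wave(width_ms, amp=350.0, grid_ms=0.5):
    t = np.arange(0.0, width_ms + grid_ms / 2, grid_ms)
    f = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / width_ms))
    return MeanWarpedTWave(t, f)


dk = np.array([2.0, 1.4, 0.8, 0.4, 0.0, 1.6])      # Delta[K+] per hour, mmol/L
widths = 180.0 * (1.0 - 0.05 * dk)                 # -5 % T width per mmol/L
reference = cosine_wave(widths[4])                  # h4 = end of dialysis

print("hour   dK (mmol/L)   T width (ms)   d_w (ms)")
for i, (d, w) in enumerate(zip(dk, widths)):
    if i == 4:
        dw = 0.0
    else:
        dw = warp_pair(reference, cosine_wave(w)).dw
    print(f"h{i}      {d:+5.2f}        {w:7.1f}      {dw:+7.2f}")

print()
print("d_w rises monotonically with Delta[K+] (a 10 % narrowing maps to")
print("dwu = 0.05 x the reference duration, here ~4.5 ms per mmol/L).")
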