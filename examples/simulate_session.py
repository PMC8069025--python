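"""Generate a synthetic dialysis Holter session and inspect its ground truth.

The generator couples T-wave morphology to a falling-then-recovering blood
potassium trajectory: each mmol/L of [K+] above the end-of-dialysis
reference narrows the T wave by 5 % and peaks it by 4 % (defaults).
A short, time-compressed session keeps the example fast.
"""

import numpy as np

from kwarp import KTrajectory, MorphologyCoupling, SessionProtocol, generate_session

protocol = SessionProtocol(
    duration_h=0.2,
    sample_hours=(0.0, 0.03, 0.06, 0.09, 0.12, 0.18),
    hd_end_h=0.12,
    fs=500.0,
)
trajectory = KTrajectory(protocol.sample_hours, (5.6, 5.0, 4.4, 4.0, 3.6, 5.2))
coupling = MorphologyCoupling()  # defaults: width -5 %/mmol/L, 10 uV noise

rec, gt = generate_session(protocol, trajectory, coupling, seed=7)

print(f"recording: {len(rec.leads)} leads x {rec.n_samples} samples at {rec.fs} Hz")
print(f"beats: {gt.r_times_s.size}, RR {gt.rr_ms.mean():.0f} ms on average")
print("hour   [K+] mmol/L   dK vs h4   true T width (ms)")
widths = gt.t_end_s - gt.t_onset_s
for i, (h, k) in enumerate(zip(gt.sample_hours, gt.k_at_samples)):
    beat = np.argmin(np.abs(gt.r_times_s - h * 3600.0))
    dk = k - gt.k_at_samples[gt.reference_index]
    print(f"h{i}    {k:5.2f}        {dk:+5.2f}      {widths[beat] * 1000:6.1f}")
print()
print("The T wave is narrowest where potassium is highest (h0): the")
print("hyperkalaemic narrowing the warping markers are built to sense.")
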