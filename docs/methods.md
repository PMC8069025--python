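# Methods

This note documents the models, algorithms and numerical choices behind
`kwarp`, and what the synthetic data do and do not establish.

## Problem setting

Hemodialysis removes potassium quickly (typically ~2 mmol/L over a
4-hour session) and the deficit rebuilds over the next two days. The six
blood samples h0–h5 — dialysis onset, hourly during dialysis, dialysis
end (h4) and just before the next session — bracket that excursion. All
quantities are *relative* to h4: Δ[K⁺](hᵢ) = [K⁺]hᵢ − [K⁺]h4, and the
ECG markers are likewise measured against the end-of-dialysis reference
window. The package estimates Δ[K⁺], never absolute concentration.

## Synthetic session generator

The generator emulates the study conditions so that every downstream
stage is testable without patient data.

* **Template beat.** Piecewise-analytic: raised-cosine P and T lobes and
  a piecewise-linear QRS. A raised-cosine T lobe is exactly zero outside
  its support with zero slope at both ends, so the true onset, peak and
  end are closed-form — which is what makes delineation accuracy
  measurable to the millisecond.
* **Potassium coupling.** T width is scaled by
  `1 + width_gain·Δ[K⁺](t)` and amplitude by `1 + amp_gain·Δ[K⁺](t)`,
  with defaults `width_gain = −0.05` per mmol/L (narrower when potassium
  is high, the hyperkalaemic direction) and `amp_gain = +0.04`. These
  gains are free simulation parameters: the literature establishes the
  sign and approximate scale of the effect, not a universal transfer
  coefficient, so no claim is made that they reproduce human physiology
  quantitatively.
* **[K⁺] trajectory.** Monotone piecewise-cubic (PCHIP) through
  5.6 → 3.6 mmol/L over dialysis, recovering to 5.2 mmol/L by h5;
  knots configurable. h4 defaults to minute 215 of the session.
* **Heart rate.** Mean RR drifts linearly 850 → 950 ms across the
  session with 2 % beat-to-beat jitter; T width optionally couples to
  relative RR deviation (`rr_width_gain`, default 0.10) so the
  heart-rate correction has a real confounder to remove.
* **Leads and noise.** One cardiac source mixed into the 8 independent
  leads (I, II, V1–V6) by a fixed full-rank weight vector, plus
  per-lead baseline wander (100 µV at 0.25 Hz) and white noise
  (10 µV SD) — a well-posed single-source problem for πCA.
* **Ground truth** carries the exact fiducials, per-beat true T widths,
  and the analytic marker `true_dw = (W_ref − W(t))/2`: for a pure
  time-scaling by factor c the mean absolute warping is |1−c|·T_ref/2,
  signed positive for narrowing.

A marker-level cohort generator (`simulate_marker_cohort`) produces
(d, Δ[K⁺]) pairs directly for model-stage studies: per-patient marker
profile proportional to the default Δ[K⁺] shape (largest at h0, zero at
h4, nearly as large at h5), patient-specific positive quadratic
coefficients, 0.15 mmol/L measurement noise, and an extra 0.15 mmol/L
mismatch at h5 emulating the common early end of Holter recordings
hours before the pre-next-dialysis blood draw. What it deliberately
lacks: any ECG, delineation or warping noise — conclusions drawn from
it concern the model-fitting stage only.

## Preprocessing

Zero-phase (forward-backward) Butterworth filtering throughout:
0.5 Hz/6th-order high-pass for baseline wander, 40 Hz/3rd-order
low-pass on the record, 20 Hz/6th-order low-pass on πC1 before T-wave
averaging. Forward-backward application squares the magnitude response;
tests verify measured attenuations against the analytic
`|H|² = 1/(1 + (tan(πf/fs)/tan(πf_c/fs))^{2n})` with the bilinear
prewarp included. Reflective padding bounds edge transients; the first
and last 10 s of a record are excluded from all analysis (windows and
πCA pairing), because the high-pass transient visibly distorts the
first seconds.

The delineator is derivative-based: QRS from a rectified-derivative
energy envelope (adaptive percentile threshold, 300 ms refractory),
R refined to the local extremum; T waves from the dominant post-QRS
lobe, with onset/end found by walking outward from the steepest flanks
until the amplitude falls below 0.5 % of the T peak relative to a
per-beat PQ-segment baseline. All amplitude thresholds scale with the
signal (the periodic components are in covariance-normalized units, not
µV). On noise-free synthetic input the 99th-percentile fiducial error
is ≤ 5 ms; beats whose T wave cannot be delineated are flagged missing
and excluded from averaging, never interpolated.

## Periodic component analysis

For each recording one transformation Ψ is estimated (never per
window). Consecutive delineated beats are paired after linearly
resampling each beat's segment (T wave → 400 samples; QRST → 600 for
the πCB variant) so one-beat periodicity is well defined under RR
drift. A = covariance of beat-to-beat differences, B = total
covariance; `scipy.linalg.eigh(A, B)` gives B-orthonormal components
ordered by ascending λ, so component 1 is the most periodic. Numerical
choices: a B condition-number guard (< 1e−12 ratio aborts with "leads
linearly dependent"); sign fixed by making each component's median
T-peak amplitude positive, which makes the whole pipeline
deterministic. With literally identical leads (a zero-noise
single-source mixture) B is singular and the eigenproblem is
degenerate by construction; the λ₁→0 property is therefore tested with
a vanishingly small (0.05 µV) sensor noise.

## Time warping and markers

Waves are compared in the square-root-slope representation
`q = sign(f′)·√|f′|` on the unit interval (supports normalised;
boundary-anchored onset↔onset, end↔end — a pure time-scaling is then
carried entirely by the support ratio and recovered exactly). The
optimal monotone warping minimises `∫(q₁ − (q₂∘γ)√γ′)²` over lattice
paths with local slope in [1/3, 3] (steps (di, dj), di, dj ≤ 3),
trapezoid edge costs, solved by dynamic programming — exact on its
lattice, verified against exhaustive path enumeration. Grid: 0.5 ms
for marker computation; 1 ms inside the iterative MWTW average, where
per-wave precision matters less than throughput. Ties in the DP are
broken toward the earliest-enumerated step, deterministically.

The MWTW of a window starts from the wave of median duration (tie:
the shorter), warps every wave onto the template, averages the aligned
amplitudes, re-normalises the support to the mean wave duration, and
iterates to a 1e−3 relative sup-norm tolerance (max 10 iterations,
warned). Beat rejection inside a 2-minute window: duration deviating
more than 25 % from the window median, or correlation with the window
average below 0.95; windows with fewer than 20 surviving waves are
flagged invalid and skipped, never silently dropped.

`d_w` of a window is the mean |γ(t) − t| over the reference support,
signed. **Sign convention:** positive when the window's T wave is
narrower than the h4 reference — the direction in which potassium rises
— so that the constrained (monotone-increasing) models see positive
markers for positive Δ[K⁺]. The opposite convention is available in
config (`wider_positive`).

`d_w,c = d_w − ĉ·(√RR − √RR_ref)` with ĉ fitted through the origin by
least squares on the final 4 h of the session (configurable), where
potassium-driven marker dynamics are low and residual variation tracks
heart rate. If the stability segment has under two usable points or no
RR variation, ĉ falls back to 0 with a warning (d_w,c = d_w) — the
honest degradation on short records.

Markers are paired to blood hours by the nearest valid window (ties to
the earlier window); the reference window scores exactly 0.

## Potassium models and evaluation

Intercept-free Vandermonde designs (d, d², d³); non-negative least
squares (active-set, deterministic) enforces coefficient non-negativity,
which is equivalent to a non-decreasing model on d > 0 and is asserted
on a dense grid in the tests. Negative markers are retained in fitting,
not clamped. Leave-one-out holds out each of {h0,h1,h2,h3,h5} in turn;
h4 stays in every training set because it anchors the model (both
marker and Δ[K⁺] are identically zero there) and is excluded from error
computation for the same reason. Correlations are computed over all six
hour points by default; `include_reference_in_corr=False` drops the
degenerate (0, 0) pair. Aggregation across patients: median and IQR
(75th − 25th percentile, linear interpolation); the ALL/h0/h5 summary
columns use |e|, while per-hour distribution-width comparisons use
signed errors.

## Problem sizes

End-to-end tests and the acceptance script run time-compressed sessions
(≈ 1.5 h at 500 Hz with 4 windows per "hour" and sample hours on the
window grid) and marker-level cohorts of 100–200 patients; these sizes
were chosen so the full suite completes in a few minutes while every
stage still operates above its minimum-data thresholds (≥ 100 πCA beat
pairs, ≥ 20 waves per window, ≥ 4 training points per model). Library
defaults remain the clinical settings: 48 h at 1 kHz, windows at minutes
5 and 35, h4 at minute 215.

## Known limitations

* The generator's single dominant source and fixed mixing make πCA's
  job easier than multi-source clinical ECG; recovery correlations near
  1 should not be read as clinical performance.
* The delineator is a contract-compatible derivative method, not a
  reimplementation of any published wavelet delineator; its accuracy is
  established on analytic beats only.
* The heart-rate correction assumes a √RR-linear width effect and a
  stable late segment; compressed test sessions often lack the latter
  and fall back to ĉ = 0.
* Marker-level cohort results bypass the signal chain entirely; the
  qualitative error patterns they establish (leave-one-out worse than
  all-samples, widest spreads at h0/h5) are model-stage properties.
* Clinical error magnitudes reported for real patients (~0.2–0.4 mmol/L)
  are not reproducible from synthetic data and are not claimed; the
  synthetic pipeline's smaller errors reflect its cleaner conditions.
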