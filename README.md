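# kwarp

Non-invasive tracking of blood-potassium variation from the ECG, for
end-stage renal disease patients on hemodialysis (ESRD-HD).

Potassium swings between dialysis sessions are clinically silent and
arrhythmogenic. Rising [K⁺] narrows and peaks the T wave, so T-wave
morphology carries a potassium signal. `kwarp` implements the full chain
from multi-lead Holter ECG to a per-patient potassium sensor:

1. **Preprocessing** — zero-phase Butterworth filters (0.5 Hz high-pass,
   6th order; 40 Hz low-pass, 3rd order), QRS detection and single-lead
   T-wave delineation.
2. **Periodic component analysis (πCA)** — the lead combination `w`
   minimising the one-beat periodicity quotient
   `ε(w) = E‖wᵀx(t′) − wᵀx(t)‖² / E‖wᵀx(t)‖²` over the T-wave segment
   (mode πCT), solved as the generalized eigenproblem `Aw = λBw`.
   The most periodic component πC1 concentrates the repolarisation
   signal and suppresses noise.
3. **Time-warping markers** — T waves in 2-minute windows (minutes 5 and
   35 of each hour) are averaged into a mean warped T wave (MWTW) via
   square-root-slope (SRSF) elastic alignment, solved exactly by dynamic
   programming on a 0.5 ms lattice. The marker of a window is

   `d_w = s · (1/N) Σₙ |γ(tₙ) − tₙ|` (ms),

   the average absolute warping of the window's MWTW onto the
   end-of-dialysis reference MWTW (h4), signed positive for T-wave
   narrowing. `d_w,c` additionally removes heart-rate-driven width
   changes via a √RR regression fitted on a late post-dialysis
   stability segment.
4. **Potassium models** — per patient and marker, intercept-free
   polynomial models `Δ̂[K⁺] = α d + β d² + γ d³` (linear/quadratic/cubic)
   fitted by non-negative least squares, so `∂Δ̂[K⁺]/∂d ≥ 0` and the
   sensor is monotone, as physiology requires. Two estimation rules:
   `m=a` (train on all six blood samples h0–h5) and `m=o` (leave-one-out
   over the five non-reference hours; h4, where marker and Δ[K⁺] are
   zero by construction, always stays in training).
5. **Evaluation** — per-patient Spearman ρ and Pearson r between
   measured and estimated Δ[K⁺], and per-hour errors
   `e(hᵢ) = Δ̂[K⁺](hᵢ) − Δ[K⁺](hᵢ)` for i ∈ {0,1,2,3,5}, aggregated
   across patients as median (IQR).

Because no clinical recordings ship with the package, a first-class
**synthetic session generator** produces ground-truthed 8-lead Holter
sessions: an analytic template beat repeated at a drifting RR, T-wave
width/amplitude coupled to a falling-then-recovering [K⁺] trajectory,
lead mixing, baseline wander and broadband noise — every fiducial and
the true width-change series known in closed form.

## Worked example

`python examples/warping_markers.py` — markers from analytic T waves
whose widths follow a potassium excursion:

```
hour   dK (mmol/L)   T width (ms)   d_w (ms)
h0      +2.00          162.0        +9.00
h1      +1.40          167.4        +6.25
h2      +0.80          172.8        +3.50
h3      +0.40          176.4        +1.75
h4      +0.00          180.0        +0.00
h5      +1.60          165.6        +7.25
```

`d_w` is zero at the h4 reference and rises monotonically with Δ[K⁺]: a
10 % narrowing corresponds to `dwu = 0.05 ×` the reference duration
(here 9 ms), the closed form the warping recovers exactly.

`python examples/full_pipeline.py` — the complete chain on a simulated,
time-compressed session:

```
marker order rule  rho_median  r_median  e_all_median
    dw     q    a         1.0  0.980723      0.143012
    dw     q    o         1.0  0.958822      0.230149
    ...
```

Estimated Δ[K⁺] follows the measured excursion with rank correlation 1.0
and median absolute error ≈ 0.14 mmol/L under the all-samples rule;
leave-one-out errors are larger, the expected cost of predicting the
extreme hours from the rest.

Other examples: `examples/simulate_session.py` (generator ground truth)
and `examples/fit_models.py` (constrained model fitting, m=a vs m=o).

A thin CLI wraps the same library code:

```bash
kwarp simulate --config sim.yaml --seed 7 --out DIR   # WFDB + lab CSV
kwarp run --config cfg.yaml --in DIR --out REPORT_DIR # or omit --in to simulate
```

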