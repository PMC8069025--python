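"""Synthetic Holter-session generator with a known potassium trajectory.

The study this package targets pairs a long (~48 h) multi-lead Holter
recording, started at hemodialysis (HD) onset, with six blood-potassium
samples: h0 at HD start, h1-h3 hourly during HD, h4 at HD end (the
reference point) and h5 just before the next session.  [K+] falls during
dialysis and drifts back up afterwards; rising [K+] narrows and peaks the
T wave, which is what the time-warping markers sense.

The generator emulates exactly that: an analytic template beat (raised-
cosine P and T lobes, piecewise-linear QRS) is repeated at a drifting RR
interval; the T-wave duration and amplitude are modulated by the instant
[K+] excess over the end-of-HD reference (and optionally by RR, to exercise
the heart-rate correction); a single cardiac source is mixed into 8 leads
(I, II, V1-V6) with lead-specific baseline wander and broadband noise.
Because the beat is analytic, every fiducial and the per-window width
change are known in closed form and are returned as ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .preprocess import INDEPENDENT_LEADS, EcgRecording

# fixed full-rank single-source lead mixing: distinct nonzero weight per lead
DEFAULT_MIXING = np.array([0.65, 1.00, -0.45, 0.55, 0.85, 1.10, 0.95, 0.70])

# template geometry (ms relative to the R peak) and amplitudes (uV)
_P_CENTER, _P_WIDTH, _P_AMP = -160.0, 90.0, 90.0
_T_ONSET, _T_WIDTH0, _T_AMP0 = 140.0, 180.0, 350.0
_QRS_T = np.array([-30.0, -22.0, -16.0, 0.0, 18.0, 28.0])
_QRS_V = np.array([0.0, -80.0, 0.0, 1100.0, -180.0, 0.0])


@dataclass(frozen=True)
class SessionProtocol:
    """Timing of the recording and of the six blood samples.

    ``sample_hours`` are h0..h5 in hours from recording start;
    ``hd_end_h`` (the reference h4) must be one of them.  Defaults follow
    the clinical protocol: HD start, hourly during HD, HD end at minute
    215, and a final sample at 48 h just before the next session.
    """

    duration_h: float = 48.0
    sample_hours: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 215.0 / 60.0, 48.0)
    hd_end_h: float = 215.0 / 60.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        hrs = np.asarray(self.sample_hours, float)
        if hrs.size != 6 or np.any(np.diff(hrs) <= 0):
            raise ValueError("sample_hours must be 6 strictly increasing values")
        if not np.any(np.isclose(hrs, self.hd_end_h)):
            raise ValueError("hd_end_h must be one of sample_hours")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_h < hrs[-1]:
            raise ValueError(
                f"duration {self.duration_h} h too short to contain the last "
                f"blood sample at {hrs[-1]} h"
            )

    @property
    def reference_index(self) -> int:
        return int(np.argmin(np.abs(np.asarray(self.sample_hours) - self.hd_end_h)))


@dataclass(frozen=True)
class KTrajectory:
    """Blood-potassium trajectory [K+](t), mmol/L, monotone-piecewise (PCHIP).

    The default shape falls from 5.6 to 3.6 mmol/L over dialysis and
    recovers to 5.2 mmol/L by the next session.
    """

    times_h: tuple[float, ...]
    k_mmol: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, float)
        k = np.asarray(self.k_mmol, float)
        if t.size != k.size or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times_h must be strictly increasing and match k_mmol")
        if np.any(k <= 0):
            raise ValueError("k_mmol must be positive everywhere")

    def __call__(self, t_h) -> np.ndarray:
        f = PchipInterpolator(np.asarray(self.times_h), np.asarray(self.k_mmol),
                              extrapolate=False)
        t = np.clip(t_h, self.times_h[0], self.times_h[-1])
        return f(t)

    @staticmethod
    def default(protocol: SessionProtocol) -> "KTrajectory":
        hrs = protocol.sample_hours
        k = (5.6, 5.0, 4.4, 4.0, 3.6, 5.2)
        return KTrajectory(tuple(hrs), k)


@dataclass(frozen=True)
class MorphologyCoupling:
    """How [K+], heart rate and noise shape the synthetic beats.

    width_gain < 0: each mmol/L of [K+] above the end-of-HD reference
    narrows the T wave by |width_gain| (fractional).  amp_gain > 0 peaks
    it.  rr_width_gain couples T width to relative RR deviation (QT-RR
    physiology) so the heart-rate correction has something to remove.
    """

    width_gain: float = -0.05        # fractional T-width change per mmol/L
    amp_gain: float = 0.04           # fractional T-amp change per mmol/L
    rr_width_gain: float = 0.10      # fractional T-width change per unit dRR/RR
    rr_start_ms: float = 850.0
    rr_end_ms: float = 950.0
    rr_jitter: float = 0.02          # beat-to-beat RR CV
    wander_uv: float = 100.0         # baseline-wander amplitude
    wander_hz: float = 0.25
    noise_uv: float = 10.0           # broadband noise SD

    def __post_init__(self) -> None:
        if self.wander_uv < 0 or self.noise_uv < 0 or self.rr_jitter < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows exactly, for downstream testing."""

    k_at_samples: np.ndarray          # mmol/L at h0..h5
    sample_hours: np.ndarray
    r_times_s: np.ndarray             # true R-peak times
    t_onset_s: np.ndarray
    t_peak_s: np.ndarray
    t_end_s: np.ndarray
    t_width_ms: np.ndarray            # true per-beat T width
    rr_ms: np.ndarray                 # RR preceding each beat
    true_dw_like: np.ndarray          # analytic signed width marker at sample hours
    mixing: np.ndarray = field(default_factory=lambda: DEFAULT_MIXING.copy())
    reference_index: int = 4
    patient_id: str = "synthetic"


def _raised_cosine(t: np.ndarray, start: float, width: float, amp: float) -> np.ndarray:
    """Single smooth lobe: exactly 0 outside [start, start+width]."""
    u = (t - start) / width
    out = np.zeros_like(t)
    m = (u > 0) & (u < 1)
    out[m] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[m]))
    return out


def beat_template(t_ms: np.ndarray, t_width: float, t_amp: float) -> np.ndarray:
    """Analytic P-QRS-T beat sampled at t_ms (ms relative to R)."""
    y = _raised_cosine(t_ms, _P_CENTER - _P_WIDTH / 2, _P_WIDTH, _P_AMP)
    y += np.interp(t_ms, _QRS_T, _QRS_V, left=0.0, right=0.0)
    y += _raised_cosine(t_ms, _T_ONSET, t_width, t_amp)
    return y


def generate_session(
    protocol: SessionProtocol,
    traj: KTrajectory | None = None,
    coupling: MorphologyCoupling | None = None,
    seed: int = 0,
    patient_id: str = "synthetic",
) -> tuple[EcgRecording, GroundTruth]:
    """Generate one 8-lead session; deterministic for a fixed seed.

    Returns the recording (uV) and the ground truth.  ``true_dw_like`` is
    the analytic counterpart of the signed warping marker at the six
    sample hours: for a pure time-scaling by c relative to the reference
    width, the mean |warp| is |1-c|*W_ref/2, signed positive for
    narrowing (the convention the potassium models expect).
    """
    traj = traj if traj is not None else KTrajectory.default(protocol)
    coupling = coupling if coupling is not None else MorphologyCoupling()
    rng = np.random.default_rng(seed)
    fs = protocol.fs
    dur_s = protocol.duration_h * 3600.0
    n = int(round(dur_s * fs))

    k_ref = float(traj(protocol.hd_end_h))

    # --- beat times: RR drifts linearly over the session with jitter
    r_times = []
    rr_list = []
    t = 0.35  # first beat shortly after record start
    while t < dur_s - 0.8:
        frac = t / dur_s
        rr_mean = coupling.rr_start_ms + (coupling.rr_end_ms - coupling.rr_start_ms) * frac
        rr = rr_mean * (1.0 + coupling.rr_jitter * rng.standard_normal())
        rr = max(rr, 300.0)
        r_times.append(t)
        rr_list.append(rr)
        t += rr / 1000.0
    r_times = np.asarray(r_times)
    rr_arr = np.asarray(rr_list)          # RR *following* each beat
    rr_prev = np.empty_like(rr_arr)       # RR preceding (first inherits)
    rr_prev[1:] = rr_arr[:-1]
    rr_prev[0] = rr_arr[0]

    # --- per-beat morphology from [K+] and RR
    t_h = r_times / 3600.0
    dk = traj(t_h) - k_ref
    rr_ref = coupling.rr_start_ms + (coupling.rr_end_ms - coupling.rr_start_ms) * (
        protocol.hd_end_h * 3600.0 / dur_s
    )
    width = _T_WIDTH0 * (1.0 + coupling.width_gain * dk) * (
        1.0 + coupling.rr_width_gain * (rr_prev - rr_ref) / rr_ref
    )
    amp = _T_AMP0 * (1.0 + coupling.amp_gain * dk)
    width = np.maximum(width, 40.0)

    # --- render the single cardiac source
    source = np.zeros(n)
    lo_ms, hi_ms = -260.0, 60.0  # template support outside the T wave
    for i, (rt, w, a) in enumerate(zip(r_times, width, amp)):
        s0 = int(np.floor((rt + lo_ms / 1000.0) * fs))
        s1 = int(np.ceil((rt + (_T_ONSET + w + 10.0) / 1000.0) * fs))
        s0c, s1c = max(s0, 0), min(s1, n)
        if s1c <= s0c:
            continue
        tt = (np.arange(s0c, s1c) / fs - rt) * 1000.0
        source[s0c:s1c] += beat_template(tt, w, a)

    # --- mix into 8 leads with lead-specific noise
    leads = np.empty((8, n))
    tvec = np.arange(n) / fs
    for l in range(8):
        y = DEFAULT_MIXING[l] * source
        if coupling.wander_uv > 0:
            phase = rng.uniform(0, 2 * np.pi)
            y = y + coupling.wander_uv * np.sin(2 * np.pi * coupling.wander_hz * tvec + phase)
        if coupling.noise_uv > 0:
            y = y + coupling.noise_uv * rng.standard_normal(n)
        leads[l] = y
    rec = EcgRecording(INDEPENDENT_LEADS, leads, fs)

    # --- ground truth
    k_samp = np.asarray(traj(np.asarray(protocol.sample_hours)), float)
    # analytic signed marker (narrowing-positive) at the sample hours:
    # width there uses the trajectory only (the RR term averages out in
    # windows and is what the heart-rate correction removes)
    w_samp = _T_WIDTH0 * (1.0 + coupling.width_gain * (k_samp - k_ref))
    w_ref = _T_WIDTH0
    true_dw = (w_ref - w_samp) / 2.0
    gt = GroundTruth(
        k_at_samples=k_samp,
        sample_hours=np.asarray(protocol.sample_hours, float),
        r_times_s=r_times,
        t_onset_s=r_times + _T_ONSET / 1000.0,
        t_peak_s=r_times + (_T_ONSET + width / 2.0) / 1000.0,
        t_end_s=r_times + (_T_ONSET + width) / 1000.0,
        t_width_ms=width,
        rr_ms=rr_prev,
        true_dw_like=true_dw,
        reference_index=protocol.reference_index,
        patient_id=patient_id,
    )
    return rec, gt


HOUR_LABELS = ("h0", "h1", "h2", "h3", "h4", "h5")


def write_lab_csv(gt: GroundTruth, path) -> None:
    """Write the six [K+] samples as a lab CSV (round-trips with read_lab_csv)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "hour_label", "time_h", "k_mmol"])
        for lbl, th, k in zip(HOUR_LABELS, gt.sample_hours, gt.k_at_samples):
            w.writerow([gt.patient_id, lbl, f"{th:.6f}", f"{k:.4f}"])


# ---------------------------------------------------------------------------
# marker-level cohort simulation (for model-stage studies)


def simulate_polynomial_patients(
    coeffs: tuple[float, ...],
    d_values: np.ndarray,
    sigma: float,
    n_patients: int,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patients whose Delta[K+] is an exact polynomial of the marker plus noise.

    ``coeffs`` are the intercept-free polynomial coefficients (alpha, beta,
    ...); each patient shares them; Gaussian noise with SD ``sigma`` mmol/L
    is added to Delta[K+] at the non-reference hours.  Returns a list of
    (d, delta_k) arrays over the six hours (reference hour has d = 0 and
    delta_k = 0 exactly).
    """
    rng = np.random.default_rng(seed)
    d = np.asarray(d_values, float)
    out = []
    for _ in range(n_patients):
        dk = np.zeros_like(d)
        for k, c in enumerate(coeffs, start=1):
            dk += c * d**k
        noise = sigma * rng.standard_normal(d.size)
        noise[np.isclose(d, 0.0)] = 0.0  # reference point is exact by definition
        out.append((d.copy(), dk + noise))
    return out


def simulate_marker_cohort(
    n_patients: int,
    seed: int = 0,
    base_profile: tuple[float, ...] = (25.0, 17.5, 10.0, 5.0, 0.0, 20.0),
    alpha_range: tuple[float, float] = (0.035, 0.075),
    beta_range: tuple[float, float] = (0.0006, 0.0018),
    sigma: float = 0.15,
    h5_desync_sd: float = 0.15,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cohort with a mildly nonlinear marker-to-potassium coupling.

    The marker profile over h0..h5 is proportional to the default
    potassium trajectory's Delta[K+] shape (2.0, 1.4, 0.8, 0.4, 0, 1.6
    mmol/L), mirroring the clinical pattern: largest just before dialysis
    (h0), decaying to 0 at the h4 reference, and nearly as large again
    before the next session (h5).  Per-patient scale, hourly
    jitter, and patient-specific quadratic coefficients (all positive,
    hence monotone) produce realistic heterogeneity; Gaussian noise of SD
    ``sigma`` mmol/L contaminates the measured Delta[K+].

    ``h5_desync_sd`` adds extra mismatch at h5 only: Holter sessions
    commonly end hours before the pre-next-dialysis blood draw (battery
    or electrode loss), so the marker paired with h5 lags the actual
    sample; at the default post-dialysis recovery slope (~0.04 mmol/L
    per hour) a ~4 h gap contributes ~0.15 mmol/L of extra uncertainty.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(base_profile, float)
    out = []
    for _ in range(n_patients):
        scale = rng.uniform(0.7, 1.3)
        jitter = 1.0 + 0.10 * rng.standard_normal(base.size)
        d = base * scale * jitter
        d[4] = 0.0  # h4 reference
        alpha = rng.uniform(*alpha_range)
        beta = rng.uniform(*beta_range)
        dk = alpha * d + beta * d**2
        noise = sigma * rng.standard_normal(d.size)
        noise[5] += h5_desync_sd * rng.standard_normal()
        noise[4] = 0.0
        out.append((d, dk + noise))
    return out
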