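"""Time-warping T-wave morphology markers.

T waves from the most periodic component are grouped in 2-minute windows
(centred on the 5th and 35th minute of each hour by default).  Each
window is summarised by a mean warped T wave (MWTW): an iterative warped
average in which every wave is elastically aligned to the running
template.  The marker d_w of a window is the average absolute time
warping needed to align its MWTW with the MWTW of the reference window at
the end of dialysis, signed by direction; d_w,c additionally removes the
part of the warping explained by heart-rate (RR) changes.

Alignment uses the square-root-slope framework: a wave f on [0, 1] is
represented by q = sign(f') sqrt(|f'|); the optimal monotone warping
gamma minimises the L2 distance between q_ref and (q_test o gamma)
sqrt(gamma'), found exactly on a discrete lattice by dynamic programming
over monotone paths with bounded local slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class TWaveWindow:
    """T waves of one 2-minute window, after beat rejection."""

    center_time_h: float
    waves: list                      # list of (t_ms, amp) arrays, t from 0 at onset
    rr_median_ms: float
    n_used: int
    n_rejected: int
    valid: bool


@dataclass
class MeanWarpedTWave:
    """Warped-domain average T wave of a window.

    ``t`` is a uniform support in ms re-anchored at T onset = 0.
    """

    t: np.ndarray
    f: np.ndarray
    center_time_h: float = np.nan
    rr_median_ms: float = np.nan
    converged: bool = True

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class WarpingResult:
    """Optimal warping of a reference MWTW onto a test MWTW."""

    t_ref: np.ndarray       # reference support (ms)
    gamma: np.ndarray       # warped times on the test support (ms)
    dwu: float              # mean |gamma(t) - t|, ms
    dw: float               # signed marker, ms
    cost: float             # SRSF alignment cost


@dataclass
class MarkerSeries:
    """Per-window markers relative to the end-of-dialysis reference."""

    times_h: np.ndarray
    dw: np.ndarray
    dwc: np.ndarray
    rr_ms: np.ndarray
    valid: np.ndarray
    reference_time_h: float
    c_hat: float = np.nan   # fitted RR-correction slope (ms per sqrt-ms)


# ---------------------------------------------------------------------------
# SRSF dynamic-programming alignment


def _srsf(f: np.ndarray) -> np.ndarray:
    """Square-root-slope function on the unit interval, L2-normalised."""
    df = np.gradient(f, 1.0 / (f.size - 1))
    q = np.sign(df) * np.sqrt(np.abs(df))
    nrm = np.sqrt(np.trapezoid(q * q, dx=1.0 / (q.size - 1)))
    return q / nrm if nrm > 0 else q


def dp_warp(q1: np.ndarray, q2: np.ndarray, max_step: int = 3):
    """Exact DP over monotone lattice paths from (0,0) to (N-1,N-1).

    Steps are (di, dj) with 1 <= di, dj <= max_step, so local slopes lie
    in [1/max_step, max_step].  Edge cost is the trapezoid-rule integral
    of (q1(t) - sqrt(m) q2(gamma(t)))^2 along the reference axis.
    Returns (path nodes as (i, j) int array, total cost).
    """
    n = q1.size
    if q2.size != n:
        raise ValueError("q1 and q2 must have equal length")
    dt = 1.0 / (n - 1)
    steps = [(di, dj) for di in range(1, max_step + 1) for dj in range(1, max_step + 1)]

    # precompute q2 interpolated at fractional offsets k*dj/di for each step
    interp = {}
    for di, dj in steps:
        m = dj / di
        for k in range(di + 1):
            off = k * m
            b = int(np.floor(off + 1e-12))
            frac = off - b
            if frac < 1e-12:
                arr = q2[b:] if b else q2
            else:
                arr = (1.0 - frac) * q2[b:-1] + frac * q2[b + 1:]
            interp[(di, dj, k)] = arr

    inf = np.inf
    E = np.full((n, n), inf)
    E[0, 0] = 0.0
    back = np.full((n, n), -1, dtype=np.int16)
    sqm = {s: np.sqrt(s[1] / s[0]) for s in steps}
    for i in range(1, n):
        for si, (di, dj) in enumerate(steps):
            i0 = i - di
            if i0 < 0:
                continue
            nb = n - dj            # number of candidate origins j0 = 0..nb-1
            prev = E[i0, :nb]
            s = sqm[(di, dj)]
            # trapezoid along the k sub-samples of this edge
            acc = None
            for k in range(di + 1):
                arr = interp[(di, dj, k)][:nb]
                g = q1[i0 + k] - s * arr
                g = g * g
                w = 0.5 if k in (0, di) else 1.0
                acc = g * w if acc is None else acc + g * w
            cand = prev + acc * dt
            row = E[i, dj:]
            better = cand < row
            row[better] = cand[better]
            back[i, dj:][better] = si

    if not np.isfinite(E[n - 1, n - 1]):
        raise RuntimeError("no admissible warping path")
    # reconstruct
    nodes = [(n - 1, n - 1)]
    i, j = n - 1, n - 1
    while (i, j) != (0, 0):
        di, dj = steps[back[i, j]]
        i, j = i - di, j - dj
        nodes.append((i, j))
    nodes.reverse()
    return np.asarray(nodes, dtype=int), float(E[n - 1, n - 1])


def _resample_uniform(t: np.ndarray, f: np.ndarray, n: int) -> np.ndarray:
    return np.interp(np.linspace(t[0], t[-1], n), t, f)


def warp_pair(
    ref: MeanWarpedTWave,
    test: MeanWarpedTWave,
    grid_ms: float = 0.5,
    max_step: int = 3,
    sign_convention: str = "narrower_positive",
) -> WarpingResult:
    """Optimal monotone warping of ``ref`` onto ``test`` and the d_w marker.

    dwu is the mean absolute deviation of gamma from identity over the
    reference support (ms).  The sign of d_w follows ``sign_convention``:
    with the default, a test wave narrower than the reference (the
    hyperkalaemic direction) yields d_w > 0, matching the physiology the
    potassium models assume; ``"wider_positive"`` flips it.
    """
    for w in (ref, test):
        if w.t.size < 50:
            raise ValueError("waves must have at least 50 samples")
        if not (np.all(np.isfinite(w.f)) and np.all(np.isfinite(w.t))):
            raise ValueError("non-finite wave")
        if np.ptp(w.f) <= 1e-12 * max(1.0, np.max(np.abs(w.f))):
            raise ValueError("unwarpable wave: near-flat amplitude")

    t_ref = ref.t - ref.t[0]
    t_test = test.t - test.t[0]
    T_ref, T_test = t_ref[-1], t_test[-1]
    n = max(int(round(max(T_ref, T_test) / grid_ms)) + 1, 64)
    q1 = _srsf(_resample_uniform(t_ref, ref.f, n))
    q2 = _srsf(_resample_uniform(t_test, test.f, n))
    nodes, cost = dp_warp(q1, q2, max_step=max_step)

    # piecewise-linear gamma through the path nodes, on the full ref grid
    gi = np.interp(np.arange(n), nodes[:, 0], nodes[:, 1])
    grid_ref = np.linspace(0.0, T_ref, n)
    gamma = gi / (n - 1) * T_test          # physical test time, ms

    dev = gamma - grid_ref
    dwu = float(np.mean(np.abs(dev)))
    s_raw = float(np.sum(dev))
    s = 1.0 if s_raw == 0 else float(np.sign(s_raw))
    if sign_convention == "narrower_positive":
        s = -s
    elif sign_convention != "wider_positive":
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    if np.any(np.diff(gamma) < 0):
        raise RuntimeError("gamma not monotone")  # DP guarantees this
    return WarpingResult(t_ref=grid_ref, gamma=gamma, dwu=dwu, dw=s * dwu, cost=cost)


# ---------------------------------------------------------------------------
# windows and mean warped T waves


def extract_windows(
    pc_samples: np.ndarray,
    fs: float,
    ann,
    duration_h: float | None = None,
    window_minutes: tuple[int, ...] = (5, 35),
    width_min: float = 2.0,
    min_beats: int = 20,
    edge_exclude_s: float = 10.0,
    corr_reject: float = 0.95,
    duration_reject: float = 0.25,
) -> list[TWaveWindow]:
    """Collect T waves of the periodic component into 2-minute windows.

    One candidate window per grid point (minutes ``window_minutes`` of
    every hour) that fits inside the recording; per-window beat rejection
    discards waves whose duration deviates more than ``duration_reject``
    from the window median or whose correlation with the window average
    falls below ``corr_reject``.  Windows with fewer than ``min_beats``
    usable waves are flagged invalid, never dropped silently.
    """
    n = pc_samples.size
    if duration_h is None:
        duration_h = n / fs / 3600.0
    ok = ann.delineated()
    t_peak_s = ann.t_peak / fs

    centers = []
    hour = 0
    while hour <= int(np.ceil(duration_h)):
        for m in window_minutes:
            c = hour + m / 60.0
            half = width_min / 2.0 / 60.0
            if (c - half) * 3600.0 >= edge_exclude_s and (c + half) * 3600.0 <= n / fs - edge_exclude_s:
                centers.append(c)
        hour += 1

    windows = []
    for c in centers:
        half_s = width_min * 60.0 / 2.0
        in_win = ok & (t_peak_s >= c * 3600.0 - half_s) & (t_peak_s <= c * 3600.0 + half_s)
        idx = np.nonzero(in_win)[0]
        waves, durs, rrs = [], [], []
        for i in idx:
            a = int(np.floor(ann.t_onset[i]))
            b = int(np.ceil(ann.t_end[i]))
            if a < 0 or b >= n or b - a < 10:
                continue
            seg = pc_samples[a:b + 1]
            t_ms = (np.arange(a, b + 1) - ann.t_onset[i]) / fs * 1000.0
            waves.append((t_ms, seg))
            durs.append(t_ms[-1])
            rrs.append(ann.rr_ms[i])
        n_found = len(waves)
        if n_found == 0:
            windows.append(TWaveWindow(c, [], np.nan, 0, 0, False))
            continue
        durs = np.asarray(durs)
        med = np.median(durs)
        keep = np.abs(durs - med) <= duration_reject * med
        # correlation screen against the window average shape
        norm_grid = np.linspace(0.0, 1.0, 101)
        shapes = np.array([
            np.interp(norm_grid, w[0] / w[0][-1], w[1]) for w in waves
        ])
        if np.any(keep):
            mean_shape = shapes[keep].mean(axis=0)
            for k in np.nonzero(keep)[0]:
                c_ = np.corrcoef(shapes[k], mean_shape)[0, 1]
                if not np.isfinite(c_) or c_ < corr_reject:
                    keep[k] = False
        kept = [w for w, k in zip(waves, keep) if k]
        kept_rr = [r for r, k in zip(rrs, keep) if k]
        n_used = len(kept)
        windows.append(TWaveWindow(
            center_time_h=c,
            waves=kept,
            rr_median_ms=float(np.median(kept_rr)) if kept_rr else np.nan,
            n_used=n_used,
            n_rejected=n_found - n_used,
            valid=n_used >= min_beats,
        ))
    return windows


def compute_mwtw(
    win: TWaveWindow,
    grid_ms: float = 1.0,
    tol: float = 1e-3,
    max_iter: int = 10,
    max_step: int = 3,
) -> MeanWarpedTWave:
    """Iterative warped average of the window's T waves.

    The template starts as the wave of median duration (tie: shorter);
    each iteration warps every wave onto the template, averages the
    aligned amplitudes, and re-normalises the support to the mean wave
    duration.  Stops when the template changes by less than ``tol``
    (relative sup-norm) or after ``max_iter`` iterations (warned).
    """
    if not win.valid or not win.waves:
        raise ValueError("cannot average an invalid window")
    durs = np.array([w[0][-1] for w in win.waves])
    t_bar = float(np.mean(durs))
    n = max(int(round(t_bar / grid_ms)) + 1, 64)
    grid = np.linspace(0.0, t_bar, n)

    order = np.lexsort((np.arange(durs.size), np.abs(durs - np.median(durs)), ))
    # tie on distance-to-median resolved toward the shorter duration
    cand = np.nonzero(np.isclose(np.abs(durs - np.median(durs)),
                                 np.abs(durs[order[0]] - np.median(durs))))[0]
    init_idx = int(cand[np.argmin(durs[cand])])
    t0, f0 = win.waves[init_idx]
    template = MeanWarpedTWave(grid, _resample_uniform(t0, f0, n),
                               win.center_time_h, win.rr_median_ms)

    uniform_waves = [
        MeanWarpedTWave(np.linspace(0.0, tw[-1], max(int(round(tw[-1] / grid_ms)) + 1, 64)),
                        _resample_uniform(tw, fw, max(int(round(tw[-1] / grid_ms)) + 1, 64)))
        for tw, fw in win.waves
    ]

    converged = False
    for _ in range(max_iter):
        aligned = np.empty((len(uniform_waves), n))
        for k, w in enumerate(uniform_waves):
            if (w.t.size == n and np.isclose(w.t[-1], t_bar)
                    and np.allclose(w.f, template.f)):
                aligned[k] = w.f
                continue
            res = warp_pair(template, w, grid_ms=grid_ms, max_step=max_step,
                            sign_convention="wider_positive")
            gmap = np.interp(grid, res.t_ref, res.gamma)
            aligned[k] = np.interp(gmap, w.t, w.f)
        f_new = aligned.mean(axis=0)
        denom = max(float(np.max(np.abs(template.f))), 1e-12)
        delta = float(np.max(np.abs(f_new - template.f))) / denom
        template = MeanWarpedTWave(grid, f_new, win.center_time_h, win.rr_median_ms)
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("MWTW did not converge in %d iterations (window %.3f h)",
                    max_iter, win.center_time_h)
    template.converged = converged
    return template


# ---------------------------------------------------------------------------
# marker series and heart-rate correction


def select_reference(mwtws: list[MeanWarpedTWave], reference_hour: float) -> MeanWarpedTWave:
    """MWTW of the valid window nearest the end-of-dialysis hour (tie: earlier)."""
    if not mwtws:
        raise ValueError("no valid windows: patient unusable (no reference MWTW)")
    times = np.array([m.center_time_h for m in mwtws])
    d = np.abs(times - reference_hour)
    best = int(np.lexsort((times, d))[0])
    return mwtws[best]


def marker_series(
    mwtws: list[MeanWarpedTWave],
    reference: MeanWarpedTWave,
    all_window_times: np.ndarray | None = None,
    grid_ms: float = 0.5,
    max_step: int = 3,
    sign_convention: str = "narrower_positive",
) -> MarkerSeries:
    """d_w of every valid window against the fixed reference MWTW.

    The reference window itself scores exactly 0.  Windows not present in
    ``mwtws`` but listed in ``all_window_times`` appear as invalid points
    so gaps stay explicit.
    """
    times = [m.center_time_h for m in mwtws]
    dw = []
    rr = []
    for m in mwtws:
        if m is reference:
            dw.append(0.0)
        else:
            res = warp_pair(reference, m, grid_ms=grid_ms, max_step=max_step,
                            sign_convention=sign_convention)
            dw.append(res.dw)
        rr.append(m.rr_median_ms)
    times = np.asarray(times, float)
    dw = np.asarray(dw, float)
    rr = np.asarray(rr, float)
    valid = np.ones(times.size, dtype=bool)

    if all_window_times is not None:
        extra = [t for t in np.asarray(all_window_times, float)
                 if not np.any(np.isclose(t, times))]
        if extra:
            times = np.concatenate([times, extra])
            dw = np.concatenate([dw, np.full(len(extra), np.nan)])
            rr = np.concatenate([rr, np.full(len(extra), np.nan)])
            valid = np.concatenate([valid, np.zeros(len(extra), bool)])
            srt = np.argsort(times)
            times, dw, rr, valid = times[srt], dw[srt], rr[srt], valid[srt]

    return MarkerSeries(
        times_h=times, dw=dw, dwc=np.full_like(dw, np.nan), rr_ms=rr,
        valid=valid, reference_time_h=float(reference.center_time_h),
    )


def hr_correct(series: MarkerSeries, stability_h: float = 4.0) -> MarkerSeries:
    """Heart-rate corrected marker d_w,c = d_w - c*(sqrt(RR) - sqrt(RR_ref)).

    The slope c is fitted per patient by least squares (through the
    origin) on a late post-dialysis stability segment — the final
    ``stability_h`` hours of the session, where potassium-driven marker
    dynamics are low and residual d_w variation tracks RR.  If the
    segment is missing or RR is constant there, c falls back to 0 and
    d_w,c = d_w (warned).
    """
    ok = series.valid & np.isfinite(series.dw) & np.isfinite(series.rr_ms)
    ref_i = np.nonzero(ok & np.isclose(series.times_h, series.reference_time_h))[0]
    if ref_i.size == 0:
        raise ValueError("reference window missing from series")
    rr_ref = series.rr_ms[ref_i[0]]
    z = np.sqrt(series.rr_ms) - np.sqrt(rr_ref)

    t_max = np.max(series.times_h[ok])
    seg = ok & (series.times_h >= t_max - stability_h)
    seg &= ~np.isclose(series.times_h, series.reference_time_h)
    c_hat = 0.0
    if np.count_nonzero(seg) >= 2 and np.sum(z[seg] ** 2) > 1e-12:
        c_hat = float(np.sum(z[seg] * series.dw[seg]) / np.sum(z[seg] ** 2))
    else:
        log.warning("no usable stability segment; heart-rate correction disabled (c=0)")

    dwc = series.dw - c_hat * z
    dwc[ref_i[0]] = 0.0
    return MarkerSeries(
        times_h=series.times_h.copy(), dw=series.dw.copy(), dwc=dwc,
        rr_ms=series.rr_ms.copy(), valid=series.valid.copy(),
        reference_time_h=series.reference_time_h, c_hat=c_hat,
    )


def markers_at_hours(series: MarkerSeries, sample_hours) -> dict:
    """Pair each blood-sample hour with the nearest valid window (tie: earlier)."""
    hrs = np.asarray(sample_hours, float)
    ok = series.valid & np.isfinite(series.dw)
    if not np.any(ok):
        raise ValueError("no valid marker windows")
    t_ok = series.times_h[ok]
    dw_ok = series.dw[ok]
    dwc_ok = series.dwc[ok]
    rr_ok = series.rr_ms[ok]
    dw, dwc, rr, w_t = [], [], [], []
    for h in hrs:
        d = np.abs(t_ok - h)
        j = int(np.lexsort((t_ok, d))[0])
        dw.append(dw_ok[j])
        dwc.append(dwc_ok[j])
        rr.append(rr_ok[j])
        w_t.append(t_ok[j])
    return {
        "hours": hrs,
        "dw": np.asarray(dw),
        "dwc": np.asarray(dwc),
        "rr_ms": np.asarray(rr),
        "window_time_h": np.asarray(w_t),
    }
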