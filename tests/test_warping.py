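"""Elastic T-wave alignment: DP vs exhaustive oracle, closed forms,
mean warped T waves, marker series and heart-rate correction."""

import numpy as np
import pytest

from conftest import spearman_bruteforce
from kwarp.warping import (
    MarkerSeries,
    MeanWarpedTWave,
    TWaveWindow,
    compute_mwtw,
    dp_warp,
    extract_windows,
    hr_correct,
    marker_series,
    markers_at_hours,
    select_reference,
    warp_pair,
    _srsf,
)


def _cosine_wave(width_ms: float, amp: float = 350.0, grid_ms: float = 0.5,
                 skew: float = 0.0) -> MeanWarpedTWave:
    """Raised-cosine T lobe, optionally skewed to break symmetry."""
    t = np.arange(0.0, width_ms + grid_ms / 2, grid_ms)
    u = t / width_ms
    if skew:
        u = u**(1.0 + skew)
    f = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    return MeanWarpedTWave(t, f)


# ---------------------------------------------------------------------------
# dynamic programming vs exhaustive monotone-path search


def _edge_cost_oracle(q1, q2, i0, j0, di, dj):
    """Independent re-derivation of the per-edge SRSF cost (trapezoid)."""
    n = q1.size
    dt = 1.0 / (n - 1)
    m = dj / di
    s = np.sqrt(m)
    total = 0.0
    for k in range(di + 1):
        off = j0 + k * m
        b = int(np.floor(off + 1e-12))
        frac = off - b
        if frac < 1e-12:
            q2v = q2[b]
        else:
            q2v = (1.0 - frac) * q2[b] + frac * q2[b + 1]
        g = (q1[i0 + k] - s * q2v) ** 2
        total += g * (0.5 if k in (0, di) else 1.0)
    return total * dt


def _exhaustive_warp(q1, q2, max_step):
    """Enumerate every monotone lattice path; return (best path, cost)."""
    n = q1.size
    steps = [(a, b) for a in range(1, max_step + 1) for b in range(1, max_step + 1)]
    best = {"cost": np.inf, "path": None}

    def recurse(i, j, cost, path):
        if cost >= best["cost"]:
            return
        if i == n - 1 and j == n - 1:
            best["cost"] = cost
            best["path"] = list(path)
            return
        for di, dj in steps:
            ni, nj = i + di, j + dj
            if ni <= n - 1 and nj <= n - 1:
                c = _edge_cost_oracle(q1, q2, i, j, di, dj)
                path.append((ni, nj))
                recurse(ni, nj, cost + c, path)
                path.pop()

    recurse(0, 0, 0.0, [(0, 0)])
    return np.asarray(best["path"]), best["cost"]


@pytest.mark.parametrize("max_step", [2, 3])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dp_matches_exhaustive_path_search(max_step, seed):
    """On 12-sample waves the DP solution equals brute-force enumeration."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, 12)
    f1 = np.sin(np.pi * t) + 0.3 * rng.standard_normal(12).cumsum() / 12
    f2 = np.sin(np.pi * t**1.2) + 0.3 * rng.standard_normal(12).cumsum() / 12
    q1, q2 = _srsf(f1), _srsf(f2)
    path_dp, cost_dp = dp_warp(q1, q2, max_step=max_step)
    path_ex, cost_ex = _exhaustive_warp(q1, q2, max_step)
    assert cost_dp == pytest.approx(cost_ex, rel=1e-12, abs=1e-15)
    np.testing.assert_array_equal(path_dp, path_ex)


# ---------------------------------------------------------------------------
# warp_pair closed forms and contracts


def test_identity_pair_zero_marker():
    w = _cosine_wave(180.0, skew=0.2)
    res = warp_pair(w, w)
    assert res.dwu == pytest.approx(0.0, abs=1e-9)
    assert res.dw == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(res.gamma, res.t_ref, atol=1e-6)


def test_pure_scaling_matches_closed_form():
    """10 % wider test wave: gamma = 1.1 t, dwu = 0.05 T_ref, dw convention."""
    T = 180.0
    ref = _cosine_wave(T)
    test = _cosine_wave(1.1 * T)
    res = warp_pair(ref, test, sign_convention="wider_positive")
    assert res.dwu == pytest.approx(0.05 * T, rel=0.05)
    assert res.dw > 0
    np.testing.assert_allclose(res.gamma, 1.1 * res.t_ref, rtol=1e-6, atol=1e-3)
    # default (narrowing-positive) convention flips the sign
    res2 = warp_pair(ref, test, sign_convention="narrower_positive")
    assert res2.dw == pytest.approx(-res.dw)
    # and a narrower test wave scores positive under the default
    res3 = warp_pair(ref, _cosine_wave(0.9 * T))
    assert res3.dw > 0


def test_known_warping_recovered():
    """test = ref o gamma^-1 with smooth monotone gamma: 2 ms RMS recovery."""
    T = 180.0
    ref = _cosine_wave(T, skew=0.15)
    tt = ref.t / T
    gam = tt + 0.05 * np.sin(np.pi * tt)
    ginv = np.interp(tt, gam, tt)
    test = MeanWarpedTWave(ref.t, np.interp(ginv, tt, ref.f))
    res = warp_pair(ref, test)
    true_gamma = np.interp(res.t_ref / T, tt, gam) * T
    rms = np.sqrt(np.mean((res.gamma - true_gamma) ** 2))
    assert rms <= 2.0


def test_warping_symmetry_bound():
    """dwu(ref, test) and dwu(test, ref) agree within 10 % on smooth pairs."""
    a = _cosine_wave(180.0, skew=0.1)
    b = _cosine_wave(200.0, skew=0.25)
    d_ab = warp_pair(a, b).dwu
    d_ba = warp_pair(b, a).dwu
    assert abs(d_ab - d_ba) <= 0.10 * max(d_ab, d_ba)


def test_gamma_monotone_and_sign_invariant():
    rng = np.random.default_rng(5)
    for _ in range(10):
        w1 = _cosine_wave(rng.uniform(140, 220), skew=rng.uniform(0, 0.3))
        w2 = _cosine_wave(rng.uniform(140, 220), skew=rng.uniform(0, 0.3))
        res = warp_pair(w1, w2)
        assert np.all(np.diff(res.gamma) >= 0)
        assert abs(res.dw) == pytest.approx(res.dwu)


def test_degenerate_waves_rejected():
    flat = MeanWarpedTWave(np.arange(0.0, 100.0, 0.5), np.zeros(200))
    good = _cosine_wave(180.0)
    with pytest.raises(ValueError, match="unwarpable"):
        warp_pair(good, flat)
    short = MeanWarpedTWave(np.arange(10.0), np.sin(np.arange(10.0)))
    with pytest.raises(ValueError, match="50 samples"):
        warp_pair(good, short)


# ---------------------------------------------------------------------------
# mean warped T waves


def _window_of(waves, center_h=1.0, rr=900.0):
    return TWaveWindow(center_time_h=center_h,
                       waves=[(w.t, w.f) for w in waves],
                       rr_median_ms=rr, n_used=len(waves), n_rejected=0, valid=True)


def test_mwtw_of_identical_waves_is_fixed_point():
    w = _cosine_wave(180.0, grid_ms=1.0, skew=0.2)
    win = _window_of([w] * 8)
    m = compute_mwtw(win, grid_ms=1.0)
    assert m.duration_ms == pytest.approx(180.0, abs=1e-9)
    ref = np.interp(m.t, w.t, w.f)
    assert np.max(np.abs(m.f - ref)) < 1e-9


def test_mwtw_of_scaled_pair_has_mean_duration():
    """0.9x and 1.1x time-scalings of one shape average to the 1.0x width."""
    win = _window_of([_cosine_wave(0.9 * 180.0), _cosine_wave(1.1 * 180.0)])
    m = compute_mwtw(win, grid_ms=1.0)
    assert m.duration_ms == pytest.approx(180.0, rel=0.02)


def test_mwtw_order_invariance():
    waves = [_cosine_wave(w, skew=s)
             for w, s in [(170, 0.0), (180, 0.1), (190, 0.2), (175, 0.05)]]
    win1 = _window_of(waves)
    win2 = _window_of(waves[::-1])
    m1 = compute_mwtw(win1, grid_ms=1.0)
    m2 = compute_mwtw(win2, grid_ms=1.0)
    np.testing.assert_allclose(m1.f, m2.f, atol=1e-9)
    assert m1.duration_ms == m2.duration_ms


def test_invalid_window_rejected():
    win = TWaveWindow(1.0, [], np.nan, 0, 0, False)
    with pytest.raises(ValueError, match="invalid window"):
        compute_mwtw(win)


# ---------------------------------------------------------------------------
# window extraction (on fabricated annotations)


def _fabricated_record(duration_h=3.0, fs=250.0, rr_ms=1000.0, width_ms=180.0):
    """Periodic raised-cosine T waves with exact annotations, cheap to build."""
    from kwarp.preprocess import BeatAnnotations

    n = int(duration_h * 3600 * fs)
    x = np.zeros(n)
    beat = int(rr_ms / 1000.0 * fs)
    r_idx = np.arange(int(0.5 * fs), n - beat, beat)
    on = r_idx + int(0.140 * fs)
    wid = int(width_ms / 1000.0 * fs)
    tpl = 300.0 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(wid + 1) / wid))
    for o in on:
        x[o:o + wid + 1] += tpl
    ann = BeatAnnotations(
        qrs=r_idx, t_onset=on.astype(float),
        t_peak=(on + wid / 2).astype(float), t_end=(on + wid).astype(float),
        rr_ms=np.full(r_idx.size, rr_ms), fs=fs)
    return x, fs, ann


def test_window_grid_and_counts():
    x, fs, ann = _fabricated_record(duration_h=3.0)
    wins = extract_windows(x, fs, ann, duration_h=3.0)
    assert len(wins) == 6  # 2 windows/hour on a 3 h record
    assert all(w.valid for w in wins)
    assert all(w.n_rejected == 0 for w in wins)  # clean input: no rejections
    assert all(abs(w.rr_median_ms - 1000.0) < 1e-9 for w in wins)
    # ~2 min of beats at RR 1000 ms
    assert all(100 <= w.n_used <= 121 for w in wins)


def test_window_over_signal_gap_flagged_invalid():
    x, fs, ann = _fabricated_record(duration_h=2.0)
    # blank out the second window's beats (minute 35 +- 1)
    lo, hi = int((35 - 1) * 60 * fs), int((35 + 1) * 60 * fs)
    keep = ~((ann.t_peak >= lo) & (ann.t_peak <= hi))
    from kwarp.preprocess import BeatAnnotations
    ann2 = BeatAnnotations(ann.qrs[keep], ann.t_onset[keep], ann.t_peak[keep],
                           ann.t_end[keep], ann.rr_ms[keep], fs)
    wins = extract_windows(x, fs, ann2, duration_h=2.0)
    assert wins[1].valid is False and wins[1].n_used == 0
    assert all(w.valid for i, w in enumerate(wins) if i != 1)


# ---------------------------------------------------------------------------
# marker series and heart-rate correction


def _mwtw_series(widths_by_hour, rr_by_hour=None):
    """One MWTW per 'hour' with prescribed width (and optional RR)."""
    out = []
    for i, w in enumerate(widths_by_hour):
        m = _cosine_wave(w, grid_ms=0.5)
        m.center_time_h = float(i)
        m.rr_median_ms = 900.0 if rr_by_hour is None else rr_by_hour[i]
        out.append(m)
    return out


def test_marker_series_zero_at_reference_and_tracks_potassium():
    """Noise-free monotone coupling: Spearman(dw, dK) = 1 at the sample hours."""
    dk = np.array([2.0, 1.4, 0.8, 0.4, 0.0, 1.6])
    widths = 180.0 * (1.0 - 0.05 * dk)   # narrower when potassium is higher
    mwtws = _mwtw_series(widths)
    ref = select_reference(mwtws, reference_hour=4.0)
    assert ref.center_time_h == 4.0
    series = marker_series(mwtws, ref)
    assert series.dw[4] == 0.0
    assert spearman_bruteforce(series.dw, dk) == pytest.approx(1.0)
    assert np.all(series.dw[dk > 0] > 0)  # narrowing scores positive


def test_marker_series_keeps_missing_windows_explicit():
    mwtws = _mwtw_series([180.0, 170.0])
    ref = select_reference(mwtws, 0.0)
    series = marker_series(mwtws, ref, all_window_times=np.array([0.0, 1.0, 2.5]))
    assert series.times_h.size == 3
    assert not series.valid[2] and np.isnan(series.dw[2])


def test_reference_selection_tie_breaks_earlier():
    mwtws = _mwtw_series([180.0, 175.0, 170.0])
    # hours 0,1,2; reference time 0.5 is equidistant from 0 and 1
    assert select_reference(mwtws, 0.5).center_time_h == 0.0
    with pytest.raises(ValueError, match="unusable"):
        select_reference([], 0.5)


def test_hr_correction_constant_rr_is_identity():
    widths = 180.0 * (1.0 - 0.05 * np.array([2.0, 1.4, 0.8, 0.4, 0.0, 1.6]))
    mwtws = _mwtw_series(widths)  # constant RR by default
    series = marker_series(mwtws, select_reference(mwtws, 4.0))
    out = hr_correct(series, stability_h=10.0)
    np.testing.assert_allclose(out.dwc, out.dw, atol=1e-12)
    assert out.c_hat == 0.0


def test_hr_correction_removes_rr_driven_changes():
    """All T-width change RR-driven: |dwc| shrinks well below |dw|."""
    rr = np.array([700.0, 760.0, 820.0, 870.0, 900.0, 1000.0])
    widths = 180.0 * (1.0 + 0.4 * (np.sqrt(rr) - np.sqrt(900.0)) / np.sqrt(900.0))
    mwtws = _mwtw_series(widths, rr_by_hour=rr)
    series = marker_series(mwtws, select_reference(mwtws, 4.0))
    out = hr_correct(series, stability_h=10.0)  # whole series is 'stable'
    sel = np.arange(6) != 4
    assert np.mean(np.abs(out.dwc[sel])) < 0.3 * np.mean(np.abs(out.dw[sel]))


def test_hr_correction_falls_back_without_stability_segment(caplog):
    widths = [170.0, 175.0, 180.0]
    rr = [850.0, 860.0, 870.0]
    mwtws = _mwtw_series(widths, rr_by_hour=rr)
    series = marker_series(mwtws, select_reference(mwtws, 2.0))
    with caplog.at_level("WARNING"):
        out = hr_correct(series, stability_h=1e-6)  # no non-reference point inside
    assert out.c_hat == 0.0
    np.testing.assert_allclose(out.dwc, out.dw, atol=1e-12)


def test_markers_at_hours_nearest_window_pairing():
    mwtws = _mwtw_series([180.0, 175.0, 172.0, 171.0, 180.0, 168.0])
    series = marker_series(mwtws, select_reference(mwtws, 4.0))
    got = markers_at_hours(series, [0.2, 1.9, 4.0, 5.4])
    np.testing.assert_allclose(got["window_time_h"], [0.0, 2.0, 4.0, 5.0])
    assert got["dw"][2] == 0.0
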