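"""Per-patient polynomial models relating warping markers to Delta[K+].

For each patient and marker d (d_w or d_w,c), intercept-free linear,
quadratic and cubic models estimate the potassium variation relative to
the end-of-dialysis reference sample h4:

    linear     dK^ = alpha_l d
    quadratic  dK^ = alpha_q d + beta_q d^2
    cubic      dK^ = alpha_c d + beta_c d^2 + gamma_c d^3

Coefficients are fitted by least squares; the physiological constraint
that dK^ increase monotonically with d (T-wave narrowing tracks rising
potassium) is enforced by restricting all coefficients to be
non-negative (non-negative least squares), which guarantees a
non-negative derivative for d > 0.  Two estimation rules are used:
"a" trains on all six samples; "o" is leave-one-out cross-validation
over the five non-reference hours (h4, where marker and Delta[K+] are
zero by construction, stays in every training set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

HOUR_LABELS = ("h0", "h1", "h2", "h3", "h4", "h5")
ERROR_HOURS = ("h0", "h1", "h2", "h3", "h5")  # h4 excluded: both series are 0 there
ORDER_DEGREE = {"l": 1, "q": 2, "c": 3}


@dataclass
class PotassiumSeries:
    """[K+] at the six sample hours and its variation versus the reference."""

    hours: tuple[str, ...]
    times_h: np.ndarray
    k_mmol: np.ndarray
    delta_k: np.ndarray
    reference_hour: str = "h4"

    @property
    def reference_index(self) -> int:
        return self.hours.index(self.reference_hour)


def delta_k(k_mmol, times_h=None, hours: tuple[str, ...] = HOUR_LABELS,
            reference_hour: str = "h4") -> PotassiumSeries:
    """Delta[K+](hi) = [K+]hi - [K+]h4 (elementwise vs the reference sample)."""
    k = np.asarray(k_mmol, float)
    if k.size != len(hours):
        raise ValueError(f"expected {len(hours)} [K+] values, got {k.size}")
    if reference_hour not in hours:
        raise ValueError(f"missing reference hour {reference_hour}")
    ref = k[hours.index(reference_hour)]
    if not np.isfinite(ref):
        raise ValueError("reference [K+] is missing")
    t = np.asarray(times_h, float) if times_h is not None else np.arange(k.size, dtype=float)
    return PotassiumSeries(tuple(hours), t, k, k - ref, reference_hour)


@dataclass
class PolynomialModel:
    """Intercept-free polynomial sensing model for one patient/marker/order."""

    marker: str                  # "dw" | "dwc"
    order: str                   # "l" | "q" | "c"
    rule: str                    # "a" | "o" (o-models also note the held-out hour)
    coefficients: tuple[float, ...]
    constrained: bool = True
    training_hours: tuple[str, ...] = HOUR_LABELS
    held_out: str | None = None

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, float)
        out = np.zeros_like(d)
        for k, c in enumerate(self.coefficients, start=1):
            out += c * d**k
        return out

    def derivative(self, d) -> np.ndarray:
        d = np.asarray(d, float)
        out = np.zeros_like(d)
        for k, c in enumerate(self.coefficients, start=1):
            out += k * c * d ** (k - 1)
        return out

    def to_dict(self) -> dict:
        return {
            "marker": self.marker, "order": self.order, "rule": self.rule,
            "coefficients": list(self.coefficients), "constrained": self.constrained,
            "training_hours": list(self.training_hours), "held_out": self.held_out,
        }


def fit_model(d, dk, order: str = "l", constrained: bool = True,
              marker: str = "dw", rule: str = "a") -> PolynomialModel:
    """Least-squares fit of one intercept-free polynomial model.

    With ``constrained`` (the default) the non-negative least squares
    problem is solved on the Vandermonde design without intercept,
    forcing every coefficient >= 0 and hence a monotone non-decreasing
    model for d > 0.  Deterministic (active-set NNLS, no seeds).
    """
    d = np.asarray(d, float)
    dk = np.asarray(dk, float)
    m = np.isfinite(d) & np.isfinite(dk)
    d, dk = d[m], dk[m]
    deg = ORDER_DEGREE[order]
    if d.size < deg + 1:
        raise ValueError(f"need at least {deg + 1} points for order {order!r}")
    if np.max(np.abs(d)) < 1e-12:
        raise ValueError("degenerate design: all marker values are zero")
    V = np.column_stack([d**k for k in range(1, deg + 1)])
    if constrained:
        coef, _ = optimize.nnls(V, dk)
    else:
        coef, *_ = np.linalg.lstsq(V, dk, rcond=None)
    return PolynomialModel(marker, order, rule, tuple(float(c) for c in coef),
                           constrained=constrained)


def estimate(model: PolynomialModel, d) -> np.ndarray:
    """Evaluate the model at marker values (the reference d = 0 maps to 0)."""
    return model.predict(d)


def fit_all_patient(
    d_by_marker: dict[str, np.ndarray],
    k: PotassiumSeries,
    orders=("l", "q", "c"),
    constrained: bool = True,
    min_points: int = 4,
) -> dict[tuple[str, str], PolynomialModel]:
    """All-samples ("m = a") models: one per (marker, order), trained on h0..h5.

    Hours with a missing marker are dropped (warned via ValueError if
    fewer than ``min_points`` remain).
    """
    out = {}
    for marker, d in d_by_marker.items():
        d = np.asarray(d, float)
        m = np.isfinite(d) & np.isfinite(k.delta_k)
        if np.count_nonzero(m) < min_points:
            raise ValueError(f"marker {marker}: only {np.count_nonzero(m)} usable hours")
        hours = tuple(h for h, keep in zip(k.hours, m) if keep)
        for order in orders:
            mod = fit_model(d[m], k.delta_k[m], order=order, constrained=constrained,
                            marker=marker, rule="a")
            mod.training_hours = hours
            out[(marker, order)] = mod
    return out


def loo_cv(
    d_by_marker: dict[str, np.ndarray],
    k: PotassiumSeries,
    orders=("l", "q", "c"),
    constrained: bool = True,
) -> dict[tuple[str, str], np.ndarray]:
    """Leave-one-out ("m = o") estimates over the six hours.

    Each non-reference hour hi in turn is excluded from training (the h4
    reference always stays in) and the refit model predicts at hi.  The
    returned series holds the held-out prediction at each non-reference
    hour and 0 at h4.
    """
    ref_i = k.reference_index
    out = {}
    for marker, d in d_by_marker.items():
        d = np.asarray(d, float)
        for order in orders:
            est = np.zeros(len(k.hours))
            for i, h in enumerate(k.hours):
                if i == ref_i:
                    continue
                train = np.ones(len(k.hours), dtype=bool)
                train[i] = False
                train &= np.isfinite(d) & np.isfinite(k.delta_k)
                mod = fit_model(d[train], k.delta_k[train], order=order,
                                constrained=constrained, marker=marker, rule="o")
                mod.held_out = h
                est[i] = mod.predict(d[i])
            out[(marker, order)] = est
    return out


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalResult:
    """Correlations and errors across patients, aggregated as median (IQR)."""

    per_patient: pd.DataFrame     # patient, marker, order, rule, rho, r
    errors: pd.DataFrame          # patient, marker, order, rule, hour, error
    summary: pd.DataFrame         # marker, order, rule, rho/r med+iqr, e med+iqr ALL/h0/h5


def _iqr(x: np.ndarray) -> float:
    return float(np.percentile(x, 75) - np.percentile(x, 25))


def correlations(dk: np.ndarray, est: np.ndarray, min_pairs: int = 3):
    """Spearman rho (mid-rank ties) and Pearson r; NaN when degenerate."""
    m = np.isfinite(dk) & np.isfinite(est)
    if np.count_nonzero(m) < min_pairs:
        return np.nan, np.nan
    x, y = dk[m], est[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    return rho, r


def evaluate(
    estimates: dict[tuple[str, str, str], np.ndarray],
    k_by_patient: dict[str, PotassiumSeries],
    include_reference_in_corr: bool = True,
) -> EvalResult:
    """Evaluate estimate series against measured Delta[K+].

    ``estimates`` maps (patient, marker, ``order:rule``) -> series over
    the six hours.  Correlations are per patient over the six points
    (optionally excluding the degenerate h4 pair); errors e(hi) =
    estimate - Delta[K+] are defined at the five non-reference hours
    only.  The summary aggregates across patients as median (IQR),
    pooled over all error hours (ALL) and segregated for h0 and h5.
    """
    pp_rows, err_rows = [], []
    for (pid, marker, combo), est in estimates.items():
        order, rule = combo.split(":")
        k = k_by_patient[pid]
        dk = k.delta_k
        est = np.asarray(est, float)
        sel = np.ones(dk.size, dtype=bool)
        if not include_reference_in_corr:
            sel[k.reference_index] = False
        rho, r = correlations(dk[sel], est[sel])
        pp_rows.append({"patient": pid, "marker": marker, "order": order,
                        "rule": rule, "rho": rho, "r": r})
        for i, h in enumerate(k.hours):
            if i == k.reference_index:
                continue
            err_rows.append({"patient": pid, "marker": marker, "order": order,
                             "rule": rule, "hour": h, "error": est[i] - dk[i]})
    per_patient = pd.DataFrame(pp_rows)
    errors = pd.DataFrame(err_rows)

    sum_rows = []
    if not per_patient.empty:
        for (marker, order, rule), g in per_patient.groupby(["marker", "order", "rule"]):
            ge = errors[(errors.marker == marker) & (errors.order == order)
                        & (errors.rule == rule)]
            abs_all = np.abs(ge.error.to_numpy())
            row = {
                "marker": marker, "order": order, "rule": rule,
                "rho_median": float(np.nanmedian(g.rho)),
                "rho_iqr": _iqr(g.rho.dropna().to_numpy()) if g.rho.notna().any() else np.nan,
                "r_median": float(np.nanmedian(g.r)),
                "r_iqr": _iqr(g.r.dropna().to_numpy()) if g.r.notna().any() else np.nan,
                "e_all_median": float(np.median(abs_all)),
                "e_all_iqr": _iqr(abs_all),
            }
            for h in ("h0", "h5"):
                eh = np.abs(ge[ge.hour == h].error.to_numpy())
                row[f"e_{h}_median"] = float(np.median(eh)) if eh.size else np.nan
                row[f"e_{h}_iqr"] = _iqr(eh) if eh.size else np.nan
            sum_rows.append(row)
    summary = pd.DataFrame(sum_rows)
    return EvalResult(per_patient=per_patient, errors=errors, summary=summary)


def models_to_json(models: dict, path) -> None:
    obj = {f"{m}:{o}": mod.to_dict() for (m, o), mod in models.items()}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
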