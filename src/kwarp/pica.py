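"""Periodic component analysis (piCA) for lead-space reduction.

piCA finds spatial combinations of the 8 independent leads that are
maximally periodic from one beat to the next.  With the periodicity
measure restricted to the T-wave segment (mode ``piCT``, the default) the
first component concentrates the repolarisation signal while pushing
uncorrelated noise into later components; ``piCB`` uses the whole QRST.

For lead vector x(t), beat-to-beat periodicity of a combination w is

    eps(w) = E||w'x(t') - w'x(t)||^2 / E||w'x(t)||^2,

where t' is the time-aligned sample of the next beat (alignment by
fiducial anchoring plus per-beat linear time normalisation of the
segment).  Minimising eps is the generalized eigenproblem A w = lambda B w
with A the covariance of beat-to-beat differences and B the total
covariance; components are ordered by ascending eigenvalue, so component 1
(piC1) is the most periodic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .preprocess import BeatAnnotations, EcgRecording


@dataclass
class PicaTransform:
    """Fitted spatial transformation; rows of ``psi`` are component weights.

    Rows are normalised to unit norm under the total-covariance metric
    (w' B w = 1), which also makes components mutually uncorrelated.
    """

    psi: np.ndarray                 # (8, 8)
    eigenvalues: np.ndarray         # ascending; [0] = most periodic
    mode: str                       # "piCT" | "piCB"
    leads: tuple[str, ...]
    segment_samples: int
    n_pairs: int
    # covariances kept for diagnostics (Rayleigh-quotient checks); not serialized
    diff_cov: np.ndarray | None = field(default=None, repr=False)
    total_cov: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path) -> None:
        obj = {
            "psi": self.psi.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "mode": self.mode,
            "leads": list(self.leads),
            "segment_samples": self.segment_samples,
            "n_pairs": self.n_pairs,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @staticmethod
    def from_json(path) -> "PicaTransform":
        with open(path) as fh:
            obj = json.load(fh)
        return PicaTransform(
            psi=np.asarray(obj["psi"], float),
            eigenvalues=np.asarray(obj["eigenvalues"], float),
            mode=obj["mode"],
            leads=tuple(obj["leads"]),
            segment_samples=int(obj["segment_samples"]),
            n_pairs=int(obj["n_pairs"]),
        )


@dataclass
class PeriodicComponent:
    """piC1 series (arbitrary units) plus a reference to its transform."""

    samples: np.ndarray
    transform: PicaTransform

    @property
    def n_samples(self) -> int:
        return self.samples.size


def _segment_bounds(ann: BeatAnnotations, mode: str, fs: float):
    """Per-beat (start, end) sample indices of the periodicity segment."""
    if mode == "piCT":
        return ann.t_onset, ann.t_end
    if mode == "piCB":
        qrs_lead = ann.qrs - int(round(0.05 * fs))  # from just before the QRS
        return qrs_lead.astype(float), ann.t_end
    raise ValueError(f"unknown piCA mode {mode!r}")


def fit_pica(
    rec: EcgRecording,
    ann: BeatAnnotations,
    mode: str = "piCT",
    segment_samples: int | None = None,
    min_beats: int = 100,
    edge_exclude_s: float = 10.0,
) -> PicaTransform:
    """Estimate the piCA transform from one recording.

    Consecutive delineated beats form the sample pairs; each beat's
    segment is linearly resampled to a fixed length (T wave: 400, QRST:
    600) so one-beat periodicity is well defined under RR drift.
    """
    if len(rec.leads) != 8:
        raise ValueError("piCA expects the 8 independent leads")
    if segment_samples is None:
        segment_samples = 400 if mode == "piCT" else 600
    starts, ends = _segment_bounds(ann, mode, rec.fs)
    ok = ann.delineated() & np.isfinite(starts) & np.isfinite(ends)
    # keep clear of the zero-phase filters' edge transients
    margin = edge_exclude_s * rec.fs
    ok &= starts >= margin
    ok &= ends < rec.n_samples - margin
    pair_idx = [i for i in range(ann.n_beats - 1) if ok[i] and ok[i + 1]]
    if len(pair_idx) < min_beats:
        raise ValueError(
            f"piCA needs at least {min_beats} consecutive delineated beat pairs, "
            f"got {len(pair_idx)}"
        )

    nl = len(rec.leads)
    A = np.zeros((nl, nl))
    B = np.zeros((nl, nl))
    n_obs = 0
    X = rec.samples
    beats_needed = sorted({i for p in pair_idx for i in (p, p + 1)})
    seg_cache: dict[int, np.ndarray] = {}
    for i in beats_needed:
        # linear time-normalisation of all leads at once
        idx = np.linspace(starts[i], ends[i], segment_samples)
        i0 = np.floor(idx).astype(int)
        frac = idx - i0
        i1 = np.minimum(i0 + 1, X.shape[1] - 1)
        seg_cache[i] = X[:, i0] * (1.0 - frac) + X[:, i1] * frac
    for i in pair_idx:
        cur, nxt = seg_cache[i], seg_cache[i + 1]
        d = nxt - cur
        A += d @ d.T
        B += cur @ cur.T
        n_obs += segment_samples
    A /= n_obs
    B /= n_obs

    bvals = np.linalg.eigvalsh(B)
    if bvals[0] <= 0 or bvals[0] / bvals[-1] < 1e-12:
        raise ValueError("leads linearly dependent: total covariance is rank-deficient")

    evals, evecs = linalg.eigh(A, B)  # ascending; evecs B-orthonormal
    psi = evecs.T.copy()

    # sign convention: median T-peak amplitude of each component positive
    pk = ann.t_peak[ok]
    pk_idx = np.round(pk[np.isfinite(pk)]).astype(int)
    comps = psi @ X[:, pk_idx] if pk_idx.size else psi @ X[:, ann.qrs]
    flip = np.median(comps, axis=1) < 0
    psi[flip] *= -1.0

    return PicaTransform(
        psi=psi,
        eigenvalues=np.asarray(evals, float),
        mode=mode,
        leads=rec.leads,
        segment_samples=segment_samples,
        n_pairs=len(pair_idx),
        diff_cov=A,
        total_cov=B,
    )


def apply_transform(rec: EcgRecording, tr: PicaTransform, component: int = 0) -> PeriodicComponent:
    """Project the record onto one periodic component (default piC1)."""
    if rec.leads != tr.leads:
        raise ValueError(f"lead mismatch: record {rec.leads} vs transform {tr.leads}")
    return PeriodicComponent(samples=tr.psi[component] @ rec.samples, transform=tr)


def apply_all(rec: EcgRecording, tr: PicaTransform) -> np.ndarray:
    """All 8 transformed leads, most periodic first."""
    if rec.leads != tr.leads:
        raise ValueError("lead mismatch")
    return tr.psi @ rec.samples


def periodicity_quotient(tr: PicaTransform, w: np.ndarray) -> float:
    """eps(w) = w'Aw / w'Bw for an arbitrary direction (diagnostic oracle)."""
    if tr.diff_cov is None or tr.total_cov is None:
        raise ValueError("transform carries no covariances (deserialized?)")
    w = np.asarray(w, float)
    return float(w @ tr.diff_cov @ w) / float(w @ tr.total_cov @ w)
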