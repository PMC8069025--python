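"""Shared fixtures: compressed synthetic sessions and one pipeline run.

Sessions are time-compressed (minutes-scale "hours", 500 Hz) so the full
signal path runs at test speed; all stage settings are ordinary config.
"""

import numpy as np
import pytest

from kwarp.config import PipelineConfig
from kwarp.pipeline import run_pipeline
from kwarp.simulate import (
    KTrajectory,
    MorphologyCoupling,
    SessionProtocol,
    generate_session,
)

# six sample hours aligned with a 4-windows-per-hour grid
COMPRESSED_HOURS = (5 / 60, 20 / 60, 35 / 60, 50 / 60, 65 / 60, 80 / 60)
K_DEFAULT = (5.6, 5.0, 4.4, 4.0, 3.6, 5.2)


def compressed_config(seed: int = 7, n_patients: int = 1) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.seed = seed
    s = cfg.simulate
    s.n_patients = n_patients
    s.duration_h = 1.5
    s.fs = 500.0
    s.sample_hours = COMPRESSED_HOURS
    s.hd_end_h = COMPRESSED_HOURS[4]
    cfg.windows.minutes = (5, 20, 35, 50)
    cfg.correction.stability_h = 0.4
    return cfg


def short_protocol(duration_h: float = 0.2, fs: float = 500.0) -> SessionProtocol:
    hrs = tuple(duration_h * f for f in (0.0, 0.15, 0.3, 0.45, 0.6, 0.9))
    return SessionProtocol(
        duration_h=duration_h, sample_hours=hrs, hd_end_h=hrs[4], fs=fs,
    )


CLEAN_COUPLING = MorphologyCoupling(
    noise_uv=0.0, wander_uv=0.0, rr_jitter=0.0, rr_width_gain=0.0
)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free session: [K+]-driven T-width modulation only."""
    proto = short_protocol()
    traj = KTrajectory(proto.sample_hours, K_DEFAULT)
    rec, gt = generate_session(proto, traj, CLEAN_COUPLING, seed=1)
    return proto, rec, gt


@pytest.fixture(scope="session")
def noisy_session():
    """Session with 20 uV broadband noise plus baseline wander."""
    proto = short_protocol()
    traj = KTrajectory(proto.sample_hours, K_DEFAULT)
    coup = MorphologyCoupling(noise_uv=20.0, wander_uv=100.0,
                              rr_jitter=0.02, rr_width_gain=0.0)
    rec, gt = generate_session(proto, traj, coup, seed=2)
    return proto, rec, gt


@pytest.fixture(scope="session")
def e2e_report(tmp_path_factory):
    """One full pipeline run on a compressed session, with written report."""
    cfg = compressed_config()
    out = tmp_path_factory.mktemp("report")
    report = run_pipeline(cfg, out_dir=str(out))
    assert not report.failures, report.failures
    return cfg, report, out


@pytest.fixture(scope="session")
def e2e_rerun(e2e_report, tmp_path_factory):
    """A second, independent run of the identical config (for determinism)."""
    out2 = tmp_path_factory.mktemp("rerun")
    report2 = run_pipeline(compressed_config(), out_dir=str(out2))
    assert not report2.failures
    return out2


def spearman_bruteforce(x, y):
    """Mid-rank Spearman on tiny vectors, by definition (test oracle)."""
    def midranks(v):
        v = np.asarray(v, float)
        r = np.empty(v.size)
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            eq = np.sum(v == vi)
            r[i] = less + (eq + 1) / 2.0
        return r
    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
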