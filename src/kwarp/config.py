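"""Pipeline configuration.

Defaults reproduce the study settings end to end: 0.5 Hz/6th-order
high-pass and 40 Hz/3rd-order low-pass on the record, 20 Hz/6th-order
low-pass on the periodic component, piCT mode, 2-minute windows at the
5th and 35th minute of each hour, the h4 (end-of-dialysis) reference,
and fully constrained linear/quadratic/cubic models under both the
all-samples and leave-one-out rules.  Every tunable of every stage is
reachable from here, and the resolved configuration is embedded in every
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class FilterConfig:
    baseline_cutoff_hz: float = 0.5
    baseline_order: int = 6
    lowpass_cutoff_hz: float = 40.0
    lowpass_order: int = 3
    pc_lowpass_cutoff_hz: float = 20.0
    pc_lowpass_order: int = 6


@dataclass
class PicaConfig:
    mode: str = "piCT"              # "piCT" (T-wave periodicity) | "piCB" (QRST)
    t_samples: int = 400            # per-beat segment resampling length, T wave
    qrst_samples: int = 600
    min_beats: int = 100
    delineation_lead: str = "II"    # lead used for the pre-transform fiducials


@dataclass
class WindowConfig:
    minutes: tuple[int, ...] = (5, 35)  # window centres within each hour
    width_min: float = 2.0
    min_beats: int = 20
    edge_exclude_s: float = 10.0
    corr_reject: float = 0.95
    duration_reject: float = 0.25


@dataclass
class WarpConfig:
    grid_ms: float = 0.5            # DP lattice resolution for marker warping
    mwtw_grid_ms: float = 1.0       # coarser grid inside the iterative average
    max_step: int = 3               # local slope bound max_step : 1/max_step
    sign_convention: str = "narrower_positive"
    mwtw_tol: float = 1e-3
    mwtw_max_iter: int = 10


@dataclass
class CorrectionConfig:
    stability_h: float = 4.0        # late post-HD segment used to fit the RR slope


@dataclass
class ModelConfig:
    orders: tuple[str, ...] = ("l", "q", "c")
    markers: tuple[str, ...] = ("dw", "dwc")
    rules: tuple[str, ...] = ("a", "o")
    constrained: bool = True
    include_reference_in_corr: bool = True
    min_points: int = 4


@dataclass
class SimulateConfig:
    n_patients: int = 1
    duration_h: float = 48.0
    sample_hours: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 215.0 / 60.0, 48.0)
    hd_end_h: float = 215.0 / 60.0
    fs: float = 1000.0
    k_mmol: tuple[float, ...] = (5.6, 5.0, 4.4, 4.0, 3.6, 5.2)
    width_gain: float = -0.05
    amp_gain: float = 0.04
    rr_width_gain: float = 0.10
    rr_start_ms: float = 850.0
    rr_end_ms: float = 950.0
    rr_jitter: float = 0.02
    wander_uv: float = 100.0
    wander_hz: float = 0.25
    noise_uv: float = 10.0


@dataclass
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    pica: PicaConfig = field(default_factory=PicaConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    warping: WarpConfig = field(default_factory=WarpConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @staticmethod
    def from_dict(obj: dict) -> "PipelineConfig":
        cfg = PipelineConfig()
        sections = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
        for key, val in (obj or {}).items():
            if key not in sections:
                raise ValueError(f"unknown config section {key!r}")
            if key == "seed":
                cfg.seed = int(val)
                continue
            section = getattr(cfg, key)
            names = {f.name for f in dataclasses.fields(section)}
            for k, v in val.items():
                if k not in names:
                    raise ValueError(f"unknown config key {key}.{k}")
                if isinstance(v, list):
                    v = tuple(v)
                setattr(section, k, v)
        return cfg

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})
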