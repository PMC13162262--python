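"""Run configuration: every tunable of the processing chain, with defaults.

The effective configuration (defaults plus overrides) is serialized
next to every output so no parameter enters a computation silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # deployment constants
    alkalinity: float = 2650.0  # umol kg-1, held constant over a deployment
    salinity: float = 38.0
    temperature: float = 25.0  # degrees C
    latitude: float = 40.7
    sensor_height_m: float = 1.15
    # community / quotient
    cn_ratio: float | None = 22.2  # direct ecosystem C:N; overrides components
    cn_components: tuple = (("epiphytes", 13.7, 1.0 / 3.0), ("seagrass", 26.8, 2.0 / 3.0))
    h_light: float = 12.0
    h_dark: float = 12.0
    par_light_threshold: float = 1.0  # umol photons m-2 s-1
    # processing
    target_rate_hz: float = 5.0
    window_min: float = 29.0
    block_min: float = 30.0
    running_mean_s: float = 500.0
    planar_fit_segment_s: float = 300.0
    max_lag_s: float = 2.0
    edge_exclusion_s: float = 250.0
    min_valid_fraction: float = 0.5
    low_corr_threshold: float = 0.05
    low_speed_cm_s: float = 2.0
    qc_r2_threshold: float = 0.8
    qc_burst_sample_fraction: float = 0.05
    qc_burst_change_fraction: float = 0.5
    despike_enabled: bool = True
    despike_n_mad: float = 6.0
    despike_window_s: float = 10.0
    # pump reversal mask (applied by the reader when not already gaps)
    pump_period_s: float = 1800.0
    pump_duration_s: float = 60.0
    pump_phase_s: float = 1740.0
    # corrections / flags
    storage_correction: bool = False
    storage_layer_m: float = 1.0
    vent_ratio_threshold: float = 3.0
    vent_o2_floor: float = 50.0
    vent_direction_sectors: tuple = ()
    # channel files and column maps (used by the readers / CLI)
    channel_paths: tuple = ()  # ((role, path), ...) roles: u,v,w,o2,ph,ph_mv,par
    isfet_gain_mv_per_ph: float = 590.0

    def effective_q(self) -> float:
        from .calcify import CommunityComposition, community_cn, photosynthetic_quotient

        n = self.cn_ratio
        if n is None:
            n = community_cn(CommunityComposition(tuple(self.cn_components)))
        return photosynthetic_quotient(n)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cn_components", "vent_direction_sectors", "channel_paths"):
            if key in data and data[key] is not None:
                data[key] = tuple(tuple(x) for x in data[key])
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
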