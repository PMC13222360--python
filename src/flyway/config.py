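"""Pipeline configuration: every fixed analysis threshold in one place.

Defaults follow the operational definitions used throughout the package:
a 24 km/h speed threshold separating flight from stationary behaviour,
stopovers of at least 60 min at a single spot, wintering residencies of
more than 20 days, a 20 km buffer around seasonal sites for departure and
arrival timing, a 0.0001 degree nest grid, and 250 km spatial clusters
(with 150/500 km alternatives for sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .exceptions import ConfigError


@dataclass
class PipelineConfig:
    speed_threshold_kmh: float = 24.0
    stopover_min_duration_min: float = 60.0
    winter_min_stay_days: float = 20.0
    site_buffer_km: float = 20.0
    nest_grid_deg: float = 0.0001
    site_radius_km: float = 20.0
    stopover_spot_radius_km: float = 5.0
    max_gap_h: float = 24.0
    cluster_radius_km: float = 250.0
    sensitivity_radii_km: tuple = (150.0, 250.0, 500.0)
    overdisp_threshold: float = 1.5
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "speed_threshold_kmh",
            "stopover_min_duration_min",
            "winter_min_stay_days",
            "site_buffer_km",
            "nest_grid_deg",
            "site_radius_km",
            "stopover_spot_radius_km",
            "max_gap_h",
            "cluster_radius_km",
            "overdisp_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.cluster_radius_km < self.site_buffer_km:
            raise ConfigError("cluster_radius_km must be >= site_buffer_km")
        if self.n_boot < 0 or self.n_perm < 0:
            raise ConfigError("n_boot and n_perm must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensitivity_radii_km"] = list(self.sensitivity_radii_km)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "sensitivity_radii_km" in d:
            d = dict(d, sensitivity_radii_km=tuple(d["sensitivity_radii_km"]))
        return cls(**d)


def load_config(path) -> dict:
    """Load a nested YAML run configuration (sections: simulate, io,
    segmentation, clustering, statistics, similarity)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("run configuration must be a mapping")
    return cfg
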