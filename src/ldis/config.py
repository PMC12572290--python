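"""Pipeline configuration.

All numeric thresholds used anywhere in the toolkit live here, so a single
config object (or TOML/JSON file mirroring these field names) pins down an
entire run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

_RATIO_FIELDS = (
    "dup_overlap_frac",
    "admin_overlap_frac",
    "circle_frac",
    "infra_cover_frac",
    "landcover_cover_frac",
    "cloud_frac_max",
)
_LENGTH_FIELDS = ("point_buffer_m", "annulus_width_m", "road_corridor_width_m")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs shared across the pipeline stages.

    Lengths are metres, everything called ``*_frac`` is a ratio in (0, 1).

    point_buffer_m
        Radius of the disc substituted for point-only site locations.
    annulus_width_m
        Outward extension defining the ring used as spatial control.
    dup_overlap_frac
        Mutual-overlap share above which two sites count as duplicates /
        nested (strict ``>``).
    admin_overlap_frac
        Mutual-overlap share above which a site is an administrative-area
        copy (strict ``>``).
    circle_frac
        Compactness at or above which a polygon counts as a perfect circle.
    infra_cover_frac
        Site share of built-up area or road corridor above which the
        infrastructure indicators fail (strict ``>``).
    landcover_cover_frac
        Site share of forest / other land cover / stable cropland at or
        above which those indicators fail (inclusive ``>=``).
    cloud_frac_max
        Scene-level cloudy share at or above which a composite is dropped.
    road_corridor_width_m
        Width used to convert road length into a covered-area share.
    greenest_k
        Number of top-NDVI months entering each annual composite.
    savi_soil_factor / savi_gain
        The soil-adjustment constants L and (1 + L) of SAVI.
    savi_uses_red
        If true, SAVI uses the red band (the textbook form) instead of the
        red-edge band the index table here defaults to.
    """

    point_buffer_m: float = 100.0
    annulus_width_m: float = 500.0
    dup_overlap_frac: float = 0.95
    admin_overlap_frac: float = 0.98
    circle_frac: float = 0.95
    infra_cover_frac: float = 0.10
    landcover_cover_frac: float = 0.20
    cloud_frac_max: float = 0.20
    road_corridor_width_m: float = 10.0
    greenest_k: int = 3
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    savi_soil_factor: float = 0.5
    savi_gain: float = 1.5
    savi_uses_red: bool = False
    composite_statistic: str = "median"  # or "mean"
    strict_missing: bool = False
    water_counts_as: str = "other_landcover"  # or "infrastructure"

    def __post_init__(self) -> None:
        for name in _RATIO_FIELDS:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in _LENGTH_FIELDS:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.greenest_k < 1 or self.bootstrap_reps < 1:
            raise ValueError("greenest_k and bootstrap_reps must be >= 1")
        if self.composite_statistic not in ("median", "mean"):
            raise ValueError("composite_statistic must be 'median' or 'mean'")
        if self.water_counts_as not in ("other_landcover", "infrastructure"):
            raise ValueError("water_counts_as must be 'other_landcover' or 'infrastructure'")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a JSON or TOML file whose keys mirror the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


__all__ = ["PipelineConfig"]
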