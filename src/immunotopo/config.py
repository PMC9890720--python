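"""Pipeline configuration: YAML-backed, schema-validated, hashable.

Unknown keys are rejected so typos fail before any stage runs; every output
CSV carries the config hash and seed in a header comment for provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StainConfig(_Strict):
    hematoxylin: list[float] = [0.650, 0.704, 0.286]
    dab: list[float] = [0.269, 0.568, 0.778]
    background: list[float] = [255.0, 255.0, 255.0]
    od_floor: float = 0.15
    estimate_per_image: bool = False


class DetectionConfig(_Strict):
    smoothing_sigma_um: float = 1.5
    background_radius_um: float = 8.0
    detection_threshold_od: float = 0.1
    min_area_um2: float = 10.0
    max_area_um2: float = 400.0
    dab_positive_threshold_od: float = 0.2
    watershed_split: bool = True
    split_min_distance_um: float = 3.0


class ClassifierConfig(_Strict):
    n_trees: int = 100
    max_depth: int = 16
    cap_per_class: int = 10000
    n_annotation_cases: int = 3
    annotations_per_class: int = 4
    annotation_box_px: int = 12
    min_region_area_um2: float = 1000.0
    mode_filter_radius_px: int = 2


class CohortConfig(_Strict):
    n_cases: int = 12
    core_diameter_um: float = 500.0
    pixel_size_um: float = 2.0
    tumour_fraction: float = 0.4
    markers: list[str] = ["CD3", "CD8", "perforin"]
    marker_corr: float = 0.9
    noise_sd: float = 0.02


class ThresholdConfig(_Strict):
    derivation: str = "cohort_median_overall"


class PipelineConfig(_Strict):
    seed: int = 0
    out_dir: str = "immunotopo_out"
    stains: StainConfig = Field(default_factory=StainConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    detection_per_marker: dict[str, DetectionConfig] = Field(default_factory=dict)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    combos: dict[str, list[str]] = Field(default_factory=lambda: {"CD3/CD8": ["CD3", "CD8"]})
    combo_rule: str = "and"
    cps_cutoff: float = 10.0

    def detection_params_for(self, marker: str) -> DetectionConfig:
        return self.detection_per_marker.get(marker, self.detection)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.model_dump(), sort_keys=True)
        return hashlib.sha1(canonical.encode()).hexdigest()[:12]


def load_config(path: Optional[str | Path] = None, **overrides) -> PipelineConfig:
    """Load a YAML config file (or defaults) with keyword overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return PipelineConfig.model_validate(data)
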