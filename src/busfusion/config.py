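"""Pipeline configuration.

Defaults mirror the reference protocol: 0.1 mm isotropic spacing, GLCM
distances 1-4 at 0/45/90/135 degrees, 1 x 1 mm ROIs kept only when fully
inside the tumor, fivefold tumor-level cross-validation, and an integer
(sigma, C) grid 1 < sigma, C < 100 searched with step 1.  ``grid_step`` can
coarsen the SVM grid, and per-arm ``fixed_svm_params`` / ``bypass_features``
skip tuning / selection entirely so a known configuration (e.g. a published
feature list) can be reproduced directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig", "ARMS"]

ARMS = ("texture_singleROI", "morphology", "combined", "texture_multiROI", "fused")


@dataclass
class PipelineConfig:
    # imaging
    target_spacing_mm: float = 0.1
    glcm_levels: int = 32
    glcm_symmetric: bool = True
    distances: tuple[int, ...] = (1, 2, 3, 4)
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    # ROI tiling
    roi_side_mm: float = 1.0
    min_inside_fraction: float = 1.0
    # morphology
    undulation_threshold_mm: float = 0.3
    nrl_bins: int = 10
    # feature selection
    selection_bins: int = 10
    top_l_max: int | None = 15
    selection_sigma: float = 5.0
    selection_C: float = 10.0
    selection_folds: int = 5
    bypass_features: dict[str, list[str]] | None = None  # arm -> feature names
    # SVM
    grid_step: int = 1
    fixed_svm_params: dict[str, tuple[float, float]] | None = None  # arm -> (sigma, C)
    platt_folds: int = 3
    max_train_rois_per_tumor: int | None = 8
    # fusion
    fusion_variant: str = "naive"
    variance_floor: float = 1e-6
    # cross-validation
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.target_spacing_mm <= 0:
            raise ConfigError("target_spacing_mm must be positive")
        if self.glcm_levels < 2:
            raise ConfigError("glcm_levels must be >= 2")
        if not 0 < self.min_inside_fraction <= 1:
            raise ConfigError("min_inside_fraction must be in (0, 1]")
        if self.grid_step < 1:
            raise ConfigError("grid_step must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.fusion_variant not in ("naive", "full"):
            raise ConfigError(f"unknown fusion_variant {self.fusion_variant!r}")
        bad_arms = set((self.bypass_features or {}) ) | set(self.fixed_svm_params or {})
        bad_arms -= set(ARMS)
        if bad_arms:
            raise ConfigError(f"unknown arms in config: {sorted(bad_arms)}")
        self.distances = tuple(self.distances)
        self.angles_deg = tuple(self.angles_deg)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["distances"] = list(self.distances)
        d["angles_deg"] = list(self.angles_deg)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "fixed_svm_params" in raw and raw["fixed_svm_params"]:
            raw["fixed_svm_params"] = {
                arm: tuple(v) for arm, v in raw["fixed_svm_params"].items()
            }
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))
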