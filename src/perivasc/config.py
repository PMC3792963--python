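"""Run configuration: thresholds, window geometry, and report settings.

One ``RunConfig`` drives the whole measurement pipeline.  Defaults
reproduce the study protocol: nonzero binarization for pre-masked vessel
channels, Otsu for raw drug intensity, hotspot windows of 0.27 mm^2,
drug-evaluation fields of 1.09 mm^2, and a low-magnification scan area of
6.82 mm^2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # binarization
    vessel_method: str = "nonzero"  # vessel channels arrive pre-masked
    vessel_fixed_threshold: float | None = None
    drug_method: str = "otsu"  # drug channels are raw intensity
    drug_fixed_threshold: float | None = None
    # component filters (px)
    min_spot_size_px: int = 4
    min_vessel_size_px: int = 4
    # window geometry (mm^2), per magnification of the protocol
    lowmag_area_mm2: float = 6.82
    drug_field_area_mm2: float = 1.09
    mvd_window_area_mm2: float = 0.27
    k_fields: int = 3
    stride_fraction: float = 0.25  # scan stride as a fraction of window side
    max_excluded_fraction: float = 0.5
    # exposure bands
    distance_band_um: float = 25.0
    distance_band_max_um: float = 250.0
    # bookkeeping
    seed: int = 0
    report_decimals: int = 2

    def __post_init__(self) -> None:
        if self.vessel_method not in ("nonzero", "otsu", "fixed"):
            raise ValueError(f"unknown vessel_method {self.vessel_method!r}")
        if self.drug_method not in ("nonzero", "otsu", "fixed"):
            raise ValueError(f"unknown drug_method {self.drug_method!r}")
        for name in ("lowmag_area_mm2", "drug_field_area_mm2", "mvd_window_area_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.stride_fraction <= 1:
            raise ValueError("stride_fraction must be in (0, 1]")

    def stride_px(self, window_side_px: int) -> int:
        return max(1, int(round(window_side_px * self.stride_fraction)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
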