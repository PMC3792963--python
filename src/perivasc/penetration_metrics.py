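"""Drug-penetration measurement: field selection, per-field distance
statistics, per-animal aggregation, and avascular-exposure summaries.

The field pipeline mirrors the imaging protocol: binarize the vessel
channel, build the distance map, binarize the drug channel, reduce each
drug spot to its center point, read the distance-map value there, and
average.  An animal's penetration distance is the mean of three fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import (
    DegenerateHistogram,
    InsufficientFields,
    NoValidField,
    NoVesselInField,
)
from .imaging_core import (
    BinaryMask,
    FieldImage,
    binarize_channel,
    compute_distance_map,
    extract_spots,
    spot_distances,
)
from .vascular_metrics import Window, HotspotSelection, select_top_windows, window_side_px, _scan_origins

log = logging.getLogger("perivasc")

FLAG_NO_VESSEL = "no-vessel"
FLAG_NO_SPOT = "no-spot"


@dataclass
class FieldMeasurement:
    """Penetration measurement for one drug-evaluation field."""

    field_id: str
    mean_penetration_um: float  # NaN when flagged
    spot_count: int
    excluded_fraction: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return not self.flags


@dataclass
class AnimalMeasurement:
    """Final per-animal quantities: means over the three fields."""

    animal_id: str
    group: int
    time_point: str
    penetration_um: float
    spot_count_mean: float
    mvd: float | None = None

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3, 4):
            raise ValueError(f"group must be 1-4, got {self.group}")


def _binarize_with_fallback(
    image: FieldImage, channel: str, method: str, fixed: float | None, tag: str
) -> BinaryMask:
    """Binarize, falling back to the nonzero rule on a constant channel."""
    try:
        return binarize_channel(
            image, channel, method=method, fixed_threshold=fixed, semantics_tag=tag
        )
    except DegenerateHistogram:
        log.warning(
            "field %s: constant %s channel, falling back to nonzero rule",
            image.field_id,
            channel,
        )
        return binarize_channel(image, channel, method="nonzero", semantics_tag=tag)


def _exclusion_mask(image: FieldImage) -> BinaryMask | None:
    if not image.has_channel("exclusion"):
        return None
    return BinaryMask(data=image.channel("exclusion") > 0, semantics_tag="exclusion")


def select_drug_fields(
    section_drug: np.ndarray,
    exclusion: BinaryMask | None = None,
    field_area_mm2: float = 1.09,
    k: int = 3,
    pixel_pitch_um: float = 1.0,
    stride_px: int | None = None,
    max_excluded_fraction: float = 0.5,
) -> HotspotSelection:
    """Choose the k fields with the highest total drug fluorescence.

    A window's score is its summed drug intensity over non-excluded
    pixels; windows with more than ``max_excluded_fraction`` excluded area
    are ineligible.  Ties resolve in raster order and the selected windows
    are pairwise non-overlapping.
    """
    h, w = section_drug.shape
    side = window_side_px(field_area_mm2, pixel_pitch_um)
    if side > h or side > w:
        raise NoValidField(
            f"section {h}x{w} px cannot hold a {side}px evaluation field"
        )
    if stride_px is None:
        stride_px = max(1, side // 4)
    excl = (
        exclusion.data
        if exclusion is not None
        else np.zeros_like(section_drug, dtype=bool)
    )
    # integral images for O(1) window sums
    drug_c = np.pad((section_drug * ~excl).cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    excl_c = np.pad(excl.astype(np.int64).cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    def winsum(table: np.ndarray, r: int, c: int) -> float:
        return (
            table[r + side, c + side]
            - table[r, c + side]
            - table[r + side, c]
            + table[r, c]
        )

    scored: list[Window] = []
    for r in _scan_origins(h, side, stride_px):
        for c in _scan_origins(w, side, stride_px):
            excluded = winsum(excl_c, r, c) / (side * side)
            if excluded > max_excluded_fraction:
                continue
            scored.append(
                Window(
                    row=r,
                    col=c,
                    height_px=side,
                    width_px=side,
                    score=float(winsum(drug_c, r, c)),
                )
            )
    if not scored:
        raise NoValidField("every candidate window exceeds the excluded-area cut")
    return HotspotSelection(windows=select_top_windows(scored, k))


def field_penetration(image: FieldImage, config: RunConfig | None = None) -> FieldMeasurement:
    """Mean spot-to-vessel distance and spot count for one field.

    Excluded pixels contribute neither vessels nor spots.  Fields without
    vessels or without detectable drug are flagged rather than reported as
    zero (a zero would bias penetration downward).
    """
    config = config or RunConfig()
    exclusion = _exclusion_mask(image)
    excluded_fraction = float(exclusion.data.mean()) if exclusion is not None else 0.0

    vessels = _binarize_with_fallback(
        image, "vessel", config.vessel_method, config.vessel_fixed_threshold, "vessel"
    )
    if exclusion is not None:
        vessels.data &= ~exclusion.data
    if not vessels.data.any():
        log.warning("field %s flagged: no vessel pixel", image.field_id)
        return FieldMeasurement(
            field_id=image.field_id,
            mean_penetration_um=float("nan"),
            spot_count=0,
            excluded_fraction=excluded_fraction,
            flags=[FLAG_NO_VESSEL],
        )
    dmap = compute_distance_map(vessels, image.pixel_pitch_um)

    drug = image.channel("drug")
    drug_mask = _binarize_with_fallback(
        image, "drug", config.drug_method, config.drug_fixed_threshold, "drug"
    )
    if exclusion is not None:
        drug_mask.data &= ~exclusion.data
    spots = extract_spots(drug_mask, drug, min_spot_size=config.min_spot_size_px)
    if len(spots) == 0:
        log.warning("field %s flagged: no drug spot above threshold", image.field_id)
        return FieldMeasurement(
            field_id=image.field_id,
            mean_penetration_um=float("nan"),
            spot_count=0,
            excluded_fraction=excluded_fraction,
            flags=[FLAG_NO_SPOT],
        )
    spots = spot_distances(spots, dmap)
    return FieldMeasurement(
        field_id=image.field_id,
        mean_penetration_um=float(spots.distances_um.mean()),
        spot_count=len(spots),
        excluded_fraction=excluded_fraction,
    )


def animal_penetration(
    fields: list[FieldMeasurement],
    animal_id: str = "",
    group: int = 1,
    time_point: str = "",
    mvd: float | None = None,
) -> AnimalMeasurement:
    """Per-animal penetration: means of exactly three usable fields."""
    if len(fields) != 3:
        raise InsufficientFields(
            f"animal {animal_id!r}: need 3 field measurements, got {len(fields)}"
        )
    flagged = [f for f in fields if not f.usable]
    if flagged:
        reasons = "; ".join(f"{f.field_id}: {','.join(f.flags)}" for f in flagged)
        raise InsufficientFields(f"animal {animal_id!r} has flagged fields ({reasons})")
    return AnimalMeasurement(
        animal_id=animal_id,
        group=group,
        time_point=time_point,
        penetration_um=float(np.mean([f.mean_penetration_um for f in fields])),
        spot_count_mean=float(np.mean([f.spot_count for f in fields])),
        mvd=mvd,
    )


def exposed_fraction(
    image: FieldImage, config: RunConfig | None = None
) -> pd.DataFrame:
    """Fraction of tissue with detectable drug, by distance-to-vessel band.

    For each band ``[k*w, (k+1)*w)`` up to ``distance_band_max_um``, the
    fraction of non-excluded pixels whose drug intensity exceeds the
    detection threshold.  Bands with no pixels report ``NaN``.
    """
    config = config or RunConfig()
    exclusion = _exclusion_mask(image)
    vessels = _binarize_with_fallback(
        image, "vessel", config.vessel_method, config.vessel_fixed_threshold, "vessel"
    )
    if exclusion is not None:
        vessels.data &= ~exclusion.data
    if not vessels.data.any():
        raise NoVesselInField(f"field {image.field_id!r} has no vessel pixel")
    dmap = compute_distance_map(vessels, image.pixel_pitch_um)
    drug_mask = _binarize_with_fallback(
        image, "drug", config.drug_method, config.drug_fixed_threshold, "drug"
    )

    w = config.distance_band_um
    n_bands = int(np.ceil(config.distance_band_max_um / w))
    valid = np.ones(image.shape, dtype=bool)
    if exclusion is not None:
        valid &= ~exclusion.data
    idx = np.floor(dmap.data[valid] / w).astype(int)
    inside = idx < n_bands
    counts = np.bincount(idx[inside], minlength=n_bands)
    hits = np.bincount(
        idx[inside], weights=drug_mask.data[valid][inside].astype(float), minlength=n_bands
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bands) * w
    return pd.DataFrame(
        {
            "band_left_um": edges,
            "band_right_um": edges + w,
            "pixel_count": counts,
            "exposed_fraction": frac,
        }
    )
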