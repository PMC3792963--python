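"""Calibrated raster types and low-level image operators.

The measurement unit of the study is a single microscope *field*: a set of
co-registered channels (drug auto-fluorescence, CD31 vessel stain, optional
nuclear stain, optional exclusion mask) on one pixel grid with a known
physical calibration.  Everything downstream — vessel counting, distance
maps, spot detection — operates on these types.

Physical calibration follows the printed field areas per magnification
(``x40`` -> 6.82 mm^2, ``x100`` -> 1.09 mm^2, ``x200`` -> 0.27 mm^2); the
pixel pitch is derived as ``sqrt(area / (width * height))`` when not given
explicitly, since camera resolution is not part of the protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogram, MissingChannel, NoVesselInField

#: Printed field area (mm^2) for each magnification tag.
MAGNIFICATION_AREA_MM2: dict[str, float] = {"x40": 6.82, "x100": 1.09, "x200": 0.27}

#: 8-connectivity structuring element used for all component labelling.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

#: Relative tolerance between declared field area and width*height*pitch^2.
AREA_RTOL = 0.02

ThresholdMethod = Literal["nonzero", "otsu", "fixed"]


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (the convention used for pixel lookups)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def derive_pixel_pitch_um(field_area_mm2: float, width_px: int, height_px: int) -> float:
    """Pixel pitch (µm/px) implied by a field area and raster dimensions."""
    return math.sqrt(field_area_mm2 * 1e6 / (width_px * height_px))


@dataclass
class FieldImage:
    """One calibrated multi-channel microscope field.

    Parameters
    ----------
    channels
        Mapping of channel name (``"drug"``, ``"vessel"``, optionally
        ``"nuclear"`` and ``"exclusion"``) to a 2-D non-negative raster.
        All rasters share one grid; square pixels are assumed.
    pixel_pitch_um
        Physical edge length of one pixel, µm.
    magnification_tag
        One of ``{"x40", "x100", "x200"}``; a calibration label, not a
        constraint on the raster size.
    field_area_mm2
        Physical area of the field.  Must agree with
        ``width * height * pitch^2`` to within 2 %.
    field_id
        Free-form identifier used in output tables and logs.
    """

    channels: dict[str, np.ndarray]
    pixel_pitch_um: float
    magnification_tag: str
    field_area_mm2: float
    field_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ValueError(f"channels must be 2-D rasters, got shapes {shapes}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channels differ in shape: {shapes}")
        if self.magnification_tag not in MAGNIFICATION_AREA_MM2:
            raise ValueError(
                f"magnification_tag must be one of {sorted(MAGNIFICATION_AREA_MM2)}, "
                f"got {self.magnification_tag!r}"
            )
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel_pitch_um must be positive")
        implied = self.height_px * self.width_px * self.pixel_pitch_um**2 * 1e-6
        if abs(implied - self.field_area_mm2) > AREA_RTOL * self.field_area_mm2:
            raise ValueError(
                f"field_area_mm2={self.field_area_mm2} inconsistent with "
                f"{self.width_px}x{self.height_px} px at {self.pixel_pitch_um} µm/px "
                f"(implies {implied:.4f} mm^2)"
            )
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative values")

    @property
    def height_px(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width_px(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannel(name) from None

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    @classmethod
    def from_channels(
        cls,
        channels: dict[str, np.ndarray],
        magnification_tag: str,
        field_area_mm2: float | None = None,
        pixel_pitch_um: float | None = None,
        field_id: str = "",
    ) -> "FieldImage":
        """Build a field, deriving area or pitch from the magnification tag.

        If ``field_area_mm2`` is omitted it is taken from the tag's printed
        area; if ``pixel_pitch_um`` is omitted it is derived from the area
        and the raster dimensions.
        """
        if field_area_mm2 is None:
            field_area_mm2 = MAGNIFICATION_AREA_MM2[magnification_tag]
        h, w = next(iter(channels.values())).shape
        if pixel_pitch_um is None:
            pixel_pitch_um = derive_pixel_pitch_um(field_area_mm2, w, h)
        return cls(
            channels=channels,
            pixel_pitch_um=pixel_pitch_um,
            magnification_tag=magnification_tag,
            field_area_mm2=field_area_mm2,
            field_id=field_id,
        )


@dataclass
class BinaryMask:
    """Boolean raster plus the semantics and threshold that produced it."""

    data: np.ndarray
    semantics_tag: Literal["vessel", "drug", "exclusion"]
    threshold: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (µm) to the nearest vessel pixel.

    This is the study's "distance filter" image: zero on vessel pixels,
    positive elsewhere, measured between pixel centers.
    """

    data: np.ndarray
    pixel_pitch_um: float
    source: BinaryMask | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def value_at(self, row: float, col: float) -> float:
        """Distance at the pixel nearest a (possibly fractional) coordinate.

        Coordinates are rounded half-away-from-zero and clamped to the grid.
        """
        r = int(np.clip(_round_half_away(row), 0, self.shape[0] - 1))
        c = int(np.clip(_round_half_away(col), 0, self.shape[1] - 1))
        return float(self.data[r, c])


@dataclass
class Spot:
    """A single detected drug-fluorescence spot (one connected component)."""

    centroid_rc: tuple[float, float]
    area_px: int
    peak_intensity: float
    nearest_vessel_distance_um: float | None = None


@dataclass
class SpotSet:
    """Detected spots for one field."""

    spots: list[Spot] = field(default_factory=list)
    grid_shape: tuple[int, int] = (0, 0)

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    @property
    def distances_um(self) -> np.ndarray:
        """Assigned nearest-vessel distances; raises if any is unassigned."""
        vals = [s.nearest_vessel_distance_um for s in self.spots]
        if any(v is None for v in vals):
            raise ValueError("spot distances not yet assigned")
        return np.asarray(vals, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": [s.centroid_rc[0] for s in self.spots],
                "col": [s.centroid_rc[1] for s in self.spots],
                "area_px": [s.area_px for s in self.spots],
                "peak_intensity": [s.peak_intensity for s in self.spots],
                "nearest_vessel_distance_um": [
                    s.nearest_vessel_distance_um for s in self.spots
                ],
            }
        )


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def binarize_channel(
    image: FieldImage,
    channel: str,
    method: ThresholdMethod = "nonzero",
    fixed_threshold: float | None = None,
    semantics_tag: str | None = None,
) -> BinaryMask:
    """Threshold a channel into a binary mask.

    ``nonzero`` keeps every pixel with intensity > 0 (the rule for
    pre-masked vessel images, where any non-zero pixel is vessel);
    ``otsu`` thresholds at the Otsu optimum of the channel histogram;
    ``fixed`` uses the supplied threshold.  The mask records the threshold
    actually applied.
    """
    if (fixed_threshold is not None) != (method == "fixed"):
        raise ValueError("fixed_threshold must be given exactly when method='fixed'")
    raster = image.channel(channel)
    if method == "nonzero":
        thr = 0.0
    elif method == "otsu":
        if np.all(raster == raster.flat[0]):
            raise DegenerateHistogram(
                f"channel {channel!r} is constant; Otsu threshold undefined"
            )
        thr = float(threshold_otsu(raster))
    elif method == "fixed":
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    tag = semantics_tag or ("vessel" if channel == "vessel" else "drug")
    return BinaryMask(data=raster > thr, semantics_tag=tag, threshold=thr, method=method)


def extract_spots(
    mask: BinaryMask, intensity: np.ndarray, min_spot_size: int = 4
) -> SpotSet:
    """8-connected components of ``mask`` with area >= ``min_spot_size``.

    The centroid is the unweighted mean pixel coordinate of the component
    (each spot is reduced to its center point); ``peak_intensity`` is the
    component maximum of ``intensity``.
    """
    if mask.shape != intensity.shape:
        raise ValueError("mask and intensity must share a grid")
    if min_spot_size < 1:
        raise ValueError("min_spot_size must be >= 1")
    labels, n = ndimage.label(mask.data, structure=EIGHT_CONNECTED)
    spots: list[Spot] = []
    if n:
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(areas >= min_spot_size) + 1
        if keep.size:
            centroids = ndimage.center_of_mass(mask.data, labels, keep)
            peaks = ndimage.maximum(intensity, labels, keep)
            for (r, c), lab, peak in zip(centroids, keep, np.atleast_1d(peaks)):
                spots.append(
                    Spot(
                        centroid_rc=(float(r), float(c)),
                        area_px=int(areas[lab - 1]),
                        peak_intensity=float(peak),
                    )
                )
    return SpotSet(spots=spots, grid_shape=mask.shape)


def compute_distance_map(vessels: BinaryMask, pixel_pitch_um: float) -> DistanceMap:
    """Euclidean distance transform of the vessel mask, in µm.

    Each pixel holds the distance from its center to the nearest
    vessel-pixel center; vessel pixels themselves are 0.
    """
    if not vessels.data.any():
        raise NoVesselInField("vessel mask has no vessel pixel")
    dist_px = ndimage.distance_transform_edt(~vessels.data)
    return DistanceMap(data=dist_px * pixel_pitch_um, pixel_pitch_um=pixel_pitch_um, source=vessels)


def spot_distances(spots: SpotSet, dmap: DistanceMap) -> SpotSet:
    """Assign each spot the distance-map value at its center pixel.

    The fractional centroid is rounded half-away-from-zero and clamped to
    the grid; the component is *not* averaged over.
    """
    if spots.grid_shape != dmap.shape:
        raise ValueError("distance map not defined on the spots' grid")
    out = [
        Spot(
            centroid_rc=s.centroid_rc,
            area_px=s.area_px,
            peak_intensity=s.peak_intensity,
            nearest_vessel_distance_um=dmap.value_at(*s.centroid_rc),
        )
        for s in spots
    ]
    return SpotSet(spots=out, grid_shape=spots.grid_shape)


def resample_to_grid(
    raster: np.ndarray, target_width_px: int, target_height_px: int
) -> np.ndarray:
    """Nearest-neighbor resampling onto a target grid.

    Source index for output pixel ``i`` along an axis of source length ``S``
    and target length ``T`` is ``floor(i * S / T)``, so integer upsampling
    replicates pixels into blocks and integer downsampling block-subsamples.
    Binary inputs stay binary (pure index mapping, no interpolation).
    """
    if target_width_px < 1 or target_height_px < 1:
        raise ValueError("target dimensions must be >= 1")
    h, w = raster.shape
    rows = (np.arange(target_height_px) * h) // target_height_px
    cols = (np.arange(target_width_px) * w) // target_width_px
    return raster[np.ix_(rows, cols)]


def intensity_profile(
    drug_channel: np.ndarray,
    dmap: DistanceMap,
    bin_width_um: float,
    exclusion: BinaryMask | None = None,
) -> pd.DataFrame:
    """Mean drug intensity binned by distance to the nearest vessel.

    Non-excluded pixels are assigned to half-open bins
    ``[k*w, (k+1)*w)``; every bin up to the grid's maximum distance is
    reported, empty ones with ``pixel_count`` 0 and mean ``NaN``.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    if drug_channel.shape != dmap.shape:
        raise ValueError("drug channel and distance map must share a grid")
    n_bins = int(np.floor(dmap.data.max() / bin_width_um)) + 1
    valid = np.ones(dmap.shape, dtype=bool)
    if exclusion is not None:
        valid &= ~exclusion.data
    idx = np.floor(dmap.data[valid] / bin_width_um).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=drug_channel[valid], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins) * bin_width_um
    return pd.DataFrame(
        {
            "bin_left_um": edges,
            "bin_right_um": edges + bin_width_um,
            "pixel_count": counts,
            "mean_intensity": means,
        }
    )
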