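"""Weidner hotspot microvessel-density (MVD) estimation.

The section is scanned at low magnification for the most vascularized
areas ("hotspots"); microvessels are then counted in three high-power
fields and the animal's MVD is the mean of the three counts.  A
microvessel is any separated endothelial structure: one 8-connected
component of the vessel mask, lumen not required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FieldTooSmall, InsufficientFields
from .imaging_core import EIGHT_CONNECTED, BinaryMask


@dataclass
class Window:
    """Axis-aligned counting window (pixel units) with its score."""

    row: int
    col: int
    height_px: int
    width_px: int
    score: float

    def overlaps(self, other: "Window") -> bool:
        return not (
            self.row + self.height_px <= other.row
            or other.row + other.height_px <= self.row
            or self.col + self.width_px <= other.col
            or other.col + other.width_px <= self.col
        )


@dataclass
class HotspotSelection:
    """The k best pairwise non-overlapping windows, scores non-increasing."""

    windows: list[Window]

    def __post_init__(self) -> None:
        scores = [w.score for w in self.windows]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("hotspot windows must be sorted by non-increasing score")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


@dataclass
class MvdResult:
    """Per-field vessel counts and their mean, the animal's MVD."""

    field_counts: tuple[int, int, int]
    mvd: float


def count_vessels(
    vessels: BinaryMask,
    exclusion: BinaryMask | None = None,
    min_size_px: int = 4,
) -> int:
    """Number of countable microvessels in a mask.

    A microvessel is an 8-connected component with area >= ``min_size_px``
    none of whose pixels falls in the exclusion mask (necrosis or staining
    artifact regions are not counted at all).
    """
    if exclusion is not None and exclusion.shape != vessels.shape:
        raise ValueError("exclusion mask must share the vessel-mask grid")
    labels, n = ndimage.label(vessels.data, structure=EIGHT_CONNECTED)
    if n == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    keep = areas >= min_size_px
    if exclusion is not None:
        touched = np.unique(labels[exclusion.data & (labels > 0)])
        if touched.size:
            keep[touched - 1] = False
    return int(keep.sum())


def window_side_px(window_area_mm2: float, pixel_pitch_um: float) -> int:
    """Side length (px) of the square window covering ``window_area_mm2``."""
    return max(1, round(math.sqrt(window_area_mm2 * 1e6) / pixel_pitch_um))


def _scan_origins(extent: int, side: int, stride: int) -> list[int]:
    """Window origins along one axis: regular stride plus a flush-end stop."""
    origins = list(range(0, extent - side + 1, stride))
    last = extent - side
    if origins[-1] != last:
        origins.append(last)
    return origins


def _greedy_pick(ordered: list[Window], k: int, first: Window | None = None) -> list[Window]:
    chosen: list[Window] = [first] if first is not None else []
    for win in ordered:
        if len(chosen) == k:
            break
        if all(not win.overlaps(c) for c in chosen):
            chosen.append(win)
    return chosen


def select_top_windows(scored: list[Window], k: int) -> list[Window]:
    """Pick the k best pairwise non-overlapping windows.

    Greedy in (-score, row, col) order, so ties resolve in raster order.
    When the window side exceeds a third of the grid the top-scoring picks
    can block each other and greedy may stop short of k even though k
    disjoint windows exist; in that case greedy is restarted from each of
    the best candidates in turn and the fullest (then highest-scoring)
    selection wins.
    """
    ordered = sorted(scored, key=lambda w: (-w.score, w.row, w.col))
    chosen = _greedy_pick(ordered, k)
    if len(chosen) < k and len(ordered) > len(chosen):
        best = chosen
        for first in ordered[:200]:
            trial = _greedy_pick(ordered, k, first=first)
            if (len(trial), sum(w.score for w in trial)) > (
                len(best),
                sum(w.score for w in best),
            ):
                best = trial
            if len(best) == k:
                break
        chosen = sorted(best, key=lambda w: (-w.score, w.row, w.col))
    return chosen


def find_hotspots(
    lowmag_vessels: BinaryMask,
    window_area_mm2: float,
    k: int,
    pixel_pitch_um: float,
    stride_px: int | None = None,
    min_size_px: int = 4,
    exclusion: BinaryMask | None = None,
) -> HotspotSelection:
    """Sliding-window hotspot scan of a low-magnification vessel mask.

    A window's vascularization score is the microvessel count restricted
    to that window (components are re-labelled within the crop, matching
    what an observer sees through the eyepiece).  Returns the ``k``
    highest-scoring pairwise non-overlapping windows; the default stride is
    a quarter window, ``stride_px=1`` gives the exhaustive scan.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    h, w = lowmag_vessels.shape
    side = window_side_px(window_area_mm2, pixel_pitch_um)
    if side > h or side > w:
        raise FieldTooSmall(
            f"grid {h}x{w} px cannot hold a {side}px window "
            f"({window_area_mm2} mm^2 at {pixel_pitch_um} µm/px)"
        )
    if stride_px is None:
        stride_px = max(1, side // 4)
    scored: list[Window] = []
    for r in _scan_origins(h, side, stride_px):
        for c in _scan_origins(w, side, stride_px):
            crop = BinaryMask(
                data=lowmag_vessels.data[r : r + side, c : c + side],
                semantics_tag="vessel",
            )
            excl_crop = None
            if exclusion is not None:
                excl_crop = BinaryMask(
                    data=exclusion.data[r : r + side, c : c + side],
                    semantics_tag="exclusion",
                )
            score = count_vessels(crop, excl_crop, min_size_px=min_size_px)
            scored.append(Window(row=r, col=c, height_px=side, width_px=side, score=score))
    return HotspotSelection(windows=select_top_windows(scored, k))


def mvd_for_animal(field_counts: list[int] | tuple[int, ...]) -> MvdResult:
    """MVD for one animal: the mean of exactly three hotspot-field counts."""
    if len(field_counts) != 3:
        raise InsufficientFields(
            f"MVD requires exactly 3 field counts, got {len(field_counts)}"
        )
    counts = tuple(int(c) for c in field_counts)
    if any(c < 0 for c in counts):
        raise ValueError("vessel counts must be non-negative")
    return MvdResult(field_counts=counts, mvd=sum(counts) / 3.0)
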