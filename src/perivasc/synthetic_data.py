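"""Seeded forward model of drug-penetration microscopy fields.

The generator emulates the structure the measurement pipeline assumes:

* microvessels placed by an inhomogeneous point process whose density is
  enriched toward one image edge (tumor-periphery vascularization),
  rendered as filled disks;
* drug-fluorescence spots seeded from perfused vessels, at a distance from
  the vessel surface drawn from a configurable decay law (exponential by
  default) with arm-specific scale λ;
* spot peak intensity decaying exponentially with the spot's true
  distance to the nearest vessel (clipped below at a detectable floor);
* a configurable fraction of vessels that are unperfused and spawn no
  drug, an avascular patch with no vessels (hence no drug), and a
  necrotic region exported as an exclusion mask;
* additive Gaussian background noise.

Every accepted spot's exact (continuous) distance to the nearest vessel
surface is recorded as ground truth, so measured penetration can be
checked against the quantity the pipeline is supposed to estimate.

A whole study — 4 treatment arms × 2 sacrifice times × animals × fields —
is generated with per-arm (λ, spot rate) parameters defaulting to the
observed arm summaries, and with every field regenerable in isolation
from a deterministic sub-seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InconsistentSpec
from .imaging_core import FieldImage, MAGNIFICATION_AREA_MM2

GROUP_LABELS = {
    1: "doxo iv",
    2: "doxo ia",
    3: "doxo ia + E",
    4: "doxo + L ia + E",
}
TIME_POINTS = ("10min", "4h")

#: Per-(group, time) penetration scale λ (µm) and expected spot count per
#: 1.09 mm^2 evaluation field, taken from the observed arm summaries.
DEFAULT_ARM_PARAMS: dict[tuple[int, str], tuple[float, float]] = {
    (1, "10min"): (12.14, 235.75),
    (1, "4h"): (7.36, 75.00),
    (2, "10min"): (40.54, 2070.50),
    (2, "4h"): (32.68, 1137.00),
    (3, "10min"): (76.29, 3130.75),
    (3, "4h"): (72.37, 3190.00),
    (4, "10min"): (38.21, 1912.00),
    (4, "4h"): (81.16, 3681.50),
}


@dataclass(frozen=True)
class AvascularPatch:
    """Disk-shaped vessel-free region (fractional center, physical radius)."""

    center_row_frac: float = 0.5
    center_col_frac: float = 0.65
    radius_um: float = 300.0


@dataclass
class SyntheticFieldSpec:
    """Forward-model parameters for one synthetic field."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_pitch_um: float = 1.0196  # 1.09 mm^2 over 1024x1024 px
    vessel_density_per_mm2: float = 30.0
    edge_enrichment: float = 3.0  # density multiplier at the col=0 edge vs far edge
    vessel_radius_um_mean: float = 4.0
    vessel_radius_um_sd: float = 1.0
    spot_rate: float = 2000.0  # expected number of accepted spots
    decay_scale_lambda_um: float = 40.0
    distance_law: str = "exponential"  # or "half-normal"
    intensity_decay_tau_um: float = 100.0
    unperfused_vessel_fraction: float = 0.05
    avascular_patch: AvascularPatch | None = None
    necrosis_fraction: float = 0.0
    background_noise: tuple[float, float] = (5.0, 2.0)  # (mean, sd)
    vessel_intensity: float = 200.0
    spot_peak_intensity: float = 180.0
    spot_min_intensity: float = 30.0  # detectability floor for rendered spots
    # small enough that adjacent spots rarely fuse into one component
    # (fusion breaks the spot <-> ground-truth correspondence); must stay
    # above ~1.2 px, the worst-case distance to the 4th-nearest pixel
    # center, so every rendered spot covers >= 4 px at any sub-pixel
    # offset and survives the default min_spot_size filter
    spot_radius_px: float = 1.3
    include_nuclear: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("raster dimensions must be >= 1")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        for name in ("decay_scale_lambda_um", "intensity_decay_tau_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("vessel_density_per_mm2", "spot_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("unperfused_vessel_fraction", "necrosis_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.distance_law not in ("exponential", "half-normal"):
            raise ValueError(f"unknown distance_law {self.distance_law!r}")
        if self.edge_enrichment < 1.0:
            raise ValueError("edge_enrichment must be >= 1")
        if self.vessel_density_per_mm2 == 0 and self.spot_rate > 0:
            raise InconsistentSpec("nonzero spot_rate with zero vessel density")

    @property
    def area_mm2(self) -> float:
        return self.width_px * self.height_px * self.pixel_pitch_um**2 * 1e-6

    @property
    def magnification_tag(self) -> str:
        """The protocol magnification whose printed area is closest."""
        return min(
            MAGNIFICATION_AREA_MM2,
            key=lambda tag: abs(MAGNIFICATION_AREA_MM2[tag] - self.area_mm2),
        )


@dataclass
class GroundTruth:
    """Exact generative state behind one rendered field."""

    spots: pd.DataFrame  # row, col, sampled_distance_um, true_distance_um, ...
    vessels: pd.DataFrame  # row, col, radius_um, perfused
    vessel_count_placed: int
    vessel_count_rendered: int
    necrosis_mask: np.ndarray
    avascular_mask: np.ndarray
    spec: SyntheticFieldSpec


@dataclass
class StudyDesign:
    """Parameters of a whole simulated study.

    ``arm_params`` maps (group, time point) to (λ µm, spot rate per
    1.09 mm^2).  ``animal_sigma_log`` is the SD of the per-animal
    log-normal multiplier applied to λ and the spot rate, reproducing
    between-animal spread of the observed summaries approximately.
    ``section_area_mm2`` sets the per-animal raster: the default is the
    full low-magnification scan area; fields equal to the evaluation-field
    area give a lighter study with pre-selected fields.
    """

    arm_params: dict[tuple[int, str], tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_ARM_PARAMS)
    )
    groups: tuple[int, ...] = (1, 2, 3, 4)
    time_points: tuple[str, ...] = TIME_POINTS
    animals_per_cell: int = 4
    fields_per_animal: int = 3
    animal_sigma_log: float = 0.20
    section_area_mm2: float = 6.82
    pixel_pitch_um: float = 2.0
    spot_rate_scale: float = 1.0  # global down-scaling knob for light runs
    vessel_density_per_mm2: float = 30.0
    edge_enrichment: float = 3.0
    unperfused_vessel_fraction: float = 0.05
    necrosis_fraction: float = 0.08
    avascular_patch: AvascularPatch | None = AvascularPatch()
    master_seed: int = 0

    def __post_init__(self) -> None:
        for key in ((g, t) for g in self.groups for t in self.time_points):
            if key not in self.arm_params:
                raise ValueError(f"arm_params missing cell {key}")
            lam, rate = self.arm_params[key]
            if lam <= 0 or rate < 0:
                raise ValueError(f"invalid parameters for cell {key}")
        if self.animals_per_cell < 0 or self.fields_per_animal < 1:
            raise ValueError("invalid study size")

    @property
    def section_side_px(self) -> int:
        return round(math.sqrt(self.section_area_mm2 * 1e6) / self.pixel_pitch_um)

    def sub_seed(self, group: int, time_point: str, animal: int, stream: int) -> int:
        """Deterministic sub-seed for one (cell, animal, stream) tuple.

        Mixing rule: a ``numpy`` ``SeedSequence`` keyed on the master seed
        and the integer indices, reduced to 31 bits.  ``stream`` 0..k-1
        addresses fields, 999 the per-animal parameter draw.
        """
        t_idx = self.time_points.index(time_point)
        ss = np.random.SeedSequence((self.master_seed, group, t_idx, animal, stream))
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def calibrated_drug_threshold(spec: SyntheticFieldSpec) -> float:
    """Detection threshold for a field with known calibration.

    Midway between the background mean and the dimmest rendered spot;
    with the default noise level this sits >6 SD above background, so the
    per-pixel false-positive rate is negligible while no spot is censored.
    Per-field Otsu is only needed when the calibration is unknown.
    """
    return 0.5 * (spec.background_noise[0] + spec.spot_min_intensity)


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------


def _disk_mask(shape: tuple[int, int], center_rc: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2


def _stamp_disks(
    raster: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    radii_px: np.ndarray,
    values: np.ndarray,
) -> None:
    """Stamp filled disks onto ``raster`` with per-disk value, max-composited."""
    h, w = raster.shape
    for r0, c0, rad, val in zip(rows, cols, radii_px, values):
        lo_r, hi_r = int(max(0, math.floor(r0 - rad))), int(min(h - 1, math.ceil(r0 + rad)))
        lo_c, hi_c = int(max(0, math.floor(c0 - rad))), int(min(w - 1, math.ceil(c0 + rad)))
        if lo_r > hi_r or lo_c > hi_c:
            continue
        rr = np.arange(lo_r, hi_r + 1)[:, None]
        cc = np.arange(lo_c, hi_c + 1)[None, :]
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        patch = raster[lo_r : hi_r + 1, lo_c : hi_c + 1]
        np.maximum(patch, np.where(disk, val, 0.0), out=patch)


def _sample_edge_enriched_cols(rng: np.random.Generator, n: int, width_px: int, enrichment: float) -> np.ndarray:
    """Columns from a linear density, ``enrichment``-fold higher at col 0."""
    if enrichment == 1.0 or n == 0:
        return rng.uniform(0, width_px, size=n)
    out = np.empty(0)
    while out.size < n:
        cand = rng.uniform(0, width_px, size=max(16, 2 * (n - out.size)))
        u = cand / width_px
        accept = rng.uniform(0, 1, size=cand.size) < (enrichment - (enrichment - 1) * u) / enrichment
        out = np.concatenate([out, cand[accept]])
    return out[:n]


def _sample_distances(rng: np.random.Generator, n: int, law: str, scale_um: float) -> np.ndarray:
    if law == "exponential":
        return rng.exponential(scale_um, size=n)
    # half-normal with the same scale parameter
    return np.abs(rng.normal(0.0, scale_um, size=n))


def generate_field(spec: SyntheticFieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its exact ground truth.

    Identical spec (including seed) gives bitwise-identical rasters and
    ground-truth tables.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    pitch = spec.pixel_pitch_um
    shape = (h, w)

    # --- exclusion / structural masks -------------------------------------
    necrosis = np.zeros(shape, dtype=bool)
    if spec.necrosis_fraction > 0:
        radius_um = math.sqrt(spec.necrosis_fraction * spec.area_mm2 * 1e6 / math.pi)
        radius_px = radius_um / pitch
        margin = min(radius_px, (min(h, w) - 1) / 2.0)
        radius_px = margin  # shrink if the disk cannot fit fully inside
        cr = rng.uniform(radius_px, h - 1 - radius_px) if h - 1 > 2 * radius_px else (h - 1) / 2
        cc = rng.uniform(radius_px, w - 1 - radius_px) if w - 1 > 2 * radius_px else (w - 1) / 2
        necrosis = _disk_mask(shape, (cr, cc), radius_px)

    avascular = np.zeros(shape, dtype=bool)
    if spec.avascular_patch is not None:
        p = spec.avascular_patch
        avascular = _disk_mask(
            shape,
            (p.center_row_frac * (h - 1), p.center_col_frac * (w - 1)),
            p.radius_um / pitch,
        )

    # --- vessels ----------------------------------------------------------
    n_vessels = int(rng.poisson(spec.vessel_density_per_mm2 * spec.area_mm2))
    v_rows = np.empty(0)
    v_cols = np.empty(0)
    while v_rows.size < n_vessels:
        need = n_vessels - v_rows.size
        cand_c = _sample_edge_enriched_cols(rng, 2 * need + 8, w, spec.edge_enrichment)
        cand_r = rng.uniform(0, h, size=cand_c.size)
        ok = ~avascular[
            np.clip(cand_r.astype(int), 0, h - 1), np.clip(cand_c.astype(int), 0, w - 1)
        ]
        v_rows = np.concatenate([v_rows, cand_r[ok]])
        v_cols = np.concatenate([v_cols, cand_c[ok]])
    v_rows, v_cols = v_rows[:n_vessels], v_cols[:n_vessels]
    v_radii_um = np.clip(
        rng.normal(spec.vessel_radius_um_mean, spec.vessel_radius_um_sd, size=n_vessels),
        0.6 * pitch,
        None,
    )
    perfused = rng.uniform(size=n_vessels) >= spec.unperfused_vessel_fraction
    if n_vessels and spec.spot_rate > 0 and not perfused.any():
        perfused[0] = True  # degenerate draw: keep the field analyzable

    vessel_ch = np.zeros(shape, dtype=float)
    _stamp_disks(
        vessel_ch,
        v_rows,
        v_cols,
        v_radii_um / pitch,
        np.full(n_vessels, spec.vessel_intensity),
    )
    from scipy import ndimage as _ndi

    from .imaging_core import EIGHT_CONNECTED

    _, vessel_count_rendered = _ndi.label(vessel_ch > 0, structure=EIGHT_CONNECTED)

    # --- spots ------------------------------------------------------------
    n_spots = int(rng.poisson(spec.spot_rate))
    if n_spots > 0 and n_vessels == 0:
        raise InconsistentSpec("cannot place spots in a field with no vessels")
    perf_idx = np.flatnonzero(perfused)
    acc_rows: list[np.ndarray] = []
    acc_cols: list[np.ndarray] = []
    acc_sampled: list[np.ndarray] = []
    acc_src: list[np.ndarray] = []
    accepted = 0
    rounds = 0
    while accepted < n_spots:
        rounds += 1
        if rounds > 200:
            raise InconsistentSpec(
                "spot placement acceptance too low; check rejection regions"
            )
        m = max(64, 2 * (n_spots - accepted))
        src = perf_idx[rng.integers(0, perf_idx.size, size=m)]
        theta = rng.uniform(0, 2 * math.pi, size=m)
        d = _sample_distances(rng, m, spec.distance_law, spec.decay_scale_lambda_um)
        rad_px = (v_radii_um[src] + d) / pitch
        rr = v_rows[src] + rad_px * np.sin(theta)
        cc = v_cols[src] + rad_px * np.cos(theta)
        ok = (rr >= 0) & (rr <= h - 1) & (cc >= 0) & (cc <= w - 1)
        ri = np.clip(rr.astype(int), 0, h - 1)
        ci = np.clip(cc.astype(int), 0, w - 1)
        ok &= ~avascular[ri, ci] & ~necrosis[ri, ci]
        # reject spots that fall inside any vessel disk
        if ok.any() and n_vessels:
            d_true = _min_vessel_distance_um(
                rr[ok], cc[ok], v_rows, v_cols, v_radii_um, pitch
            )
            inside = d_true <= 0
            sel = np.flatnonzero(ok)
            ok[sel[inside]] = False
        take = np.flatnonzero(ok)[: n_spots - accepted]
        acc_rows.append(rr[take])
        acc_cols.append(cc[take])
        acc_sampled.append(d[take])
        acc_src.append(src[take])
        accepted += take.size

    s_rows = np.concatenate(acc_rows) if acc_rows else np.empty(0)
    s_cols = np.concatenate(acc_cols) if acc_cols else np.empty(0)
    s_sampled = np.concatenate(acc_sampled) if acc_sampled else np.empty(0)
    s_src = np.concatenate(acc_src) if acc_src else np.empty(0, dtype=int)
    if n_vessels and s_rows.size:
        s_true = _min_vessel_distance_um(s_rows, s_cols, v_rows, v_cols, v_radii_um, pitch)
    else:
        s_true = np.empty(0)

    # --- drug channel -------------------------------------------------------
    drug = np.clip(
        rng.normal(spec.background_noise[0], spec.background_noise[1], size=shape),
        0.0,
        None,
    )
    peaks = np.clip(
        spec.spot_peak_intensity * np.exp(-s_true / spec.intensity_decay_tau_um),
        spec.spot_min_intensity,
        None,
    )
    _stamp_disks(drug, s_rows, s_cols, np.full(s_rows.size, spec.spot_radius_px), peaks)

    channels = {
        "drug": drug,
        "vessel": vessel_ch,
        "exclusion": necrosis.astype(float) * 255.0,
    }
    if spec.include_nuclear:
        nuc = np.zeros(shape, dtype=float)
        n_nuc = int(rng.poisson(2000.0 * spec.area_mm2))
        _stamp_disks(
            nuc,
            rng.uniform(0, h - 1, size=n_nuc),
            rng.uniform(0, w - 1, size=n_nuc),
            np.full(n_nuc, 3.0 / pitch),
            np.full(n_nuc, 100.0),
        )
        channels["nuclear"] = nuc

    image = FieldImage(
        channels=channels,
        pixel_pitch_um=pitch,
        magnification_tag=spec.magnification_tag,
        field_area_mm2=spec.area_mm2,
        field_id=f"synthetic-seed{spec.seed}",
    )
    truth = GroundTruth(
        spots=pd.DataFrame(
            {
                "row": s_rows,
                "col": s_cols,
                "sampled_distance_um": s_sampled,
                "true_distance_um": s_true,
                "peak_intensity": peaks,
                "source_vessel": s_src,
            }
        ),
        vessels=pd.DataFrame(
            {
                "row": v_rows,
                "col": v_cols,
                "radius_um": v_radii_um,
                "perfused": perfused,
            }
        ),
        vessel_count_placed=n_vessels,
        vessel_count_rendered=int(vessel_count_rendered),
        necrosis_mask=necrosis,
        avascular_mask=avascular,
        spec=spec,
    )
    return image, truth


def _min_vessel_distance_um(
    rows: np.ndarray,
    cols: np.ndarray,
    v_rows: np.ndarray,
    v_cols: np.ndarray,
    v_radii_um: np.ndarray,
    pitch: float,
    chunk: int = 2048,
) -> np.ndarray:
    """Continuous distance (µm) from points to the nearest vessel surface.

    Negative inside a vessel; clipped to 0 only by callers that want the
    surface convention.
    """
    out = np.empty(rows.size)
    for lo in range(0, rows.size, chunk):
        hi = min(lo + chunk, rows.size)
        dr = (rows[lo:hi, None] - v_rows[None, :]) * pitch
        dc = (cols[lo:hi, None] - v_cols[None, :]) * pitch
        d = np.sqrt(dr**2 + dc**2) - v_radii_um[None, :]
        out[lo:hi] = d.min(axis=1)
    return out


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------


def field_spec_for(
    design: StudyDesign,
    group: int,
    time_point: str,
    animal: int,
    field_index: int,
) -> SyntheticFieldSpec:
    """Resolve the field spec for one (cell, animal, field) coordinate.

    Per-animal biological variability enters as one log-normal multiplier
    (median 1) applied to both λ and the spot rate, drawn from the
    animal's own deterministic sub-seed so all its fields share it.
    """
    lam, rate = design.arm_params[(group, time_point)]
    a_rng = np.random.default_rng(design.sub_seed(group, time_point, animal, 999))
    mult = float(np.exp(a_rng.normal(0.0, design.animal_sigma_log)))
    side = design.section_side_px
    area_scale = design.section_area_mm2 / 1.09  # rates are per evaluation field
    return SyntheticFieldSpec(
        width_px=side,
        height_px=side,
        pixel_pitch_um=design.pixel_pitch_um,
        vessel_density_per_mm2=design.vessel_density_per_mm2,
        edge_enrichment=design.edge_enrichment,
        spot_rate=rate * mult * area_scale * design.spot_rate_scale,
        decay_scale_lambda_um=lam * mult,
        unperfused_vessel_fraction=design.unperfused_vessel_fraction,
        necrosis_fraction=design.necrosis_fraction,
        avascular_patch=design.avascular_patch,
        seed=design.sub_seed(group, time_point, animal, field_index),
    )


def _animal_id(group: int, time_point: str, animal: int) -> str:
    return f"g{group}_{time_point}_a{animal + 1}"


MANIFEST_COLUMNS = [
    "animal_id",
    "group",
    "time_point",
    "field_index",
    "drug_path",
    "vessel_path",
    "exclusion_path",
    "magnification_tag",
    "field_area_mm2",
    "pixel_pitch_um",
]


def generate_study(design: StudyDesign, out_dir: str | Path) -> pd.DataFrame:
    """Render a whole study to disk and return its manifest.

    Writes one 16-bit grayscale TIFF per channel and record, a manifest
    CSV, per-spot and per-animal ground-truth CSVs, and the design as
    YAML.  Each animal contributes ``fields_per_animal`` records when the
    section area equals the evaluation-field area (pre-selected fields),
    or a single section record otherwise.
    """
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    section_mode = design.section_area_mm2 > 1.5 * 1.09
    n_records = 1 if section_mode else design.fields_per_animal

    manifest_rows = []
    truth_rows = []
    spot_frames = []
    for group in design.groups:
        for tp in design.time_points:
            for animal in range(design.animals_per_cell):
                aid = _animal_id(group, tp, animal)
                for fidx in range(n_records):
                    spec = field_spec_for(design, group, tp, animal, fidx)
                    image, truth = generate_field(spec)
                    paths = {}
                    for ch in ("drug", "vessel", "exclusion"):
                        p = img_dir / f"{aid}_f{fidx}_{ch}.tif"
                        tifffile.imwrite(
                            p, np.round(image.channels[ch]).astype(np.uint16)
                        )
                        paths[ch] = str(p.relative_to(out))
                    manifest_rows.append(
                        {
                            "animal_id": aid,
                            "group": group,
                            "time_point": tp,
                            "field_index": fidx,
                            "drug_path": paths["drug"],
                            "vessel_path": paths["vessel"],
                            "exclusion_path": paths["exclusion"],
                            "magnification_tag": image.magnification_tag,
                            "field_area_mm2": image.field_area_mm2,
                            "pixel_pitch_um": image.pixel_pitch_um,
                        }
                    )
                    truth_rows.append(
                        {
                            "animal_id": aid,
                            "group": group,
                            "time_point": tp,
                            "field_index": fidx,
                            "lambda_um": spec.decay_scale_lambda_um,
                            "spot_rate": spec.spot_rate,
                            "n_spots": len(truth.spots),
                            "mean_true_distance_um": (
                                float(truth.spots["true_distance_um"].mean())
                                if len(truth.spots)
                                else float("nan")
                            ),
                            "vessel_count_placed": truth.vessel_count_placed,
                            "vessel_count_rendered": truth.vessel_count_rendered,
                        }
                    )
                    sf = truth.spots.copy()
                    sf.insert(0, "field_index", fidx)
                    sf.insert(0, "animal_id", aid)
                    spot_frames.append(sf)

    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(
        truth_rows,
        columns=[
            "animal_id",
            "group",
            "time_point",
            "field_index",
            "lambda_um",
            "spot_rate",
            "n_spots",
            "mean_true_distance_um",
            "vessel_count_placed",
            "vessel_count_rendered",
        ],
    ).to_csv(out / "ground_truth_fields.csv", index=False)
    spots_all = (
        pd.concat(spot_frames, ignore_index=True)
        if spot_frames
        else pd.DataFrame(
            columns=[
                "animal_id",
                "field_index",
                "row",
                "col",
                "sampled_distance_um",
                "true_distance_um",
                "peak_intensity",
                "source_vessel",
            ]
        )
    )
    spots_all.to_csv(out / "ground_truth_spots.csv", index=False)

    design_dict = dataclasses.asdict(design)
    design_dict["arm_params"] = {
        f"{g}:{t}": list(v) for (g, t), v in design.arm_params.items()
    }
    if design.avascular_patch is not None:
        design_dict["avascular_patch"] = dataclasses.asdict(design.avascular_patch)
    (out / "design.yaml").write_text(yaml.safe_dump(design_dict, sort_keys=False))
    return manifest
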