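"""Study-level orchestration: manifest I/O, measurement, and summaries.

``run_simulate`` renders a synthetic study to disk, ``run_measure`` turns
a manifest of channel TIFFs into per-field / per-animal / per-group
tables, and ``run_summarize`` builds the group summary (subgroup rows,
pooled Total rows) plus the ANOVA/LSD comparison table from per-animal
values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import RunConfig
from .errors import InsufficientData, InsufficientFields, IOFailure, NoValidField, NoVesselInField
from .group_stats import SummaryStats, anova_oneway, combine_subgroups, lsd_t, summarize
from .imaging_core import BinaryMask, FieldImage, binarize_channel
from .penetration_metrics import (
    FieldMeasurement,
    animal_penetration,
    field_penetration,
    select_drug_fields,
)
from .synthetic_data import MANIFEST_COLUMNS, StudyDesign, generate_study
from .vascular_metrics import count_vessels, find_hotspots, mvd_for_animal, window_side_px

log = logging.getLogger("perivasc")

FIELD_COLUMNS = [
    "animal_id",
    "group",
    "time_point",
    "field_id",
    "mean_penetration_um",
    "spot_count",
    "excluded_fraction",
    "flags",
]
ANIMAL_COLUMNS = [
    "animal_id",
    "group",
    "time_point",
    "mvd",
    "penetration_um",
    "spot_count_mean",
    "flags",
]
GROUP_COLUMNS = [
    "group",
    "time_point",
    "n",
    "mvd_mean",
    "mvd_sd",
    "penetration_mean_um",
    "penetration_sd_um",
    "spot_count_mean",
    "spot_count_sd",
]
COMPARISON_COLUMNS = [
    "metric",
    "time_point",
    "anova_F",
    "anova_p",
    "group_a",
    "group_b",
    "t",
    "p",
]

METRICS = {
    "mvd": "mvd",
    "penetration_um": "penetration_um",
    "spot_count": "spot_count_mean",
}


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a study manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"manifest not found: {path}")
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise IOFailure(f"manifest missing columns: {sorted(missing)}")
    if len(manifest):
        dup = manifest.duplicated(subset=["animal_id", "field_index"])
        if dup.any():
            raise IOFailure("duplicate (animal_id, field_index) records in manifest")
        bad = ~manifest["group"].isin([1, 2, 3, 4])
        if bad.any():
            raise IOFailure(f"invalid group values: {manifest.loc[bad, 'group'].unique()}")
    return manifest


def _load_record_image(record: pd.Series, base_dir: Path) -> FieldImage:
    channels = {}
    for ch, col in (("drug", "drug_path"), ("vessel", "vessel_path"), ("exclusion", "exclusion_path")):
        rel = record.get(col)
        if col == "exclusion_path" and (pd.isna(rel) or rel == ""):
            continue
        p = base_dir / str(rel)
        if not p.exists():
            raise IOFailure(f"record {record['animal_id']}: missing file {p}")
        channels[ch] = tifffile.imread(p).astype(float)
    return FieldImage(
        channels=channels,
        pixel_pitch_um=float(record["pixel_pitch_um"]),
        magnification_tag=str(record["magnification_tag"]),
        field_area_mm2=float(record["field_area_mm2"]),
        field_id=f"{record['animal_id']}_f{record['field_index']}",
    )


def _crop_field(image: FieldImage, row: int, col: int, side: int, area_mm2: float, tag: str, field_id: str) -> FieldImage:
    channels = {
        name: ch[row : row + side, col : col + side] for name, ch in image.channels.items()
    }
    return FieldImage(
        channels=channels,
        pixel_pitch_um=image.pixel_pitch_um,
        magnification_tag=tag,
        field_area_mm2=area_mm2,
        field_id=field_id,
    )


def _measure_animal(
    records: pd.DataFrame, base_dir: Path, config: RunConfig
) -> tuple[list[FieldMeasurement], float | None]:
    """All field measurements plus the MVD for one animal.

    With a single section record, the drug-evaluation fields and the MVD
    counting windows are selected from the section by their respective
    hotspot scans; with pre-selected field records, each record is one
    evaluation field and contributes its best counting window to the MVD.
    """
    images = [_load_record_image(rec, base_dir) for _, rec in records.iterrows()]
    field_measurements: list[FieldMeasurement] = []
    mvd_counts: list[int] = []

    for image in images:
        exclusion = None
        if image.has_channel("exclusion"):
            exclusion = BinaryMask(image.channel("exclusion") > 0, "exclusion")
        vessels = binarize_channel(image, "vessel", method=config.vessel_method,
                                   fixed_threshold=config.vessel_fixed_threshold)

        drug_side = window_side_px(config.drug_field_area_mm2, image.pixel_pitch_um)
        if drug_side < min(image.shape):  # section: select evaluation fields
            try:
                selection = select_drug_fields(
                    image.channel("drug"),
                    exclusion=exclusion,
                    field_area_mm2=config.drug_field_area_mm2,
                    k=config.k_fields,
                    pixel_pitch_um=image.pixel_pitch_um,
                    stride_px=config.stride_px(drug_side),
                    max_excluded_fraction=config.max_excluded_fraction,
                )
            except NoValidField:
                log.warning("%s: no eligible drug field", image.field_id)
                selection = None
            if selection is not None:
                for i, win in enumerate(selection):
                    crop = _crop_field(
                        image, win.row, win.col, win.height_px,
                        config.drug_field_area_mm2, "x100",
                        f"{image.field_id}_w{i}",
                    )
                    field_measurements.append(field_penetration(crop, config))
        else:  # the record already is one evaluation field
            field_measurements.append(field_penetration(image, config))

        # MVD hotspot windows from the same vessel mask
        k = config.k_fields if len(images) == 1 else 1
        try:
            hotspots = find_hotspots(
                vessels,
                config.mvd_window_area_mm2,
                k=k,
                pixel_pitch_um=image.pixel_pitch_um,
                stride_px=config.stride_px(
                    window_side_px(config.mvd_window_area_mm2, image.pixel_pitch_um)
                ),
                min_size_px=config.min_vessel_size_px,
                exclusion=exclusion,
            )
        except Exception as exc:  # FieldTooSmall on unusually small records
            log.warning("%s: hotspot scan failed (%s)", image.field_id, exc)
            continue
        mvd_counts.extend(int(w.score) for w in hotspots)

    mvd = None
    if len(mvd_counts) >= 3:
        mvd = mvd_for_animal(mvd_counts[:3]).mvd
    return field_measurements, mvd


def run_measure(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    base_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Measure every animal in a manifest.

    Returns (and optionally writes) the per-field, per-animal, per-group
    and comparison tables.  An empty manifest yields header-only tables.
    """
    config = config or RunConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        base_dir = base_dir or manifest_path.parent
        manifest = read_manifest(manifest_path)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    field_rows = []
    animal_rows = []
    for (aid, group, tp), records in manifest.groupby(
        ["animal_id", "group", "time_point"], sort=True
    ):
        records = records.sort_values("field_index")
        measurements, mvd = _measure_animal(records, base_dir, config)
        for m in measurements:
            field_rows.append(
                {
                    "animal_id": aid,
                    "group": group,
                    "time_point": tp,
                    "field_id": m.field_id,
                    "mean_penetration_um": m.mean_penetration_um,
                    "spot_count": m.spot_count,
                    "excluded_fraction": m.excluded_fraction,
                    "flags": ";".join(m.flags),
                }
            )
        usable = [m for m in measurements if m.usable][: config.k_fields]
        try:
            if len(usable) < 3:
                raise InsufficientFields(
                    f"animal {aid}: {len(usable)} usable fields of {len(measurements)}"
                )
            animal = animal_penetration(usable, aid, int(group), str(tp), mvd=mvd)
            animal_rows.append(
                {
                    "animal_id": aid,
                    "group": group,
                    "time_point": tp,
                    "mvd": animal.mvd,
                    "penetration_um": animal.penetration_um,
                    "spot_count_mean": animal.spot_count_mean,
                    "flags": "",
                }
            )
        except InsufficientFields as exc:
            log.warning("animal %s skipped: %s", aid, exc)
            animal_rows.append(
                {
                    "animal_id": aid,
                    "group": group,
                    "time_point": tp,
                    "mvd": mvd,
                    "penetration_um": np.nan,
                    "spot_count_mean": np.nan,
                    "flags": "insufficient-fields",
                }
            )

    fields = pd.DataFrame(field_rows, columns=FIELD_COLUMNS)
    animals = pd.DataFrame(animal_rows, columns=ANIMAL_COLUMNS)
    groups, comparisons = run_summarize(animals)

    tables = {
        "fields": fields,
        "animals": animals,
        "groups": groups,
        "comparisons": comparisons,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables


def _cell_summary(values: pd.Series) -> SummaryStats | None:
    vals = values.dropna().to_numpy(dtype=float)
    if vals.size < 2:
        return None
    return summarize(vals)


def run_summarize(animals: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summary table (subgroup + Total rows) and comparison table.

    Total rows are pooled from the two equal-n time-point subgroups with
    the exact subgroup-combination identity; comparisons are one-way
    ANOVA across groups followed by pairwise LSD-t, per metric and per
    time point (including "Total" on the pooled per-animal values).
    """
    group_rows = []
    comparison_rows = []
    if len(animals) == 0:
        return (
            pd.DataFrame(columns=GROUP_COLUMNS),
            pd.DataFrame(columns=COMPARISON_COLUMNS),
        )
    usable = animals[animals["flags"].fillna("") == ""]
    time_points = [t for t in ("10min", "4h") if t in set(usable["time_point"])]
    groups_present = sorted(usable["group"].unique())

    summaries: dict[tuple[int, str, str], SummaryStats | None] = {}
    for g in groups_present:
        per_group = usable[usable["group"] == g]
        for tp in time_points:
            cell = per_group[per_group["time_point"] == tp]
            row = {"group": g, "time_point": tp, "n": len(cell)}
            for metric, col in METRICS.items():
                s = _cell_summary(cell[col])
                summaries[(g, tp, metric)] = s
                row[_mean_col(metric)] = s.mean if s else np.nan
                row[_sd_col(metric)] = s.sd if s else np.nan
            group_rows.append(row)
        if len(time_points) == 2:
            row = {"group": g, "time_point": "Total"}
            n_total = 0
            for metric in METRICS:
                a = summaries.get((g, time_points[0], metric))
                b = summaries.get((g, time_points[1], metric))
                if a is not None and b is not None and a.n == b.n:
                    s = combine_subgroups(a, b)
                elif len(per_group):
                    s = _cell_summary(per_group[METRICS[metric]])
                else:
                    s = None
                summaries[(g, "Total", metric)] = s
                row[_mean_col(metric)] = s.mean if s else np.nan
                row[_sd_col(metric)] = s.sd if s else np.nan
                n_total = s.n if s else len(per_group)
            row["n"] = n_total
            group_rows.append(row)

    for metric, col in METRICS.items():
        for tp in [*time_points] + (["Total"] if len(time_points) == 2 else []):
            cell_values = []
            cell_groups = []
            for g in groups_present:
                sub = usable[usable["group"] == g]
                if tp != "Total":
                    sub = sub[sub["time_point"] == tp]
                vals = sub[col].dropna().to_numpy(dtype=float)
                if vals.size >= 2:
                    cell_values.append(vals)
                    cell_groups.append(g)
            if len(cell_values) < 2:
                continue
            try:
                anova = anova_oneway(cell_values)
            except Exception as exc:
                log.warning("ANOVA skipped for %s/%s: %s", metric, tp, exc)
                continue
            stats_by_group = {g: summarize(v) for g, v in zip(cell_groups, cell_values)}
            for i, ga in enumerate(cell_groups):
                for gb in cell_groups[i + 1 :]:
                    t, p = lsd_t(stats_by_group[ga], stats_by_group[gb], anova)
                    comparison_rows.append(
                        {
                            "metric": metric,
                            "time_point": tp,
                            "anova_F": anova.F,
                            "anova_p": anova.p_value,
                            "group_a": ga,
                            "group_b": gb,
                            "t": t,
                            "p": p,
                        }
                    )

    groups_df = pd.DataFrame(group_rows, columns=GROUP_COLUMNS)
    comparisons_df = pd.DataFrame(comparison_rows, columns=COMPARISON_COLUMNS)
    return groups_df, comparisons_df


def _mean_col(metric: str) -> str:
    return {
        "mvd": "mvd_mean",
        "penetration_um": "penetration_mean_um",
        "spot_count": "spot_count_mean",
    }[metric]


def _sd_col(metric: str) -> str:
    return {
        "mvd": "mvd_sd",
        "penetration_um": "penetration_sd_um",
        "spot_count": "spot_count_sd",
    }[metric]


def measure_simulated_study(
    design: StudyDesign, config: RunConfig | None = None
) -> pd.DataFrame:
    """Generate and measure a study in memory, without touching disk.

    Only valid for designs whose section area equals the evaluation-field
    area (each generated raster is one pre-selected field).  Returns the
    per-animal table of ``run_measure``; animals with fewer than three
    usable fields appear with NaN measurements and a flag.
    """
    from .synthetic_data import field_spec_for, generate_field

    if config is None:
        from .synthetic_data import SyntheticFieldSpec, calibrated_drug_threshold

        config = RunConfig(
            drug_method="fixed",
            drug_fixed_threshold=calibrated_drug_threshold(SyntheticFieldSpec()),
        )
    rows = []
    for group in design.groups:
        for tp in design.time_points:
            for animal in range(design.animals_per_cell):
                aid = f"g{group}_{tp}_a{animal + 1}"
                measurements = []
                mvd_counts: list[int] = []
                for fidx in range(design.fields_per_animal):
                    spec = field_spec_for(design, group, tp, animal, fidx)
                    image, _ = generate_field(spec)
                    image.field_id = f"{aid}_f{fidx}"
                    measurements.append(field_penetration(image, config))
                    vessels = binarize_channel(
                        image, "vessel", method=config.vessel_method,
                        fixed_threshold=config.vessel_fixed_threshold,
                    )
                    exclusion = BinaryMask(image.channel("exclusion") > 0, "exclusion")
                    hotspots = find_hotspots(
                        vessels,
                        config.mvd_window_area_mm2,
                        k=1,
                        pixel_pitch_um=image.pixel_pitch_um,
                        stride_px=config.stride_px(
                            window_side_px(
                                config.mvd_window_area_mm2, image.pixel_pitch_um
                            )
                        ),
                        min_size_px=config.min_vessel_size_px,
                        exclusion=exclusion,
                    )
                    mvd_counts.extend(int(w.score) for w in hotspots)
                usable = [m for m in measurements if m.usable]
                mvd = mvd_for_animal(mvd_counts[:3]).mvd if len(mvd_counts) >= 3 else None
                row = {
                    "animal_id": aid,
                    "group": group,
                    "time_point": tp,
                    "mvd": mvd,
                    "penetration_um": np.nan,
                    "spot_count_mean": np.nan,
                    "flags": "insufficient-fields",
                }
                if len(usable) >= 3:
                    animal_m = animal_penetration(
                        usable[:3], aid, int(group), str(tp), mvd=mvd
                    )
                    row.update(
                        penetration_um=animal_m.penetration_um,
                        spot_count_mean=animal_m.spot_count_mean,
                        flags="",
                    )
                rows.append(row)
    return pd.DataFrame(rows, columns=ANIMAL_COLUMNS)


def run_simulate(
    design: StudyDesign, config: RunConfig | None = None, out_dir: str | Path = "study"
) -> pd.DataFrame:
    """Render a synthetic study and write the resolved config next to it.

    A simulated study has a known calibration, so the default config it
    ships uses the fixed calibrated drug threshold instead of per-field
    Otsu (which censors the dimmest far-from-vessel spots).
    """
    if config is None:
        from .synthetic_data import SyntheticFieldSpec, calibrated_drug_threshold

        config = RunConfig(
            drug_method="fixed",
            drug_fixed_threshold=calibrated_drug_threshold(SyntheticFieldSpec()),
            seed=design.master_seed,
        )
    manifest = generate_study(design, out_dir)
    config.to_yaml(Path(out_dir) / "config.yaml")
    return manifest
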