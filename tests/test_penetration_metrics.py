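"""Tests for drug-field selection, penetration measurement and exposure."""

import numpy as np
import pytest

from perivasc.config import RunConfig
from perivasc.errors import InsufficientFields, NoValidField
from perivasc.imaging_core import BinaryMask
from perivasc.penetration_metrics import (
    animal_penetration,
    exposed_fraction,
    field_penetration,
    select_drug_fields,
)
from perivasc.synthetic_data import (
    SyntheticFieldSpec,
    calibrated_drug_threshold,
    generate_field,
)

from conftest import make_field
from oracles import exhaustive_window_sums


def _fixed_cfg(spec=None, **kw):
    spec = spec or SyntheticFieldSpec()
    return RunConfig(
        drug_method="fixed", drug_fixed_threshold=calibrated_drug_threshold(spec), **kw
    )


class TestSelectDrugFields:
    def test_bright_region_wins(self, rng):
        section = rng.uniform(0, 1, size=(80, 80))
        section[50:70, 10:30] += 100.0
        sel = select_drug_fields(section, field_area_mm2=400e-6, k=1, pixel_pitch_um=1.0)
        w = sel.windows[0]
        assert w.row <= 60 and w.row + w.height_px >= 55
        assert w.col <= 20 and w.col + w.width_px >= 15

    def test_fully_excluded_section_raises(self):
        excl = BinaryMask(np.ones((50, 50), dtype=bool), "exclusion")
        with pytest.raises(NoValidField):
            select_drug_fields(
                np.ones((50, 50)), exclusion=excl, field_area_mm2=100e-6,
                k=1, pixel_pitch_um=1.0,
            )

    def test_scores_match_exhaustive_window_sum_oracle(self, rng):
        section = rng.uniform(size=(40, 40))
        side = 10
        stride = 2
        sel = select_drug_fields(
            section, field_area_mm2=100e-6, k=2, pixel_pitch_um=1.0, stride_px=stride
        )
        origins = list(range(0, 31, stride))
        if origins[-1] != 30:
            origins.append(30)
        oracle = exhaustive_window_sums(section, side, origins, origins)
        assert sel.windows[0].score == pytest.approx(max(oracle.values()), rel=1e-12)
        for w in sel.windows:
            assert w.score == pytest.approx(oracle[(w.row, w.col)], rel=1e-12)

    def test_excluded_pixels_do_not_contribute_to_score(self):
        section = np.ones((30, 30))
        section[0:10, 0:10] = 50.0
        excl = np.zeros((30, 30), dtype=bool)
        excl[0:10, 0:10] = True  # the bright block is artifact
        sel = select_drug_fields(
            section,
            exclusion=BinaryMask(excl, "exclusion"),
            field_area_mm2=100e-6,
            k=1,
            pixel_pitch_um=1.0,
            stride_px=1,
        )
        w = sel.windows[0]
        # a window avoiding the excluded block outscores any window on it
        assert w.score == pytest.approx(100.0)


class TestFieldPenetration:
    def test_two_spots_at_known_distances(self):
        vessel = np.zeros((20, 60))
        vessel[:, 0] = 255.0
        drug = np.zeros((20, 60))
        drug[8:10, 9:11] = 50.0  # centroid col 9.5 -> rounds to 10 µm at pitch 1
        drug[14:16, 29:31] = 50.0  # -> 30 µm
        field = make_field(drug, vessel, pixel_pitch_um=1.0)
        m = field_penetration(
            field, RunConfig(drug_method="fixed", drug_fixed_threshold=10.0)
        )
        assert m.spot_count == 2
        assert m.mean_penetration_um == pytest.approx(20.0, abs=1e-9)
        assert m.usable

    def test_no_drug_above_threshold_flags_field(self):
        vessel = np.zeros((16, 16))
        vessel[8, 8] = 255.0
        field = make_field(np.zeros((16, 16)), vessel, pixel_pitch_um=1.0)
        m = field_penetration(field, RunConfig(drug_method="fixed", drug_fixed_threshold=10.0))
        assert m.spot_count == 0
        assert not m.usable and "no-spot" in m.flags
        assert np.isnan(m.mean_penetration_um)

    def test_no_vessel_flags_field(self):
        drug = np.zeros((16, 16))
        drug[4:6, 4:6] = 99.0
        field = make_field(drug, np.zeros((16, 16)), pixel_pitch_um=1.0)
        m = field_penetration(field, RunConfig(drug_method="fixed", drug_fixed_threshold=10.0))
        assert "no-vessel" in m.flags

    def test_simulator_field_recovers_ground_truth_mean(self):
        spec = SyntheticFieldSpec(
            width_px=1536, height_px=1536, spot_rate=1000,
            decay_scale_lambda_um=40.0, seed=21,
        )
        image, truth = generate_field(spec)
        m = field_penetration(image, _fixed_cfg(spec))
        t = truth.spots["true_distance_um"]
        tol = 3 * t.std() / np.sqrt(len(t))
        assert m.mean_penetration_um == pytest.approx(t.mean(), abs=tol)

    def test_raising_threshold_never_increases_spot_count(self):
        spec = SyntheticFieldSpec(width_px=512, height_px=512, pixel_pitch_um=2.0392,
                                  spot_rate=300, seed=5)
        image, _ = generate_field(spec)
        counts = []
        for thr in (10.0, 40.0, 120.0):
            m = field_penetration(
                image, RunConfig(drug_method="fixed", drug_fixed_threshold=thr)
            )
            counts.append(m.spot_count)
        assert counts == sorted(counts, reverse=True)

    def test_excluded_region_contributes_no_spots(self):
        vessel = np.zeros((20, 20))
        vessel[0, 0] = 255.0
        drug = np.zeros((20, 20))
        drug[10:12, 10:12] = 99.0
        excl = np.zeros((20, 20))
        excl[8:14, 8:14] = 255.0
        field = make_field(drug, vessel, exclusion=excl, pixel_pitch_um=1.0)
        m = field_penetration(field, RunConfig(drug_method="fixed", drug_fixed_threshold=10.0))
        assert m.spot_count == 0 and "no-spot" in m.flags


class TestAnimalPenetration:
    @staticmethod
    def _measurements(means, counts):
        from perivasc.penetration_metrics import FieldMeasurement

        return [
            FieldMeasurement(field_id=f"f{i}", mean_penetration_um=m,
                             spot_count=c)
            for i, (m, c) in enumerate(zip(means, counts))
        ]

    def test_animal_means_over_three_fields(self):
        fields = self._measurements([10.0, 20.0, 30.0], [100, 200, 300])
        a = animal_penetration(fields, "a1", 2, "10min")
        assert a.penetration_um == 20.0
        assert a.spot_count_mean == 200.0

    def test_field_order_does_not_matter(self):
        f = self._measurements([10.0, 20.0, 30.0], [1, 2, 3])
        a = animal_penetration(f, "a", 1, "4h")
        b = animal_penetration(f[::-1], "a", 1, "4h")
        assert a.penetration_um == b.penetration_um

    def test_flagged_or_missing_fields_rejected(self):
        from perivasc.penetration_metrics import FieldMeasurement

        two = self._measurements([10.0, 20.0], [1, 2])
        with pytest.raises(InsufficientFields):
            animal_penetration(two, "a", 1, "10min")
        flagged = self._measurements([10.0, 20.0], [1, 2]) + [
            FieldMeasurement("f2", float("nan"), 0, flags=["no-spot"])
        ]
        with pytest.raises(InsufficientFields, match="no-spot"):
            animal_penetration(flagged, "a", 1, "10min")


class TestExposedFraction:
    def test_saturated_and_empty_fields(self):
        vessel = np.zeros((40, 40))
        vessel[20, 20] = 255.0
        hot = make_field(np.full((40, 40), 99.0), vessel, pixel_pitch_um=1.0)
        cfg = RunConfig(drug_method="fixed", drug_fixed_threshold=10.0,
                        distance_band_um=10.0, distance_band_max_um=30.0)
        frac = exposed_fraction(hot, cfg)
        assert np.allclose(frac.exposed_fraction.dropna(), 1.0)
        cold = make_field(np.zeros((40, 40)), vessel, pixel_pitch_um=1.0)
        assert np.allclose(exposed_fraction(cold, cfg).exposed_fraction.dropna(), 0.0)

    def test_drug_confined_near_vessels_leaves_far_bands_unexposed(self):
        spec = SyntheticFieldSpec(
            width_px=1024, height_px=1024, spot_rate=1500,
            decay_scale_lambda_um=15.0, seed=9,
        )
        image, _ = generate_field(spec)
        cfg = _fixed_cfg(spec, distance_band_um=50.0, distance_band_max_um=200.0)
        frac = exposed_fraction(image, cfg)
        far = frac[frac.band_left_um >= 100.0].exposed_fraction.dropna()
        assert (far < 0.05).all()

    def test_fraction_non_increasing_with_distance_on_decay_fields(self):
        spec = SyntheticFieldSpec(
            width_px=1024, height_px=1024, spot_rate=2000,
            decay_scale_lambda_um=30.0, seed=13,
        )
        image, _ = generate_field(spec)
        frac = exposed_fraction(image, _fixed_cfg(spec))
        vals = frac.exposed_fraction.dropna().to_numpy()
        counts = frac.pixel_count[frac.exposed_fraction.notna()].to_numpy()
        se = np.sqrt(np.maximum(vals * (1 - vals), 1e-12) / np.maximum(counts, 1))
        for i in range(1, len(vals)):
            assert vals[i] <= vals[i - 1] + 3 * (se[i] + se[i - 1])
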