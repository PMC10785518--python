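"""DVH metrics against closed forms and direct-count oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaptrt.grids import DoseGrid, EmptyMaskError, GridGeometry, ValidationError
from adaptrt.dosimetry import (
    compute_metric,
    d_mean,
    d_volume,
    dvh_curve,
    evaluate_plan,
    resample_dose,
    v100,
    v_dose,
)

from conftest import box_mask, make_mask


@pytest.fixture
def geom():
    return GridGeometry(shape=(10, 10, 20), spacing=(2.0, 2.0, 2.0))


def uniform_dose(geom, value, rx=45.0):
    return DoseGrid(geom, np.full(geom.shape, float(value)), prescription=rx)


def ramp_dose(geom, lo=0.0, hi=60.0, rx=45.0):
    """Dose increasing linearly along z from lo at slice 0 to hi at the top."""
    nz = geom.shape[2]
    ramp = np.linspace(lo, hi, nz)
    return DoseGrid(geom, np.broadcast_to(ramp, geom.shape).copy(), prescription=rx)


class TestResample:
    def test_identity_on_same_geometry(self, geom):
        d = ramp_dose(geom)
        out = resample_dose(d, geom)
        assert np.array_equal(out.dose, d.dose)

    def test_linear_field_reproduced_on_finer_grid(self):
        src = GridGeometry(shape=(8, 8, 8), spacing=(2, 2, 2))
        x = src.axis_coords(0)[:, None, None]
        y = src.axis_coords(1)[None, :, None]
        z = src.axis_coords(2)[None, None, :]
        field = 1.0 + 0.5 * x + 0.25 * y + 0.1 * z
        dose = DoseGrid(src, np.broadcast_to(field, src.shape).copy(), prescription=45)
        fine = GridGeometry(shape=(13, 13, 13), spacing=(1, 1, 1), origin=(0.5, 0.5, 0.5))
        out = resample_dose(dose, fine)
        fx = fine.axis_coords(0)[:, None, None]
        fy = fine.axis_coords(1)[None, :, None]
        fz = fine.axis_coords(2)[None, None, :]
        expected = 1.0 + 0.5 * fx + 0.25 * fy + 0.1 * fz
        assert out.dose == pytest.approx(np.broadcast_to(expected, fine.shape), rel=1e-12)

    def test_disjoint_extents_error(self, geom):
        far = GridGeometry(shape=(4, 4, 4), spacing=(1, 1, 1), origin=(500, 0, 0))
        with pytest.raises(ValidationError, match="disjoint"):
            resample_dose(uniform_dose(geom, 10), far)

    def test_outside_extent_zero_filled_with_warning(self, geom):
        big = GridGeometry(shape=(10, 10, 30), spacing=(2, 2, 2))
        with pytest.warns(UserWarning, match="outside"):
            out = resample_dose(uniform_dose(geom, 10), big)
        assert out.dose[:, :, -1] == pytest.approx(0.0)


class TestDvhCurve:
    def test_uniform_dose_step(self, geom):
        mask = box_mask(geom, (2, 2, 2), (7, 7, 10))
        curve = dvh_curve(uniform_dose(geom, 45.0), mask, bin_width=1.0)
        below = curve.dose_edges <= 45.0
        assert np.all(curve.cum_volume_pct[below] == 100.0)
        assert np.all(curve.cum_volume_pct[~below] == 0.0)

    def test_two_level_field_hand_count(self, geom):
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        dose = np.full(geom.shape, 10.0)
        dose[:, :, 10:] = 30.0  # half the voxels
        curve = dvh_curve(DoseGrid(geom, dose, 45.0), mask, bin_width=1.0)
        assert curve.cum_volume_pct[curve.dose_edges <= 10.0] == pytest.approx(100.0)
        mid = (curve.dose_edges > 10.0) & (curve.dose_edges <= 30.0)
        assert curve.cum_volume_pct[mid] == pytest.approx(50.0)
        assert curve.cum_volume_pct[curve.dose_edges > 30.0] == pytest.approx(0.0)

    def test_random_field_curve_non_increasing(self, geom):
        rng = np.random.default_rng(0)
        dose = DoseGrid(geom, rng.uniform(0, 60, geom.shape), 45.0)
        mask = box_mask(geom, (1, 1, 1), (8, 8, 18))
        curve = dvh_curve(dose, mask, bin_width=0.5)
        assert np.all(np.diff(curve.cum_volume_pct) <= 0)


class TestVDose:
    def test_threshold_equal_dose_counts_as_covered(self, geom):
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        assert v_dose(uniform_dose(geom, 30.0), mask, 30.0) == 100.0
        assert v_dose(uniform_dose(geom, 30.0), mask, 30.0001) == 0.0

    def test_linear_ramp_half_coverage(self, geom):
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        dose = ramp_dose(geom, 0.0, 60.0)
        got = v_dose(dose, mask, 30.0)
        assert got == pytest.approx(50.0, abs=100.0 / geom.shape[2])  # one-slice quantization

    def test_cm3_and_percent_agree_through_volume(self, geom):
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        dose = ramp_dose(geom)
        pct = v_dose(dose, mask, 30.0, mode="percent")
        cm3 = v_dose(dose, mask, 30.0, mode="cm3")
        assert cm3 == pytest.approx(pct / 100.0 * mask.volume_cm3)

    def test_monotone_in_threshold(self, geom):
        rng = np.random.default_rng(1)
        dose = DoseGrid(geom, rng.uniform(0, 60, geom.shape), 45.0)
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        values = [v_dose(dose, mask, t) for t in np.linspace(0, 65, 14)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestV100:
    def test_uniform_at_prescription(self, geom):
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        assert v100(uniform_dose(geom, 45.0, rx=45.0), mask) == 100.0
        assert v100(uniform_dose(geom, 0.99 * 45.0, rx=45.0), mask) == 0.0

    def test_constructed_ninety_percent_coverage(self, geom):
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        dose = np.full(geom.shape, 46.0)
        dose[:, :, :2] = 44.0  # 2 of 20 slices below prescription
        assert v100(DoseGrid(geom, dose, prescription=45.0), mask) == pytest.approx(90.0)


class TestDVolume:
    def test_uniform_d50(self, geom):
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        assert d_volume(uniform_dose(geom, 45.0), mask, 50.0) == 45.0

    def test_rank_rule_on_distinct_doses(self):
        geom = GridGeometry(shape=(10, 10, 1), spacing=(1, 1, 1))
        dose = np.arange(1.0, 101.0).reshape(10, 10, 1)
        mask = box_mask(geom, (0, 0, 0), (9, 9, 0))
        grid = DoseGrid(geom, dose, prescription=45.0)
        assert d_volume(grid, mask, 5.0) == 96.0  # hottest 5 voxels -> rank 5
        assert d_volume(grid, mask, 100.0) == 1.0  # minimum dose
        assert d_volume(grid, mask, 1.0) == 100.0  # hottest voxel

    def test_d2cm3_on_exactly_2cm3_mask_is_min_dose(self):
        geom = GridGeometry(shape=(20, 10, 10), spacing=(1, 1, 1))
        mask = box_mask(geom, (0, 0, 0), (19, 9, 9))  # 2000 voxels = 2 cm^3
        rng = np.random.default_rng(4)
        dose = DoseGrid(geom, rng.uniform(10, 50, geom.shape), 45.0)
        assert d_volume(dose, mask, 2.0, unit="cm3") == pytest.approx(
            dose.dose[mask.voxels].min())

    def test_q_bounds(self, geom):
        mask = box_mask(geom, (0, 0, 0), (4, 4, 4))
        dose = uniform_dose(geom, 45.0)
        with pytest.raises(ValidationError):
            d_volume(dose, mask, 0.0)
        with pytest.raises(ValidationError):
            d_volume(dose, mask, mask.volume_cm3 * 2, unit="cm3")

    def test_monotone_in_q_and_consistency_with_v_dose(self, geom):
        rng = np.random.default_rng(2)
        dose = DoseGrid(geom, rng.uniform(0, 60, geom.shape), 45.0)
        mask = box_mask(geom, (0, 0, 0), (9, 9, 19))
        qs = np.linspace(1, 100, 25)
        values = [d_volume(dose, mask, q) for q in qs]
        assert all(a >= b for a, b in zip(values, values[1:]))
        n = mask.n_voxels
        for q in (5.0, 37.0, 80.0):
            # coverage at the Dq threshold is at least q, within one voxel
            assert v_dose(dose, mask, d_volume(dose, mask, q)) >= q - 100.0 / n


class TestDMean:
    def test_two_voxel_average(self):
        geom = GridGeometry(shape=(2, 1, 1), spacing=(1, 1, 1))
        dose = DoseGrid(geom, np.array([[[10.0]], [[30.0]]]), 45.0)
        mask = box_mask(geom, (0, 0, 0), (1, 0, 0))
        assert d_mean(dose, mask) == 20.0

    def test_random_field_matches_direct_summation(self, geom):
        rng = np.random.default_rng(3)
        dose = DoseGrid(geom, rng.uniform(0, 60, geom.shape), 45.0)
        mask = box_mask(geom, (2, 3, 4), (7, 8, 15))
        expected = dose.dose[mask.voxels].sum() / mask.n_voxels
        assert d_mean(dose, mask) == pytest.approx(expected, rel=1e-12)


class TestEvaluatePlan:
    def test_uniform_prescription_gives_full_target_coverage(self, geom):
        mask = box_mask(geom, (2, 2, 2), (7, 7, 17), name="CTV-N")
        recs = evaluate_plan(uniform_dose(geom, 45.0, rx=45.0), {"CTV-N": mask},
                             {"CTV-N": ["V100_pct"]}, plan="S-Adapted")
        assert len(recs) == 1
        assert recs[0].value == 100.0

    def test_records_match_independent_recomputation(self, geom):
        rng = np.random.default_rng(6)
        dose = DoseGrid(geom, rng.uniform(0, 60, geom.shape), 45.0)
        mask = box_mask(geom, (1, 1, 1), (8, 8, 18), name="bladder")
        panel = {"bladder": ["V40Gy_pct", "V30Gy_pct", "Dmean_Gy", "D50pct_Gy", "V40Gy_cm3"]}
        recs = {r.metric: r.value for r in evaluate_plan(dose, {"bladder": mask}, panel)}
        d = dose.dose[mask.voxels]
        assert recs["V40Gy_pct"] == pytest.approx(100.0 * (d >= 40).mean())
        assert recs["V40Gy_cm3"] == pytest.approx((d >= 40).sum() * 8.0 / 1000.0)
        assert recs["Dmean_Gy"] == pytest.approx(d.mean())
        assert recs["D50pct_Gy"] == pytest.approx(np.sort(d)[::-1][int(np.ceil(d.size / 2)) - 1])

    def test_unknown_metric_rejected(self, geom):
        mask = box_mask(geom, (2, 2, 2), (7, 7, 17), name="roi")
        with pytest.raises(ValidationError, match="unknown"):
            compute_metric(uniform_dose(geom, 45.0), mask, "Q17_banana")

    def test_empty_mask_raises(self, geom):
        empty = make_mask(geom, np.zeros(geom.shape, bool))
        with pytest.raises(EmptyMaskError):
            v_dose(uniform_dose(geom, 45.0), empty, 10.0)
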