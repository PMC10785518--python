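"""Phantom generator: determinism, anatomy, deformation recovery, dose."""
import numpy as np
import pytest

from adaptrt.grids import GridGeometry, ValidationError
from adaptrt.metrics import asd, centroid_deviation, dsc, hd95
from adaptrt.subdivision import split_ctvn
from adaptrt.synthetic import (
    CohortDeformationParams,
    DeformationSpec,
    PhantomConfig,
    StructureDeformation,
    build_ptvs,
    make_cohort,
    make_dose,
    make_phantom,
    perturb,
    snapped_translation,
)
from adaptrt.dosimetry import v100

from conftest import SMALL_GEOMETRY, sphere_mask


class TestMakePhantom:
    def test_deterministic(self, small_phantom_config):
        s1, lm1 = make_phantom(small_phantom_config)
        s2, lm2 = make_phantom(small_phantom_config)
        assert lm1 == lm2
        assert set(s1) == set(s2)
        for name in s1:
            assert np.array_equal(s1[name].voxels, s2[name].voxels)

    def test_nodal_chains_fill_all_eleven_subregions(self, small_phantom):
        structures, landmarks = small_phantom
        parts = split_ctvn(structures["CTV-N"], landmarks)
        assert len(parts.labels) == 11

    def test_structures_pairwise_disjoint(self, small_phantom):
        structures, _ = small_phantom
        names = sorted(structures)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (structures[a].voxels & structures[b].voxels).any(), (a, b)

    def test_cohort_inventories(self):
        post, _ = make_phantom(PhantomConfig(geometry=SMALL_GEOMETRY, cohort="postoperative"))
        uter, _ = make_phantom(PhantomConfig(geometry=SMALL_GEOMETRY, cohort="uterine"))
        assert {"CTV-N", "CTV-V"} <= set(post) and "CTV-U" not in post
        assert {"CTV-N", "CTV-U", "CTV-C"} <= set(uter) and "CTV-V" not in uter

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValidationError):
            PhantomConfig(geometry=SMALL_GEOMETRY, cohort="nope")


class TestBuildPtvs:
    def test_ptv_margins_applied(self, small_phantom):
        structures, _ = small_phantom
        ptvs = build_ptvs(structures)
        assert set(ptvs) == {"PTV-N", "PTV-U", "PTV-C"}
        for name, ptv in ptvs.items():
            ctv = structures[name.replace("PTV", "CTV", 1)]
            assert (ctv.voxels <= ptv.voxels).all()
            assert ptv.n_voxels > ctv.n_voxels


class TestPerturb:
    def test_zero_spec_is_identity(self, small_phantom):
        structures, _ = small_phantom
        out = perturb(structures, DeformationSpec(per_structure={
            "CTV-U": StructureDeformation()}, seed=0))
        assert np.array_equal(out["CTV-U"].voxels, structures["CTV-U"].voxels)
        assert out["bladder"] is structures["bladder"]  # untouched pass-through

    def test_pure_translation_recovered_by_centroid_deviation(self, small_phantom):
        structures, _ = small_phantom
        spec = DeformationSpec(per_structure={
            "CTV-U": StructureDeformation(translation_mm=(3.0, 4.0, 0.0))}, seed=0)
        out = perturb(structures, spec)
        # (3, 4, 0) mm snaps exactly on the 3 mm grid -> (3, 3, 0)? no: 3/3=1, 4/3->1
        shift, realized = snapped_translation((3.0, 4.0, 0.0), SMALL_GEOMETRY.spacing)
        expected = float(np.linalg.norm(realized))
        assert centroid_deviation(structures["CTV-U"], out["CTV-U"]) == pytest.approx(
            expected, abs=1e-9)

    def test_pure_dilation_recovered_by_surface_metrics(self):
        geom = GridGeometry(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0))
        sphere = sphere_mask(geom, (23.5, 23.5, 23.5), 15.0, name="CTV-U")
        spec = DeformationSpec(per_structure={
            "CTV-U": StructureDeformation(margin_mm=2.0)}, seed=0)
        out = perturb({"CTV-U": sphere}, spec)
        diag = np.sqrt(3.0)
        assert asd(sphere, out["CTV-U"]) == pytest.approx(2.0, abs=diag)
        assert hd95(sphere, out["CTV-U"]) == pytest.approx(2.0, abs=diag)

    def test_jitter_is_seeded_and_deterministic(self, small_phantom):
        structures, _ = small_phantom
        spec = DeformationSpec(per_structure={
            "CTV-U": StructureDeformation(jitter_amp_mm=2.0)}, seed=42)
        a = perturb(structures, spec)
        b = perturb(structures, spec)
        assert np.array_equal(a["CTV-U"].voxels, b["CTV-U"].voxels)
        other = perturb(structures, DeformationSpec(per_structure={
            "CTV-U": StructureDeformation(jitter_amp_mm=2.0)}, seed=43))
        assert not np.array_equal(a["CTV-U"].voxels, other["CTV-U"].voxels)

    def test_erosion_that_empties_structure_raises(self):
        geom = GridGeometry(shape=(16, 16, 16), spacing=(1, 1, 1))
        tiny = sphere_mask(geom, (7.5, 7.5, 7.5), 2.0, name="t")
        with pytest.raises(ValidationError, match="emptied"):
            perturb({"t": tiny}, DeformationSpec(per_structure={
                "t": StructureDeformation(margin_mm=-5.0)}, seed=0))


class TestMakeDose:
    def test_interior_near_prescription_exterior_near_zero(self):
        geom = GridGeometry(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0))
        target = sphere_mask(geom, (23.5, 23.5, 23.5), 15.0)
        dose = make_dose(geom, target, prescription=45.0, falloff_mm=1.0)
        center = dose.dose[24, 24, 24]
        assert center == pytest.approx(45.0, rel=0.06)
        assert dose.dose[0, 0, 0] < 0.5
        assert np.all(dose.dose >= 0)

    def test_v100_on_generating_target_high(self):
        geom = GridGeometry(shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0))
        target = sphere_mask(geom, (23.5, 23.5, 23.5), 15.0)
        dose = make_dose(geom, target, prescription=45.0, falloff_mm=1.0)
        assert v100(dose, target) >= 95.0

    def test_falloff_validation(self):
        geom = GridGeometry(shape=(8, 8, 8), spacing=(1, 1, 1))
        target = sphere_mask(geom, (3.5, 3.5, 3.5), 2.0)
        with pytest.raises(ValidationError):
            make_dose(geom, target, 45.0, falloff_mm=0.0)


class TestMakeCohort:
    def test_same_seed_reproduces_cohort(self, small_phantom_config):
        a = make_cohort(small_phantom_config, 3, seed=5, with_dose=False)
        b = make_cohort(small_phantom_config, 3, seed=5, with_dose=False)
        for fa, fb in zip(a, b):
            assert fa.truth == fb.truth
            for name in fa.manual:
                assert np.array_equal(fa.manual[name].voxels, fb.manual[name].voxels)

    def test_uterus_motion_dominates_nodal_motion(self, small_phantom_config):
        fractions = make_cohort(small_phantom_config, 25, seed=11, with_dose=False)
        cd_u = np.mean([centroid_deviation(f.auto["CTV-U"], f.manual["CTV-U"])
                        for f in fractions])
        cd_n = np.mean([centroid_deviation(f.auto["CTV-N"], f.manual["CTV-N"])
                        for f in fractions])
        assert cd_u > cd_n

    def test_translation_recovery_against_truth(self, small_phantom_config):
        """Cohort-mean CD of the uterus must track the mean injected
        (grid-snapped) translation magnitude within 3 standard errors."""
        params = CohortDeformationParams(
            uterus_translation_sigma_mm=6.0, uterus_margin_sigma_mm=0.0,
            uterus_jitter_amp_mm=0.0)
        fractions = make_cohort(small_phantom_config, 30, seed=3,
                                params=params, with_dose=False)
        spacing = small_phantom_config.geometry.spacing
        measured = np.array([
            centroid_deviation(f.auto["CTV-U"], f.manual["CTV-U"]) for f in fractions])
        injected = np.array([
            np.linalg.norm(snapped_translation(
                f.truth.per_structure["CTV-U"].translation_mm, spacing)[1])
            for f in fractions])
        assert measured == pytest.approx(injected, abs=1e-9)

    def test_adapted_plan_covers_target_better_than_scheduled(self, small_phantom_config):
        fractions = make_cohort(small_phantom_config, 6, seed=7, with_dose=True)
        adapted, scheduled = [], []
        for f in fractions:
            ptvs = build_ptvs(f.manual)
            adapted.append(v100(f.doses["S-Adapted"], ptvs["PTV-U"]))
            scheduled.append(v100(f.doses["S-Scheduled"], ptvs["PTV-U"]))
        assert np.mean(adapted) >= np.mean(scheduled)

    def test_severity_increases_with_deformation_scale(self, small_phantom_config):
        """Edit labels must shift toward 'major' as deformations grow."""
        from adaptrt.editclass import SEVERITY_ORDER, classify_edit, slice_changes

        def mean_severity(scale):
            params = CohortDeformationParams(
                uterus_translation_sigma_mm=2.0 * scale,
                uterus_jitter_amp_mm=1.0 * scale,
                uterus_margin_sigma_mm=0.5 * scale)
            fractions = make_cohort(small_phantom_config, 12, seed=21,
                                    params=params, with_dose=False)
            ranks = []
            for f in fractions:
                changes = slice_changes(f.auto["CTV-U"], f.manual["CTV-U"])
                ranks.append(SEVERITY_ORDER.index(classify_edit(changes).label))
            return np.mean(ranks)

        assert mean_severity(0.2) < mean_severity(3.0)
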