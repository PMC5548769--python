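import numpy as np
import pytest
from scipy import ndimage

from ossimetry import morphometry as mm
from ossimetry import phantom as ph
from ossimetry.errors import ErosionTargetError, PhantomError


class TestMakeOssicle:
    def test_sphere_volume_analytic(self, sphere50):
        analytic = 4.0 / 3.0 * np.pi * 0.05**3
        assert sphere50.truth[1].BV == pytest.approx(analytic, rel=0.02)
        assert sphere50.analytic["BV_mm3"] == pytest.approx(analytic, rel=1e-12)

    def test_sphere_specific_surface_analytic(self, sphere50):
        assert sphere50.truth[1].BS_BV == pytest.approx(60.0, rel=0.10)
        assert sphere50.analytic["BS_BV_mm-1"] == pytest.approx(60.0)

    @pytest.mark.parametrize("kind,size", [
        ("sphere", {"radius_um": 30.0}),
        ("pyramid", {"base_um": 60.0, "height_um": 50.0}),
        ("lunula", {"radius_um": 40.0}),
    ])
    def test_deterministic(self, kind, size):
        a = ph.make_ossicle(kind, size, 2.0, seed=7)
        b = ph.make_ossicle(kind, size, 2.0, seed=7)
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("kind,size", [
        ("sphere", {"radius_um": 30.0}),
        ("pyramid", {"base_um": 60.0, "height_um": 50.0}),
        ("lunula", {"radius_um": 40.0}),
    ])
    def test_single_6connected_component(self, kind, size):
        p = ph.make_ossicle(kind, size, 2.0)
        _, n = ndimage.label(p.volume, structure=ph.STRUCT_6)
        assert n == 1

    def test_bv_is_exact_voxel_count(self, sphere50):
        expected = sphere50.volume.sum() * 2.0**3 * 1e-9
        assert sphere50.truth[1].BV == expected

    def test_tv_at_least_bv(self, hollow_sphere80):
        t = hollow_sphere80.truth[1]
        assert t.TV >= t.BV
        assert t.BV_TV < 1.0  # cavity present

    def test_truth_ratio_consistency(self, hollow_sphere80):
        t = hollow_sphere80.truth[1]
        assert t.BV_TV * t.BS_BV == pytest.approx(t.BS_TV, rel=1e-12)

    def test_margin_violation_raises(self):
        with pytest.raises(PhantomError, match="boundary|margin"):
            ph.make_ossicle("sphere", {"radius_um": 100.0}, 2.0,
                            grid_shape=(40, 40, 40))

    def test_small_margin_rejected(self):
        with pytest.raises(PhantomError):
            ph.make_ossicle("sphere", {"radius_um": 20.0}, 2.0, margin_vox=1)

    def test_unknown_shape(self):
        with pytest.raises(PhantomError):
            ph.make_ossicle("torus", {"radius_um": 20.0}, 2.0)

    def test_oversized_cavity_rejected(self):
        with pytest.raises(PhantomError, match="cavity"):
            ph.make_ossicle("sphere", {"radius_um": 30.0}, 2.0,
                            cavity_fraction=0.9)


class TestErosion:
    def test_zero_target_is_identity(self, hollow_sphere80):
        spec = ph.ErosionSpec(target_bvtv_drop=0.0, seed=3)
        out = ph.erode_phantom(hollow_sphere80, spec)
        assert np.array_equal(out.volume, hollow_sphere80.volume)

    def test_programmed_drop_reached(self, eroded_pair):
        orig, eroded = eroded_pair
        ratio = eroded.truth[1].BV_TV / orig.truth[1].BV_TV
        assert ratio == pytest.approx(0.89, abs=0.01)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_specific_surface_rises_and_bv_falls(self, hollow_sphere80, seed):
        spec = ph.ErosionSpec(target_bvtv_drop=0.11, removal_prob=0.2,
                              max_iters=200, seed=seed)
        out = ph.erode_phantom(hollow_sphere80, spec)
        assert out.truth[1].BS_BV > hollow_sphere80.truth[1].BS_BV
        assert out.truth[1].BS_TV > hollow_sphere80.truth[1].BS_TV
        assert out.truth[1].BV < hollow_sphere80.truth[1].BV

    def test_cavity_volume_preserved(self, eroded_pair):
        # pure surface erosion: the sealed cavity (TV - BV) is untouched
        orig, eroded = eroded_pair
        vs3 = orig.voxel_size_um**3 * 1e-9
        cav0 = round((orig.truth[1].TV - orig.truth[1].BV) / vs3)
        cav1 = round((eroded.truth[1].TV - eroded.truth[1].BV) / vs3)
        assert cav0 == cav1 > 0

    def test_connectivity_preserved(self, eroded_pair):
        _, eroded = eroded_pair
        _, n = ndimage.label(eroded.volume, structure=ph.STRUCT_6)
        assert n == 1

    def test_only_surface_voxels_removed(self, hollow_sphere80):
        # a tiny target is met within the first sweep, so every removed voxel
        # must come from the initial exposed-surface set
        spec = ph.ErosionSpec(target_bvtv_drop=0.01, removal_prob=0.9, seed=9)
        out = ph.erode_phantom(hollow_sphere80, spec)
        removed = hollow_sphere80.volume & ~out.volume
        surface = ph.surface_voxels(hollow_sphere80.volume)
        assert removed.sum() > 0
        assert not (removed & ~surface).any()

    def test_unreachable_target_raises(self):
        solid = ph.make_ossicle("sphere", {"radius_um": 30.0}, 2.0)
        spec = ph.ErosionSpec(target_bvtv_drop=0.11, removal_prob=0.5,
                              max_iters=3, seed=0)
        with pytest.raises(ErosionTargetError, match="achieved"):
            ph.erode_phantom(solid, spec)

    def test_invalid_spec(self):
        with pytest.raises(PhantomError):
            ph.ErosionSpec(target_bvtv_drop=1.5)
        with pytest.raises(PhantomError):
            ph.ErosionSpec(removal_prob=0.0)


class TestCohort:
    def test_balanced_groups(self):
        spec = ph.ErosionSpec(target_bvtv_drop=0.08, removal_prob=0.3,
                              max_iters=100, seed=0)
        cohort = ph.make_cohort(3, spec, 0.04, seed=5,
                                shape_kind="sphere",
                                size_params={"radius_um": 50.0},
                                cavity_fraction=0.2)
        assert len(cohort) == 6
        groups = [g for _, g in cohort]
        assert groups.count("control") == 3
        assert groups.count("arthritis") == 3

    def test_no_effect_no_jitter_identical_groups(self):
        spec = ph.ErosionSpec(target_bvtv_drop=0.0, seed=0)
        cohort = ph.make_cohort(2, spec, 0.0, seed=5, shape_kind="sphere",
                                size_params={"radius_um": 40.0},
                                cavity_fraction=0.0)
        ctrl = [p for p, g in cohort if g == "control"]
        arth = [p for p, g in cohort if g == "arthritis"]
        for c, a in zip(ctrl, arth):
            assert np.array_equal(c.volume, a.volume)

    def test_seed_reproducibility(self):
        spec = ph.ErosionSpec(target_bvtv_drop=0.08, removal_prob=0.3,
                              max_iters=100, seed=2)
        kw = dict(n_per_group=2, effect=spec, between_animal_cv=0.05, seed=11,
                  shape_kind="sphere", size_params={"radius_um": 50.0},
                  cavity_fraction=0.2)
        a = ph.make_cohort(**kw)
        b = ph.make_cohort(**kw)
        for (pa, ga), (pb, gb) in zip(a, b):
            assert ga == gb
            assert np.array_equal(pa.volume, pb.volume)

    def test_erosion_monotonicity_across_cohort(self):
        spec = ph.ErosionSpec(target_bvtv_drop=0.08, removal_prob=0.3,
                              max_iters=100, seed=4)
        cohort = ph.make_cohort(2, spec, 0.03, seed=21, shape_kind="sphere",
                                size_params={"radius_um": 50.0},
                                cavity_fraction=0.2)
        by_animal = {}
        for p, g in cohort:
            by_animal.setdefault(p.meta["animal"], {})[g] = p.truth[1]
        for pair in by_animal.values():
            assert pair["arthritis"].BV <= pair["control"].BV
            assert pair["arthritis"].BS_TV >= pair["control"].BS_TV

    def test_n_below_two_rejected(self):
        with pytest.raises(PhantomError):
            ph.make_cohort(1, ph.ErosionSpec(seed=0), 0.0, seed=0)
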