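import numpy as np
import pytest

from conftest import cube_mask
from oracles import hausdorff_allpairs, msd_allpairs, surface_voxels_loop

from etecim import (
    MaskVolume,
    PerturbationSpec,
    center_of_mass_shift,
    compare_masks,
    confusion_counts,
    conformity_index,
    degree_of_inclusion,
    dice,
    hausdorff,
    mean_surface_distance,
    motion_vector,
    perturb_mask,
    surface_points,
)
from etecim.errors import EmptyForegroundError, GeometryMismatchError, UndefinedMetricError
from etecim.phantoms import PhantomSpec, make_ellipsoid_mask


class TestConfusion:
    def test_identical_masks(self):
        m = cube_mask()
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn) == (64, 0, 0)

    def test_shifted_cube_counts(self):
        a = cube_mask(offset=(4, 4, 4))
        b = cube_mask(offset=(4, 4, 5))
        c = confusion_counts(b, a)
        assert (c.tp, c.fp, c.fn) == (48, 16, 16)

    def test_disjoint_masks(self):
        a = cube_mask(side=3, offset=(0, 0, 0))
        b = cube_mask(side=2, offset=(8, 8, 8))
        c = confusion_counts(a, b)
        assert (c.tp, c.fp, c.fn) == (0, 27, 8)

    def test_shape_mismatch_names_both_shapes(self):
        a = cube_mask(shape=(10, 10, 10), offset=(2, 2, 2))
        b = cube_mask(shape=(12, 12, 12))
        with pytest.raises(GeometryMismatchError, match=r"10.*12"):
            confusion_counts(a, b)


class TestDice:
    def test_direct_formula(self):
        from etecim.metrics import ConfusionCounts

        assert dice(ConfusionCounts(tp=50, fp=10, fn=10)) == pytest.approx(50 / 60)

    def test_both_empty_is_undefined_not_zero(self):
        from etecim.metrics import ConfusionCounts

        with pytest.raises(UndefinedMetricError):
            dice(ConfusionCounts(tp=0, fp=0, fn=0))


class TestSurface:
    def test_cube_3x3x3_has_26_surface_voxels(self):
        m = cube_mask(side=3, shape=(7, 7, 7), offset=(2, 2, 2))
        assert len(surface_points(m)) == 26

    def test_single_voxel_is_its_own_surface(self):
        m = cube_mask(side=1, shape=(3, 3, 3), offset=(1, 1, 1))
        assert len(surface_points(m)) == 1

    def test_thin_plate_is_all_surface(self):
        vox = np.zeros((5, 5, 5), dtype=np.uint8)
        vox[2] = 1
        m = MaskVolume(voxels=vox, spacing=(1, 1, 1))
        assert len(surface_points(m)) == 25

    def test_lattice_border_counts_as_background(self):
        m = MaskVolume(voxels=np.ones((3, 3, 3), dtype=np.uint8), spacing=(1, 1, 1))
        assert len(surface_points(m)) == 26  # all but the center voxel

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_exhaustive_neighbor_check(self, seed):
        rng = np.random.default_rng(seed)
        vox = (rng.random((8, 9, 10)) > 0.5).astype(np.uint8)
        m = MaskVolume(voxels=vox, spacing=(1.0, 1.0, 1.0))
        got = {tuple(int(v) for v in p[::-1]) for p in surface_points(m).points}  # (z,y,x)
        assert got == surface_voxels_loop(vox)


class TestSurfaceDistances:
    def test_identical_surfaces_are_zero(self):
        s = surface_points(cube_mask())
        assert hausdorff(s, s) == 0.0
        assert mean_surface_distance(s, s) == 0.0

    def test_two_points_3mm_apart(self):
        a = cube_mask(side=1, shape=(1, 1, 5), offset=(0, 0, 0))
        b = cube_mask(side=1, shape=(1, 1, 5), offset=(0, 0, 3))
        sa, sb = surface_points(a), surface_points(b)
        assert hausdorff(sa, sb) == 3.0
        assert mean_surface_distance(sa, sb) == 3.0

    def test_offset_cubes_match_allpairs_oracle(self):
        a = cube_mask(offset=(4, 4, 2))
        b = cube_mask(offset=(4, 4, 4))
        sa, sb = surface_points(a), surface_points(b)
        assert hausdorff(sa, sb) == pytest.approx(
            hausdorff_allpairs(sa.points, sb.points), abs=1e-10)
        assert hausdorff(sa, sb) == 2.0
        assert mean_surface_distance(sa, sb) == pytest.approx(
            msd_allpairs(sa.points, sb.points), abs=1e-10)

    def test_hd_bounds_msd(self):
        rng = np.random.default_rng(8)
        a = MaskVolume((rng.random((6, 8, 8)) > 0.6).astype(np.uint8), (1, 1, 2))
        b = MaskVolume((rng.random((6, 8, 8)) > 0.6).astype(np.uint8), (1, 1, 2))
        sa, sb = surface_points(a), surface_points(b)
        assert hausdorff(sa, sb) >= mean_surface_distance(sa, sb) >= 0.0


class TestSetOverlap:
    def test_ci_and_dice_identity(self):
        a = cube_mask(offset=(4, 4, 4))
        b = cube_mask(offset=(4, 4, 6))
        ci = conformity_index(a, b)
        d = dice(confusion_counts(a, b))
        assert d == pytest.approx(2 * ci / (1 + ci), abs=1e-12)

    def test_subset_inclusion(self):
        inner = cube_mask(side=2, offset=(5, 5, 5))
        outer = cube_mask(side=4, offset=(4, 4, 4))
        di_p, di_g = degree_of_inclusion(inner, outer)
        assert di_p == 1.0
        assert di_g == pytest.approx(8 / 64)

    def test_di_ci_reciprocal_identity(self):
        a = cube_mask(offset=(4, 4, 4))
        b = cube_mask(offset=(5, 5, 4))
        ci = conformity_index(a, b)
        di1, di2 = degree_of_inclusion(a, b)
        assert 1 / ci == pytest.approx(1 / di1 + 1 / di2 - 1, abs=1e-12)

    def test_empty_inputs_flagged(self):
        empty = MaskVolume(np.zeros((12, 12, 12), dtype=np.uint8), (1, 1, 1))
        full = cube_mask()
        with pytest.raises(UndefinedMetricError):
            conformity_index(empty, empty)
        with pytest.raises(UndefinedMetricError, match="predicted"):
            degree_of_inclusion(empty, full)


class TestCenterOfMass:
    def test_identical_masks_zero_shift(self):
        m = cube_mask()
        assert center_of_mass_shift(m, m) == (0.0, 0.0, 0.0)

    def test_translation_recovered_with_spacing(self):
        a = cube_mask(offset=(4, 4, 4), spacing=(1, 1, 5))
        b = cube_mask(offset=(5, 4, 4), spacing=(1, 1, 5))  # +1 slice in z
        assert center_of_mass_shift(b, a) == pytest.approx((0.0, 0.0, 5.0))

    def test_motion_vector_236_quadruple(self):
        assert motion_vector(2, 3, 6) == 7.0
        assert motion_vector(-2, 3, -6) == 7.0
        assert motion_vector(0, 0, 0) == 0.0


class TestCompareMasks:
    def test_perfect_agreement(self):
        m = cube_mask()
        rep = compare_masks(m, m)
        assert rep.dsc == 1.0 and rep.ci == 1.0
        assert rep.hd == 0.0 and rep.msd == 0.0
        assert rep.di_pred_in_gt == rep.di_gt_in_pred == 1.0
        assert rep.mv == 0.0

    def test_translated_pair_motion_vector(self):
        gt = cube_mask(shape=(16, 16, 16), offset=(2, 2, 2))
        pred = perturb_mask(gt, PerturbationSpec(translation=(2, 3, 6)))
        rep = compare_masks(pred, gt)
        assert rep.mv == pytest.approx(7.0, abs=1e-12)
        assert (rep.lr, rep.ap, rep.cc) == pytest.approx((2.0, 3.0, 6.0))

    def test_empty_pred_flags_undefined_fields(self):
        gt = cube_mask()
        empty = MaskVolume(np.zeros_like(gt.voxels), gt.spacing)
        rep = compare_masks(empty, gt)
        assert rep.dsc == 0.0 and rep.ci == 0.0
        assert rep.hd is None and rep.msd is None and rep.mv is None

    def test_empty_gt_raises(self):
        gt = MaskVolume(np.zeros((5, 5, 5), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(EmptyForegroundError):
            compare_masks(cube_mask(shape=(5, 5, 5), side=2, offset=(1, 1, 1)), gt)

    def test_symmetry_and_antisymmetry_under_swap(self):
        spec = PhantomSpec(shape="ellipsoid", lattice=(12, 32, 32), spacing=(1, 1, 2),
                           semi_axes=(10.0, 8.0, 9.0))
        gt = make_ellipsoid_mask(spec).mask
        pred = perturb_mask(gt, PerturbationSpec(translation=(1, 2, 1),
                                                 boundary_flip_rate=0.1, seed=11))
        fwd, rev = compare_masks(pred, gt), compare_masks(gt, pred)
        assert fwd.hd == rev.hd and fwd.msd == rev.msd and fwd.ci == rev.ci
        assert fwd.di_pred_in_gt == rev.di_gt_in_pred
        assert (fwd.lr, fwd.ap, fwd.cc) == pytest.approx((-rev.lr, -rev.ap, -rev.cc))

    def test_perturbed_pair_equals_bruteforce_suite(self):
        spec = PhantomSpec(shape="ellipsoid", lattice=(10, 24, 24), spacing=(1, 1, 2),
                           semi_axes=(8.0, 7.0, 8.0))
        gt = make_ellipsoid_mask(spec).mask
        pred = perturb_mask(gt, PerturbationSpec(translation=(1, 0, 1),
                                                 boundary_flip_rate=0.2, seed=11))
        rep = compare_masks(pred, gt)
        p = pred.voxels.astype(bool)
        g = gt.voxels.astype(bool)
        tp = int((p & g).sum())
        assert rep.dsc == pytest.approx(2 * tp / (p.sum() + g.sum()), abs=1e-12)
        assert rep.ci == pytest.approx(tp / int((p | g).sum()), abs=1e-12)
        sp, sg = surface_points(pred), surface_points(gt)
        assert rep.hd == pytest.approx(hausdorff_allpairs(sp.points, sg.points), abs=1e-10)
        assert rep.msd == pytest.approx(msd_allpairs(sp.points, sg.points), abs=1e-10)
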