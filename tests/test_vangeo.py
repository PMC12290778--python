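import math

import numpy as np
import pytest

from vasobold.vangeo import (
    LABEL_ARTERY,
    LABEL_VEIN,
    VesselVolume,
    cross_section_footprint,
    fbv_map,
    local_orientation,
    merge_centerline_sources,
    perivascular_shells,
    voxelize_vessels,
)

from conftest import straight_vessel_volume


class TestMerge:
    def _single(self, diam=1.0, label=LABEL_ARTERY, where=(1, 1, 1)):
        c = np.zeros((4, 4, 4), bool)
        d = np.zeros((4, 4, 4))
        lab = np.zeros((4, 4, 4), np.uint8)
        c[where] = True
        d[where] = diam
        lab[where] = label
        return VesselVolume(c, d, lab, 0.8)

    def test_single_source_identity(self):
        v = self._single()
        out = merge_centerline_sources([v])
        assert np.array_equal(out.centreline, v.centreline)
        assert np.array_equal(out.diameter, v.diameter)
        assert np.array_equal(out.label, v.label)

    def test_highest_diameter_wins_on_overlap(self):
        a = self._single(diam=1.2)
        b = self._single(diam=2.0)
        out = merge_centerline_sources([a, b])
        assert out.diameter[1, 1, 1] == 2.0

    def test_disjoint_union_preserves_diameters(self):
        a = self._single(diam=1.2, where=(0, 0, 0))
        b = self._single(diam=2.0, where=(3, 3, 3))
        out = merge_centerline_sources([a, b])
        assert out.centreline.sum() == 2
        assert out.diameter[0, 0, 0] == 1.2
        assert out.diameter[3, 3, 3] == 2.0

    def test_commutative_and_idempotent(self):
        a = self._single(diam=1.2, label=LABEL_ARTERY)
        b = self._single(diam=2.0, label=LABEL_VEIN, where=(2, 2, 2))
        ab = merge_centerline_sources([a, b])
        ba = merge_centerline_sources([b, a])
        aa = merge_centerline_sources([a, a])
        assert np.array_equal(ab.diameter, ba.diameter)
        assert np.array_equal(ab.label, ba.label)
        assert np.array_equal(aa.diameter, a.diameter)

    def test_label_conflict_resolves_to_vein_with_warning(self):
        a = self._single(label=LABEL_ARTERY)
        b = self._single(label=LABEL_VEIN)
        with pytest.warns(UserWarning, match="conflicting"):
            out = merge_centerline_sources([a, b])
        assert out.label[1, 1, 1] == LABEL_VEIN

    def test_mismatched_grids_rejected(self):
        a = self._single()
        c = np.zeros((5, 5, 5), bool)
        c[1, 1, 1] = True
        d = np.where(c, 1.0, 0.0)
        b = VesselVolume(c, d, np.where(c, 1, 0).astype(np.uint8), 0.8)
        with pytest.raises(ValueError, match="common grid"):
            merge_centerline_sources([a, b])


class TestLocalOrientation:
    @pytest.mark.parametrize(
        "axis,zenith,azimuth",
        [(2, 0.0, None), (0, math.pi / 2, 0.0), (1, math.pi / 2, math.pi / 2)],
    )
    def test_straight_axis_aligned(self, axis, zenith, azimuth):
        v = straight_vessel_volume(n=9, axis=axis)
        om = local_orientation(v)
        zs = om.zenith[v.centreline]
        assert np.allclose(zs, zenith, atol=1e-12)
        if azimuth is not None:
            assert np.allclose(om.azimuth[v.centreline], azimuth, atol=1e-12)

    def test_diagonal_gives_45_degrees(self):
        n = 9
        c = np.zeros((n, n, n), bool)
        for i in range(n):
            c[i, 4, i] = True  # x = z diagonal
        v = VesselVolume(c, np.where(c, 1.0, 0), np.where(c, 2, 0).astype(np.uint8), 0.8)
        om = local_orientation(v)
        assert np.allclose(om.zenith[c], math.pi / 4, atol=1e-12)

    def test_reversal_invariance_by_construction(self):
        # zenith folded into [0, pi/2]: flipping the volume along z leaves it
        v = straight_vessel_volume(n=9, axis=2)
        om1 = local_orientation(v)
        flipped = VesselVolume(
            v.centreline[:, :, ::-1].copy(),
            v.diameter[:, :, ::-1].copy(),
            v.label[:, :, ::-1].copy(),
            v.voxel_size,
        )
        om2 = local_orientation(flipped)
        assert np.allclose(
            om1.zenith[v.centreline], om2.zenith[flipped.centreline]
        )

    def test_isolated_voxel_is_undefined(self):
        c = np.zeros((7, 7, 7), bool)
        c[3, 3, 3] = True
        v = VesselVolume(c, np.where(c, 1.0, 0), np.where(c, 1, 0).astype(np.uint8), 0.8)
        om = local_orientation(v)
        assert not om.defined().any()

    def test_direction_cosines_rotate_zenith(self):
        # a grid-z vessel in a volume whose grid z maps to scanner x
        rot = np.array([[0.0, 0, 1], [0, 1, 0], [-1, 0, 0]])
        v = straight_vessel_volume(n=9, axis=2)
        v = VesselVolume(v.centreline, v.diameter, v.label, v.voxel_size, rot)
        om = local_orientation(v)
        assert np.allclose(om.zenith[v.centreline], math.pi / 2, atol=1e-12)


class TestVoxelize:
    def test_13_voxel_cross_section(self):
        # 0.8 mm vessel on a 0.2 mm grid, axis through a cell centre
        assert cross_section_footprint(0.8, 0.2) == 13

    def test_voxelized_tube_matches_footprint(self):
        # voxel_size 1.0 -> the centreline passes through 0.2 mm cell centres
        v = straight_vessel_volume(n=5, voxel_size=1.0, axis=2, diameter=0.8)
        mask = voxelize_vessels(v, 0.2)
        per_slice = mask.sum(axis=(0, 1))
        inner = per_slice[5:-5]  # away from volume ends
        assert np.all(inner == 13)

    def test_radius_scale_zero_keeps_centreline_only(self):
        v = straight_vessel_volume(n=5, voxel_size=1.0, axis=2, diameter=0.8)
        mask = voxelize_vessels(v, 0.2, radius_scale=0)
        assert mask.sum() <= v.centreline.sum() * 13  # thin trace
        per_slice = mask.sum(axis=(0, 1))
        assert per_slice.max() == 1

    def test_fbv_convergence_with_resolution(self):
        # quantized occupancy approaches pi (d/2)^2 / L^2 as the grid refines
        analytic = math.pi * 0.4**2 / 16.0
        errs = []
        for res in (0.2, 0.04):
            v = straight_vessel_volume(n=4, voxel_size=1.0, axis=2, diameter=0.8)
            mask = voxelize_vessels(v, res)
            fm = fbv_map(mask, res, 4.0)
            # the single fMRI voxel is fully crossed by the vessel
            errs.append(abs(fm.fbv.max() - analytic) / analytic)
        assert errs[1] < errs[0]
        assert errs[1] < 0.03

    def test_empty_centreline_empty_mask(self):
        z = np.zeros((4, 4, 4))
        v = VesselVolume(z.astype(bool), z, z.astype(np.uint8), 0.8)
        assert not voxelize_vessels(v, 0.2).any()

    def test_coarse_grid_warns(self):
        v = straight_vessel_volume(n=5, voxel_size=1.0, axis=2, diameter=0.8)
        with pytest.warns(UserWarning, match="under-resolved"):
            voxelize_vessels(v, 0.5)


class TestFbvMap:
    def test_counting(self):
        mask = np.zeros((20, 20, 20), bool)
        fm_empty = fbv_map(mask, 0.2, 4.0)
        assert fm_empty.fbv.max() == 0.0
        mask[:, :, :] = True
        assert fbv_map(mask, 0.2, 4.0).fbv.min() == 1.0
        mask[:] = False
        mask.reshape(-1)[:400] = True
        assert fbv_map(mask, 0.2, 4.0).fbv.ravel()[0] == pytest.approx(0.05)

    def test_non_integer_ratio_rejected(self):
        mask = np.zeros((10, 10, 10), bool)
        with pytest.raises(ValueError, match="integer multiple"):
            fbv_map(mask, 0.3, 4.0)

    def test_dominant_orientation_from_largest_diameter(self):
        # a thick z vessel and a thin x vessel through the same fMRI voxel
        n = 5
        c = np.zeros((n, n, n), bool)
        d = np.zeros((n, n, n))
        lab = np.zeros((n, n, n), np.uint8)
        c[2, 2, :] = True
        d[2, 2, :] = 2.0
        lab[2, 2, :] = 2
        c[:, 2, 1] = True
        d[:, 2, 1] = np.where(d[:, 2, 1] > 0, d[:, 2, 1], 0.9)
        d[2, 2, 1] = 2.0  # overlap keeps the thick diameter
        lab[:, 2, 1] = np.where(lab[:, 2, 1] > 0, lab[:, 2, 1], 1)
        v = VesselVolume(c, d, lab, 0.8)
        om = local_orientation(v)
        mask = voxelize_vessels(v, 0.2, orient=om)
        fm = fbv_map(mask, 0.2, 4.0, v=v, orient=om)
        assert fm.zenith[0, 0, 0] == pytest.approx(0.0, abs=1e-9)


class TestPerivascularShells:
    def test_single_voxel_26_connected_counts(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        shells = perivascular_shells(mask, n_shells=2)
        assert shells[0].sum() == 26  # 3^3 - 1
        assert shells[1].sum() == 5**3 - 3**3

    def test_six_connected_first_shell(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[3, 3, 3] = True
        shells = perivascular_shells(mask, n_shells=1, connectivity=6)
        assert shells[0].sum() == 6

    def test_disjoint_and_telescoping(self, rng):
        mask = rng.random((12, 12, 12)) > 0.9
        shells = perivascular_shells(mask, n_shells=3)
        union = mask.copy()
        for i, s in enumerate(shells):
            assert not (s & mask).any()
            for t in shells[i + 1 :]:
                assert not (s & t).any()
            union |= s
        from scipy import ndimage

        dil3 = ndimage.binary_dilation(
            mask, structure=np.ones((3, 3, 3), bool), iterations=3
        )
        assert np.array_equal(union, dil3)
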