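import math

import numpy as np
import pytest

from vasobold import (
    CylinderGeometry,
    build_3d_voxel,
    cylinder_field_offset,
    dipole_kernel,
    field_offset_volume,
)


def surface_offset(params, y):
    """Magnitude of the extravascular offset at the vessel surface, theta=pi/2."""
    return 0.5 * params.delta_chi * params.hct * abs(params.y_tissue - y)


class TestDipoleKernel:
    def test_special_points(self):
        k = dipole_kernel((8, 8, 8), 1.0)
        assert k[0, 0, 0] == 0.0
        assert k[0, 0, 1] == pytest.approx(-2.0 / 3.0)  # on the kz axis
        assert k[1, 0, 0] == pytest.approx(1.0 / 3.0)  # in the kz=0 plane
        assert k[0, 2, 0] == pytest.approx(1.0 / 3.0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            dipole_kernel((1, 8, 8), 1.0)


class TestFieldOffsetVolume:
    def test_uniform_susceptibility_gives_zero_field(self):
        # only the k=0 component is present, which the kernel zeroes out
        # (pad=0 keeps the grid periodic, hence truly uniform)
        chi = np.full((12, 12, 12), 3e-7)
        fv = field_offset_volume(chi, 1.0, pad=0)
        assert np.max(np.abs(fv.data)) < 1e-18

    def test_linearity(self, rng):
        chi1 = rng.normal(size=(10, 10, 10)) * 1e-7
        chi2 = rng.normal(size=(10, 10, 10)) * 1e-7
        f1 = field_offset_volume(chi1, 0.5).data
        f2 = field_offset_volume(chi2, 0.5).data
        f12 = field_offset_volume(chi1 + chi2, 0.5).data
        assert np.allclose(f12, f1 + f2, atol=1e-20)

    def test_sphere_matches_analytic_dipole(self):
        # voxelized sphere, >=8 voxels per diameter; on the B0 axis at
        # r = 2a the analytic exterior offset is (dchi/3)(a/r)^3*(3cos^2-1)
        # = dchi/12; the interior offset is 0
        n, a_vox = 48, 8.0
        chi0 = 1e-6
        x = np.arange(n) - n / 2 + 0.5
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        chi = np.where(r <= a_vox, chi0, 0.0)
        fld = field_offset_volume(chi, 1.0).data
        i0 = n // 2  # x=y=+0.5 column; on-axis within half a voxel
        z_query = 40  # dz = 16.5 voxels ~ 2a along B0
        p = np.array([x[i0], x[i0], x[z_query]])
        rq = np.linalg.norm(p)
        cos_t = p[2] / rq
        # exterior point dipole: (dchi/3) (a/r)^3 (3cos^2 - 1); at theta=0,
        # r=2a this is dchi/12
        expected = chi0 / 3.0 * (a_vox / rq) ** 3 * (3 * cos_t**2 - 1)
        got = fld[i0, i0, z_query]
        assert got == pytest.approx(expected, rel=0.05)
        assert chi0 / 3.0 * (1 / 2.0) ** 3 * 2 == pytest.approx(chi0 / 12.0)
        centre = fld[i0, i0, i0]
        assert abs(centre) < 0.05 * chi0 / 3.0

    def test_nonfinite_input_rejected(self):
        chi = np.zeros((4, 4, 4))
        chi[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            field_offset_volume(chi, 1.0)

    def test_axis_aligned_cylinder_has_no_exterior_field(self, params):
        # theta = 0: sin^2(theta) = 0 so the exterior offset vanishes
        vox = build_3d_voxel(0.4, 0.0, 0.0, params.y_v, params, n=60)
        ref = surface_offset(params, params.y_v)
        sub = vox.subvoxel
        n = vox.n
        x = (np.arange(n) + 0.5) * sub - n * sub / 2
        R = np.sqrt(x[:, None] ** 2 + x[None, :] ** 2)
        mid = vox.field[:, :, n // 2]
        exterior = R > 2 * 0.4
        assert np.max(np.abs(mid[exterior])) < 0.02 * ref


class TestCylinderOracleEquivalence:
    @pytest.mark.parametrize("theta", [0.0, math.pi / 4, math.pi / 2])
    def test_numeric_field_matches_analytic(self, params, theta):
        """Fourier dipole field vs closed-form infinite cylinder.

        The cylinder spans >=4 voxels per diameter; agreement is required
        within 5% of the surface offset at exterior points r > 2a.
        """
        a = 0.4
        y = params.y_v
        vox = build_3d_voxel(a, theta, 0.0, y, params, n=60)
        n, sub = vox.n, vox.subvoxel
        x = (np.arange(n) + 0.5) * sub - n * sub / 2
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        d = np.array([math.sin(theta), 0.0, math.cos(theta)])
        proj = pts @ d
        perp = pts - proj[..., None] * d
        r = np.linalg.norm(perp, axis=-1)
        b0 = np.array([0.0, 0.0, 1.0])
        bperp = b0 - (b0 @ d) * d
        nb = np.linalg.norm(bperp)
        geom = CylinderGeometry(radius_a=a, zenith_theta=theta)
        if nb < 1e-12:
            phi = np.zeros_like(r)  # theta=0: exterior field is 0 anyway
        else:
            bperp = bperp / nb
            with np.errstate(invalid="ignore", divide="ignore"):
                cphi = np.clip(perp @ bperp / np.where(r > 0, r, 1.0), -1, 1)
            phi = np.arccos(cphi)
        ana = cylinder_field_offset(r, phi, geom, y, params)
        ref = surface_offset(params, y)
        sel = r > 2 * a
        err = np.abs(vox.field[sel] - np.asarray(ana)[sel]) / ref
        assert err.max() < 0.05

    def test_azimuth_rotation_consistency(self, params):
        # rotating the cylinder azimuth by 90 deg permutes the grid axes
        v0 = build_3d_voxel(0.4, math.pi / 4, 0.0, params.y_v, params, n=40)
        v90 = build_3d_voxel(
            0.4, math.pi / 4, math.pi / 2, params.y_v, params, n=40
        )
        assert np.allclose(
            v90.field, np.transpose(v0.field, (1, 0, 2)), atol=1e-12
        )


class TestAnalyticCylinder:
    def test_parallel_cylinder_exterior_zero(self, params):
        geom = CylinderGeometry(radius_a=1.0, zenith_theta=0.0)
        out = cylinder_field_offset(
            np.array([1.5, 3.0, 10.0]), np.array([0.0, 1.0, 2.0]),
            geom, params.y_v, params,
        )
        assert np.all(out == 0.0)

    def test_magic_angle_interior_zero(self, params):
        theta_magic = math.acos(1.0 / math.sqrt(3.0))
        geom = CylinderGeometry(radius_a=1.0, zenith_theta=theta_magic)
        assert cylinder_field_offset(0.3, 0.7, geom, params.y_v, params) == (
            pytest.approx(0.0, abs=1e-22)
        )

    def test_venous_surface_offset_value(self, params):
        # 2*pi * (dchi/4pi) * Hct * (Yt - Yv) at theta=pi/2, r=a, phi=0
        geom = CylinderGeometry(radius_a=0.5, zenith_theta=math.pi / 2)
        got = cylinder_field_offset(0.5, 0.0, geom, 0.6, params)
        assert got == pytest.approx(2 * math.pi * 0.27e-6 * 0.4 * 0.25, rel=1e-9)
        # ~21.7 Hz at 3 T
        hz = got * params.gamma * params.b0 / (2 * math.pi)
        assert hz == pytest.approx(21.7, abs=0.1)

    def test_continuity_at_surface_parallel_case(self, params):
        # at theta=0 the interior value 2/3*scale, exterior 0: documented
        # discontinuity of the idealized model at the wall
        geom = CylinderGeometry(radius_a=1.0, zenith_theta=0.0)
        inner = cylinder_field_offset(0.999, 0.0, geom, 0.6, params)
        scale = 0.5 * params.delta_chi * params.hct * 0.25
        assert inner == pytest.approx(2.0 / 3.0 * scale, rel=1e-9)
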