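"""System model: CDRF, forward/back projection, adjointness, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spectrecon as sr
from spectrecon.grid import MuMap
from spectrecon.projector import Sinogram, cdrf_fwhm


class TestCdrf:
    def test_constant_when_slope_and_intrinsic_zero(self):
        m = sr.CDRFModel(slope=0.0, intercept_mm=5.0, intrinsic_mm=0.0)
        d = np.array([0.0, 50.0, 400.0])
        assert np.allclose(cdrf_fwhm(d, m), 5.0)

    @given(
        a=st.floats(0, 0.3), b=st.floats(0, 10), ri=st.floats(0, 8),
        d1=st.floats(0, 400), d2=st.floats(0, 400),
    )
    def test_monotone_in_distance(self, a, b, ri, d1, d2):
        m = sr.CDRFModel(slope=a, intercept_mm=b, intrinsic_mm=ri)
        lo, hi = sorted((d1, d2))
        assert cdrf_fwhm(hi, m) >= cdrf_fwhm(lo, m)

    def test_sigma_closed_form(self):
        m = sr.CDRFModel(slope=0.0, intercept_mm=10.0, intrinsic_mm=0.0)
        assert m.sigma_mm(0.0) == pytest.approx(4.2466, abs=1e-4)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            cdrf_fwhm(-1.0, sr.CDRFModel())


def _system(grid, geo, mu=None, psf=False, attenuation=False):
    return sr.SystemModel(grid, geo, sr.CDRFModel() if psf else None, mu,
                          psf=psf, attenuation=attenuation)


class TestForward:
    def test_zero_image_zero_sinogram(self, small_system, small_grid):
        img = sr.ActivityImage(small_grid, np.zeros(small_grid.dims))
        assert not sr.forward_project(img, small_system).values.any()

    def test_projection_conservation_without_psf_attenuation(self, small_grid, small_geometry, small_dro):
        system = _system(small_grid, small_geometry)
        sino = system.forward(small_dro.values)
        sums = sino.sum(axis=-1)
        expected = small_dro.values.sum() * small_grid.voxel_size_mm / 10.0
        assert np.allclose(sums, expected, rtol=1e-3)

    def test_uniform_disk_chord_profile(self):
        """PSF/attenuation off: bin profile equals direct column sums
        (independent oracle) and tracks the analytic chord 2c sqrt(r^2-s^2)."""
        grid = sr.VoxelGrid((64, 64), 4.8)
        yy, xx = grid.coord_grids()
        r_mm, conc = 40.0, 500.0
        disk = np.where(yy ** 2 + xx ** 2 <= r_mm ** 2, conc, 0.0)
        geo = sr.AcquisitionGeometry(n_views=4, angular_range_deg=360, n_bins=64,
                                     bin_size_mm=4.8, radii_mm=(200.0,) * 4)
        system = _system(grid, geo)
        profile = system.forward(disk, views=[0])[0]
        oracle = disk.sum(axis=0) * grid.voxel_size_mm / 10.0  # direct column sums
        assert np.allclose(profile, oracle, rtol=1e-10, atol=1e-9)
        s = geo.bin_coords_mm()
        inner = np.abs(s) < 0.7 * r_mm
        analytic = 2.0 * conc * np.sqrt(r_mm ** 2 - s[inner] ** 2) / 10.0
        assert np.all(np.abs(profile[inner] - analytic) / analytic < 0.06)

    def test_point_source_lands_at_expected_bin(self):
        grid = sr.VoxelGrid((33, 33), 4.8)
        geo = sr.AcquisitionGeometry(n_views=12, angular_range_deg=360, n_bins=33,
                                     bin_size_mm=4.8, radii_mm=(150.0,) * 12)
        system = _system(grid, geo)
        iy, ix = 20, 14  # world (y, x) = (+19.2, -9.6) mm
        img = np.zeros(grid.dims)
        img[iy, ix] = 1.0
        y_mm = grid.axis_coords(0)[iy]
        x_mm = grid.axis_coords(1)[ix]
        sino = system.forward(img)
        for v, ang in enumerate(np.deg2rad(geo.angles_deg)):
            t = -np.sin(ang) * y_mm + np.cos(ang) * x_mm
            expected_bin = int(np.round(t / geo.bin_size_mm + (geo.n_bins - 1) / 2))
            assert abs(int(np.argmax(sino[v])) - expected_bin) <= 1

    def test_attenuation_strictly_decreases_bins(self, small_grid, small_geometry, small_mu, small_dro):
        free = _system(small_grid, small_geometry).forward(small_dro.values)
        att = _system(small_grid, small_geometry, small_mu, attenuation=True).forward(small_dro.values)
        nz = free > 1e-9
        assert np.all(att[nz] < free[nz])


class TestAdjointness:
    @pytest.mark.parametrize("psf,attenuation", [(False, False), (True, False),
                                                 (False, True), (True, True)])
    def test_2d_dot_product_identity(self, small_grid, small_geometry, small_mu,
                                     psf, attenuation):
        system = _system(small_grid, small_geometry, small_mu, psf, attenuation)
        rng = np.random.default_rng(0)
        x = rng.random(small_grid.dims)
        y = rng.random(system.sino_shape())
        lhs = np.vdot(system.forward(x), y)
        rhs = np.vdot(x, system.back(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    @pytest.mark.parametrize("psf,attenuation", [(True, True), (True, False)])
    def test_3d_dot_product_identity(self, psf, attenuation):
        grid = sr.VoxelGrid((6, 16, 16), 4.8)
        rng = np.random.default_rng(1)
        mu = MuMap(grid, rng.random(grid.dims) * 0.02)
        geo = sr.AcquisitionGeometry(n_views=8, angular_range_deg=360, n_bins=16,
                                     bin_size_mm=4.8, radii_mm=(60.0,) * 8)
        system = _system(grid, geo, mu, psf, attenuation)
        x = rng.random(grid.dims)
        y = rng.random(system.sino_shape())
        lhs = np.vdot(system.forward(x), y)
        rhs = np.vdot(x, system.back(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-6


class TestBackProjection:
    def test_zero_sinogram_zero_image(self, small_system):
        sino = Sinogram(np.zeros(small_system.sino_shape()), small_system.geometry)
        assert not sr.back_project(sino, small_system).values.any()

    def test_uniform_sinogram_gives_flat_interior(self):
        grid = sr.VoxelGrid((48, 48), 4.8)
        geo = sr.AcquisitionGeometry(n_views=48, angular_range_deg=360, n_bins=48,
                                     bin_size_mm=4.8, radii_mm=(200.0,) * 48)
        system = _system(grid, geo)
        img = system.back(np.ones(system.sino_shape()))
        yy, xx = grid.coord_grids()
        interior = yy ** 2 + xx ** 2 < (0.5 * 48 * 4.8 / 2) ** 2
        vals = img[interior]
        assert vals.std() / vals.mean() < 0.02


class TestSensitivity:
    def test_matches_explicit_matrix_column_sums(self):
        """Explicit small system matrix assembled column-by-column."""
        grid = sr.VoxelGrid((16, 16), 4.8)
        spec = sr.PhantomSpec(body_semi_axes_mm=(30.0, 25.0), spheres=())
        mu = sr.make_mu_map(spec, grid)
        geo = sr.AcquisitionGeometry(n_views=12, angular_range_deg=360, n_bins=16,
                                     bin_size_mm=4.8, radii_mm=(60.0,) * 12)
        system = _system(grid, geo, mu, psf=True, attenuation=True)
        colsums = np.zeros(grid.dims)
        for j in range(16 * 16):
            e = np.zeros(16 * 16)
            e[j] = 1.0
            colsums.ravel()[j] = system.forward(e.reshape(grid.dims)).sum()
        sens = sr.sensitivity_image(system)
        assert np.allclose(sens, colsums, rtol=1e-10, atol=1e-12)

    def test_subset_linearity_and_positivity(self, small_system):
        full = sr.sensitivity_image(small_system)
        subsets = [list(range(s, 24, 4)) for s in range(4)]
        partial = sum(sr.sensitivity_image(small_system, v) for v in subsets)
        assert np.allclose(full, partial, rtol=1e-12)
        assert np.all(full > 0)
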