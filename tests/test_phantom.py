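"""Phantom voxelisation, attenuation map, PET priors and ROI construction."""

import numpy as np
import pytest
from scipy import ndimage

import spectrecon as sr
from spectrecon.phantom import (
    Sphere,
    body_mask,
    fwhm_to_sigma,
    lesionless_prior,
    sphere_masks,
)


def brute_force_dro(spec, grid):
    """Independent voxel-centre inclusion oracle (plain Python loops)."""
    vals = np.zeros(grid.dims)
    ys = grid.axis_coords(0)
    xs = grid.axis_coords(1)
    a, b = spec.body_semi_axes_mm
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            if (x / a) ** 2 + (y / b) ** 2 <= 1.0:
                vals[i, j] = spec.background_kbq_ml
                for s in spec.spheres:
                    cy, cx = s.center_mm[0], s.center_mm[1]
                    if (y - cy) ** 2 + (x - cx) ** 2 <= s.radius_mm ** 2:
                        vals[i, j] = spec.sphere_kbq_ml
    return vals


class TestIecDro:
    def test_matches_center_inclusion_oracle(self, iec_spec, grid128, dro128):
        assert np.array_equal(dro128.values, brute_force_dro(iec_spec, grid128))

    def test_zero_concentrations_give_zero_image(self, grid128):
        spec = sr.PhantomSpec(sphere_kbq_ml=0.0, background_kbq_ml=0.0)
        assert not sr.make_iec_dro(spec, grid128).values.any()

    def test_uniform_fill_without_spheres(self, grid128):
        spec = sr.PhantomSpec(spheres=(), background_kbq_ml=317.0)
        dro = sr.make_iec_dro(spec, grid128)
        body = body_mask(spec, grid128)
        assert np.all(dro.values[body] == 317.0)
        assert np.all(dro.values[~body] == 0.0)

    def test_37mm_sphere_voxel_count_in_3d(self, iec_spec):
        """Voxelised 37 mm sphere: count equals a brute-force bounding-box
        oracle and is within 15 % of the continuum value ~240."""
        grid3 = sr.VoxelGrid((32, 128, 128), 4.8)
        count = int(sphere_masks(iec_spec, grid3)[1].sum())
        s = iec_spec.sphere_by_label(1)
        # independent loop-based oracle over the bounding box
        zs, ys, xs = (grid3.axis_coords(a) for a in range(3))
        cy, cx = s.center_mm
        n = 0
        for z in zs[np.abs(zs) <= s.radius_mm + 5]:
            for y in ys[np.abs(ys - cy) <= s.radius_mm + 5]:
                for x in xs[np.abs(xs - cx) <= s.radius_mm + 5]:
                    if z * z + (y - cy) ** 2 + (x - cx) ** 2 <= s.radius_mm ** 2:
                        n += 1
        assert count == n
        continuum = (4 / 3) * np.pi * 18.5 ** 3 / 4.8 ** 3
        assert abs(count - continuum) / continuum < 0.15

    def test_sphere_outside_grid_rejected(self, iec_spec):
        tiny = sr.VoxelGrid((16, 16), 4.8)
        with pytest.raises(ValueError):
            sr.make_iec_dro(iec_spec, tiny)


class TestMuMap:
    def test_zero_mu_gives_zero_map(self, iec_spec, grid128):
        assert not sr.make_mu_map(iec_spec, grid128, 0.0).values.any()

    def test_uniform_body_value_and_zero_outside(self, iec_spec, grid128):
        mu = sr.make_mu_map(iec_spec, grid128, 0.136)
        body = body_mask(iec_spec, grid128)
        assert np.all(mu.values[body] == 0.136)
        assert np.all(mu.values[~body] == 0.0)

    def test_negative_mu_rejected(self, iec_spec, grid128):
        with pytest.raises(ValueError):
            sr.make_mu_map(iec_spec, grid128, -0.1)

    def test_line_integral_transmission(self):
        """20 cm of mu=0.15/cm water: transmission exp(-3) = 0.0498."""
        spec = sr.PhantomSpec(body_semi_axes_mm=(100.0, 100.0), spheres=())
        grid = sr.VoxelGrid((40, 40), 5.0)
        mu = sr.make_mu_map(spec, grid, 0.15)
        row = np.argmin(np.abs(grid.axis_coords(0)))  # row nearest the centre
        integral = mu.values[row].sum() * 0.5  # voxel length in cm
        assert integral == pytest.approx(3.0)
        assert np.exp(-integral) == pytest.approx(0.0498, abs=2e-4)


def oracle_gaussian_at(values, center, fwhm_mm, voxel_mm):
    """Brute-force discrete separable Gaussian convolution at one voxel,
    replicating truncated-kernel, zero-padded smoothing."""
    sigma = fwhm_to_sigma(fwhm_mm) / voxel_mm
    radius = int(4.0 * sigma + 0.5)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k /= k.sum()
    total = 0.0
    cy, cx = center
    ny, nx = values.shape
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            y, x = cy + dy, cx + dx
            if 0 <= y < ny and 0 <= x < nx:
                total += values[y, x] * k[dy + radius] * k[dx + radius]
    return total


class TestPetPrior:
    def test_zero_fwhm_no_removal_is_identity(self, dro128, iec_spec):
        prior = sr.make_pet_prior(dro128, iec_spec, fwhm_mm=0.0)
        assert np.array_equal(prior.values, dro128.values)

    def test_total_preserved_by_smoothing(self, dro128, iec_spec):
        prior = sr.make_pet_prior(dro128, iec_spec, fwhm_mm=7.5)
        assert abs(prior.total - dro128.total) / dro128.total < 1e-3

    def test_lesionless_center_matches_convolution_oracle(self, dro128, iec_spec, grid128):
        optimal = sr.make_pet_prior(dro128, iec_spec, fwhm_mm=7.5)
        lless = lesionless_prior(dro128, iec_spec, fwhm_mm=7.5)
        removed_input = dro128.values.copy()
        masks = sphere_masks(iec_spec, grid128)
        for lab in (2, 4, 6):
            removed_input[masks[lab]] = iec_spec.background_kbq_ml
        for lab in (2, 4, 6):
            s = iec_spec.sphere_by_label(lab)
            cy = np.argmin(np.abs(grid128.axis_coords(0) - s.center_mm[0]))
            cx = np.argmin(np.abs(grid128.axis_coords(1) - s.center_mm[1]))
            got = lless.values[cy, cx]
            expected = oracle_gaussian_at(removed_input, (cy, cx), 7.5, 4.8)
            assert got == pytest.approx(expected, rel=1e-6)
            assert got < optimal.values[cy, cx]

    @pytest.mark.parametrize("label", [1, 3, 5])
    def test_peak_monotone_in_fwhm(self, dro128, iec_spec, grid128, label):
        s = iec_spec.sphere_by_label(label)
        cy = np.argmin(np.abs(grid128.axis_coords(0) - s.center_mm[0]))
        cx = np.argmin(np.abs(grid128.axis_coords(1) - s.center_mm[1]))
        peaks = [
            sr.make_pet_prior(dro128, iec_spec, fwhm_mm=f).values[cy, cx]
            for f in (0.0, 5.0, 7.5, 12.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(peaks, peaks[1:]))

    def test_unknown_removed_label_rejected(self, dro128, iec_spec):
        with pytest.raises(ValueError):
            sr.make_pet_prior(dro128, iec_spec, removed_sphere_labels=(9,))

    def test_reference_sd_matches_3d_volume_convention(self, iec_spec):
        sd = sr.prior_reference_sd(iec_spec)
        # whole-volume SD of the mostly-empty 128^3 prior, ~70 for the
        # default phantom; far below the body-only SD (~470)
        assert 50 < sd < 100


class TestRois:
    def test_sphere_counts_respect_truth_bound(self, iec_spec, grid128, rois128):
        # 2D: 37 mm circular ROI capped at floor(pi 18.5^2 / 4.8^2) = 46
        assert rois128.sphere(1).n_voxels == 46
        for roi in rois128.spheres():
            measure = roi.n_voxels * grid128.voxel_area_mm2
            assert measure <= roi.true_measure + 1e-9

    def test_3d_10mm_voi_count(self, iec_spec):
        grid3 = sr.VoxelGrid((32, 128, 128), 4.8)
        rois = sr.make_rois(iec_spec, grid3)
        assert rois.sphere(6).n_voxels <= 4
        for roi in rois.spheres():
            assert roi.n_voxels * grid3.voxel_volume_ml <= roi.true_measure + 1e-12

    def test_background_disjoint_from_spheres(self, rois128, grid128):
        bg = rois128.background.mask(grid128.dims)
        for roi in rois128.spheres():
            assert not (bg & roi.mask(grid128.dims)).any()

    def test_background_avoids_body_edge(self, iec_spec, grid128, rois128):
        shrunk = ndimage.binary_erosion(body_mask(iec_spec, grid128), iterations=4)
        assert np.all(shrunk[rois128.background.indices])
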