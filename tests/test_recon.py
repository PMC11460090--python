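"""EM reconstruction: convergence, likelihood, kernel reduction, models."""

import numpy as np
import pytest

import spectrecon as sr
from spectrecon.metrics import background_cov_percent


class TestOsem:
    def test_nonnegative_output(self, small_pn, small_system):
        res = sr.osem(small_pn["PN1"], small_system,
                      cfg=sr.ReconConfig(iterations=3, subsets=4))
        assert np.all(res.image.values >= 0)

    def test_mlem_loglikelihood_monotone(self, small_pn, small_system):
        """One subset on noise-free data: the Poisson log-likelihood never
        decreases (the defining EM property)."""
        cfg = sr.ReconConfig(iterations=50, subsets=1, compute_loglik=True)
        res = sr.osem(small_pn["PN1_expected"], small_system, cfg=cfg)
        diffs = np.diff(res.loglik)
        assert np.all(diffs >= -np.abs(res.loglik[1:]) * 1e-10 - 1e-6)

    def test_uniform_disk_convergence(self):
        """Noise-free uniform disk, PSF/attenuation off: interior voxels
        within 5 % of truth after 100 MLEM iterations."""
        grid = sr.VoxelGrid((32, 32), 4.8)
        yy, xx = grid.coord_grids()
        truth = np.where(yy ** 2 + xx ** 2 <= 40.0 ** 2, 200.0, 0.0)
        geo = sr.AcquisitionGeometry(n_views=24, angular_range_deg=360, n_bins=32,
                                     bin_size_mm=4.8, radii_mm=(100.0,) * 24)
        system = sr.SystemModel(grid, geo, None, None, psf=False, attenuation=False)
        sino = sr.Sinogram(system.forward(truth), geo)
        res = sr.osem(sino, system, cfg=sr.ReconConfig(iterations=100, subsets=1))
        interior = yy ** 2 + xx ** 2 <= 20.0 ** 2
        rel = np.abs(res.image.values[interior] - 200.0) / 200.0
        assert rel.max() < 0.05
        # count conservation at (near) convergence
        refit = system.forward(res.image.values * res.model.calibration)
        assert abs(refit.sum() - sino.total) / sino.total < 0.005

    def test_all_zero_data_returns_zero_image(self, small_system):
        sino = sr.Sinogram(np.zeros(small_system.sino_shape()), small_system.geometry)
        with pytest.warns(UserWarning):
            res = sr.osem(sino, small_system, cfg=sr.ReconConfig(iterations=2, subsets=4))
        assert not res.image.values.any()

    def test_subsets_must_divide_views(self, small_pn, small_system):
        with pytest.raises(ValueError):
            sr.osem(small_pn["PN1"], small_system,
                    cfg=sr.ReconConfig(iterations=1, subsets=7))

    def test_calibration_converts_counts_to_concentration(self, small_pn, small_system, small_dro):
        """Reconstructed means land near the simulated kBq/ml truth."""
        res = sr.osem(small_pn["PN1"], small_system,
                      cfg=sr.ReconConfig(iterations=10, subsets=4))
        body = small_dro.values > 0
        ratio = res.image.values[body].sum() / small_dro.values[body].sum()
        assert 0.8 < ratio < 1.2


class TestSpectre:
    def test_identity_kernel_reduces_to_osem_bitwise(self, small_pn, small_system, small_prior):
        cfg = sr.ReconConfig(iterations=3, subsets=4)
        a = sr.osem(small_pn["PN1"], small_system, cfg=cfg)
        b = sr.spectre(small_pn["PN1"], small_system, small_prior,
                       params=sr.KernelParams(nn=1), cfg=cfg)
        assert np.array_equal(a.image.values, b.image.values)

    def test_nonnegative_for_table_parameters(self, small_pn, small_system, small_prior):
        cfg = sr.ReconConfig(iterations=2, subsets=4)
        for p in sr.investigation1_sweep():
            res = sr.spectre(small_pn["PN1"], small_system, small_prior, params=p, cfg=cfg)
            assert np.all(res.image.values >= 0)

    def test_prior_grid_mismatch_rejected(self, small_pn, small_system):
        other = sr.VoxelGrid((16, 16), 4.8)
        prior = sr.ActivityImage(other, np.ones(other.dims))
        with pytest.raises(ValueError):
            sr.SpectreModel(small_pn["PN1"], small_system, prior)

    def test_smoothing_limit_reduces_background_noise(self, iec_spec, grid128, rois128):
        """Uninformative (constant) prior with sigma_s -> inf: on
        high-noise data the windowed kernel acts as a smoother, so the
        background COV cannot exceed OSEM_RM's at matched iterations."""
        dro = sr.make_iec_dro(iec_spec, grid128)
        mu = sr.make_mu_map(iec_spec, grid128)
        geo = sr.default_geometry(iec_spec.body_semi_axes_mm)
        system = sr.SystemModel(grid128, geo, sr.CDRFModel(), mu)
        data = sr.make_pn_datasets(dro, system, sr.CountModel(), seed=7)
        const_prior = sr.ActivityImage(grid128, np.full(grid128.dims, 100.0))
        cfg = sr.ReconConfig(iterations=20, subsets=12)
        cov_osem = background_cov_percent(sr.osem(data["PN2"], system, cfg=cfg).image, rois128)
        params = sr.KernelParams(sigma_p=1.0, sigma_s=1e9, sigma_dp=5, sigma_ds=5, nn=5)
        cov_kem = background_cov_percent(
            sr.spectre(data["PN2"], system, const_prior, params=params, cfg=cfg).image,
            rois128)
        assert cov_kem <= cov_osem

    def test_recorded_iterates_and_summary(self, small_pn, small_system, small_prior):
        cfg = sr.ReconConfig(iterations=4, subsets=4, record=(2,))
        res = sr.spectre(small_pn["PN1"], small_system, small_prior,
                         params=sr.KernelParams(nn=3), cfg=cfg)
        assert set(res.iterates) == {2, 4}
        text = res.summary()
        assert "SPECTRE" in text and "NN=3" in text


class TestParameterSweep:
    def test_sweep_of_length_one_matches_single_run(self, small_pn, small_system,
                                                    small_prior, small_spec, small_grid):
        rois = sr.make_rois(small_spec, small_grid, background_margin_vox=2,
                            sphere_exclusion_vox=2)
        cfg = sr.ReconConfig(iterations=2, subsets=4)
        p = sr.KernelParams(nn=3)
        df = sr.parameter_sweep(small_pn["PN1"], small_system, small_prior, [p],
                                rois, cfg=cfg, include_osem_rm=False)
        res = sr.spectre(small_pn["PN1"], small_system, small_prior, params=p, cfg=cfg)
        direct = res.roi_metrics(rois)
        assert np.allclose(df["mean"].to_numpy(), direct["mean"].to_numpy())

    def test_design_emits_ten_unique_rows(self):
        sweep = sr.investigation1_sweep()
        assert len(sweep) == 9  # + OSEM_RM reference = 10 rows
        keys = {(p.sigma_p, p.sigma_s, p.sigma_dp, p.sigma_ds, p.nn) for p in sweep}
        assert len(keys) == 9

    def test_sweep_table_structure(self, small_pn, small_system, small_prior,
                                   small_spec, small_grid):
        rois = sr.make_rois(small_spec, small_grid, background_margin_vox=2,
                            sphere_exclusion_vox=2)
        cfg = sr.ReconConfig(iterations=1, subsets=4)
        df = sr.parameter_sweep(small_pn["PN1"], small_system, small_prior,
                                sr.investigation1_sweep()[:2], rois, cfg=cfg)
        n_regions = len(rois.regions)
        assert len(df) == 3 * n_regions  # 2 SPECTRE + 1 OSEM_RM
        assert set(df.algorithm) == {"SPECTRE", "OSEM_RM"}
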