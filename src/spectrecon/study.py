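"""Canonical simulated-study conditions and measurement helpers.

Builds the complete simulated Lu-177 IEC-phantom study the package's
quantitative evaluation runs on: the 2D (single central slice, 128x128,
120 views) and a scaled-down 3D (16 slices, 64x64, 60 views) rig, each
bundling phantom, attenuation map, system model, PET priors, truth-
matched ROIs and the PN1/PN2 noisy datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .grid import ActivityImage, MuMap, VoxelGrid
from .metrics import evaluate_image
from .phantom import (
    PhantomSpec,
    ROISet,
    lesionless_prior,
    make_iec_dro,
    make_mu_map,
    make_pet_prior,
    make_rois,
    reconstruction_mask,
)
from .projector import CDRFModel, Sinogram, SystemModel, default_geometry
from .recon import ReconstructionResult
from .simulate import CountModel, make_pn_datasets

__all__ = ["Study", "build_study_2d", "build_study_3d",
           "background_cov", "mean_sphere_snr", "sphere_mean_bias_pct",
           "sphere_rc_max"]


@dataclass
class Study:
    """One fully-specified simulated acquisition ready to reconstruct."""

    spec: PhantomSpec
    grid: VoxelGrid
    dro: ActivityImage
    mu: MuMap
    system: SystemModel
    rois: ROISet
    prior_optimal: ActivityImage
    prior_lesionless: ActivityImage
    data: Dict[str, Sinogram]
    mask: np.ndarray

    @property
    def pn1(self) -> Sinogram:
        return self.data["PN1"]

    @property
    def pn2(self) -> Sinogram:
        return self.data["PN2"]


def _build(spec: PhantomSpec, grid: VoxelGrid, n_views: int, n_bins: int,
           seed: Optional[int]) -> Study:
    dro = make_iec_dro(spec, grid)
    mu = make_mu_map(spec, grid)
    geo = default_geometry(spec.body_semi_axes_mm, n_views=n_views, n_bins=n_bins,
                           bin_size_mm=grid.voxel_size_mm)
    system = SystemModel(grid, geo, CDRFModel(), mu, psf=True, attenuation=True)
    data = make_pn_datasets(dro, system, CountModel(), seed=seed)
    return Study(
        spec=spec,
        grid=grid,
        dro=dro,
        mu=mu,
        system=system,
        rois=make_rois(spec, grid),
        prior_optimal=make_pet_prior(dro, spec),
        prior_lesionless=lesionless_prior(dro, spec),
        data=data,
        mask=reconstruction_mask(spec, grid),
    )


def build_study_2d(seed: Optional[int] = 0) -> Study:
    """The single-slice study: 128x128 at 4.8 mm, 120 views over 360 deg."""
    return _build(PhantomSpec(), VoxelGrid((128, 128), 4.8), 120, 128, seed)


def build_study_3d(seed: Optional[int] = 0, n_slices: int = 16,
                   transaxial: int = 64, n_views: int = 60) -> Study:
    """Scaled-down 3D study used for 2D-vs-3D trend checks."""
    grid = VoxelGrid((n_slices, transaxial, transaxial), 4.8)
    return _build(PhantomSpec(), grid, n_views, transaxial, seed)


# -- measurement helpers ------------------------------------------------------

def background_cov(image: ActivityImage, rois: ROISet) -> float:
    """Background COV in % (100 SD/mean over the background region)."""
    df = evaluate_image(image, rois).set_index("region")
    return float(df.loc["background", "cov_pct"])


def mean_sphere_snr(image: ActivityImage, rois: ROISet) -> float:
    """SNR averaged over the six spheres (background mean/SD based)."""
    df = evaluate_image(image, rois)
    return float(df[df.kind == "sphere"].snr.mean())


def sphere_mean_bias_pct(image: ActivityImage, rois: ROISet, label: int) -> float:
    df = evaluate_image(image, rois).set_index("region")
    return float(df.loc[f"sphere{label}", "mean_bias_pct"])


def sphere_rc_max(image: ActivityImage, rois: ROISet, label: int) -> float:
    df = evaluate_image(image, rois).set_index("region")
    return float(df.loc[f"sphere{label}", "rc_max"])
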