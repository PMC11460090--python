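"""Shared fixtures: the full-size IEC phantom rig and a small fast rig."""

import numpy as np
import pytest
from hypothesis import settings

import spectrecon as sr
from spectrecon.phantom import Sphere

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


# -- full-size IEC phantom (no reconstruction in unit tests) ----------------

@pytest.fixture(scope="session")
def iec_spec():
    return sr.PhantomSpec()


@pytest.fixture(scope="session")
def grid128():
    return sr.VoxelGrid((128, 128), 4.8)


@pytest.fixture(scope="session")
def dro128(iec_spec, grid128):
    return sr.make_iec_dro(iec_spec, grid128)


@pytest.fixture(scope="session")
def rois128(iec_spec, grid128):
    return sr.make_rois(iec_spec, grid128)


# -- small phantom rig for projector/reconstruction tests -------------------

@pytest.fixture(scope="session")
def small_spec():
    spheres = (
        Sphere(center_mm=(0.0, 25.0), diameter_mm=20.0, label=1),
        Sphere(center_mm=(0.0, -25.0), diameter_mm=12.0, label=2),
    )
    return sr.PhantomSpec(
        body_semi_axes_mm=(60.0, 45.0), body_length_mm=80.0, spheres=spheres
    )


@pytest.fixture(scope="session")
def small_grid():
    return sr.VoxelGrid((32, 32), 4.8)


@pytest.fixture(scope="session")
def small_geometry(small_spec):
    return sr.default_geometry(small_spec.body_semi_axes_mm, n_views=24, n_bins=32)


@pytest.fixture(scope="session")
def small_mu(small_spec, small_grid):
    return sr.make_mu_map(small_spec, small_grid)


@pytest.fixture(scope="session")
def small_system(small_grid, small_geometry, small_mu):
    return sr.SystemModel(small_grid, small_geometry, sr.CDRFModel(), small_mu,
                          psf=True, attenuation=True)


@pytest.fixture(scope="session")
def small_dro(small_spec, small_grid):
    return sr.make_iec_dro(small_spec, small_grid)


@pytest.fixture(scope="session")
def small_pn(small_dro, small_system):
    return sr.make_pn_datasets(small_dro, small_system, sr.CountModel(), seed=11)


@pytest.fixture(scope="session")
def small_prior(small_dro, small_spec):
    return sr.make_pet_prior(small_dro, small_spec)
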