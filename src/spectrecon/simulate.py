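"""Analytical simulation of noisy SPECT projection data.

Noise-free projections from the forward model are rescaled to a target
expected count level and corrupted with independent Poisson noise.  Two
count levels model a Lu-177 therapy study imaged at an early ("PN1",
low noise) and a late ("PN2", high noise) time point: the activity in
the field of view at the early scan is taken from the phantom itself
(ground-truth sum x voxel volume), and the late scan is scaled down by
radioactive decay plus biological washout with a configurable effective
half-life.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .grid import ActivityImage
from .projector import Sinogram, SystemModel, forward_project

__all__ = ["CountModel", "expected_counts", "add_poisson", "make_pn_datasets"]

LU177_HALF_LIFE_DAYS = 6.647


@dataclass(frozen=True)
class CountModel:
    """Count calibration for the simulated acquisition.

    ``sensitivity_cps_per_mbq`` is the planar system sensitivity per
    camera head (12.2 cps/MBq for the Lu-177 208 keV window this
    simulation models).  Total expected counts for an acquisition are

        sensitivity x activity(MBq) x dwell(s) x n_views

    with each view acquired for the full dwell by one head (the head
    count shortens wall-clock time, it does not double counts).  The
    PN2 level applies ``pn2_fraction`` on top of PN1: by default
    2^(-96/60), i.e. decay + washout with a 60 h effective half-life
    between 24 h and 120 h post-administration.
    """

    sensitivity_cps_per_mbq: float = 12.2
    pn2_fraction: float = float(2.0 ** (-(120.0 - 24.0) / 60.0))
    seed: Optional[int] = None

    def __post_init__(self):
        if self.sensitivity_cps_per_mbq <= 0:
            raise ValueError("sensitivity must be positive")
        if not (0.0 < self.pn2_fraction <= 1.0):
            raise ValueError("pn2_fraction must be in (0, 1]")

    def total_counts(self, activity_mbq: float, geometry) -> float:
        return (
            self.sensitivity_cps_per_mbq
            * activity_mbq
            * geometry.dwell_s
            * geometry.n_views
        )


def expected_counts(
    sino_noise_free: Sinogram, activity_total_mbq: float, model: CountModel
) -> Sinogram:
    """Rescale a noise-free sinogram to its expected-count level.

    The output is bin-wise proportional to the geometric projection,
    with total expected counts = sensitivity x activity x dwell x
    n_views.  The scale factor (counts per projection unit) is recorded
    in ``meta["calibration"]`` so reconstructions can convert back to
    kBq/ml.
    """
    if activity_total_mbq < 0:
        raise ValueError("activity must be nonnegative")
    target = model.total_counts(activity_total_mbq, sino_noise_free.geometry)
    s = sino_noise_free.total
    if target == 0:
        out = sino_noise_free.copy_with(np.zeros_like(sino_noise_free.values))
        out.meta["calibration"] = 1.0
        return out
    if s <= 0:
        raise ValueError("cannot scale an all-zero sinogram to nonzero counts")
    cal = target / s
    out = sino_noise_free.copy_with(sino_noise_free.values * cal)
    out.meta["calibration"] = cal
    out.meta["expected_total_counts"] = target
    return out


def add_poisson(expected: Sinogram, seed: Optional[int] = None) -> Sinogram:
    """Independent Poisson draw per bin; reproducible under a fixed seed."""
    if np.any(expected.values < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = expected.copy_with(rng.poisson(expected.values).astype(float))
    noisy.meta["seed"] = seed
    return noisy


def make_pn_datasets(
    dro: ActivityImage,
    system: SystemModel,
    model: CountModel,
    seed: Optional[int] = None,
) -> Dict[str, Sinogram]:
    """Simulate the low-noise (PN1) and high-noise (PN2) datasets.

    Both derive from one noise-free forward projection of the ground
    truth; PN2's expected counts are PN1's times ``model.pn2_fraction``.
    The activity in the field of view is read off the phantom itself.
    """
    if seed is None:
        seed = model.seed
    noise_free = forward_project(dro, system)
    activity_mbq = dro.total_activity_mbq
    pn1_exp = expected_counts(noise_free, activity_mbq, model)
    pn2_exp = pn1_exp.copy_with(pn1_exp.values * model.pn2_fraction)
    pn2_exp.meta["calibration"] = pn1_exp.meta["calibration"] * model.pn2_fraction
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    pn1 = add_poisson(pn1_exp, s1)
    pn2 = add_poisson(pn2_exp, s2)
    for sino, exp in ((pn1, pn1_exp), (pn2, pn2_exp)):
        sino.meta["calibration"] = exp.meta["calibration"]
        sino.meta["parent_seed"] = seed
    pn1.meta["level"] = "PN1"
    pn2.meta["level"] = "PN2"
    return {"PN1": pn1, "PN2": pn2, "noise_free": noise_free,
            "PN1_expected": pn1_exp, "PN2_expected": pn2_exp}
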