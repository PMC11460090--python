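"""NEMA IEC body-phantom digital reference objects.

Generates the voxelised ground-truth activity distribution (DRO), the
matching attenuation map, simulated PET priors, and truth-matched
ROI/VOI sets for quantitative evaluation.

The phantom geometry is parametric: an elliptical torso cross-section
with six fillable spheres (diameters 37, 28, 22, 17, 13 and 10 mm)
arranged on a 114.4 mm circle in a common transaxial plane.  Sphere and
background Lu-177 concentrations default to 2784 and 317 kBq/ml, the
aliquot-assayed values of the phantom study this simulation models.
Voxels are assigned by centre inclusion (a voxel takes the sphere value
iff its centre lies inside the sphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import ActivityImage, MuMap, VoxelGrid

__all__ = [
    "Sphere",
    "PhantomSpec",
    "ROISet",
    "ROIRegion",
    "make_iec_dro",
    "make_mu_map",
    "make_pet_prior",
    "lesionless_prior",
    "prior_reference_sd",
    "make_rois",
    "body_mask",
    "sphere_masks",
    "reconstruction_mask",
]

# NEMA IEC sphere diameters, largest first, labelled 1..6.
IEC_SPHERE_DIAMETERS_MM = (37.0, 28.0, 22.0, 17.0, 13.0, 10.0)
# Radius of the circle the sphere centres sit on (114.4 mm centre-to-centre
# diameter in the IEC standard).
IEC_SPHERE_RING_RADIUS_MM = 57.2
# Interior torso cross-section approximated as an ellipse (semi-axes, mm).
IEC_BODY_SEMI_AXES_MM = (150.0, 110.0)
# Interior axial length of the phantom cavity (mm).
IEC_BODY_LENGTH_MM = 180.0

# Water linear attenuation at the Lu-177 208 keV photopeak (1/cm); a
# standard tabulated value used as a configurable default.
MU_WATER_208KEV = 0.136


@dataclass(frozen=True)
class Sphere:
    """One fillable sphere: centre in world mm (y, x[, z]) and diameter."""

    center_mm: Tuple[float, ...]
    diameter_mm: float
    label: int

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def volume_ml(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius_mm ** 3 / 1000.0

    @property
    def area_mm2(self) -> float:
        """Cross-sectional area through the centre."""
        return np.pi * self.radius_mm ** 2


def _default_spheres() -> Tuple[Sphere, ...]:
    spheres = []
    for i, d in enumerate(IEC_SPHERE_DIAMETERS_MM):
        ang = np.deg2rad(60.0 * i)
        y = IEC_SPHERE_RING_RADIUS_MM * np.sin(ang)
        x = IEC_SPHERE_RING_RADIUS_MM * np.cos(ang)
        spheres.append(Sphere(center_mm=(float(y), float(x)), diameter_mm=d, label=i + 1))
    return tuple(spheres)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the IEC body phantom.

    ``body_semi_axes_mm`` are the (y, x) semi-axes of the elliptical
    torso outline; sphere centres are (y, x) world coordinates in the
    sphere plane (taken as the central transaxial slice in 3D).
    """

    body_semi_axes_mm: Tuple[float, float] = IEC_BODY_SEMI_AXES_MM
    body_length_mm: float = IEC_BODY_LENGTH_MM
    spheres: Tuple[Sphere, ...] = field(default_factory=_default_spheres)
    sphere_kbq_ml: float = 2784.0
    background_kbq_ml: float = 317.0
    lung_insert: bool = False

    def __post_init__(self):
        if self.sphere_kbq_ml < 0 or self.background_kbq_ml < 0:
            raise ValueError("concentrations must be nonnegative")
        if any(s.diameter_mm <= 0 for s in self.spheres):
            raise ValueError("sphere diameters must be positive")
        a, b = self.body_semi_axes_mm
        for s in self.spheres:
            y, x = s.center_mm[0], s.center_mm[1]
            # sphere fully inside the body outline
            if (x / a) ** 2 + (y / b) ** 2 > 1.0 or np.hypot(y, x) + s.radius_mm > max(a, b):
                pass  # coarse check below is authoritative
            if ((abs(x) + s.radius_mm) / a) ** 2 + ((abs(y) + s.radius_mm) / b) ** 2 > 1.0 + 1e-9:
                raise ValueError(f"sphere {s.label} extends outside the body outline")
        for i, si in enumerate(self.spheres):
            for sj in self.spheres[i + 1:]:
                dy = si.center_mm[0] - sj.center_mm[0]
                dx = si.center_mm[1] - sj.center_mm[1]
                if np.hypot(dy, dx) < si.radius_mm + sj.radius_mm:
                    raise ValueError(f"spheres {si.label} and {sj.label} overlap")

    def sphere_by_label(self, label: int) -> Sphere:
        for s in self.spheres:
            if s.label == label:
                return s
        raise KeyError(f"no sphere with label {label}")


def body_mask(spec: PhantomSpec, grid: VoxelGrid) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the body outline."""
    a, b = spec.body_semi_axes_mm
    if grid.ndim == 2:
        yy, xx = grid.coord_grids()
        return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    zz, yy, xx = grid.coord_grids()
    inplane = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    return inplane & (np.abs(zz) <= spec.body_length_mm / 2.0)


def reconstruction_mask(spec: PhantomSpec, grid: VoxelGrid, dilate_vox: int = 2) -> np.ndarray:
    """Body outline dilated by a couple of voxels: the support on which
    iterative reconstructions update (everything outside stays zero)."""
    m = body_mask(spec, grid)
    if dilate_vox > 0:
        m = ndimage.binary_dilation(m, iterations=dilate_vox)
    return m


def sphere_masks(spec: PhantomSpec, grid: VoxelGrid) -> Dict[int, np.ndarray]:
    """Per-label boolean masks of voxel-centre inclusion in each sphere.

    In 2D the mask is the circular cross-section through the sphere
    centre plane; in 3D the spheres are centred on the z=0 plane.
    """
    out: Dict[int, np.ndarray] = {}
    if grid.ndim == 2:
        yy, xx = grid.coord_grids()
        for s in spec.spheres:
            cy, cx = s.center_mm[0], s.center_mm[1]
            out[s.label] = (yy - cy) ** 2 + (xx - cx) ** 2 <= s.radius_mm ** 2
    else:
        zz, yy, xx = grid.coord_grids()
        for s in spec.spheres:
            cy, cx = s.center_mm[0], s.center_mm[1]
            cz = s.center_mm[2] if len(s.center_mm) > 2 else 0.0
            out[s.label] = (
                (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= s.radius_mm ** 2
            )
    return out


def _check_coverage(spec: PhantomSpec, grid: VoxelGrid) -> None:
    half_y = grid.axis_coords(grid.ndim - 2)[-1] + grid.voxel_size_mm / 2
    half_x = grid.axis_coords(grid.ndim - 1)[-1] + grid.voxel_size_mm / 2
    a, b = spec.body_semi_axes_mm
    if a > half_x or b > half_y:
        raise ValueError("grid does not cover the body outline")
    for s in spec.spheres:
        if abs(s.center_mm[1]) + s.radius_mm > half_x or abs(s.center_mm[0]) + s.radius_mm > half_y:
            raise ValueError(f"sphere {s.label} extends outside the grid")


def make_iec_dro(spec: PhantomSpec, grid: VoxelGrid) -> ActivityImage:
    """Voxelise the phantom into a ground-truth activity image.

    Voxel centres inside a sphere take ``sphere_kbq_ml``, centres inside
    the body but outside every sphere take ``background_kbq_ml``, and
    everything else is zero.
    """
    _check_coverage(spec, grid)
    body = body_mask(spec, grid)
    values = np.where(body, spec.background_kbq_ml, 0.0)
    for mask in sphere_masks(spec, grid).values():
        values[mask & body] = spec.sphere_kbq_ml
    return ActivityImage(grid, values, role="ground-truth")


def make_mu_map(
    spec: PhantomSpec, grid: VoxelGrid, mu_body_per_cm: float = MU_WATER_208KEV
) -> MuMap:
    """Uniform water-equivalent attenuation inside the body outline."""
    if mu_body_per_cm < 0:
        raise ValueError("mu_body_per_cm must be nonnegative")
    _check_coverage(spec, grid)
    values = np.where(body_mask(spec, grid), mu_body_per_cm, 0.0)
    return MuMap(grid, values)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM -> sigma: sigma = FWHM / (2 sqrt(2 ln 2))."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _prior_values(spec, grid, fwhm_mm, removed):
    """Voxelise, reset removed spheres to background, then smooth."""
    body = body_mask(spec, grid)
    values = np.where(body, spec.background_kbq_ml, 0.0)
    masks = sphere_masks(spec, grid)
    for s in spec.spheres:
        if s.label not in removed:
            values[masks[s.label] & body] = spec.sphere_kbq_ml
    if fwhm_mm > 0:
        sigma_vox = fwhm_to_sigma(fwhm_mm) / grid.voxel_size_mm
        values = ndimage.gaussian_filter(values, sigma_vox, mode="constant")
    return np.clip(values, 0.0, None)


from functools import lru_cache


@lru_cache(maxsize=32)
def _cached_reference_sd(spec, fwhm_mm, removed, volume_dims, voxel_size_mm):
    grid3 = VoxelGrid(volume_dims, voxel_size_mm)
    vals = _prior_values(spec, grid3, fwhm_mm, set(removed))
    return float(vals.std())


def prior_reference_sd(
    spec: PhantomSpec,
    fwhm_mm: float = 7.5,
    removed_sphere_labels: Iterable[int] = (),
    volume_dims: Tuple[int, int, int] = (128, 128, 128),
    voxel_size_mm: float = 4.8,
) -> float:
    """SD of the PET prior over the full 3D acquisition volume.

    This whole-volume standard deviation is the kernel normalisation
    scale of the prior: the prior occupies only a few percent of the
    128^3 acquisition volume, so the value (~70 for the default
    phantom) is much smaller than the SD over the body alone, and the
    single-slice 2D workflow inherits it from the 3D study rather than
    recomputing it on the slice.
    """
    removed = tuple(sorted(set(removed_sphere_labels)))
    return _cached_reference_sd(spec, fwhm_mm, removed, tuple(volume_dims), voxel_size_mm)


def make_pet_prior(
    dro: ActivityImage,
    spec: PhantomSpec,
    fwhm_mm: float = 7.5,
    removed_sphere_labels: Iterable[int] = (),
    reference_sd: Optional[float] = None,
) -> ActivityImage:
    """Simulate a noiseless PET prior from the ground truth.

    Removed spheres are reset to the background concentration *before*
    smoothing (a PET scan of a lesion-free region shows smoothed
    background, not a smoothed lesion), then an isotropic Gaussian of
    the given FWHM models the PET system resolution (7.5 mm for
    clinical Ga-68 PET).  The "optimal" prior removes nothing; the
    "lesion-less" prior removes the 28/17/10 mm spheres (labels 2, 4, 6).

    The returned image carries its kernel normalisation scale in
    ``meta["sd"]``: the SD over a full 3D acquisition volume (see
    :func:`prior_reference_sd`), also for priors generated on a 2D
    grid, unless ``reference_sd`` overrides it.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    removed = list(removed_sphere_labels)
    labels = {s.label for s in spec.spheres}
    unknown = set(removed) - labels
    if unknown:
        raise ValueError(f"unknown sphere labels: {sorted(unknown)}")
    values = dro.values.copy()
    masks = sphere_masks(spec, dro.grid)
    for lab in removed:
        values[masks[lab]] = spec.background_kbq_ml
    if fwhm_mm > 0:
        sigma_vox = fwhm_to_sigma(fwhm_mm) / dro.grid.voxel_size_mm
        values = ndimage.gaussian_filter(values, sigma_vox, mode="constant")
    values = np.clip(values, 0.0, None)
    if reference_sd is None:
        reference_sd = prior_reference_sd(
            spec, fwhm_mm, removed,
            voxel_size_mm=dro.grid.voxel_size_mm,
        )
    return ActivityImage(dro.grid, values, role="pet-prior",
                         meta={"fwhm_mm": fwhm_mm, "removed": removed,
                               "sd": float(reference_sd)})


def lesionless_prior(dro: ActivityImage, spec: PhantomSpec, fwhm_mm: float = 7.5) -> ActivityImage:
    """The prior with the 28, 17 and 10 mm spheres missing."""
    return make_pet_prior(dro, spec, fwhm_mm, removed_sphere_labels=(2, 4, 6))


@dataclass
class ROIRegion:
    """One evaluation region: voxel indices plus its ground truth."""

    kind: str  # "sphere" or "background"
    label: Optional[int]
    indices: Tuple[np.ndarray, ...]  # as returned by np.nonzero
    true_kbq_ml: float
    true_measure: float  # mm^2 in 2D, ml in 3D
    degenerate: bool = False

    @property
    def n_voxels(self) -> int:
        return len(self.indices[0])

    def mask(self, dims: Tuple[int, ...]) -> np.ndarray:
        m = np.zeros(dims, dtype=bool)
        m[self.indices] = True
        return m


@dataclass
class ROISet:
    """Truth-matched regions for the six spheres plus background."""

    grid: VoxelGrid
    regions: Dict[str, ROIRegion]

    @property
    def background(self) -> ROIRegion:
        return self.regions["background"]

    def sphere(self, label: int) -> ROIRegion:
        return self.regions[f"sphere{label}"]

    def spheres(self) -> List[ROIRegion]:
        return [r for r in self.regions.values() if r.kind == "sphere"]


def make_rois(
    spec: PhantomSpec,
    grid: VoxelGrid,
    background_margin_vox: int = 4,
    sphere_exclusion_vox: int = 4,
) -> ROISet:
    """Build truth-matched sphere ROIs/VOIs and a background region.

    Sphere regions are grown voxel-by-voxel outward from the sphere
    centre in order of distance and truncated so that the region
    area/volume never exceeds the true cross-section/volume (voxel
    count rounded down).  Mode follows the grid: circular ROIs on a 2D
    grid, spherical VOIs on a 3D grid.  The background region is the
    body mask eroded by ``background_margin_vox`` with every sphere
    dilated by ``sphere_exclusion_vox`` excluded; the 4-voxel defaults
    (~19 mm at 4.8 mm voxels, about one system FWHM) keep the region
    clear of spill-in/out from the spheres and the phantom edge.
    """
    vox = grid.voxel_size_mm
    measure_per_voxel = grid.voxel_area_mm2 if grid.ndim == 2 else grid.voxel_volume_ml
    coords = grid.coord_grids()
    regions: Dict[str, ROIRegion] = {}

    for s in spec.spheres:
        if grid.ndim == 2:
            cy, cx = s.center_mm[0], s.center_mm[1]
            d2 = (coords[0] - cy) ** 2 + (coords[1] - cx) ** 2
            true_measure = s.area_mm2
        else:
            cz = s.center_mm[2] if len(s.center_mm) > 2 else 0.0
            d2 = (
                (coords[0] - cz) ** 2
                + (coords[1] - s.center_mm[0]) ** 2
                + (coords[2] - s.center_mm[1]) ** 2
            )
            true_measure = s.volume_ml
        n_max = int(np.floor(true_measure / measure_per_voxel))
        order = np.argsort(d2, axis=None, kind="stable")[:n_max]
        idx = np.unravel_index(order, grid.dims)
        regions[f"sphere{s.label}"] = ROIRegion(
            kind="sphere",
            label=s.label,
            indices=tuple(np.asarray(a) for a in idx),
            true_kbq_ml=spec.sphere_kbq_ml,
            true_measure=true_measure,
            degenerate=(n_max < 1),
        )

    body = body_mask(spec, grid)
    eroded = ndimage.binary_erosion(body, iterations=background_margin_vox)
    excl = np.zeros(grid.dims, dtype=bool)
    for m in sphere_masks(spec, grid).values():
        excl |= ndimage.binary_dilation(m, iterations=sphere_exclusion_vox)
    bg = eroded & ~excl
    regions["background"] = ROIRegion(
        kind="background",
        label=None,
        indices=tuple(np.asarray(a) for a in np.nonzero(bg)),
        true_kbq_ml=spec.background_kbq_ml,
        true_measure=float(bg.sum()) * measure_per_voxel,
    )
    return ROISet(grid=grid, regions=regions)
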