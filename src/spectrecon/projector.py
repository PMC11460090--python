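"""Rotation-based SPECT forward/back projector.

The system matrix couples image voxels to sinogram bins through three
linear stages applied per view:

1. splat the image onto the detector-aligned frame (one sparse
   bilinear rotation matrix per view angle; columns sum to one, so the
   rotation conserves mass exactly for in-field activity);
2. weight each voxel by its cumulative attenuation towards the detector
   (diagonal, from the rotated mu-map);
3. blur each constant-distance row with a distance-dependent Gaussian
   collimator-detector response (CDRF) and sum rows into detector bins.

Back-projection applies the exact transposes of the same stages in
reverse order, so the pair is adjoint to machine precision: the bilinear
matrix is transposed explicitly, the attenuation weights are diagonal,
and a zero-padded convolution with a symmetric kernel is self-adjoint.

Projection values are line integrals approximated as (voxel sum along
the ray) x (voxel length in cm), so a kBq/ml image projects to
kBq.cm/ml per bin before count calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .grid import ActivityImage, MuMap, VoxelGrid

__all__ = [
    "AcquisitionGeometry",
    "CDRFModel",
    "Sinogram",
    "SystemModel",
    "cdrf_fwhm",
    "forward_project",
    "back_project",
    "sensitivity_image",
    "default_geometry",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AcquisitionGeometry:
    """SPECT orbit: 120 views over 360 deg with per-view radii.

    ``radii_mm`` holds one rotation radius per view (non-circular,
    body-contoured orbits).  ``dwell_s`` is the per-view acquisition
    time and ``n_heads`` the number of camera heads; both enter only
    through the count calibration.
    """

    n_views: int = 120
    angular_range_deg: float = 360.0
    n_bins: int = 128
    bin_size_mm: float = 4.8
    radii_mm: Tuple[float, ...] = ()
    dwell_s: float = 30.0
    n_heads: int = 2

    def __post_init__(self):
        radii = self.radii_mm
        if len(radii) == 0:
            radii = (200.0,) * self.n_views
        if len(radii) != self.n_views:
            raise ValueError("need one radius per view")
        object.__setattr__(self, "radii_mm", tuple(float(r) for r in radii))
        if self.n_views < 1 or self.n_bins < 1:
            raise ValueError("n_views and n_bins must be positive")

    @property
    def step_deg(self) -> float:
        return self.angular_range_deg / self.n_views

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * self.step_deg

    def bin_coords_mm(self) -> np.ndarray:
        n = self.n_bins
        return (np.arange(n) - (n - 1) / 2.0) * self.bin_size_mm


def default_geometry(
    body_semi_axes_mm: Tuple[float, float] = (150.0, 110.0),
    clearance_mm: float = 20.0,
    n_views: int = 120,
    n_bins: int = 128,
    bin_size_mm: float = 4.8,
    dwell_s: float = 30.0,
) -> AcquisitionGeometry:
    """Body-contoured orbit: per-view radius = body support extent along
    the view normal + a fixed clearance."""
    step = 360.0 / n_views
    angles = np.deg2rad(np.arange(n_views) * step)
    a, b = body_semi_axes_mm  # a along x, b along y
    # detector normal u = (cos th, sin th) in (y, x); ellipse support
    support = np.sqrt((a * np.sin(angles)) ** 2 + (b * np.cos(angles)) ** 2)
    radii = tuple(float(r) for r in support + clearance_mm)
    return AcquisitionGeometry(
        n_views=n_views,
        n_bins=n_bins,
        bin_size_mm=bin_size_mm,
        radii_mm=radii,
        dwell_s=dwell_s,
    )


@dataclass(frozen=True)
class CDRFModel:
    """Distance-dependent collimator-detector response.

    ``FWHM(d) = sqrt((a d + b)^2 + Ri^2)`` with collimator slope ``a``
    (mm FWHM per mm distance), intercept ``b`` (mm) and intrinsic
    detector resolution ``Ri`` (mm).  Defaults model a medium-energy
    low-penetration parallel-hole collimator at the Lu-177 208 keV
    photopeak (hole diameter 2.94 mm, effective hole length 38.9 mm):
    a = 2.94/38.9, b = 2.94, Ri = 3.8.
    """

    slope: float = 2.94 / 38.9
    intercept_mm: float = 2.94
    intrinsic_mm: float = 3.8

    def __post_init__(self):
        if self.slope < 0 or self.intercept_mm < 0 or self.intrinsic_mm < 0:
            raise ValueError("CDRF coefficients must be nonnegative")

    def fwhm_mm(self, distance_mm):
        d = np.asarray(distance_mm, dtype=float)
        if np.any(d < 0):
            raise ValueError("distance must be nonnegative")
        return np.sqrt((self.slope * d + self.intercept_mm) ** 2 + self.intrinsic_mm ** 2)

    def sigma_mm(self, distance_mm):
        return self.fwhm_mm(distance_mm) * _FWHM_TO_SIGMA


def cdrf_fwhm(distance_mm, model: CDRFModel):
    """FWHM (mm) of the CDRF at a collimator-face distance (mm)."""
    return model.fwhm_mm(distance_mm)


@dataclass
class Sinogram:
    """Projection data: (views, bins) in 2D or (views, rows, bins) in 3D."""

    values: np.ndarray
    geometry: AcquisitionGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.geometry.n_views or self.values.shape[-1] != self.geometry.n_bins:
            raise ValueError("sinogram shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")
        if np.any(self.values < 0):
            raise ValueError("sinogram values must be nonnegative")

    @property
    def is_3d(self) -> bool:
        return self.values.ndim == 3

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy_with(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(np.asarray(values, dtype=float), self.geometry, dict(self.meta))


def _gaussian_kernel(sigma_bins: float) -> np.ndarray:
    """Odd-length, unit-sum, symmetric Gaussian kernel (counts preserving)."""
    if sigma_bins < 1e-3:
        return np.ones(1)
    half = int(np.ceil(4.0 * sigma_bins))
    k = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (k / sigma_bins) ** 2)
    return kern / kern.sum()


def _convolve_same(row: np.ndarray, kern: np.ndarray) -> np.ndarray:
    if kern.size == 1:
        return row * kern[0]
    return np.convolve(row, kern, mode="same")


class SystemModel:
    """Bundles geometry, CDRF, attenuation and flags into the projector.

    Parameters
    ----------
    grid : VoxelGrid
        Image lattice (2D or 3D; 3D is handled slice-wise in-plane).
    geometry : AcquisitionGeometry
    cdrf : CDRFModel, optional
        Ignored when ``psf=False``.
    mu_map : MuMap, optional
        Ignored when ``attenuation=False``.
    psf, attenuation : bool
        Model flags.  In 3D the CDRF blur is applied both transaxially
        and axially (isotropic distance-dependent Gaussian).
    """

    def __init__(
        self,
        grid: VoxelGrid,
        geometry: AcquisitionGeometry,
        cdrf: Optional[CDRFModel] = None,
        mu_map: Optional[MuMap] = None,
        psf: bool = True,
        attenuation: bool = True,
    ):
        if psf and cdrf is None:
            cdrf = CDRFModel()
        if attenuation and mu_map is None:
            raise ValueError("attenuation=True requires a mu_map")
        if mu_map is not None and mu_map.grid.dims != grid.dims:
            raise ValueError("mu_map grid does not match image grid")
        self.grid = grid
        self.geometry = geometry
        self.cdrf = cdrf
        self.mu_map = mu_map
        self.psf = psf
        self.attenuation = attenuation
        self._plane_dims = grid.dims[-2:]
        self.n_depth = self._plane_dims[0]
        self._build()

    # ------------------------------------------------------------------
    def _build(self) -> None:
        geo = self.geometry
        grid = self.grid
        ny, nx = self._plane_dims
        vox = grid.voxel_size_mm
        u_coords = (np.arange(ny) - (ny - 1) / 2.0) * vox  # depth axis
        t_coords = geo.bin_coords_mm()
        self._u_coords = u_coords
        self._scale = vox / 10.0  # ray-step length in cm

        yy, xx = np.meshgrid(
            (np.arange(ny) - (ny - 1) / 2.0) * vox,
            (np.arange(nx) - (nx - 1) / 2.0) * vox,
            indexing="ij",
        )

        # Each image voxel is splatted bilinearly onto the detector-aligned
        # (depth u, transaxial t) lattice: the splat matrix is the transpose
        # of bilinear sampling, so its columns sum to 1 and forward
        # projection conserves mass exactly for in-field activity.
        self._rot: List[sparse.csr_matrix] = []
        self._rot_t: List[sparse.csr_matrix] = []
        for ang in np.deg2rad(geo.angles_deg):
            u = np.cos(ang) * yy + np.sin(ang) * xx  # toward the detector
            t = -np.sin(ang) * yy + np.cos(ang) * xx  # along the bins
            fu = u / vox + (ny - 1) / 2.0
            ft = t / geo.bin_size_mm + (geo.n_bins - 1) / 2.0
            B = self._bilinear_matrix(fu.ravel(), ft.ravel(), ny, geo.n_bins)
            self._rot.append(B.T.tocsr())
            self._rot_t.append(B)

        # per-view CDRF kernels, one per depth row
        self._kernels: List[List[np.ndarray]] = []
        for v in range(geo.n_views):
            if self.psf:
                d = np.clip(geo.radii_mm[v] - u_coords, 0.0, None)
                sig = self.cdrf.sigma_mm(d) / geo.bin_size_mm
                self._kernels.append([_gaussian_kernel(s) for s in sig])
            else:
                self._kernels.append([np.ones(1)] * ny)

        # per-view attenuation weights on the detector frame
        self._atten: List[Optional[np.ndarray]] = []
        if self.attenuation:
            mu = self.mu_map.values
            mu_planes = mu[None] if mu.ndim == 2 else mu
            for v in range(geo.n_views):
                R = self._rot[v]
                w = np.empty((mu_planes.shape[0], ny, geo.n_bins))
                for z in range(mu_planes.shape[0]):
                    mur = (R @ mu_planes[z].ravel()).reshape(ny, geo.n_bins)
                    # cumulative path towards the detector (+depth side),
                    # counting half of the emitting voxel itself
                    beyond = np.cumsum(mur[::-1], axis=0)[::-1] - mur
                    w[z] = np.exp(-self._scale * (beyond + 0.5 * mur))
                self._atten.append(w if mu.ndim == 3 else w[0])
        else:
            self._atten = [None] * geo.n_views

    @staticmethod
    def _bilinear_matrix(fy: np.ndarray, fx: np.ndarray, ny: int, nx: int) -> sparse.csr_matrix:
        """Sparse matrix sampling a (ny, nx) image at fractional points."""
        n_out = fy.size
        iy0 = np.floor(fy).astype(int)
        ix0 = np.floor(fx).astype(int)
        wy = fy - iy0
        wx = fx - ix0
        rows, cols, vals = [], [], []
        out_idx = np.arange(n_out)
        for dy, dx, w in (
            (0, 0, (1 - wy) * (1 - wx)),
            (0, 1, (1 - wy) * wx),
            (1, 0, wy * (1 - wx)),
            (1, 1, wy * wx),
        ):
            yy = iy0 + dy
            xx = ix0 + dx
            ok = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx) & (w > 0)
            rows.append(out_idx[ok])
            cols.append((yy * nx + xx)[ok])
            vals.append(w[ok])
        M = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_out, ny * nx),
        )
        return M.tocsr()

    # ------------------------------------------------------------------
    def _forward_view_plane(self, plane: np.ndarray, v: int, atten) -> np.ndarray:
        geo = self.geometry
        rot = (self._rot[v] @ plane.ravel()).reshape(self.n_depth, geo.n_bins)
        if atten is not None:
            rot = rot * atten
        out = np.zeros(geo.n_bins)
        kerns = self._kernels[v]
        for i in range(self.n_depth):
            out += _convolve_same(rot[i], kerns[i])
        return out * self._scale

    def _back_view_plane(self, proj: np.ndarray, v: int, atten) -> np.ndarray:
        geo = self.geometry
        tmp = np.empty((self.n_depth, geo.n_bins))
        kerns = self._kernels[v]
        for i in range(self.n_depth):
            tmp[i] = _convolve_same(proj, kerns[i])
        if atten is not None:
            tmp = tmp * atten
        return (self._rot_t[v] @ tmp.ravel()).reshape(self._plane_dims) * self._scale

    def _forward_view_volume(self, vol: np.ndarray, v: int) -> np.ndarray:
        from scipy.ndimage import convolve1d

        geo = self.geometry
        nz = vol.shape[0]
        flat = vol.reshape(nz, -1)
        rot = (self._rot[v] @ flat.T).T.reshape(nz, self.n_depth, geo.n_bins)
        atten = self._atten[v]
        if atten is not None:
            rot = rot * atten
        out = np.zeros((nz, geo.n_bins))
        kerns = self._kernels[v]
        for i in range(self.n_depth):
            sl = rot[:, i, :]
            k = kerns[i]
            if k.size > 1:
                sl = convolve1d(sl, k, axis=1, mode="constant")
                sl = convolve1d(sl, k, axis=0, mode="constant")
            out += sl
        return out * self._scale

    def _back_view_volume(self, proj: np.ndarray, v: int) -> np.ndarray:
        from scipy.ndimage import convolve1d

        geo = self.geometry
        nz = proj.shape[0]
        tmp = np.empty((nz, self.n_depth, geo.n_bins))
        kerns = self._kernels[v]
        for i in range(self.n_depth):
            sl = proj
            k = kerns[i]
            if k.size > 1:
                sl = convolve1d(sl, k, axis=0, mode="constant")
                sl = convolve1d(sl, k, axis=1, mode="constant")
            tmp[:, i, :] = sl
        atten = self._atten[v]
        if atten is not None:
            tmp = tmp * atten
        flat = (self._rot_t[v] @ tmp.reshape(nz, -1).T).T
        return flat.reshape((nz,) + self._plane_dims) * self._scale

    # ------------------------------------------------------------------
    def forward(self, values: np.ndarray, views: Optional[Sequence[int]] = None) -> np.ndarray:
        """Forward-project an image array over the given views (all by
        default); returns the sinogram array restricted to those views."""
        if values.shape != self.grid.dims:
            raise ValueError("image shape does not match system grid")
        geo = self.geometry
        views = range(geo.n_views) if views is None else views
        views = list(views)
        if self.grid.ndim == 2:
            out = np.zeros((len(views), geo.n_bins))
            for k, v in enumerate(views):
                out[k] = self._forward_view_plane(values, v, self._atten[v])
        else:
            nz = self.grid.dims[0]
            out = np.zeros((len(views), nz, geo.n_bins))
            for k, v in enumerate(views):
                out[k] = self._forward_view_volume(values, v)
        return out

    def back(self, proj: np.ndarray, views: Optional[Sequence[int]] = None) -> np.ndarray:
        """Adjoint of :meth:`forward` over the same views."""
        geo = self.geometry
        views = range(geo.n_views) if views is None else views
        views = list(views)
        if len(proj) != len(views):
            raise ValueError("projection first axis must match the view list")
        out = np.zeros(self.grid.dims)
        if self.grid.ndim == 2:
            for k, v in enumerate(views):
                out += self._back_view_plane(proj[k], v, self._atten[v])
        else:
            for k, v in enumerate(views):
                out += self._back_view_volume(proj[k], v)
        return out

    def sino_shape(self) -> Tuple[int, ...]:
        geo = self.geometry
        if self.grid.ndim == 2:
            return (geo.n_views, geo.n_bins)
        return (geo.n_views, self.grid.dims[0], geo.n_bins)


def forward_project(image: ActivityImage, system: SystemModel) -> Sinogram:
    """Project an activity image into noise-free projection data."""
    if image.grid.dims != system.grid.dims:
        raise ValueError("image grid does not match system grid")
    return Sinogram(system.forward(image.values), system.geometry)


def back_project(sino: Sinogram, system: SystemModel) -> ActivityImage:
    """Exact adjoint of :func:`forward_project` (not an inverse)."""
    if sino.values.shape != system.sino_shape():
        raise ValueError("sinogram shape does not match system")
    vals = system.back(sino.values)
    return ActivityImage(system.grid, np.clip(vals, 0.0, None), role="reconstruction")


def sensitivity_image(system: SystemModel, views: Optional[Sequence[int]] = None,
                      mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Back-projection of an all-ones sinogram over the given views.

    This is the EM normalisation term (column sums of the system
    matrix).  Raises if the sensitivity vanishes anywhere inside the
    mask, which would make the EM update undefined there.
    """
    geo = system.geometry
    views = list(range(geo.n_views)) if views is None else list(views)
    shape = system.sino_shape()
    ones = np.ones((len(views),) + shape[1:])
    sens = system.back(ones, views)
    if mask is not None and np.any(sens[mask] <= 0):
        raise ValueError("zero sensitivity inside the reconstruction mask")
    return sens
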