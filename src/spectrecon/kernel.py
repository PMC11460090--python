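"""Hybrid PET/SPECT similarity kernel for kernelised EM reconstruction.

Each image voxel f is expressed as a weighted combination of its
neighbours j inside an NN x NN (x NN) search window,

    x = K alpha,    K[f, j] = k_p(f, j) * k_s(f, j),

where the PET factor ``k_p`` compares intensities in a fixed prior
image and the SPECT factor ``k_s`` compares intensities in the current
update image, each multiplied by a radial Gaussian in the voxel-to-
voxel Euclidean distance:

    k_p = exp(-(v_f - v_j)^2 / (2 sigma_p^2 SD_v^2))
          * exp(-d_fj^2 / (2 sigma_dp^2))
    k_s = exp(-(z_f - z_j)^2 / (2 sigma_s^2 SD_z^2))
          * exp(-d_fj^2 / (2 sigma_ds^2))

Intensity differences are normalised to the (population) standard
deviation of the respective image over the reconstruction mask, and
distances d_fj are in voxel units.  Rows are normalised to unit sum by
default so that K leaves a constant image unchanged.

A constant image has zero SD; its intensity factor is then set to 1
(the documented degenerate rule), which makes the kernel a pure
distance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .grid import ActivityImage

__all__ = ["KernelParams", "KernelOperator", "build_hybrid_kernel"]


@dataclass(frozen=True)
class KernelParams:
    """The five adjustable kernel parameters.

    sigma_p, sigma_s : intensity weights for the prior and the update
        image (dimensionless; multiply the image SD).
    sigma_dp, sigma_ds : Euclidean distance weights in voxel units.
    nn : odd edge length of the search window (NN^2 neighbours in 2D,
        NN^3 in 3D); nn=1 gives the identity kernel.
    row_normalize : scale each kernel row to unit sum.
    intensity_norm : support for the SD that normalises intensity
        differences: "image-sd" (SD over the whole image, the
        convention the printed prior SDs follow), "mask-sd" (SD over
        the reconstruction mask only) or "none" (raw differences).
    sd_prior, sd_estimate : explicit normalisation scales overriding
        the computed SD.  ``sd_prior`` defaults to the scale the prior
        image itself carries (its whole-3D-volume SD) when available.
    """

    sigma_p: float = 1.0
    sigma_s: float = 1.0
    sigma_dp: float = 5.0
    sigma_ds: float = 5.0
    nn: int = 5
    row_normalize: bool = True
    intensity_norm: str = "image-sd"
    sd_prior: Optional[float] = None
    sd_estimate: Optional[float] = None

    def __post_init__(self):
        if min(self.sigma_p, self.sigma_s, self.sigma_dp, self.sigma_ds) <= 0:
            raise ValueError("all kernel sigmas must be positive")
        if self.nn < 1 or self.nn % 2 == 0:
            raise ValueError("nn must be odd and >= 1")
        if self.intensity_norm not in ("image-sd", "mask-sd", "none"):
            raise ValueError("intensity_norm must be 'image-sd', 'mask-sd' or 'none'")


def _offsets(nn: int, ndim: int) -> List[Tuple[int, ...]]:
    h = nn // 2
    return list(product(range(-h, h + 1), repeat=ndim))


def _shift_pair(shape, off):
    """Index slices so that a[src] aligns voxel f with neighbour f+off."""
    dst, src = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            dst.append(slice(0, n - o))
            src.append(slice(o, n))
        else:
            dst.append(slice(-o, n))
            src.append(slice(0, n + o))
    return tuple(dst), tuple(src)


def _image_sd(values: np.ndarray, mask: Optional[np.ndarray], norm: str) -> float:
    """Population SD (ddof=0) over the chosen support; 1.0 for 'none'."""
    if norm == "none":
        return 1.0
    v = values[mask] if norm == "mask-sd" and mask is not None else values.ravel()
    return float(np.std(v))


def _intensity_factor(values, off, sigma, sd, shape):
    """exp(-(v_f - v_j)^2 / (2 sigma^2 sd^2)) on the valid f-region."""
    dst, src = _shift_pair(shape, off)
    out = np.zeros(shape)
    if sd <= 0:
        out[dst] = 1.0
        return out
    diff = (values[dst] - values[src]) / sd
    out[dst] = np.exp(-0.5 * (diff / sigma) ** 2)
    return out


class KernelOperator:
    """Sparse hybrid kernel over an image lattice.

    Wraps the row-stochastic (if normalised) sparse matrix K and the
    fixed prior-side factors so that only the SPECT-side factor needs
    recomputation when the update image changes.
    """

    def __init__(self, prior: np.ndarray, params: KernelParams,
                 mask: Optional[np.ndarray] = None,
                 sd_prior: Optional[float] = None):
        self.shape = prior.shape
        self.ndim = prior.ndim
        self.params = params
        self.mask = np.ones(self.shape, dtype=bool) if mask is None else mask.astype(bool)
        self.n = int(np.prod(self.shape))
        self._offs = _offsets(params.nn, self.ndim)
        self._dist2 = [float(sum(o * o for o in off)) for off in self._offs]
        if params.sd_prior is not None:
            sd_p = params.sd_prior
        elif sd_prior is not None:
            sd_p = sd_prior
        else:
            sd_p = _image_sd(prior, self.mask, params.intensity_norm)
        # fixed prior-side factor per offset: k_p intensity x both distance terms
        self._prior_part: List[np.ndarray] = []
        inv2dp = 0.5 / params.sigma_dp ** 2
        inv2ds = 0.5 / params.sigma_ds ** 2
        for off, d2 in zip(self._offs, self._dist2):
            w = _intensity_factor(prior, off, params.sigma_p, sd_p, self.shape)
            w *= np.exp(-d2 * inv2dp) * np.exp(-d2 * inv2ds)
            self._prior_part.append(w)
        self._flat_mask = self.mask.ravel()
        self._build_structure()
        self.matrix: sparse.csr_matrix = sparse.identity(self.n, format="csr")
        self.update(prior)  # placeholder estimate; callers update() again

    def _build_structure(self) -> None:
        """Precompute the fixed sparsity pattern and per-entry index maps.

        The pattern never changes between updates (it is set by the
        window and the mask), so each rebuild only recomputes the data
        vector: entry e couples voxel f = _rows[e] to neighbour
        j = _cols[e] with weight prior_part[e] * k_s(e).
        """
        if self.params.nn == 1:
            self._rows = self._cols = self._wp = None
            return
        flat_idx = np.arange(self.n).reshape(self.shape)
        rows_l, cols_l, wp_l = [], [], []
        for off, wp in zip(self._offs, self._prior_part):
            dst, src = _shift_pair(self.shape, off)
            valid = np.zeros(self.shape, dtype=bool)
            valid[dst] = self.mask[dst] & self.mask[src]  # mask both ends
            r = flat_idx[valid]
            shift = flat_idx[src].ravel()[0] - flat_idx[dst].ravel()[0]
            rows_l.append(r)
            cols_l.append(r + shift)
            wp_l.append(wp[valid])
        # identity entries keep voxels outside the mask inert
        out_idx = np.nonzero(~self._flat_mask)[0]
        rows_l.append(out_idx)
        cols_l.append(out_idx)
        wp_l.append(np.ones(out_idx.size))
        rows = np.concatenate(rows_l)
        cols = np.concatenate(cols_l)
        self._wp = np.concatenate(wp_l)
        order = np.lexsort((cols, rows))
        self._order = order
        self._rows = rows
        self._cols = cols
        self._indices = cols[order]
        self._indptr = np.concatenate(
            ([0], np.cumsum(np.bincount(rows, minlength=self.n)))
        ).astype(np.int64)

    def update(self, estimate: np.ndarray) -> None:
        """Rebuild the SPECT-side factor from the current update image."""
        p = self.params
        if p.nn == 1:
            self.matrix = sparse.identity(self.n, format="csr")
            return
        sd_s = (p.sd_estimate if p.sd_estimate is not None
                else _image_sd(estimate, self.mask, p.intensity_norm))
        est = estimate.ravel()
        if sd_s > 0:
            diff = (est[self._rows] - est[self._cols]) / (sd_s * p.sigma_s)
            data = self._wp * np.exp(-0.5 * diff * diff)
        else:  # constant estimate: intensity factor 1 (degenerate rule)
            data = self._wp.copy()
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite kernel weights")
        data = data[self._order]
        K = sparse.csr_matrix((data, self._indices, self._indptr),
                              shape=(self.n, self.n))
        if p.row_normalize:
            rs = np.add.reduceat(data, self._indptr[:-1],
                                 dtype=float)
            rs[np.diff(self._indptr) == 0] = 1.0
            inv = np.where(rs > 0, 1.0 / np.where(rs > 0, rs, 1.0), 0.0)
            K.data *= np.repeat(inv, np.diff(self._indptr))
        self.matrix = K

    # linear-operator surface -------------------------------------------------
    def apply(self, alpha: np.ndarray) -> np.ndarray:
        """x = K alpha (flattened in, flattened out)."""
        return self.matrix @ alpha

    def apply_adjoint(self, r: np.ndarray) -> np.ndarray:
        return self.matrix.T @ r

    def row(self, f: int) -> np.ndarray:
        return np.asarray(self.matrix[f].todense()).ravel()


def build_hybrid_kernel(
    prior: ActivityImage,
    estimate: ActivityImage,
    params: KernelParams,
    mask: Optional[np.ndarray] = None,
) -> KernelOperator:
    """Build K from a prior image and a current estimate on one grid.

    The prior's own normalisation scale (``prior.meta["sd"]``) is used
    for the PET-side intensity factor when present.
    """
    if prior.grid.dims != estimate.grid.dims:
        raise ValueError("prior and estimate must share the grid")
    sd = getattr(prior, "meta", {}).get("sd")
    op = KernelOperator(prior.values, params, mask, sd_prior=sd)
    op.update(estimate.values)
    return op
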