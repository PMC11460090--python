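"""Quantitative phantom metrics over truth-matched regions.

Implements the standard recovery/noise measures used to score
reconstructions against the known phantom concentrations:

* contrast recovery coefficient  CRC = ((x/B) - 1) / ((A_s/A_b) - 1)
* sphere SNR                     SNR = (x - B) / B_sigma
* RMSE                           sqrt(COV^2 RC^2 + (RC - 1)^2)
  (noise and bias contributions in quadrature, COV as a fraction)
* mean / max bias (%)            100 (x - A) / A

where x and B are image means over a sphere region and the background
region, A_s / A_b the true concentrations, RC the mean recovery and COV
the region coefficient of variation.  Region SDs use the n-1
denominator; single-voxel regions have undefined SD and are excluded
from SD-based metrics (RMSE is restricted to regions with at least
``rmse_min_voxels`` voxels, mirroring the exclusion of the smallest
spheres).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .grid import ActivityImage
from .phantom import ROIRegion, ROISet

__all__ = [
    "roi_stats",
    "crc",
    "snr",
    "rmse",
    "bias",
    "evaluate_image",
    "background_cov_percent",
    "MetricsReport",
]

RMSE_MIN_VOXELS = 20


def roi_stats(image: ActivityImage, roi: ROIRegion) -> Dict[str, float]:
    """Mean, max, SD (ddof=1) and voxel count over one region."""
    vals = image.values[roi.indices]
    if vals.size == 0:
        raise ValueError("empty ROI")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return {"mean": float(vals.mean()), "max": float(vals.max()), "sd": sd, "n": int(vals.size)}


def crc(mean_voi: float, bkg_mean: float, a_sphere: float, a_bkg: float) -> float:
    """Contrast recovery coefficient; 1 at perfect recovery."""
    if bkg_mean <= 0:
        raise ValueError("background mean must be positive")
    if a_sphere == a_bkg:
        raise ValueError("true sphere and background concentrations must differ")
    return ((mean_voi / bkg_mean) - 1.0) / ((a_sphere / a_bkg) - 1.0)


def snr(mean_voi: float, bkg_mean: float, bkg_sd: float) -> float:
    """Sphere signal-to-noise ratio against background noise."""
    if not bkg_sd > 0:
        raise ValueError("background SD must be positive")
    return (mean_voi - bkg_mean) / bkg_sd


def rmse(cov_fraction: float, rc: float) -> float:
    """Root-mean-square error of the noise-bias decomposition.

    ``cov_fraction`` is the region COV as a fraction (not %), ``rc``
    the mean recovery coefficient.
    """
    if cov_fraction < 0 or rc < 0:
        raise ValueError("cov and rc must be nonnegative")
    return float(np.sqrt((cov_fraction * rc) ** 2 + (rc - 1.0) ** 2))


def bias(mean_voi: float, max_voi: float, a_true: float) -> Dict[str, float]:
    """Mean and maximum bias in percent of the true concentration."""
    if a_true <= 0:
        raise ValueError("true concentration must be positive")
    return {
        "mean_bias_pct": 100.0 * (mean_voi - a_true) / a_true,
        "max_bias_pct": 100.0 * (max_voi - a_true) / a_true,
    }


def background_cov_percent(image: ActivityImage, roiset: ROISet) -> float:
    """100 x SD/mean over the background region."""
    st = roi_stats(image, roiset.background)
    return 100.0 * st["sd"] / st["mean"]


@dataclass
class MetricsReport:
    """Tidy per-region metrics table with the truth carried along."""

    table: pd.DataFrame

    def region(self, name: str) -> pd.Series:
        return self.table.set_index("region").loc[name]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def evaluate_image(
    image: ActivityImage,
    roiset: ROISet,
    rmse_min_voxels: int = RMSE_MIN_VOXELS,
) -> pd.DataFrame:
    """Score one reconstruction over every region of a ROI set.

    Returns one row per region with mean/max/SD, COV %, CRC, SNR, RMSE
    (only for sphere regions with >= ``rmse_min_voxels`` voxels),
    recovery coefficients and mean/max bias %.
    """
    bstats = roi_stats(image, roiset.background)
    a_bkg = roiset.background.true_kbq_ml
    rows = []
    for name, roi in roiset.regions.items():
        st = roi_stats(image, roi)
        a_true = roi.true_kbq_ml
        b = bias(st["mean"], st["max"], a_true)
        rc_mean = st["mean"] / a_true
        rc_max = st["max"] / a_true
        cov = 100.0 * st["sd"] / st["mean"] if st["n"] > 1 and st["mean"] > 0 else np.nan
        row = {
            "region": name,
            "kind": roi.kind,
            "n_voxels": st["n"],
            "mean": st["mean"],
            "max": st["max"],
            "sd": st["sd"],
            "cov_pct": cov,
            "rc_mean": rc_mean,
            "rc_max": rc_max,
            "mean_bias_pct": b["mean_bias_pct"],
            "max_bias_pct": b["max_bias_pct"],
            "true_kbq_ml": a_true,
        }
        if roi.kind == "sphere":
            row["crc"] = crc(st["mean"], bstats["mean"], a_true, a_bkg)
            # SNR undefined on a noiseless background (SD = 0)
            row["snr"] = (snr(st["mean"], bstats["mean"], bstats["sd"])
                          if bstats["sd"] > 0 else np.nan)
            if st["n"] >= rmse_min_voxels and np.isfinite(cov):
                row["rmse"] = rmse(cov / 100.0, rc_mean)
            else:
                row["rmse"] = np.nan
        else:
            row["crc"] = np.nan
            row["snr"] = np.nan
            row["rmse"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
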