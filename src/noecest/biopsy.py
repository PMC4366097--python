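"""Biopsy-site MRI readout and correlation with histologic cell density.

Biopsy coordinates live in world (scanner) space; each site is mapped to its
nearest voxel and the MTR_asym and ADC values are averaged over the
surrounding 3x3x3 voxels to absorb residual registration and sampling
inaccuracy.  Cell density is then rank-correlated with both averaged
contrasts, and an ordinary least-squares line is fitted for the scatterplot
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .region_stats import spearman

#: Fig-5 style region tags, from the phantom tissue label at the site.
REGION_TAGS = {
    "CE_TUMOR": "contrast-enhancing",
    "NECROSIS": "necrotic",
}
DEFAULT_TAG = "non-enhancing"


class InsufficientDataError(ValueError):
    """Raised when fewer than 5 complete biopsy samples are available."""


def world_to_voxel(
    world_mm, affine: np.ndarray, shape: tuple[int, int, int] | None = None
) -> tuple[int, int, int]:
    """Nearest 0-based voxel index of a world coordinate (voxel-center convention).

    With ``shape`` given, raises IndexError for out-of-volume points.
    """
    inv = np.linalg.inv(np.asarray(affine, float))
    w = np.append(np.asarray(world_mm, float), 1.0)
    v = inv @ w
    ijk = tuple(int(i) for i in np.rint(v[:3]))
    if shape is not None and not all(0 <= ijk[d] < shape[d] for d in range(3)):
        raise IndexError(f"world point {tuple(world_mm)} maps outside the volume: {ijk}")
    return ijk


def neighborhood_mean(
    volume: np.ndarray, center: tuple[int, int, int], radius: int = 1
) -> tuple[float, int]:
    """Mean over the (2r+1)^3 cube around ``center``, clipped to the volume.

    Non-finite voxels are excluded; returns (mean, n_used), with
    (nan, 0) when every voxel of the cube is non-finite.
    """
    if not all(0 <= center[d] < volume.shape[d] for d in range(3)):
        raise IndexError(f"center {center} outside volume of shape {volume.shape}")
    sl = tuple(
        slice(max(0, c - radius), min(s, c + radius + 1))
        for c, s in zip(center, volume.shape)
    )
    cube = volume[sl]
    finite = np.isfinite(cube)
    n = int(finite.sum())
    if n == 0:
        return float("nan"), 0
    return float(cube[finite].mean()), n


def read_out_biopsies(
    samples: pd.DataFrame,
    mtr_values_percent: np.ndarray,
    adc: np.ndarray,
    affine: np.ndarray,
    label_map: np.ndarray | None = None,
    radius: int = 1,
) -> pd.DataFrame:
    """Attach neighborhood-averaged MRI values to a biopsy sample table.

    Expects the CSV schema written by the phantom module (x_mm, y_mm, z_mm,
    cell_density_per_mm3, ...).  Adds mtr_asym_mean_percent, adc_mean,
    n_voxels_used and a region tag.
    """
    out = samples.copy()
    mtr_means, adc_means, n_used, tags = [], [], [], []
    for _, row in samples.iterrows():
        world = (row["x_mm"], row["y_mm"], row["z_mm"])
        try:
            ijk = world_to_voxel(world, affine, shape=mtr_values_percent.shape)
        except IndexError:
            mtr_means.append(np.nan)
            adc_means.append(np.nan)
            n_used.append(0)
            tags.append("outside")
            continue
        m, nm = neighborhood_mean(mtr_values_percent, ijk, radius)
        a, _ = neighborhood_mean(adc, ijk, radius)
        mtr_means.append(m)
        adc_means.append(a)
        n_used.append(nm)
        if label_map is not None:
            from .phantom import Tissue

            tags.append(REGION_TAGS.get(Tissue(int(label_map[ijk])).name, DEFAULT_TAG))
        else:
            tags.append(DEFAULT_TAG)
    out["mtr_asym_mean_percent"] = mtr_means
    out["adc_mean"] = adc_means
    out["n_voxels_used"] = n_used
    out["region_tag"] = tags
    return out


@dataclass
class BiopsyCorrelation:
    """Cell-density correlations of one biopsy series (one Table-2 row)."""

    n_samples: int
    r_sp_mtr_cell: float
    p_mtr_cell: float
    r_sp_adc_cell: float
    p_adc_cell: float
    max_cell_density: float
    regression_mtr: dict
    regression_adc: dict


def _ols(x: np.ndarray, y: np.ndarray) -> dict:
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }


def correlate_biopsies(samples: pd.DataFrame) -> BiopsyCorrelation:
    """Spearman and OLS of cell density against MTR_asym and ADC.

    Uses only rows with finite cell density and MRI means; raises
    InsufficientDataError below 5 complete samples.
    """
    needed = ["cell_density_per_mm3", "mtr_asym_mean_percent", "adc_mean"]
    sub = samples.dropna(subset=needed)
    sub = sub[np.isfinite(sub[needed]).all(axis=1)]
    if len(sub) < 5:
        raise InsufficientDataError(
            f"need at least 5 complete biopsy samples, got {len(sub)}"
        )
    cell = sub["cell_density_per_mm3"].to_numpy()
    mtr = sub["mtr_asym_mean_percent"].to_numpy()
    adc = sub["adc_mean"].to_numpy()
    r_m, p_m = spearman(cell, mtr)
    r_a, p_a = spearman(cell, adc)
    return BiopsyCorrelation(
        n_samples=len(sub),
        r_sp_mtr_cell=r_m,
        p_mtr_cell=p_m,
        r_sp_adc_cell=r_a,
        p_adc_cell=p_a,
        max_cell_density=float(cell.max()),
        regression_mtr=_ols(mtr, cell),
        regression_adc=_ols(adc, cell),
    )
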