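"""ROI handling and the voxelwise MTR_asym-vs-ADC correlation statistics.

Per subject and region of interest (contrast-enhancing tumor on CE-T1,
peritumoral edema on T2) the analysis pairs each voxel's MTR_asym value with
its registered ADC value, computes the Spearman rank correlation with a
t-distribution p-value, attaches the Bonett-Wright 95% confidence interval
(Fisher z with standard error sqrt((1 + r^2/2)/(n - 3))), and assigns an
association class.  Classification mirrors the interpretation used for this
contrast pair: insignificant p or |r| <= 0.15 count as no association;
0.15 < |r| < 0.40 is weak, 0.40 <= |r| < 0.65 moderate, |r| >= 0.65 strong,
signed by the direction of the correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ASSOCIATION_CLASSES = (
    "positive-weak",
    "positive-moderate",
    "positive-strong",
    "negative-weak",
    "negative-moderate",
    "negative-strong",
    "none-negligible",
    "none-insignificant",
)

#: |r| band edges: (negligible, weak->moderate, moderate->strong)
DEFAULT_BANDS = (0.15, 0.40, 0.65)


class DegenerateDataError(ValueError):
    """Raised when a correlation is requested on constant or too-short input."""


@dataclass
class RoiMaskSet:
    """Binary ROI masks on the common reference grid.

    The edema ROI excludes contrast enhancement and necrosis by definition,
    so ``ce_t1_tumor`` and ``t2_edema`` must be disjoint.
    """

    ce_t1_tumor: np.ndarray
    t2_edema: np.ndarray
    swi_exclusion: np.ndarray
    necrosis: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            m.shape
            for m in (self.ce_t1_tumor, self.t2_edema, self.swi_exclusion, self.necrosis)
        }
        if len(shapes) != 1:
            raise ValueError("all ROI masks must share one grid shape")
        if np.any(self.ce_t1_tumor & self.t2_edema):
            raise ValueError("CE-T1 tumor and T2 edema ROIs must be disjoint")


@dataclass
class CorrelationResult:
    """One ROI of one subject: the voxelwise correlation and its class."""

    patient: str
    roi: str
    r_sp: float
    p_value: float
    n_voxels: int
    ci95: tuple[float, float]
    association_class: str


def apply_exclusions(rois: RoiMaskSet) -> RoiMaskSet:
    """Remove SWI-hypointensity and necrosis voxels from both ROIs.

    Micro-bleeds (SWI signal voids) bias ADC and are eliminated from the
    analysis; necrotic voxels never belong to either ROI.  Emits a warning
    if an ROI is emptied entirely.
    """
    drop = rois.swi_exclusion | rois.necrosis
    ce = rois.ce_t1_tumor & ~drop
    ed = rois.t2_edema & ~drop
    for name, before, after in (
        ("CE-T1 tumor", rois.ce_t1_tumor, ce),
        ("T2 edema", rois.t2_edema, ed),
    ):
        if before.any() and not after.any():
            warnings.warn(f"exclusion masks removed every voxel of the {name} ROI")
    return RoiMaskSet(
        ce_t1_tumor=ce, t2_edema=ed, swi_exclusion=rois.swi_exclusion, necrosis=rois.necrosis
    )


def extract_pairs(
    mtr_values_percent: np.ndarray, adc: np.ndarray, rois: RoiMaskSet
) -> pd.DataFrame:
    """Voxelwise (MTR_asym, ADC) readout table over the cleaned ROIs.

    One row per ROI voxel where both maps are finite; the number of rows
    dropped for non-finite values is recorded in ``df.attrs['n_dropped']``
    per ROI.
    """
    if mtr_values_percent.shape != adc.shape or adc.shape != rois.ce_t1_tumor.shape:
        raise ValueError("MTR_asym, ADC and ROI masks must share one grid")
    frames = []
    dropped = {}
    for name, mask in (("ce_t1_tumor", rois.ce_t1_tumor), ("t2_edema", rois.t2_edema)):
        ijk = np.argwhere(mask)
        m = mtr_values_percent[mask]
        a = adc[mask]
        ok = np.isfinite(m) & np.isfinite(a)
        dropped[name] = int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "i": ijk[ok, 0],
                    "j": ijk[ok, 1],
                    "k": ijk[ok, 2],
                    "mtr_asym_percent": m[ok],
                    "adc": a[ok],
                    "roi": name,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.attrs["n_dropped"] = dropped
    return df


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Mid-ranks for ties; p from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom, two-sided.  Raises DegenerateDataError for n < 4 or constant
    input rather than returning a meaningless r = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 4:
        raise DegenerateDataError(f"need at least 4 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant input has no defined rank correlation")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)


def spearman_exact_formula(x, y) -> float:
    """Classical 1 - 6*sum(d^2)/(n(n^2-1)) (valid without ties); test oracle."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    d2 = np.sum((rx - ry) ** 2)
    return 1.0 - 6.0 * d2 / (n * (n * n - 1.0))


def bonett_wright_ci(r_sp: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Bonett-Wright confidence interval for a Spearman coefficient.

    Fisher z-transform of r with standard error sqrt((1 + r^2/2)/(n - 3)),
    symmetric normal interval in z, back-transformed through tanh.
    """
    if n <= 4:
        raise ValueError("Bonett-Wright interval needs n > 4")
    if not -1.0 < r_sp < 1.0:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    zr = np.arctanh(r_sp)
    se = np.sqrt((1.0 + r_sp * r_sp / 2.0) / (n - 3))
    q = sps.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(zr - q * se)), float(np.tanh(zr + q * se))


def classify_association(
    r_sp: float,
    p_value: float,
    alpha: float = 0.05,
    bands: tuple[float, float, float] = DEFAULT_BANDS,
) -> str:
    """Map one (r, p) pair to its association class.

    p > alpha -> none-insignificant; |r| <= bands[0] -> none-negligible;
    otherwise the sign of r with the magnitude band weak/moderate/strong.
    """
    if not -1.0 <= r_sp <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    negligible, weak_hi, moderate_hi = bands
    if p_value > alpha:
        return "none-insignificant"
    mag = abs(r_sp)
    if mag <= negligible:
        return "none-negligible"
    sign = "positive" if r_sp > 0 else "negative"
    if mag < weak_hi:
        return f"{sign}-weak"
    if mag < moderate_hi:
        return f"{sign}-moderate"
    return f"{sign}-strong"


def correlate_roi(
    pairs: pd.DataFrame,
    roi: str,
    patient: str = "synthetic",
    alpha: float = 0.05,
    bands: tuple[float, float, float] = DEFAULT_BANDS,
) -> CorrelationResult:
    """Spearman + CI + class for one ROI of one subject's pair table."""
    sub = pairs[pairs["roi"] == roi]
    r, p = spearman(sub["mtr_asym_percent"].to_numpy(), sub["adc"].to_numpy())
    ci = bonett_wright_ci(r, len(sub)) if abs(r) < 1.0 and len(sub) > 4 else (r, r)
    return CorrelationResult(
        patient=patient,
        roi=roi,
        r_sp=r,
        p_value=p,
        n_voxels=len(sub),
        ci95=ci,
        association_class=classify_association(r, p, alpha=alpha, bands=bands),
    )


def summarize_cohort(results: list[CorrelationResult]) -> dict:
    """Per-ROI counts of each association class plus the coefficient lists.

    Returns a JSON-ready dict; ``cohort_table`` is the row-per-result layout
    used for the CSV export.
    """
    if not results:
        raise ValueError("at least one correlation result is required")
    per_roi: dict[str, dict] = {}
    for res in results:
        entry = per_roi.setdefault(
            res.roi,
            {"counts": {c: 0 for c in ASSOCIATION_CLASSES}, "r_values": []},
        )
        entry["counts"][res.association_class] += 1
        entry["r_values"].append(res.r_sp)
    for entry in per_roi.values():
        cnt = entry["counts"]
        entry["n_positive"] = sum(cnt[f"positive-{b}"] for b in ("weak", "moderate", "strong"))
        entry["n_negative"] = sum(cnt[f"negative-{b}"] for b in ("weak", "moderate", "strong"))
        entry["n_none"] = cnt["none-negligible"] + cnt["none-insignificant"]
    table = pd.DataFrame(
        {
            "patient": [r.patient for r in results],
            "roi": [r.roi for r in results],
            "r_sp": [r.r_sp for r in results],
            "p": [r.p_value for r in results],
            "n": [r.n_voxels for r in results],
            "ci_lo": [r.ci95[0] for r in results],
            "ci_hi": [r.ci95[1] for r in results],
            "class": [r.association_class for r in results],
        }
    )
    return {"per_roi": per_roi, "cohort_table": table}
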