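"""Z-spectrum processing: normalization, B0 mapping and MTR_asym.

The chain implemented here is the standard asymmetry analysis for
NOE-dominated CEST at 7 T: the saturated signal M is normalized by the
unsaturated M0 to Z = M/M0; a cubic spline through the sampled Z-spectrum is
minimized within a search window to estimate the per-voxel B0 deviation; the
spectrum is re-interpolated at the shifted offsets to re-center water at
0 ppm; and the contrast

    MTR_asym(3.3 ppm) = Z(-3.3 ppm) - Z(+3.3 ppm)

is read out by spline interpolation of the corrected spectrum, stored in
percent.  On the 13-point equidistant grid between -4 and +4 ppm the node
closest to the nominal readout is 10/3 ppm, which is used as the default
readout offset.  High (less negative) MTR_asym marks decreased NOE-mediated
saturation.  Splines are natural cubic splines and are never extrapolated:
shifted offsets outside the acquired range become non-finite and drop out of
the analysis mask downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

READOUT_PPM = 10.0 / 3.0
DISPLAY_WINDOW = (-10.0, 5.0)


@dataclass
class ZSpectrumVolume:
    """Normalized Z = M/M0 stack with its offset axis, affine and mask."""

    data: np.ndarray  # (x, y, z, offset)
    offsets_ppm: np.ndarray
    affine: np.ndarray
    mask: np.ndarray  # (x, y, z) bool, analyzable voxels

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, float)
        if self.data.ndim != 4:
            raise ValueError("Z-spectrum data must be 4-D (x, y, z, offset)")
        if self.offsets_ppm.size != self.data.shape[3]:
            raise ValueError("offset axis length must match the 4th data dimension")
        if self.offsets_ppm.size > 1 and not np.all(np.diff(self.offsets_ppm) > 0):
            raise ValueError("offsets must be strictly increasing")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")


@dataclass
class B0Map:
    """Per-voxel water-center deviation (ppm) and a validity flag.

    A voxel is invalid when its spectral minimum hits the boundary of the
    search window, i.e. the minimum was not bracketed.
    """

    delta_ppm: np.ndarray
    valid: np.ndarray
    search_halfwidth_ppm: float


@dataclass
class MTRasymMap:
    """Asymmetry contrast in percent at a stated readout offset."""

    values_percent: np.ndarray
    readout_ppm: float
    window: tuple[float, float] = DISPLAY_WINDOW

    def __post_init__(self) -> None:
        if self.readout_ppm <= 0:
            raise ValueError("readout offset must be positive")
        lo, hi = self.window
        if lo >= hi:
            raise ValueError("display window must satisfy lo < hi")


def normalize(
    saturated: np.ndarray,
    m0: np.ndarray,
    offsets_ppm: np.ndarray,
    affine: np.ndarray | None = None,
    m0_floor_rel: float = 0.05,
) -> ZSpectrumVolume:
    """Voxelwise Z = M/M0 with a relative M0 floor.

    Voxels whose M0 falls below ``m0_floor_rel`` times the robust maximum
    (99th percentile) of M0 are excluded from the mask rather than forced to
    a value: background noise voxels would otherwise produce unbounded Z.
    """
    saturated = np.asarray(saturated, float)
    m0 = np.asarray(m0, float)
    if saturated.shape[:3] != m0.shape:
        raise ValueError(
            f"stack spatial shape {saturated.shape[:3]} does not match M0 {m0.shape}"
        )
    floor = m0_floor_rel * np.percentile(m0, 99.0)
    mask = m0 > max(floor, 0.0)
    z = np.full(saturated.shape, np.nan)
    z[mask] = saturated[mask] / m0[mask, None]
    if affine is None:
        affine = np.eye(4)
    return ZSpectrumVolume(data=z, offsets_ppm=np.asarray(offsets_ppm, float),
                           affine=np.asarray(affine, float), mask=mask)


def _spline_rows(offsets: np.ndarray, rows: np.ndarray) -> CubicSpline:
    """Natural cubic spline through each row of (n_vox, n_offsets)."""
    return CubicSpline(offsets, rows, axis=1, bc_type="natural")


def estimate_b0(
    z: ZSpectrumVolume,
    search_halfwidth_ppm: float = 1.0,
    grid_step_ppm: float = 0.001,
    chunk: int = 8192,
) -> B0Map:
    """B0 deviation map from the spline minima of the Z-spectra.

    Per masked voxel a natural cubic spline is fitted through the sampled
    spectrum and evaluated on a dense grid within +-search_halfwidth_ppm of
    0; the argmin is the water-center deviation.  Minima landing on the
    window boundary are flagged invalid.
    """
    offsets = z.offsets_ppm
    if offsets.size < 4:
        raise ValueError("B0 estimation needs at least 4 offsets")
    if not (offsets[0] < 0.0 < offsets[-1]):
        raise ValueError("offset grid must span 0 ppm")
    hw = float(search_halfwidth_ppm)
    dense = np.arange(-hw, hw + 0.5 * grid_step_ppm, grid_step_ppm)
    shape = z.data.shape[:3]
    delta = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    vox = np.argwhere(z.mask)
    rows = z.data[z.mask]
    ok_rows = np.all(np.isfinite(rows), axis=1)
    for start in range(0, len(rows), chunk):
        sel = slice(start, start + chunk)
        sub = rows[sel]
        sub_ok = ok_rows[sel]
        if not np.any(sub_ok):
            continue
        cs = _spline_rows(offsets, sub[sub_ok])
        vals = cs(dense)
        amin = np.argmin(vals, axis=1)
        d = dense[amin]
        interior = (amin > 0) & (amin < dense.size - 1)
        ii = vox[sel][sub_ok]
        delta[ii[:, 0], ii[:, 1], ii[:, 2]] = d
        valid[ii[:, 0], ii[:, 1], ii[:, 2]] = interior
    return B0Map(delta_ppm=delta, valid=valid, search_halfwidth_ppm=hw)


def _eval_spline_per_row(cs: CubicSpline, x_rows: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Evaluate row i of a vectorized spline at x_rows[i] (no extrapolation).

    ``cs`` interpolates rows along axis 1, coefficient array (4, n_seg, n_row).
    Points outside the acquired range come back NaN.
    """
    n_row, n_pts = x_rows.shape
    seg = np.clip(np.searchsorted(offsets, x_rows, side="right") - 1, 0, offsets.size - 2)
    dx = x_rows - offsets[seg]
    c = cs.c  # (4, n_seg, n_row)
    ridx = np.arange(n_row)[:, None]
    out = (
        ((c[0, seg, ridx] * dx + c[1, seg, ridx]) * dx + c[2, seg, ridx]) * dx
        + c[3, seg, ridx]
    )
    out[(x_rows < offsets[0]) | (x_rows > offsets[-1])] = np.nan
    return out


def correct_b0(z: ZSpectrumVolume, b0: B0Map, chunk: int = 8192) -> ZSpectrumVolume:
    """Re-center each spectrum at its estimated water frequency.

    The spectrum spline is re-interpolated at (offsets + delta) so the
    corrected minimum sits at 0 ppm.  Shifted offsets outside the acquired
    range are set non-finite; voxels with an invalid B0 estimate pass
    through unshifted but are removed from the mask.
    """
    if b0.delta_ppm.shape != z.data.shape[:3]:
        raise ValueError("B0 map shape does not match the Z-spectrum grid")
    offsets = z.offsets_ppm
    out = z.data.copy()
    usable = z.mask & b0.valid & np.isfinite(b0.delta_ppm)
    vox = np.argwhere(usable)
    rows = z.data[usable]
    deltas = b0.delta_ppm[usable]
    finite = np.all(np.isfinite(rows), axis=1)
    for start in range(0, len(rows), chunk):
        sel = slice(start, start + chunk)
        sub = rows[sel][finite[sel]]
        if sub.size == 0:
            continue
        cs = _spline_rows(offsets, sub)
        x_rows = offsets[None, :] + deltas[sel][finite[sel]][:, None]
        shifted = _eval_spline_per_row(cs, x_rows, offsets)
        ii = vox[sel][finite[sel]]
        out[ii[:, 0], ii[:, 1], ii[:, 2], :] = shifted
    return ZSpectrumVolume(
        data=out, offsets_ppm=offsets, affine=z.affine, mask=usable
    )


def compute_mtr_asym(z: ZSpectrumVolume, readout_ppm: float = READOUT_PPM) -> MTRasymMap:
    """MTR_asym(readout) = Z(-readout) - Z(+readout), in percent.

    Both sides are read by spline interpolation of the (corrected) spectrum;
    for voxels whose edge offsets became non-finite after B0 shifting, the
    spline uses the finite subset provided it still brackets +-readout with
    at least 4 points.  Negative values mean the upfield (NOE) dip exceeds
    the downfield one.
    """
    offsets = z.offsets_ppm
    r = float(readout_ppm)
    if not (offsets[0] <= -r and r <= offsets[-1]):
        raise ValueError(f"readout +-{r} ppm lies outside the offset range")
    shape = z.data.shape[:3]
    values = np.full(shape, np.nan)
    vox = np.argwhere(z.mask)
    rows = z.data[z.mask]
    finite = np.isfinite(rows)
    # Group voxels by their finite-offset pattern so each group is one
    # vectorized spline; after a bounded B0 shift only edge offsets drop out.
    patterns, inverse = np.unique(finite, axis=0, return_inverse=True)
    flat_vals = np.full(len(rows), np.nan)
    tol = 1e-9  # grid nodes may sit one ulp below the nominal readout
    for p_idx, pat in enumerate(patterns):
        members = inverse == p_idx
        xs = offsets[pat]
        if pat.sum() < 4 or xs[0] > -r + tol or xs[-1] < r - tol:
            continue
        cs = _spline_rows(xs, rows[members][:, pat])
        flat_vals[members] = 100.0 * (cs(-r) - cs(r))
    values[vox[:, 0], vox[:, 1], vox[:, 2]] = flat_vals
    return MTRasymMap(values_percent=values, readout_ppm=r)


def window_display(
    m: MTRasymMap, lo: float = DISPLAY_WINDOW[0], hi: float = DISPLAY_WINDOW[1]
) -> np.ndarray:
    """Clip the contrast to the display window (rendering only).

    Statistics always run on the unclipped values: clipping destroys ranks
    in the tails.
    """
    if lo >= hi:
        raise ValueError("display window must satisfy lo < hi")
    return np.clip(m.values_percent, lo, hi)
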