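"""Digital glioblastoma phantom for NOE-mediated CEST analysis.

Generates everything the downstream processing chain consumes without any
patient data: a tissue label map with the geometry of a rim-enhancing
glioblastoma (necrotic core inside a contrast-enhancing shell inside
peritumoral edema, embedded in normal-appearing white matter with a CSF
rim), per-voxel multi-pool Lorentzian Z-spectra, a smooth B0 offset field,
Rician-noise magnitude acquisition, ADC and cell-density fields whose rank
correlations with the local NOE amplitude are configurable, and stereotactic
biopsy trajectories.

The Z-spectrum generative model is a sum of Lorentzians

    Z(dw) = 1 - sum_k L_k(dw - dB0),   L_k(x) = A_k (G_k/2)^2 / ((G_k/2)^2 + (x - c_k)^2)

with a central pool lumping direct water saturation and residual semisolid
MT, an NOE pool upfield at -3.3 ppm and an amide (APT) pool at +3.5 ppm.
This analytic form is the ground-truth oracle against which the spline-based
processing chain is validated; saturation power and timing are carried as
metadata only (no Bloch-McConnell integration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


class Tissue(IntEnum):
    """Integer labels of the phantom tissue classes."""

    BACKGROUND = 0
    NAWM = 1
    EDEMA = 2
    CE_TUMOR = 3
    NECROSIS = 4
    CSF = 5


#: Tissue classes in the order of decreasing NOE amplitude stated for
#: glioblastoma (normal white matter -> edema -> enhancing tumor -> necrosis).
NOE_ORDER = (Tissue.NAWM, Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS)

#: Tissue classes in the order of increasing mean ADC.
ADC_ORDER = (Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS)


@dataclass(frozen=True)
class PoolSpec:
    """One saturation pool of the Lorentzian Z-spectrum model.

    Parameters
    ----------
    center_ppm : chemical-shift offset of the pool; water at 0 ppm,
        NOE upfield (negative), amide downfield (positive).
    amplitude : peak saturation depth as a fraction of Z, in [0, 1).
    width_ppm : full width at half maximum in ppm.
    """

    center_ppm: float
    amplitude: float
    width_ppm: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"pool amplitude must be >= 0, got {self.amplitude}")
        if self.width_ppm <= 0:
            raise ValueError(f"pool width must be > 0, got {self.width_ppm}")


@dataclass(frozen=True)
class AcquisitionParams:
    """Saturation-pulse-train and readout parameters of one CEST acquisition.

    b1_uT, n_pulses and the pulse timings are protocol metadata; only the
    offset list, the effective saturation time bookkeeping and noise_sigma
    (Rician noise scale relative to M0) influence the simulated signal.
    """

    offsets_ppm: tuple[float, ...] = tuple(np.linspace(-4.0, 4.0, 13))
    b1_uT: float = 0.7
    n_pulses: int = 5
    pulse_ms: float = 100.0
    interpulse_ms: float = 100.0
    noise_sigma: float = 0.01

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets_ppm, dtype=float)
        if off.ndim != 1 or off.size < 1:
            raise ValueError("offsets_ppm must be a non-empty 1-D sequence")
        if off.size > 1 and not np.all(np.diff(off) > 0):
            raise ValueError("offsets_ppm must be strictly increasing")
        if self.pulse_ms <= 0 or self.interpulse_ms <= 0:
            raise ValueError("pulse durations must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class TrajectorySpec:
    """A straight stereotactic path from a skull entry point to a target.

    sample_distances_mm are signed distances from the target along the
    target->entry direction (positive toward the entry point), one per
    biopsy specimen.
    """

    entry_world_mm: tuple[float, float, float]
    target_world_mm: tuple[float, float, float]
    sample_distances_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.entry_world_mm, float)
        t = np.asarray(self.target_world_mm, float)
        if np.allclose(e, t):
            raise ValueError("entry and target points must differ")
        d = np.asarray(self.sample_distances_mm, float)
        if d.size < 1:
            raise ValueError("at least one sample distance is required")
        if not np.all(np.diff(d) >= 0):
            raise ValueError("sample distances must be sorted")

    @property
    def n_samples(self) -> int:
        return len(self.sample_distances_mm)

    def positions_world(self) -> np.ndarray:
        """World coordinates (n, 3) of the samples along the path."""
        e = np.asarray(self.entry_world_mm, float)
        t = np.asarray(self.target_world_mm, float)
        u = (e - t) / np.linalg.norm(e - t)
        d = np.asarray(self.sample_distances_mm, float)
        return t[None, :] + d[:, None] * u[None, :]


# ---------------------------------------------------------------------------
# Z-spectrum model


def make_offset_grid(min_ppm: float, max_ppm: float, n: int) -> np.ndarray:
    """Equidistant saturation-offset grid from min_ppm to max_ppm inclusive.

    The study protocol uses 13 equidistant offsets between -4 and +4 ppm,
    whose nodes closest to the 3.3 ppm readout are +-10/3 ppm.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 1 and min_ppm >= max_ppm:
        raise ValueError("min_ppm must be < max_ppm for n > 1")
    return np.linspace(min_ppm, max_ppm, n)


def lorentzian(x: np.ndarray, center: float, amplitude: float, fwhm: float) -> np.ndarray:
    hw = 0.5 * fwhm
    x = np.asarray(x, dtype=float)
    return amplitude * hw * hw / (hw * hw + (x - center) ** 2)


def zspectrum_model(
    offset_ppm: float | np.ndarray,
    pools: list[PoolSpec] | tuple[PoolSpec, ...],
    b0_shift_ppm: float = 0.0,
) -> np.ndarray:
    """Noise-free normalized Z value(s) of a multi-pool Lorentzian spectrum.

    Z(dw) = 1 - sum_k L_k(dw - b0_shift).  Requires the total pool amplitude
    to stay below 1 so that Z remains positive at every offset.
    """
    total = sum(p.amplitude for p in pools)
    if total >= 1.0:
        raise ValueError(f"sum of pool amplitudes must be < 1, got {total:.3f}")
    x = np.asarray(offset_ppm, dtype=float) - b0_shift_ppm
    z = np.ones_like(x, dtype=float)
    for p in pools:
        z = z - lorentzian(x, p.center_ppm, p.amplitude, p.width_ppm)
    return z


def effective_saturation_ms(acq: AcquisitionParams) -> float:
    """Total saturation duration: pulses plus interpulse gaps.

    For the study protocol (5 x 100 ms pulses, 100 ms delays) this is 900 ms.
    """
    if acq.n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    return acq.n_pulses * acq.pulse_ms + (acq.n_pulses - 1) * acq.interpulse_ms


# ---------------------------------------------------------------------------
# Phantom configuration and construction

# Central pool lumping direct water saturation and residual semisolid MT.
# Broad enough (FWHM 3 ppm) that the spline minimum search over the coarse
# 13-point grid is well conditioned; a narrow pure-DS dip cannot be located
# to the accuracy the B0 correction needs from 2/3-ppm sampling.
WATER_POOL = PoolSpec(center_ppm=0.0, amplitude=0.72, width_ppm=3.0)

NOE_CENTER_PPM = -3.3
NOE_FWHM_PPM = 3.0
APT_CENTER_PPM = 3.5
APT_FWHM_PPM = 1.5
APT_TO_NOE = 0.6  # amide amplitude as a fraction of the class NOE amplitude

DEFAULT_NOE_AMPLITUDE = {
    Tissue.NAWM: 0.12,
    Tissue.EDEMA: 0.08,
    Tissue.CE_TUMOR: 0.045,
    Tissue.NECROSIS: 0.02,
    Tissue.CSF: 0.005,
}
DEFAULT_ADC = {  # 1e-6 mm^2/s
    Tissue.NAWM: 800.0,
    Tissue.EDEMA: 1100.0,
    Tissue.CE_TUMOR: 1300.0,
    Tissue.NECROSIS: 1800.0,
    Tissue.CSF: 3000.0,
}
DEFAULT_CELL_DENSITY = {  # cells/mm^3
    Tissue.NAWM: 3000.0,
    Tissue.EDEMA: 3500.0,
    Tissue.CE_TUMOR: 8000.0,
    Tissue.NECROSIS: 1500.0,
    Tissue.CSF: 0.0,
}
# Rank correlation between cellularity and the local NOE amplitude.  Negative
# in tumor and edema: NOE-mediated saturation falls where tumor cells pack
# densely, which is what makes MTR_asym rise with cellularity.
DEFAULT_RHO_CELL = {
    Tissue.NAWM: 0.0,
    Tissue.EDEMA: -0.9,
    Tissue.CE_TUMOR: -0.75,
    Tissue.NECROSIS: 0.0,
    Tissue.CSF: 0.0,
}
# Rank correlation between ADC and cellularity: classically negative in
# edema, near zero in the heterogeneous enhancing tumor.
DEFAULT_RHO_ADC = {
    Tissue.NAWM: 0.0,
    Tissue.EDEMA: -0.4,
    Tissue.CE_TUMOR: 0.0,
    Tissue.NECROSIS: 0.0,
    Tissue.CSF: 0.0,
}


@dataclass
class PhantomConfig:
    """Geometry, tissue parameters and statistical couplings of the phantom.

    All lengths are mm.  ``rho_cell[c]`` is the Spearman correlation between
    cellularity and NOE amplitude within class c; ``rho_adc[c]`` between ADC
    and cellularity.  ``correlation_length_voxels`` sets the Gaussian
    smoothing of the latent cellularity driver field (tumor cellularity
    varies smoothly at the mm scale, which is what makes a 3x3x3 biopsy
    readout representative of the sampled point).
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size_mm: tuple[float, float, float] = (1.8, 1.8, 2.0)
    seed: int = 0
    brain_semiaxes_mm: tuple[float, float, float] = (38.0, 38.0, 27.0)
    csf_rim_fraction: float = 0.92
    tumor_center_mm: tuple[float, float, float] = (10.0, 6.0, 0.0)
    necrosis_radius_mm: float = 5.5
    ce_outer_radius_mm: float = 10.5
    edema_semiaxes_mm: tuple[float, float, float] = (21.0, 19.0, 16.0)
    noe_amplitude: dict = field(default_factory=lambda: dict(DEFAULT_NOE_AMPLITUDE))
    noe_variability: float = 0.6
    adc_mean: dict = field(default_factory=lambda: dict(DEFAULT_ADC))
    adc_log_sigma: float = 0.12
    cell_mean: dict = field(default_factory=lambda: dict(DEFAULT_CELL_DENSITY))
    cell_log_sigma: float = 0.45
    rho_cell: dict = field(default_factory=lambda: dict(DEFAULT_RHO_CELL))
    rho_adc: dict = field(default_factory=lambda: dict(DEFAULT_RHO_ADC))
    b0_amplitude_ppm: float = 0.3
    correlation_length_voxels: float = 1.0

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("phantom dimensions must be at least 16 voxels")
        amps = [self.noe_amplitude[c] for c in NOE_ORDER]
        if not all(a > b for a, b in zip(amps, amps[1:])):
            raise ValueError(
                "NOE amplitudes must decrease along NAWM > edema > CE-tumor > necrosis"
            )
        adcs = [self.adc_mean[c] for c in ADC_ORDER]
        if not all(a < b for a, b in zip(adcs, adcs[1:])):
            raise ValueError("mean ADC must increase along edema < CE-tumor < necrosis")
        worst = max(
            self.noe_amplitude[c] * (1.0 + self.noe_variability)
            + APT_TO_NOE * self.noe_amplitude[c]
            for c in NOE_ORDER
        )
        if WATER_POOL.amplitude + worst >= 1.0:
            raise ValueError("pool amplitudes would exceed 1 at the deepest voxel")


@dataclass
class DigitalPhantom:
    """A fully specified synthetic subject.

    The per-voxel spectral truth is the Lorentzian pool model: a shared
    central (water + MT) pool, an NOE pool whose amplitude is the
    ``noe_amplitude_map`` value, and a class-level amide pool.  All 3-D
    fields share one grid and affine.
    """

    label_map: np.ndarray
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    b0_field_ppm: np.ndarray
    adc_map: np.ndarray
    cellularity_map: np.ndarray
    noe_amplitude_map: np.ndarray
    pool_params: dict
    config: PhantomConfig

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_map.shape

    def pools_at(self, index: tuple[int, int, int]) -> list[PoolSpec]:
        """Lorentzian pools of one voxel (empty in background)."""
        cls = Tissue(int(self.label_map[index]))
        if cls == Tissue.BACKGROUND:
            return []
        apt_amp = APT_TO_NOE * self.config.noe_amplitude[cls]
        return [
            WATER_POOL,
            PoolSpec(NOE_CENTER_PPM, float(self.noe_amplitude_map[index]), NOE_FWHM_PPM),
            PoolSpec(APT_CENTER_PPM, apt_amp, APT_FWHM_PPM),
        ]

    def noise_free_z(self, offsets_ppm: np.ndarray, shifted: bool = True) -> np.ndarray:
        """Analytic Z stack (x, y, z, offset); the oracle for the pipeline.

        With ``shifted=False`` the B0 field is ignored, i.e. the spectrum a
        perfect B0 correction would recover.
        """
        offsets = np.asarray(offsets_ppm, float)
        lbl = self.label_map
        shift = self.b0_field_ppm if shifted else np.zeros_like(self.b0_field_ppm)
        x = offsets[None, None, None, :] - shift[..., None]
        z = np.ones(lbl.shape + (offsets.size,))
        inside = lbl > 0
        z[inside] -= lorentzian(
            x[inside], WATER_POOL.center_ppm, 1.0, WATER_POOL.width_ppm
        ) * WATER_POOL.amplitude
        z[inside] -= (
            lorentzian(x[inside], NOE_CENTER_PPM, 1.0, NOE_FWHM_PPM)
            * self.noe_amplitude_map[inside, None]
        )
        apt_amp = np.zeros(lbl.shape)
        for cls in NOE_ORDER + (Tissue.CSF,):
            apt_amp[lbl == cls] = APT_TO_NOE * self.config.noe_amplitude[cls]
        z[inside] -= lorentzian(x[inside], APT_CENTER_PPM, 1.0, APT_FWHM_PPM) * apt_amp[
            inside, None
        ]
        z[~inside] = 1.0
        return z


def spectral_minimum_map(
    phantom: "DigitalPhantom",
    search_halfwidth_ppm: float = 1.0,
    grid_step_ppm: float = 0.001,
    chunk: int = 4096,
) -> np.ndarray:
    """True location of each voxel's analytic Z-spectrum minimum near 0 ppm.

    The independent oracle for B0 estimation: the argmin of the continuous
    Lorentzian model on a dense grid.  For asymmetric spectra this differs
    from the injected B0 shift by the genuine tilt that the NOE and amide
    pools impose on the water dip; the spline-minimum estimator targets this
    quantity, not the water-center field itself.  NaN in background.
    """
    dense = np.arange(
        -search_halfwidth_ppm, search_halfwidth_ppm + 0.5 * grid_step_ppm, grid_step_ppm
    )
    out = np.full(phantom.shape, np.nan)
    inside = phantom.label_map > 0
    vox = np.argwhere(inside)
    deltas = phantom.b0_field_ppm[inside]
    noe_amp = phantom.noe_amplitude_map[inside]
    apt_amp = np.empty(len(vox))
    lbl = phantom.label_map[inside]
    for cls in NOE_ORDER + (Tissue.CSF,):
        apt_amp[lbl == cls] = APT_TO_NOE * phantom.config.noe_amplitude[cls]
    mins = np.empty(len(vox))
    for start in range(0, len(vox), chunk):
        sel = slice(start, start + chunk)
        x = dense[None, :] - deltas[sel][:, None]
        z = 1.0 - lorentzian(x, WATER_POOL.center_ppm, 1.0, WATER_POOL.width_ppm) * WATER_POOL.amplitude
        z -= lorentzian(x, NOE_CENTER_PPM, 1.0, NOE_FWHM_PPM) * noe_amp[sel][:, None]
        z -= lorentzian(x, APT_CENTER_PPM, 1.0, APT_FWHM_PPM) * apt_amp[sel][:, None]
        mins[sel] = dense[np.argmin(z, axis=1)]
    out[vox[:, 0], vox[:, 1], vox[:, 2]] = mins
    return out


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-filtered standard-normal field renormalized to unit variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return (f - f.mean()) / f.std()


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    r2 = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semiaxes))
    return r2 <= 1.0


def _latent_rho(rho_spearman: float) -> float:
    """Pearson correlation of latent Gaussians giving a target Spearman rho."""
    return 2.0 * np.sin(np.pi * rho_spearman / 6.0)


def build_phantom(config: PhantomConfig) -> DigitalPhantom:
    """Construct the deterministic phantom described by ``config``.

    The label map contains all five tissue classes; the NOE amplitude and
    mean ADC respect the glioblastoma region ordering; cellularity and ADC
    are tied to the local NOE amplitude through a Gaussian copula whose
    latent driver field is spatially smooth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nx, ny, nz = cfg.shape
    vx, vy, vz = cfg.voxel_size_mm
    affine = np.diag([vx, vy, vz, 1.0])
    # voxel-centred world origin at the grid centre
    affine[:3, 3] = -0.5 * np.array([vx * (nx - 1), vy * (ny - 1), vz * (nz - 1)])

    idx = np.indices(cfg.shape, dtype=float)
    coords = [idx[i] * cfg.voxel_size_mm[i] + affine[i, 3] for i in range(3)]

    brain = _ellipsoid(coords, (0.0, 0.0, 0.0), cfg.brain_semiaxes_mm)
    inner = _ellipsoid(
        coords, (0.0, 0.0, 0.0), tuple(a * cfg.csf_rim_fraction for a in cfg.brain_semiaxes_mm)
    )
    label = np.zeros(cfg.shape, dtype=np.int16)
    label[brain] = Tissue.CSF
    label[inner] = Tissue.NAWM

    tc = cfg.tumor_center_mm
    edema = _ellipsoid(coords, tc, cfg.edema_semiaxes_mm) & inner
    ce = _ellipsoid(coords, tc, (cfg.ce_outer_radius_mm,) * 3) & inner
    nec = _ellipsoid(coords, tc, (cfg.necrosis_radius_mm,) * 3) & inner
    label[edema] = Tissue.EDEMA
    label[ce] = Tissue.CE_TUMOR
    label[nec] = Tissue.NECROSIS
    for cls in (Tissue.NAWM, Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS, Tissue.CSF):
        if not np.any(label == cls):
            raise ValueError(f"phantom geometry leaves tissue class {cls.name} empty")

    # B0 field: low-order polynomial plus one Gaussian bump, scaled to the
    # configured peak amplitude.
    xn = [coords[i] / np.abs(coords[i]).max() for i in range(3)]
    bump_center = np.array([0.3, -0.2, 0.1])
    r2 = sum((xn[i] - bump_center[i]) ** 2 for i in range(3))
    b0 = 0.25 * xn[0] + 0.15 * xn[1] - 0.1 * xn[2] + 0.9 * np.exp(-r2 / (2 * 0.35**2))
    b0 = b0 * (cfg.b0_amplitude_ppm / np.abs(b0).max())

    # Latent Gaussian fields: S drives cellularity and is smooth; the NOE and
    # ADC latents mix S with iid innovations at the class coupling strengths.
    sigma = cfg.correlation_length_voxels
    S = _smooth_unit_field(rng, cfg.shape, sigma)
    E_noe = rng.standard_normal(cfg.shape)
    E_adc = rng.standard_normal(cfg.shape)

    z_noe = np.zeros(cfg.shape)
    z_adc = np.zeros(cfg.shape)
    noe_amp = np.zeros(cfg.shape)
    adc = np.zeros(cfg.shape)
    cell = np.zeros(cfg.shape)
    for cls in (Tissue.NAWM, Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS, Tissue.CSF):
        m = label == cls
        a = _latent_rho(cfg.rho_cell.get(cls, 0.0))
        b = _latent_rho(cfg.rho_adc.get(cls, 0.0))
        z_noe[m] = a * S[m] + np.sqrt(1.0 - a * a) * E_noe[m]
        z_adc[m] = b * S[m] + np.sqrt(1.0 - b * b) * E_adc[m]
        noe_amp[m] = cfg.noe_amplitude[cls] * (
            1.0 + cfg.noe_variability * np.tanh(0.5 * z_noe[m])
        )
        adc[m] = cfg.adc_mean[cls] * np.exp(cfg.adc_log_sigma * z_adc[m])
        if cls == Tissue.CSF:
            cell[m] = 0.0
        else:
            cell[m] = cfg.cell_mean[cls] * np.exp(cfg.cell_log_sigma * S[m])

    pool_params = {
        cls: [
            WATER_POOL,
            PoolSpec(NOE_CENTER_PPM, cfg.noe_amplitude[cls], NOE_FWHM_PPM),
            PoolSpec(APT_CENTER_PPM, APT_TO_NOE * cfg.noe_amplitude[cls], APT_FWHM_PPM),
        ]
        for cls in (Tissue.NAWM, Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS, Tissue.CSF)
    }
    return DigitalPhantom(
        label_map=label,
        affine=affine,
        voxel_size_mm=cfg.voxel_size_mm,
        b0_field_ppm=b0,
        adc_map=adc,
        cellularity_map=cell,
        noe_amplitude_map=noe_amp,
        pool_params=pool_params,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Acquisition simulation


@dataclass
class Acquisition:
    """One simulated CEST scan: saturated stack, M0 volume, offsets, affine."""

    saturated: np.ndarray  # (x, y, z, offset)
    m0: np.ndarray  # (x, y, z)
    offsets_ppm: np.ndarray
    affine: np.ndarray
    params: AcquisitionParams


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return signal.astype(float)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_acquisition(
    phantom: DigitalPhantom,
    acq: AcquisitionParams,
    seed: int,
    m0_signal: float = 1000.0,
) -> Acquisition:
    """Magnitude acquisition of the phantom under the given protocol.

    Each saturated volume is M0 * Z(model) at one offset plus Rician noise of
    scale ``noise_sigma * m0_signal``; the M0 volume carries the same noise.
    Background voxels hold pure noise.
    """
    rng = np.random.default_rng(seed)
    offsets = np.asarray(acq.offsets_ppm, float)
    z = phantom.noise_free_z(offsets, shifted=True)
    inside = phantom.label_map > 0
    m0_clean = np.where(inside, m0_signal, 0.0)
    sat_clean = m0_clean[..., None] * z
    sat_clean[~inside] = 0.0
    sigma = acq.noise_sigma * m0_signal
    sat = _rician(rng, sat_clean, sigma)
    m0 = _rician(rng, m0_clean, sigma)
    return Acquisition(
        saturated=sat, m0=m0, offsets_ppm=offsets, affine=phantom.affine, params=acq
    )


# ---------------------------------------------------------------------------
# Biopsy simulation


def simulate_biopsy_set(
    phantom: DigitalPhantom,
    traj: TrajectorySpec,
    seed: int,
    density_noise_cv: float = 0.05,
) -> pd.DataFrame:
    """Cell densities sampled along a stereotactic trajectory.

    One row per specimen with its world position, signed distance from the
    target, the phantom cellularity at the nearest voxel perturbed by
    multiplicative counting noise, and an ``in_volume`` flag; out-of-volume
    samples are flagged, never dropped.
    """
    rng = np.random.default_rng(seed)
    pos = traj.positions_world()
    inv = np.linalg.inv(phantom.affine)
    vox = (inv[:3, :3] @ pos.T + inv[:3, 3:4]).T
    ijk = np.rint(vox).astype(int)
    shape = np.array(phantom.shape)
    in_vol = np.all((ijk >= 0) & (ijk < shape[None, :]), axis=1)
    rows = []
    for s in range(traj.n_samples):
        if in_vol[s]:
            i, j, k = ijk[s]
            dens = float(phantom.cellularity_map[i, j, k])
            if density_noise_cv > 0:
                dens *= max(0.0, 1.0 + rng.normal(0.0, density_noise_cv))
            tissue = Tissue(int(phantom.label_map[i, j, k])).name
        else:
            dens = np.nan
            tissue = "OUTSIDE"
        rows.append(
            {
                "sample_id": s + 1,
                "x_mm": pos[s, 0],
                "y_mm": pos[s, 1],
                "z_mm": pos[s, 2],
                "distance_from_target_mm": traj.sample_distances_mm[s],
                "cell_density_per_mm3": dens,
                "tissue": tissue,
                "in_volume": bool(in_vol[s]),
            }
        )
    return pd.DataFrame(rows)


def default_trajectory(
    phantom: DigitalPhantom,
    n_samples: int = 12,
    spacing_mm: float = 1.4,
) -> TrajectorySpec:
    """A clinically shaped default path: skull entry toward the CE-tumor core.

    Samples start at the target (inside the enhancing zone) and step toward
    the entry, crossing contrast-enhancing tissue into edema the way serial
    stereotactic specimens do.
    """
    tc = np.asarray(phantom.config.tumor_center_mm, float)
    target = tc + np.array([0.6 * phantom.config.ce_outer_radius_mm, 0.0, 0.0])
    entry = np.array(
        [
            phantom.config.brain_semiaxes_mm[0] * 0.95,
            tc[1] + 12.0,
            tc[2] + 8.0,
        ]
    )
    distances = tuple(spacing_mm * np.arange(n_samples))
    return TrajectorySpec(
        entry_world_mm=tuple(entry), target_world_mm=tuple(target), sample_distances_mm=distances
    )
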