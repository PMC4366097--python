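"""Monte-Carlo validation studies of the processing and statistics chain.

Each study runs the package's own machinery end to end under known ground
truth and measures how well it recovers it: B0 and MTR_asym accuracy against
the analytic Lorentzian oracle, Bonett-Wright interval coverage, copula
rank-correlation fidelity of the generator, and the empirical type-I rate of
the biopsy correlation at the study's sample size of 12.  Used by the test
suite and by the acceptance script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import zspec
from .biopsy import correlate_biopsies, read_out_biopsies
from .phantom import (
    AcquisitionParams,
    DEFAULT_RHO_CELL,
    PhantomConfig,
    Tissue,
    TrajectorySpec,
    build_phantom,
    simulate_acquisition,
    simulate_biopsy_set,
    spectral_minimum_map,
)
from .region_stats import bonett_wright_ci, spearman


def process_chain(phantom, noise_sigma: float, seed: int):
    """Simulate one acquisition and run the full processing chain."""
    acq = simulate_acquisition(
        phantom, AcquisitionParams(noise_sigma=noise_sigma), seed=seed
    )
    z = zspec.normalize(acq.saturated, acq.m0, acq.offsets_ppm, acq.affine)
    b0 = zspec.estimate_b0(z)
    zc = zspec.correct_b0(z, b0)
    mtr = zspec.compute_mtr_asym(zc)
    return z, b0, zc, mtr


def b0_recovery_rmse(phantom, noise_sigma: float, seed: int) -> float:
    """RMSE (ppm) of the spline-minimum B0 estimate against the analytic
    spectral-minimum oracle, over valid in-brain voxels."""
    z, b0, _, _ = process_chain(phantom, noise_sigma, seed)
    oracle = spectral_minimum_map(phantom)
    ok = z.mask & b0.valid & (phantom.label_map > 0)
    err = b0.delta_ppm[ok] - oracle[ok]
    return float(np.sqrt(np.mean(err**2)))


def mtr_oracle_errors(phantom, seed: int) -> dict:
    """Noise-free pipeline MTR_asym against the two-sided Lorentzian truth.

    Returns max and RMS absolute error in fraction units (MTR/100).
    """
    z, b0, zc, mtr = process_chain(phantom, noise_sigma=0.0, seed=seed)
    r = mtr.readout_ppm
    truth = phantom.noise_free_z(np.array([-r, r]), shifted=False)
    truth_pct = 100.0 * (truth[..., 0] - truth[..., 1])
    ok = zc.mask & np.isfinite(mtr.values_percent) & (phantom.label_map > 0)
    err = (mtr.values_percent[ok] - truth_pct[ok]) / 100.0
    return {
        "max_abs": float(np.abs(err).max()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "n": int(ok.sum()),
    }


def bonett_wright_coverage(
    seed: int, rho_s: float = 0.3, n: int = 100, reps: int = 2000, level: float = 0.95
) -> float:
    """Empirical coverage (percent) of the Bonett-Wright interval.

    Samples bivariate Gaussian pairs whose latent Pearson correlation
    2 sin(pi rho_s / 6) gives population Spearman exactly rho_s, and counts
    how often the interval covers it.
    """
    rng = np.random.default_rng(seed)
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    x = rng.standard_normal((reps, n))
    y = rho_p * x + np.sqrt(1.0 - rho_p**2) * rng.standard_normal((reps, n))
    rx = sps.rankdata(x, axis=1)
    ry = sps.rankdata(y, axis=1)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    r = (rx * ry).sum(1) / np.sqrt((rx**2).sum(1) * (ry**2).sum(1))
    covered = 0
    for ri in r:
        lo, hi = bonett_wright_ci(float(ri), n, level)
        covered += lo <= rho_s <= hi
    return 100.0 * covered / reps


def big_tumor_config(rho_ce: float, seed: int) -> PhantomConfig:
    """Phantom with an enlarged enhancing shell (>= 2000 CE voxels)."""
    rho = dict(DEFAULT_RHO_CELL)
    rho[Tissue.CE_TUMOR] = rho_ce
    return PhantomConfig(
        seed=seed,
        ce_outer_radius_mm=16.0,
        necrosis_radius_mm=6.0,
        edema_semiaxes_mm=(26.0, 24.0, 20.0),
        rho_cell=rho,
    )


def copula_recovery(seed: int, rhos=(0.0, 0.2, 0.5), n: int = 2000) -> dict:
    """Sample Spearman between cellularity and NOE amplitude in the CE class
    for configured couplings, at n voxels."""
    out = {}
    for rho in rhos:
        ph = build_phantom(big_tumor_config(rho, seed))
        m = ph.label_map == Tissue.CE_TUMOR
        idx = np.argwhere(m)[:n]
        cell = ph.cellularity_map[idx[:, 0], idx[:, 1], idx[:, 2]]
        noe = ph.noe_amplitude_map[idx[:, 0], idx[:, 1], idx[:, 2]]
        out[rho] = spearman(cell, noe)[0]
    return out


def _null_trajectories(phantom, rng: np.random.Generator, count: int):
    """Random straight 12-sample paths fully inside NAWM, 4.5 mm spacing.

    The spacing decorrelates the 12 samples despite the smooth cellularity
    field and the overlapping 3x3x3 readout cubes, and random centers and
    directions keep replicate paths from resampling one field profile, so
    the nominal significance level is actually being tested.
    """
    distances = -24.75 + 4.5 * np.arange(12)
    inv = np.linalg.inv(phantom.affine)
    produced = 0
    while produced < count:
        center = rng.uniform((-32.0, -32.0, -20.0), (32.0, 32.0, 20.0))
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        pos = center[None, :] + distances[:, None] * u[None, :]
        vox = np.rint(inv[:3, :3] @ pos.T + inv[:3, 3:4]).astype(int).T
        if np.any(vox < 0) or np.any(vox >= np.array(phantom.shape)[None, :]):
            continue
        labels = phantom.label_map[vox[:, 0], vox[:, 1], vox[:, 2]]
        if not np.all(labels == Tissue.NAWM):
            continue
        produced += 1
        yield TrajectorySpec(
            tuple(center + 40.0 * u), tuple(center), tuple(distances)
        )


def biopsy_type_one_rate(
    seed: int, reps: int = 1000, n_phantoms: int = 5, alpha: float = 0.05
) -> float:
    """Empirical percent of null biopsy series declared significant.

    Phantoms are generated with rho_cell = 0 everywhere (cellularity
    independent of the NOE amplitude) and 12-sample trajectories are drawn
    through normal white matter; the rate of p < alpha for the
    cellularity-MTR_asym Spearman test estimates the type-I error.
    """
    rng = np.random.default_rng(seed)
    per_phantom = reps // n_phantoms
    hits = total = 0
    null_rho = {c: 0.0 for c in DEFAULT_RHO_CELL}
    for p in range(n_phantoms):
        ph = build_phantom(
            PhantomConfig(seed=int(rng.integers(2**31)), rho_cell=null_rho)
        )
        _, _, _, mtr = process_chain(ph, noise_sigma=0.01, seed=int(rng.integers(2**31)))
        for traj in _null_trajectories(ph, rng, per_phantom):
            s = simulate_biopsy_set(ph, traj, seed=int(rng.integers(2**31)))
            s = read_out_biopsies(
                s, mtr.values_percent, ph.adc_map, ph.affine, label_map=ph.label_map
            )
            res = correlate_biopsies(s)
            total += 1
            hits += res.p_mtr_cell < alpha
    return 100.0 * hits / total


def biopsy_power(
    seed: int, reps: int = 25, rho_ce: float = -0.9, alpha: float = 0.05
) -> float:
    """Percent of replicates with a significant positive cellularity-MTR_asym
    correlation along the default tumor trajectory at strong coupling."""
    from .phantom import default_trajectory

    rng = np.random.default_rng(seed)
    rho = dict(DEFAULT_RHO_CELL)
    rho[Tissue.CE_TUMOR] = rho_ce
    hits = 0
    for _ in range(reps):
        ph = build_phantom(PhantomConfig(seed=int(rng.integers(2**31)), rho_cell=rho))
        _, _, _, mtr = process_chain(ph, noise_sigma=0.01, seed=int(rng.integers(2**31)))
        s = simulate_biopsy_set(ph, default_trajectory(ph), seed=int(rng.integers(2**31)))
        s = read_out_biopsies(
            s, mtr.values_percent, ph.adc_map, ph.affine, label_map=ph.label_map
        )
        res = correlate_biopsies(s)
        hits += (res.r_sp_mtr_cell > 0) and (res.p_mtr_cell < alpha)
    return 100.0 * hits / reps
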