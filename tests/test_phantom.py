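"""Generator correctness: spectra, geometry, couplings, acquisition, biopsies."""

import numpy as np
import pandas as pd
import pytest

import noecest as nc
from noecest.phantom import (
    AcquisitionParams,
    DEFAULT_RHO_CELL,
    PhantomConfig,
    PoolSpec,
    Tissue,
    TrajectorySpec,
    build_phantom,
    default_trajectory,
    effective_saturation_ms,
    lorentzian,
    make_offset_grid,
    simulate_acquisition,
    simulate_biopsy_set,
    zspectrum_model,
)
from noecest.region_stats import spearman


class TestOffsetGrid:
    def test_study_grid_has_13_nodes_including_readout(self):
        grid = make_offset_grid(-4, 4, 13)
        assert grid.size == 13
        assert np.allclose(np.diff(grid), 2.0 / 3.0)
        assert np.isclose(grid[1], -10.0 / 3.0)
        assert np.isclose(grid[11], 10.0 / 3.0)

    @pytest.mark.parametrize(
        "args, expected",
        [((0, 0, 1), [0.0]), ((-1, 1, 2), [-1.0, 1.0])],
    )
    def test_degenerate_grids(self, args, expected):
        assert make_offset_grid(*args).tolist() == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_offset_grid(-4, 4, 0)
        with pytest.raises(ValueError):
            make_offset_grid(1, -1, 5)


class TestZSpectrumModel:
    def test_no_pools_means_no_saturation(self):
        assert zspectrum_model(1.7, []) == 1.0

    def test_on_resonance_peak_depth(self):
        pool = PoolSpec(center_ppm=-3.3, amplitude=0.3, width_ppm=2.0)
        assert np.isclose(zspectrum_model(-3.3, [pool]), 0.7)

    def test_two_pool_closed_form(self):
        # independent hand evaluation of the two Lorentzians at -10/3 ppm
        water = PoolSpec(0.0, 0.8, 1.4)
        noe = PoolSpec(-3.3, 0.05, 3.0)
        x = -10.0 / 3.0
        l_water = 0.8 * 0.7**2 / (0.7**2 + x**2)
        l_noe = 0.05 * 1.5**2 / (1.5**2 + (x + 3.3) ** 2)
        assert np.isclose(zspectrum_model(x, [water, noe]), 1.0 - l_water - l_noe)

    def test_amplitude_sum_guard(self):
        pools = [PoolSpec(0.0, 0.7, 1.4), PoolSpec(-3.3, 0.35, 3.0)]
        with pytest.raises(ValueError):
            zspectrum_model(0.0, pools)

    def test_b0_shift_moves_the_spectrum(self):
        pool = PoolSpec(0.0, 0.5, 2.0)
        assert np.isclose(zspectrum_model(0.3, [pool], b0_shift_ppm=0.3), 0.5)


class TestEffectiveSaturation:
    @pytest.mark.parametrize(
        "n, pulse, gap, expected",
        [(5, 100, 100, 900.0), (1, 100, 50, 100.0), (3, 50, 25, 200.0)],
    )
    def test_pulse_train_duration(self, n, pulse, gap, expected):
        acq = AcquisitionParams(n_pulses=n, pulse_ms=pulse, interpulse_ms=gap)
        assert effective_saturation_ms(acq) == expected


class TestValidation:
    def test_pool_invariants(self):
        with pytest.raises(ValueError):
            PoolSpec(0.0, -0.1, 1.0)
        with pytest.raises(ValueError):
            PoolSpec(0.0, 0.1, 0.0)

    def test_acquisition_invariants(self):
        with pytest.raises(ValueError):
            AcquisitionParams(offsets_ppm=(0.0, 0.0))
        with pytest.raises(ValueError):
            AcquisitionParams(noise_sigma=-0.01)

    def test_impossible_orderings_rejected(self):
        amps = dict(PhantomConfig().noe_amplitude)
        amps[Tissue.NECROSIS] = 0.2  # would invert the NOE region ordering
        with pytest.raises(ValueError):
            PhantomConfig(noe_amplitude=amps)
        adc = dict(PhantomConfig().adc_mean)
        adc[Tissue.NECROSIS] = 500.0
        with pytest.raises(ValueError):
            PhantomConfig(adc_mean=adc)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(shape=(8, 48, 32))


class TestBuildPhantom:
    def test_deterministic_for_fixed_seed(self):
        a = build_phantom(PhantomConfig(seed=11))
        b = build_phantom(PhantomConfig(seed=11))
        assert np.array_equal(a.label_map, b.label_map)
        assert np.array_equal(a.cellularity_map, b.cellularity_map)
        assert np.array_equal(a.noe_amplitude_map, b.noe_amplitude_map)
        assert np.array_equal(a.b0_field_ppm, b.b0_field_ppm)

    def test_all_tissue_classes_present(self, default_phantom):
        present = set(np.unique(default_phantom.label_map))
        assert {int(c) for c in Tissue} <= present

    def test_region_orderings(self, default_phantom):
        ph = default_phantom
        noe_means = [
            ph.noe_amplitude_map[ph.label_map == c].mean()
            for c in (Tissue.NAWM, Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS)
        ]
        assert all(a > b for a, b in zip(noe_means, noe_means[1:]))
        adc_means = [
            ph.adc_map[ph.label_map == c].mean()
            for c in (Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS)
        ]
        assert all(a < b for a, b in zip(adc_means, adc_means[1:]))

    def test_mtr_contrast_increases_toward_necrosis(self, default_phantom, analytic_mtr_truth):
        # weaker NOE -> higher (less negative) asymmetry along the cascade
        means = [
            analytic_mtr_truth[default_phantom.label_map == c].mean()
            for c in (Tissue.NAWM, Tissue.EDEMA, Tissue.CE_TUMOR, Tissue.NECROSIS)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_field_invariants(self, default_phantom):
        ph = default_phantom
        assert np.all(ph.adc_map >= 0)
        assert np.all(ph.cellularity_map >= 0)
        assert np.all(ph.cellularity_map[ph.label_map == Tissue.CSF] == 0)
        assert np.all(ph.cellularity_map[ph.label_map == Tissue.BACKGROUND] == 0)
        assert np.isfinite(np.linalg.inv(ph.affine)).all()
        assert np.abs(ph.b0_field_ppm).max() <= ph.config.b0_amplitude_ppm + 1e-12

    def test_noise_free_z_stays_in_unit_interval(self, default_phantom):
        z = default_phantom.noise_free_z(make_offset_grid(-4, 4, 13))
        assert np.all(z > 0.0)
        assert np.all(z <= 1.0 + 1e-12)


@pytest.fixture(scope="module")
def big_tumor_config():
    def make(rho_ce):
        rho = dict(DEFAULT_RHO_CELL)
        rho[Tissue.CE_TUMOR] = rho_ce
        return PhantomConfig(
            seed=7,
            ce_outer_radius_mm=16.0,
            necrosis_radius_mm=6.0,
            edema_semiaxes_mm=(26.0, 24.0, 20.0),
            rho_cell=rho,
        )

    return make


class TestCopulaFidelity:
    def test_independence_setting(self, big_tumor_config):
        ph = build_phantom(big_tumor_config(0.0))
        m = ph.label_map == Tissue.CE_TUMOR
        assert m.sum() >= 1000
        r, _ = spearman(ph.cellularity_map[m], ph.noe_amplitude_map[m])
        assert abs(r) < 0.1

    @pytest.mark.parametrize("rho", [0.8, -0.8])
    def test_configured_rank_correlation_recovered(self, big_tumor_config, rho):
        ph = build_phantom(big_tumor_config(rho))
        m = ph.label_map == Tissue.CE_TUMOR
        r, _ = spearman(ph.cellularity_map[m], ph.noe_amplitude_map[m])
        assert abs(r - rho) < 0.05


class TestSimulateAcquisition:
    def test_noise_free_round_trip_recovers_model(self, default_phantom):
        acq = simulate_acquisition(
            default_phantom, AcquisitionParams(noise_sigma=0.0), seed=0
        )
        inside = default_phantom.label_map > 0
        z = acq.saturated[inside] / acq.m0[inside, None]
        truth = default_phantom.noise_free_z(acq.offsets_ppm)[inside]
        assert np.allclose(z, truth, atol=1e-12)
        assert np.all(acq.saturated[~inside] == 0)

    def test_noisy_stack_is_deterministic(self, default_phantom):
        acq1 = simulate_acquisition(default_phantom, AcquisitionParams(), seed=5)
        acq2 = simulate_acquisition(default_phantom, AcquisitionParams(), seed=5)
        assert np.array_equal(acq1.saturated, acq2.saturated)
        assert np.array_equal(acq1.m0, acq2.m0)

    def test_carries_offsets_and_affine(self, default_phantom):
        acq = simulate_acquisition(default_phantom, AcquisitionParams(), seed=5)
        assert acq.saturated.shape[3] == acq.offsets_ppm.size == 13
        assert np.array_equal(acq.affine, default_phantom.affine)


class TestBiopsySimulation:
    def test_all_distances_zero_lands_on_target(self, default_phantom):
        traj = TrajectorySpec((60.0, 0.0, 0.0), (5.0, 5.0, 0.0), (0.0,) * 12)
        s = simulate_biopsy_set(default_phantom, traj, seed=1)
        assert len(s) == 12
        assert np.allclose(s[["x_mm", "y_mm", "z_mm"]].to_numpy(), (5.0, 5.0, 0.0))

    def test_twelve_samples_along_trajectory(self, default_phantom):
        traj = default_trajectory(default_phantom)
        s = simulate_biopsy_set(default_phantom, traj, seed=1)
        assert len(s) == 12
        d = s["distance_from_target_mm"].to_numpy()
        assert np.all(np.diff(d) > 0)
        assert s["in_volume"].all()

    def test_noise_free_sampling_is_exact_lookup(self, default_phantom):
        ph = default_phantom
        ijk = (24, 24, 16)
        world = ph.affine[:3, :3] @ np.array(ijk, float) + ph.affine[:3, 3]
        traj = TrajectorySpec(tuple(world + np.array([30.0, 0, 0])), tuple(world), (0.0,))
        s = simulate_biopsy_set(ph, traj, seed=1, density_noise_cv=0.0)
        assert s.loc[0, "cell_density_per_mm3"] == ph.cellularity_map[ijk]

    def test_outside_sample_flagged_not_dropped(self, default_phantom):
        traj = TrajectorySpec(
            (200.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 500.0)
        )
        s = simulate_biopsy_set(default_phantom, traj, seed=1)
        assert len(s) == 2
        assert s.loc[1, "in_volume"] == False  # noqa: E712
        assert np.isnan(s.loc[1, "cell_density_per_mm3"])

    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            TrajectorySpec((0, 0, 0), (0, 0, 0), (0.0,))
        with pytest.raises(ValueError):
            TrajectorySpec((1, 0, 0), (0, 0, 0), (3.0, 1.0))
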