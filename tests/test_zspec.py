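"""Processing-chain correctness: normalization, B0 search, correction, MTR_asym."""

import numpy as np
import pytest

import noecest as nc
from noecest import zspec
from noecest.phantom import PoolSpec, make_offset_grid, zspectrum_model
from tests.conftest import run_chain

OFFSETS = make_offset_grid(-4, 4, 13)


def single_voxel_volume(z_row, offsets=OFFSETS):
    data = np.asarray(z_row, float).reshape(1, 1, 1, -1)
    return zspec.ZSpectrumVolume(
        data=data, offsets_ppm=offsets, affine=np.eye(4), mask=np.ones((1, 1, 1), bool)
    )


EDEMA_POOLS = [
    PoolSpec(0.0, 0.72, 3.0),
    PoolSpec(-3.3, 0.08, 3.0),
    PoolSpec(3.5, 0.048, 1.5),
]


class TestNormalize:
    def test_equal_signals_give_unit_z(self):
        sat = np.full((4, 4, 4, 13), 800.0)
        m0 = np.full((4, 4, 4), 800.0)
        z = zspec.normalize(sat, m0, OFFSETS)
        assert np.allclose(z.data[z.mask], 1.0)

    def test_half_signal(self):
        sat = np.full((2, 2, 2, 13), 500.0)
        m0 = np.full((2, 2, 2), 1000.0)
        z = zspec.normalize(sat, m0, OFFSETS)
        assert np.allclose(z.data[z.mask], 0.5)

    def test_zero_m0_voxel_masked_out(self):
        sat = np.full((3, 3, 3, 13), 500.0)
        m0 = np.full((3, 3, 3), 1000.0)
        m0[1, 1, 1] = 0.0
        z = zspec.normalize(sat, m0, OFFSETS)
        assert not z.mask[1, 1, 1]
        assert z.mask.sum() == 26

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            zspec.normalize(np.ones((2, 2, 2, 13)), np.ones((3, 3, 3)), OFFSETS)


class TestEstimateB0:
    def test_symmetric_spectrum_centered(self):
        z = single_voxel_volume(zspectrum_model(OFFSETS, [PoolSpec(0.0, 0.72, 3.0)]))
        b0 = zspec.estimate_b0(z)
        assert b0.valid[0, 0, 0]
        assert abs(b0.delta_ppm[0, 0, 0]) <= 0.01

    def test_known_shift_recovered_within_grid_accuracy(self):
        # oracle: argmin of the analytic model on a 0.001-ppm grid
        shift = 0.30
        z = single_voxel_volume(zspectrum_model(OFFSETS, EDEMA_POOLS, b0_shift_ppm=shift))
        dense = np.arange(-1.0, 1.0005, 0.001)
        oracle = dense[np.argmin(zspectrum_model(dense, EDEMA_POOLS, b0_shift_ppm=shift))]
        b0 = zspec.estimate_b0(z)
        assert b0.valid[0, 0, 0]
        assert abs(b0.delta_ppm[0, 0, 0] - oracle) <= 0.02
        assert abs(b0.delta_ppm[0, 0, 0] - shift) <= 0.05

    def test_minimum_at_window_edge_flagged_invalid(self):
        z = single_voxel_volume(
            zspectrum_model(OFFSETS, [PoolSpec(0.0, 0.72, 3.0)], b0_shift_ppm=1.5)
        )
        b0 = zspec.estimate_b0(z, search_halfwidth_ppm=1.0)
        assert not b0.valid[0, 0, 0]

    def test_too_few_offsets_rejected(self):
        z = single_voxel_volume([1.0, 0.5, 1.0], offsets=np.array([-1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            zspec.estimate_b0(z)


class TestCorrectB0:
    def test_zero_map_is_identity(self):
        row = zspectrum_model(OFFSETS, EDEMA_POOLS)
        z = single_voxel_volume(row)
        b0 = zspec.B0Map(
            delta_ppm=np.zeros((1, 1, 1)), valid=np.ones((1, 1, 1), bool),
            search_halfwidth_ppm=1.0,
        )
        zc = zspec.correct_b0(z, b0)
        assert np.allclose(zc.data[0, 0, 0], row, atol=1e-12)

    def test_corrected_minimum_sits_at_zero(self):
        z = single_voxel_volume(zspectrum_model(OFFSETS, EDEMA_POOLS, b0_shift_ppm=0.25))
        b0 = zspec.estimate_b0(z)
        zc = zspec.correct_b0(z, b0)
        # re-estimating on the corrected spectrum finds (numerically) no shift
        row = zc.data[0, 0, 0]
        keep = np.isfinite(row)
        z2 = single_voxel_volume(row[keep], offsets=OFFSETS[keep])
        b0_after = zspec.estimate_b0(z2)
        assert abs(b0_after.delta_ppm[0, 0, 0]) <= 0.02

    def test_out_of_range_offset_becomes_non_finite(self):
        z = single_voxel_volume(zspectrum_model(OFFSETS, EDEMA_POOLS, b0_shift_ppm=0.25))
        b0 = zspec.B0Map(
            delta_ppm=np.full((1, 1, 1), 0.25), valid=np.ones((1, 1, 1), bool),
            search_halfwidth_ppm=1.0,
        )
        zc = zspec.correct_b0(z, b0)
        row = zc.data[0, 0, 0]
        assert np.isnan(row[-1])  # +4 ppm shifted past the acquired range
        assert np.isfinite(row[:-1]).all()

    def test_invalid_voxels_drop_from_mask(self):
        z = single_voxel_volume(zspectrum_model(OFFSETS, EDEMA_POOLS))
        b0 = zspec.B0Map(
            delta_ppm=np.full((1, 1, 1), np.nan), valid=np.zeros((1, 1, 1), bool),
            search_halfwidth_ppm=1.0,
        )
        zc = zspec.correct_b0(z, b0)
        assert not zc.mask[0, 0, 0]
        assert np.allclose(zc.data[0, 0, 0], z.data[0, 0, 0])


class TestComputeMtrAsym:
    def test_symmetric_spectrum_has_zero_asymmetry(self):
        z = single_voxel_volume(zspectrum_model(OFFSETS, [PoolSpec(0.0, 0.72, 3.0)]))
        mtr = zspec.compute_mtr_asym(z)
        assert abs(mtr.values_percent[0, 0, 0]) < 1e-9

    def test_direct_arithmetic(self):
        row = np.ones(13)
        row[1] = 0.60  # Z(-10/3)
        row[11] = 0.75  # Z(+10/3)
        mtr = zspec.compute_mtr_asym(single_voxel_volume(row))
        assert np.isclose(mtr.values_percent[0, 0, 0], -15.0)

    def test_two_pool_closed_form_oracle(self):
        pools = [PoolSpec(0.0, 0.85, 1.4), PoolSpec(-3.3, 0.05, 3.0)]
        r = zspec.READOUT_PPM
        mtr = zspec.compute_mtr_asym(single_voxel_volume(zspectrum_model(OFFSETS, pools)))
        # hand evaluation of the two Lorentzians at the readout nodes
        def lor(x, c, a, f):
            return a * (f / 2) ** 2 / ((f / 2) ** 2 + (x - c) ** 2)

        z_neg = 1 - lor(-r, 0, 0.85, 1.4) - lor(-r, -3.3, 0.05, 3.0)
        z_pos = 1 - lor(r, 0, 0.85, 1.4) - lor(r, -3.3, 0.05, 3.0)
        expected = 100 * (z_neg - z_pos)
        # readout nodes are grid nodes, so spline interpolation is exact there
        assert np.isclose(mtr.values_percent[0, 0, 0], expected, atol=1e-9)

    def test_readout_outside_range_rejected(self):
        z = single_voxel_volume(np.ones(13))
        with pytest.raises(ValueError):
            zspec.compute_mtr_asym(z, readout_ppm=5.0)

    def test_antisymmetry_under_axis_negation(self):
        rng = np.random.default_rng(0)
        rows = 0.5 + 0.4 * rng.random((6, 13))
        data = rows.reshape(6, 1, 1, 13)
        z = zspec.ZSpectrumVolume(
            data=data, offsets_ppm=OFFSETS, affine=np.eye(4), mask=np.ones((6, 1, 1), bool)
        )
        flipped = zspec.ZSpectrumVolume(
            data=data[..., ::-1].copy(),
            offsets_ppm=-OFFSETS[::-1],
            affine=np.eye(4),
            mask=np.ones((6, 1, 1), bool),
        )
        a = zspec.compute_mtr_asym(z).values_percent
        b = zspec.compute_mtr_asym(flipped).values_percent
        assert np.allclose(a, -b, atol=1e-9)


class TestWindowDisplay:
    @pytest.mark.parametrize("value, clipped", [(-12.0, -10.0), (7.0, 5.0), (-3.0, -3.0)])
    def test_clipping(self, value, clipped):
        m = zspec.MTRasymMap(values_percent=np.full((1, 1, 1), value), readout_ppm=10 / 3)
        assert zspec.window_display(m)[0, 0, 0] == clipped

    def test_invalid_window_rejected(self):
        m = zspec.MTRasymMap(values_percent=np.zeros((1, 1, 1)), readout_ppm=10 / 3)
        with pytest.raises(ValueError):
            zspec.window_display(m, lo=5.0, hi=-10.0)

    def test_statistics_are_untouched(self):
        vals = np.array([[[-20.0]]])
        m = zspec.MTRasymMap(values_percent=vals, readout_ppm=10 / 3)
        zspec.window_display(m)
        assert m.values_percent[0, 0, 0] == -20.0


class TestChainProperties:
    def test_rmse_degrades_monotonically_with_noise(self, default_phantom, analytic_mtr_truth):
        ph = default_phantom
        rng = np.random.default_rng(123)
        inside = np.argwhere(ph.label_map > 0)
        sample = inside[rng.choice(len(inside), 200, replace=False)]
        rmses = []
        for sigma in (0.0, 0.01, 0.02):
            _, _, _, mtr = run_chain(ph, noise_sigma=sigma, seed=77)
            vals = mtr.values_percent[sample[:, 0], sample[:, 1], sample[:, 2]]
            truth = analytic_mtr_truth[sample[:, 0], sample[:, 1], sample[:, 2]]
            ok = np.isfinite(vals)
            rmses.append(np.sqrt(np.mean((vals[ok] - truth[ok]) ** 2)))
        assert rmses[0] < rmses[1] < rmses[2]

    def test_noise_free_chain_is_finite_inside_mask(self, noise_free_chain):
        z, b0, zc, mtr = noise_free_chain
        assert np.isfinite(mtr.values_percent[zc.mask]).all()
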