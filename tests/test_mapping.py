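"""Binning, per-superpixel fitting, map masking/smoothing, topology."""

import numpy as np
import pytest
from scipy import stats

import tofdepth.simulate as sim
import tofdepth.stacks as stk
from tofdepth.calibration import CalibrationChain
from tofdepth.core import GateTimeAxis, IntensityImage, TimeScan
from tofdepth.errors import DataQualityWarning
from tofdepth.mapping import (
    ParameterMap,
    bin_scan,
    fit_map,
    mask_by_intensity,
    smooth_map,
    tof_to_topology,
)


@pytest.fixture(scope="module")
def cylinder_maps():
    """Fitted maps of a binned two-cylinder scene (module-scoped: fits once)."""
    axis = GateTimeAxis(n_steps=400)
    sensor = sim.SensorResponse()
    scene = sim.two_cylinder_scene(
        shape=(24, 32), depths_mm=(2.5, 5.6), il_percent=2.0, band_rows=4,
        amplitude=2500.0,
    )
    fluo = sim.simulate_scan(scene, axis, sensor, "fluorescence", seed=21)
    irf_scan = sim.simulate_scan(scene, axis, sensor, "irf", seed=22)
    binned = bin_scan(fluo, 4)
    irf_binned = bin_scan(irf_scan, 4)
    maps = fit_map(binned, irf_binned, tau_ns=0.7, n_top=15, n_tail=40, bin_factor=4)
    return scene, fluo, maps


class TestBinScan:
    def test_sensor_area_bins_to_32x59(self):
        axis = GateTimeAxis(n_steps=2)
        scan = TimeScan(
            np.zeros((256, 472, 2), dtype=np.uint8), axis, modality="fluorescence"
        )
        assert bin_scan(scan, 8).shape[:2] == (32, 59)

    def test_factor_one_is_identity(self, rng):
        axis = GateTimeAxis(n_steps=4)
        scan = TimeScan(
            rng.integers(0, 9, (5, 7, 4)), axis, modality="fluorescence"
        )
        assert bin_scan(scan, 1) is scan

    def test_partial_blocks_dropped(self):
        axis = GateTimeAxis(n_steps=3)
        scan = TimeScan(np.ones((10, 10, 3), dtype=int), axis, modality="irf")
        out = bin_scan(scan, 8)
        assert out.shape == (1, 1, 3)
        assert np.all(out.counts == 64)

    def test_oversized_factor_rejected(self):
        axis = GateTimeAxis(n_steps=2)
        scan = TimeScan(np.ones((4, 4, 2), dtype=int), axis, modality="irf")
        with pytest.raises(ValueError, match="factor"):
            bin_scan(scan, 5)


class TestFitMap:
    def test_cylinder_region_ordering(self, cylinder_maps):
        """Shallow cylinder: smaller fitted TOF and dispersion than deep one."""
        scene, _, maps = cylinder_maps
        gt = scene.depth_mm[::4, ::4]  # nearest ground-truth depth per superpixel
        dmap = maps["delta_tissue_ps"]
        shallow = np.isclose(gt, 2.5) & dmap.mask
        deep = np.isclose(gt, 5.6) & dmap.mask
        assert shallow.sum() > 3 and deep.sum() > 3
        assert dmap.values[shallow].mean() < dmap.values[deep].mean()
        smap = maps["sigma_ps"]
        assert smap.values[shallow].mean() < smap.values[deep].mean()

    def test_background_pixels_masked(self, cylinder_maps):
        scene, _, maps = cylinder_maps
        gt = scene.depth_mm[::4, ::4]
        background = np.isnan(gt)
        # background has no pulse: those fits must be masked out
        assert maps["delta_tissue_ps"].mask[background].mean() < 0.2

    def test_uniform_scene_map_constant_within_gate_step(self):
        axis = GateTimeAxis(n_steps=400)
        sensor = sim.SensorResponse()
        scene = sim.uniform_scene((8, 8), 2.0, il_percent=2.0, amplitude=2500.0)
        fluo = sim.simulate_scan(scene, axis, sensor, "fluorescence", seed=31)
        irf_scan = sim.simulate_scan(scene, axis, sensor, "irf", seed=32)
        maps = fit_map(
            bin_scan(fluo, 4), bin_scan(irf_scan, 4), n_top=15, n_tail=40
        )
        dmap = maps["delta_tissue_ps"]
        assert dmap.mask.all()
        spread = dmap.valid_values.max() - dmap.valid_values.min()
        assert spread < 2 * axis.dt_ps

    def test_matches_independent_profile_fits(self, cylinder_maps):
        """Map fitting has no cross-talk: equals per-superpixel profile fits."""
        from tofdepth.fitting import fit_fluorescence
        from tofdepth.profiles import extract_profile, normalize_profile

        scene, fluo, maps = cylinder_maps
        axis = fluo.axis
        sensor = sim.SensorResponse()
        irf_scan = sim.simulate_scan(scene, axis, sensor, "irf", seed=22)
        binned, irf_binned = bin_scan(fluo, 4), bin_scan(irf_scan, 4)
        r, c = np.argwhere(maps["delta_tissue_ps"].mask)[0]
        tp = normalize_profile(extract_profile(binned, (r, c, 1, 1)), 15, 40)
        res = fit_fluorescence(tp, extract_profile(irf_binned, (r, c, 1, 1)))
        assert res.delta_tissue_ps == pytest.approx(
            maps["delta_tissue_ps"].values[r, c], abs=1e-9
        )


class TestMaskByIntensity:
    def test_zero_threshold_is_identity(self):
        pmap = ParameterMap(np.ones((4, 4)), np.ones((4, 4), bool), "x")
        img = IntensityImage(np.random.default_rng(0).random((4, 4)), 1)
        out = mask_by_intensity(pmap, img, threshold=0.0)
        assert np.array_equal(out.mask, pmap.mask)

    def test_threshold_above_max_masks_all_with_warning(self):
        pmap = ParameterMap(np.ones((4, 4)), np.ones((4, 4), bool), "x")
        img = IntensityImage(np.ones((4, 4)), 1)
        with pytest.warns(DataQualityWarning, match="every pixel"):
            out = mask_by_intensity(pmap, img, threshold=2.0)
        assert not out.mask.any()

    def test_separates_footprint_from_background(self, cylinder_maps):
        """SNR-style masking keeps the inclusion footprint, drops background."""
        scene, fluo, maps = cylinder_maps
        img = stk.intensity_image(bin_scan(fluo, 4))
        gt = scene.depth_mm[::4, ::4]
        pmap = ParameterMap(
            maps["delta_tissue_ps"].values, np.ones_like(gt, dtype=bool),
            "delta_tissue_ps", 4,
        )
        out = mask_by_intensity(pmap, img, threshold=2.0, background_roi=(2, 0, 2, 8))
        shallow = np.isclose(gt, 2.5)
        background = np.isnan(gt)
        assert out.mask[shallow].mean() >= 0.95
        assert (~out.mask[background]).mean() >= 0.95


class TestSmoothMap:
    def test_zero_sigma_is_identity(self):
        vals = np.arange(16.0).reshape(4, 4)
        pmap = ParameterMap(vals, np.ones((4, 4), bool), "x")
        out = smooth_map(pmap, 0.0)
        assert np.array_equal(out.values, vals)

    def test_constant_map_with_holes_restored(self):
        vals = np.full((8, 8), 5.0)
        mask = np.ones((8, 8), bool)
        mask[3, 3] = mask[5, 2] = False
        vals[~mask] = np.nan
        out = smooth_map(ParameterMap(vals, mask, "x"), 1.5)
        np.testing.assert_allclose(out.values[out.mask], 5.0, rtol=1e-12)

    def test_impulse_reproduces_gaussian_kernel(self):
        n = 21
        vals = np.zeros((n, n))
        vals[10, 10] = 1.0
        out = smooth_map(ParameterMap(vals, np.ones((n, n), bool), "x"), 1.0)
        x = np.arange(n) - 10.0
        g1 = np.exp(-0.5 * x**2)
        g1 /= g1.sum()
        expected = np.outer(g1, g1)
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_no_bleed_into_far_masked_regions(self):
        vals = np.zeros((16, 16))
        mask = np.zeros((16, 16), bool)
        mask[:4, :] = True
        vals[:4, :] = 7.0
        out = smooth_map(ParameterMap(vals, mask, "x"), 1.0)
        assert np.all(np.isnan(out.values[8:, :]))
        assert not out.mask[8:, :].any()


class TestTopology:
    def _identity_chain(self, k=1.0):
        return CalibrationChain(
            branch="sfdi", k_corr=0.0, c_corr=k, c_fluo_ps=10.0,
            k_sfdi=1.0, c_sfdi=0.0,
        )

    def test_constant_map_gives_zero_relative_depth(self):
        pmap = ParameterMap(np.full((4, 4), 55.0), np.ones((4, 4), bool), "d")
        topo = tof_to_topology(pmap, self._identity_chain(), 2.0)
        np.testing.assert_allclose(topo.values, 0.0, atol=1e-12)

    def test_scales_rereferenced_delta_by_slope(self):
        vals = np.array([[100.0, 150.0], [200.0, 250.0]])
        pmap = ParameterMap(vals, np.ones((2, 2), bool), "d")
        topo = tof_to_topology(pmap, self._identity_chain(k=50.0), 2.0)
        np.testing.assert_allclose(topo.values, (vals - 100.0) / 50.0, atol=1e-12)

    def test_cylinder_depth_difference_recovered(self, cylinder_maps):
        """Region-mean relative depth difference approximates 5.6 - 2.5 mm."""
        import pandas as pd
        from tofdepth.calibration import build_chain

        scene, _, maps = cylinder_maps
        # chain from the same ground-truth forward map, multiple IL levels
        rows = []
        for il in (1.0, 2.0, 3.0):
            s = sim.uniform_scene((1, 1), 0.0, il_percent=il)
            for z in (1.0, 2.0, 3.0, 4.0, 5.0):
                rows.append((il, z, s.delta_tissue_ps(z)))
        depth_df = pd.DataFrame(
            rows, columns=["il_percent", "depth_mm", "delta_tissue_ps"]
        )
        medium_df = pd.DataFrame(
            {"il_percent": [1.0, 2.0, 3.0], "mu_s_prime_per_mm": [1.0, 2.0, 3.0]}
        )
        chain = build_chain(depth_df, medium_df, branch="sfdi")
        topo = tof_to_topology(
            maps["delta_tissue_ps"], chain, scene.mu_s_prime_per_mm
        )
        gt = scene.depth_mm[::4, ::4]
        shallow = np.isclose(gt, 2.5) & topo.mask
        deep = np.isclose(gt, 5.6) & topo.mask
        diff = topo.values[deep].mean() - topo.values[shallow].mean()
        assert diff == pytest.approx(3.1, abs=0.5)

    def test_empty_map_rejected(self):
        pmap = ParameterMap(np.full((2, 2), np.nan), np.zeros((2, 2), bool), "d")
        with pytest.raises(ValueError, match="no valid"):
            tof_to_topology(pmap, self._identity_chain(), 2.0)
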