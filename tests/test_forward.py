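"""Projector, surface depth, normalization, mu-rebinning, detector response."""

import numpy as np
import pytest

from bremstomo import (CameraModel, EnergySpectrum, Phantom,
                       apply_detector_response, default_camera, normalize,
                       parallel_lor, pinhole_lor, project, rebin_to_mu,
                       surface_depth, point_source_phantom)
from bremstomo.forward import ray_segments


def water_slab_phantom(z_lo=10.0, z_hi=20.0, extent=10.0, voxel=0.5):
    n = int(extent / voxel)
    nz = int(np.ceil((z_hi + 2) / voxel))
    medium = np.zeros((n, n, nz), dtype=np.int16)
    zc = (np.arange(nz) + 0.5) * voxel
    medium[:, :, (zc > z_lo) & (zc < z_hi)] = 1
    act = np.zeros((n, n, nz))
    return Phantom(activity=act, medium=medium,
                   medium_names=("air", "water"), voxel_size=(voxel,) * 3,
                   origin=(-extent / 2, -extent / 2, 0.0))


def hot_voxel(phantom, x, y, z, activity=1.0):
    lo, _ = phantom.bounds
    idx = tuple(int((c - o) / v) for c, o, v in
                zip((x, y, z), lo, phantom.voxel_size))
    act = phantom.activity.copy()
    act[idx] = activity
    return Phantom(activity=act, medium=phantom.medium,
                   medium_names=phantom.medium_names,
                   voxel_size=phantom.voxel_size, origin=phantom.origin)


class TestSurfaceDepth:
    def test_axis_aligned_water_slab(self):
        ph = water_slab_phantom(z_lo=10.0)
        for x, y in [(0.25, 0.25), (-2.0, 3.0), (4.0, -4.0)]:
            assert surface_depth(ph, parallel_lor(x, y)) == pytest.approx(
                10.0, abs=0.26)

    def test_miss_gives_inf_and_zero_counts(self, parallel_camera):
        ph = hot_voxel(water_slab_phantom(), 0.25, 0.25, 15.0)
        lor = parallel_lor(50.0, 50.0)  # far outside the grid
        assert surface_depth(ph, lor) == np.inf
        spec = project(ph, parallel_camera, pixels=[(50.0, 50.0)])
        assert np.all(spec.values == 0)

    def test_oblique_pinhole_vs_fine_ray_marching(self):
        # oracle: 10 um marching along the LOR, flag first non-air sample
        ph = water_slab_phantom(z_lo=16.0, z_hi=20.0, extent=16.0)
        lor = pinhole_lor(3.0, -2.0, 15.0)
        lp = surface_depth(ph, lor)
        step = 1e-3  # cm
        ls = np.arange(0.0, 30.0, step)
        pts = lor.point_at(ls)
        lo, hi = ph.bounds
        inside = np.all((pts >= lo) & (pts < hi), axis=1)
        idx = np.floor((pts[inside] - lo) / np.asarray(ph.voxel_size))
        idx = idx.astype(int)
        codes = ph.medium[idx[:, 0], idx[:, 1], idx[:, 2]]
        l_oracle = ls[inside][np.nonzero(codes != 0)[0][0]]
        assert lp == pytest.approx(l_oracle, abs=step)


class TestProject:
    def test_zero_activity_projects_to_zero(self, parallel_camera):
        ph = water_slab_phantom()
        spec = project(ph, parallel_camera, pixels=[(0.25, 0.25)])
        assert np.all(spec.values == 0)

    @pytest.mark.parametrize("depth", [5.0, 10.0, 15.0])
    def test_single_voxel_closed_form(self, lib, parallel_camera, depth):
        # c(E) = a(E) A G dl exp(-mu(E) d), d the voxel-center depth
        ph = point_source_phantom(depth, shell_thickness=0.0, activity=2.0)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        e = spec.bin_centers
        lor = parallel_lor(0.0, 0.0)
        lp = surface_depth(ph, lor)
        d = ph.meta["source_center_z"] - lp
        from bremstomo.geometry import geometric_efficiency
        g = geometric_efficiency(parallel_camera.collimator,
                                 (0.0, 0.0, ph.meta["source_center_z"]))
        expected = (np.asarray(lib.brems_yield(e)) * 2.0 * g
                    * ph.voxel_size[2]
                    * np.exp(-np.asarray(lib.water_mu(e)) * d))
        np.testing.assert_allclose(spec.values[0], expected, rtol=5e-3)

    def test_matches_brute_force_integrator(self, lib):
        # oracle: 10 um step quadrature of the attenuated line integral
        rng = np.random.default_rng(7)
        voxel = 1.0
        act = rng.uniform(0.0, 1.0, (8, 8, 8))
        medium = np.zeros((8, 8, 8), dtype=np.int16)
        ph = Phantom(activity=act, medium=medium, medium_names=("water",),
                     origin=(-4.0, -4.0, 16.0), voxel_size=(voxel,) * 3)
        cam = default_camera("pinhole")
        energies = np.array([60.0, 100.0, 180.0, 260.0, 340.0])
        edges = np.sort(np.unique(np.concatenate([energies - 1, energies + 1])))
        for px, py in [(0.25, 0.25), (2.25, -1.25), (-3.75, 0.75)]:
            spec = project(ph, cam, energies=edges, pixels=[(px, py)])
            centers = spec.bin_centers
            lor = cam.lor(px, py)
            # brute force
            step = 1e-3
            ls = np.arange(0.0, 40.0, step) + step / 2
            pts = lor.point_at(ls)
            lo, hi = ph.bounds
            inside = np.all((pts >= lo) & (pts < hi), axis=1)
            vals = np.zeros_like(spec.values[0])
            if inside.any():
                idx = np.floor((pts[inside] - lo) / voxel).astype(int)
                a_line = act[idx[:, 0], idx[:, 1], idx[:, 2]]
                from bremstomo.geometry import geometric_efficiency
                g = geometric_efficiency(cam.collimator, pts[inside])
                water_path = np.cumsum(np.full(inside.sum(), step)) - step / 2
                mu = np.asarray(lib.water_mu(centers))
                atten = np.exp(-np.outer(mu, water_path))
                vals = (np.asarray(lib.brems_yield(centers))
                        * (atten @ (a_line * g * step)))
            np.testing.assert_allclose(spec.values[0], vals, rtol=5e-3)

    def test_linearity_in_activity(self, parallel_camera):
        base = water_slab_phantom()
        ph1 = hot_voxel(base, 0.25, 0.25, 12.0, 1.0)
        ph2 = hot_voxel(base, 1.25, -0.75, 17.0, 3.0)
        both = Phantom(activity=ph1.activity + ph2.activity,
                       medium=base.medium, medium_names=base.medium_names,
                       voxel_size=base.voxel_size, origin=base.origin)
        pixels = [(0.25, 0.25), (1.25, -0.75)]
        s1 = project(ph1, parallel_camera, pixels=pixels).values
        s2 = project(ph2, parallel_camera, pixels=pixels).values
        s12 = project(both, parallel_camera, pixels=pixels).values
        np.testing.assert_allclose(s12, s1 + s2, rtol=1e-10)

    def test_deeper_source_attenuates_more(self, parallel_camera):
        shallow = project(point_source_phantom(5.0, shell_thickness=0.0),
                          parallel_camera, pixels=[(0.0, 0.0)]).values[0]
        deep = project(point_source_phantom(15.0, shell_thickness=0.0),
                       parallel_camera, pixels=[(0.0, 0.0)]).values[0]
        assert np.all(deep < shallow)

    def test_energy_grid_out_of_range(self, parallel_camera):
        ph = water_slab_phantom()
        with pytest.raises(ValueError):
            project(ph, parallel_camera, energies=np.array([1.0, 5.0, 9.0]))


class TestNormalize:
    def test_definition_pointwise(self, lib, parallel_camera):
        ph = point_source_phantom(8.0, shell_thickness=0.0)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        lp = 4.5
        norm = normalize(spec, lp)
        e = spec.bin_centers
        expected = (spec.values[0]
                    * np.exp(-np.asarray(lib.water_mu(e)) * lp)
                    / np.asarray(lib.brems_yield(e)))
        np.testing.assert_allclose(norm.values[0], expected, rtol=1e-12)

    def test_zero_lp_is_yield_division_only(self, lib, parallel_camera):
        ph = point_source_phantom(8.0, shell_thickness=0.0)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        norm = normalize(spec, 0.0)
        a = np.asarray(lib.brems_yield(spec.bin_centers))
        np.testing.assert_allclose(norm.values[0] * a, spec.values[0],
                                   rtol=1e-12)

    def test_log_is_linear_in_mu_with_source_position_slope(
            self, lib, parallel_camera):
        ph = point_source_phantom(10.0, shell_thickness=0.0)
        lor = parallel_lor(0.0, 0.0)
        lp = surface_depth(ph, lor)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        norm = normalize(spec, lp)
        mu = np.asarray(lib.water_mu(norm.energies))
        slope = np.polyfit(mu, np.log(norm.values[0]), 1)[0]
        assert -slope == pytest.approx(ph.meta["source_center_z"], rel=0.01)

    def test_vanishing_yield_raises(self, parallel_camera):
        ph = point_source_phantom(8.0, shell_thickness=0.0)
        edges = np.array([2290.0, 2310.0])  # a(E) = 0 at the 2300 center
        spec = project(ph, parallel_camera, energies=edges,
                       pixels=[(0.0, 0.0)])
        with pytest.raises(ValueError):
            normalize(spec, 0.0)

    def test_infinite_lp_raises(self, parallel_camera):
        ph = point_source_phantom(8.0, shell_thickness=0.0)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        with pytest.raises(ValueError):
            normalize(spec, np.inf)


class TestRebinToMu:
    def test_round_trip_relabeling(self, lib, parallel_camera):
        ph = point_source_phantom(10.0, shell_thickness=0.0)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        norm = normalize(spec, 10.0)
        mu_spec = rebin_to_mu(norm)[0]
        # definitional: C_hat(mu(E)) = C(E) on the shared grid
        mu_of_e = np.asarray(lib.water_mu(norm.energies))
        for j, m in enumerate(mu_of_e):
            i = np.argmin(np.abs(mu_spec.mu - m))
            assert mu_spec.values[i] == norm.values[0, j]

    def test_mu_grid_ascends_when_energy_descends(self, parallel_camera):
        ph = point_source_phantom(10.0, shell_thickness=0.0)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        mu_spec = rebin_to_mu(normalize(spec, 10.0))[0]
        assert np.all(np.diff(mu_spec.mu) > 0)

    def test_complete_monotonicity_of_laplace_data(self, parallel_camera):
        # C_hat from a nonnegative phantom is positive, decreasing, convex
        ph = point_source_phantom(12.0, shell_thickness=0.0)
        spec = project(ph, parallel_camera, pixels=[(0.0, 0.0)])
        lp = surface_depth(ph, parallel_lor(0.0, 0.0))
        mu_spec = rebin_to_mu(normalize(spec, lp))[0]
        v = mu_spec.values
        assert np.all(v > 0)
        assert np.all(np.diff(v) < 0)
        # convexity on the (nonuniform) mu grid: divided-difference
        # slopes must be nondecreasing
        slopes = np.diff(v) / np.diff(mu_spec.mu)
        assert np.all(np.diff(slopes) > -1e-9 * np.abs(slopes).max())


class TestDetectorResponse:
    def make_spectrum(self, rng, nbin=100):
        edges = np.linspace(20.0, 420.0, nbin + 1)
        vals = rng.uniform(0.0, 1.0, (1, nbin))
        return EnergySpectrum(pixels=[(0.0, 0.0)], bin_edges=edges,
                              values=vals)

    def test_null_response_is_identity(self, rng):
        spec = self.make_spectrum(rng)
        cam = default_camera("parallel", resolution_r=0.0,
                             window=(1e-9, 1e9))
        out = apply_detector_response(spec, cam,
                                      efficiency=lambda e: np.ones_like(e))
        np.testing.assert_allclose(out.values, spec.values, rtol=1e-14)

    def test_window_removes_out_of_band_mass(self, rng):
        spec = self.make_spectrum(rng)
        cam = default_camera("parallel", window=(50.0, 350.0))
        out = apply_detector_response(spec, cam)
        c = out.bin_centers
        outside = (c < 50.0) | (c > 350.0)
        assert np.all(out.values[:, outside] == 0)
        assert np.any(out.values[:, ~outside] > 0)

    def test_blur_conserves_counts(self, rng):
        cam = default_camera("parallel", resolution_r=0.2,
                             window=(1e-9, 1e9))
        for _ in range(100):
            spec = self.make_spectrum(rng, nbin=50)
            out = apply_detector_response(
                spec, cam, efficiency=lambda e: np.ones_like(e))
            assert out.total()[0] == pytest.approx(spec.total()[0],
                                                   rel=1e-9)

    def test_crystal_efficiency_scaling(self, lib, rng):
        from bremstomo import CrystalSlab
        edges = np.linspace(50.0, 350.0, 101)
        spec = EnergySpectrum(pixels=[(0.0, 0.0)], bin_edges=edges,
                              values=rng.uniform(0.0, 1.0, (1, 100)))
        cam = default_camera("parallel", crystal=CrystalSlab("bgo", 3.0),
                             window=(1e-9, 1e9))
        out = apply_detector_response(spec, cam)
        eps = np.asarray(lib.absorption_probability("bgo", 3.0,
                                                    spec.bin_centers))
        np.testing.assert_allclose(out.values, spec.values * eps, rtol=1e-12)
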