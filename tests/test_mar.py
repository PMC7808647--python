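import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smallfov_mar import (MARConfig, NoiseModel, ReconImage, ScanGeometry,
                          Sinogram, Spectrum, build_prior, compute_trace,
                          fbp_reconstruct, forward_project, hu_to_mu,
                          lmar_inpaint, make_ellipse_phantom, mu_to_hu,
                          nmar_inpaint, previous_pipeline, proposed_pipeline,
                          segment_metal, simulate_measurement)
from smallfov_mar.physics import effective_mu_water


def _hu_image(values, pixel_size=1.0, fov_radius=32.0, mu_water=0.02):
    return ReconImage(np.asarray(values, dtype=float), pixel_size=pixel_size,
                      fov_radius=fov_radius, unit="HU", mu_water=mu_water)


class TestSegmentMetal:
    def test_subthreshold_image_gives_empty_mask(self):
        img = _hu_image(np.full((16, 16), 500.0))
        assert not segment_metal(img).any()

    def test_bright_blob_is_segmented(self):
        vals = np.zeros((16, 16))
        vals[4:8, 4:8] = 3000.0
        mask = segment_metal(_hu_image(vals))
        assert np.array_equal(mask, vals > 2000.0)

    def test_threshold_sweep_monotone(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-1000, 5000, (32, 32))
        img = _hu_image(vals)
        lo = segment_metal(img, MARConfig(metal_threshold_hu=1500.0))
        hi = segment_metal(img, MARConfig(metal_threshold_hu=3000.0))
        assert np.all(lo[hi])  # higher-threshold mask is a subset


class TestComputeTrace:
    def test_empty_mask_gives_empty_trace(self, tiny_geom):
        trace = compute_trace(np.zeros((64, 64), dtype=bool), tiny_geom)
        assert not trace.any()

    def test_centered_metal_covers_central_bin_every_view(self, tiny_geom):
        mask = np.zeros((64, 64), dtype=bool)
        mask[31:33, 31:33] = True  # straddles iso-center
        trace = compute_trace(mask, tiny_geom, oversample=5, dilation=0)
        center_bins = trace[:, tiny_geom.n_detectors // 2 - 1:
                            tiny_geom.n_detectors // 2 + 1]
        assert np.all(center_bins.any(axis=1))

    def test_offcenter_point_traces_fan_beam_sinusoid(self, tiny_geom):
        """The traced bin follows the analytic fan-beam trajectory of the
        point over the full rotation."""
        g = tiny_geom
        px, py = 10.5, -4.5  # pixel-center aligned
        mask = np.zeros((64, 64), dtype=bool)
        ix = int(round(px / g.pixel_size + 32 - 0.5))
        iy = int(round(py / g.pixel_size + 32 - 0.5))
        mask[iy, ix] = True
        trace = compute_trace(mask, g, oversample=5, dilation=1)
        u = g.detector_coords()
        for v, beta in enumerate(g.view_angles()):
            d_along = g.source_to_iso - (px * math.cos(beta)
                                         + py * math.sin(beta))
            s = (-px * math.sin(beta) + py * math.cos(beta)) \
                * g.source_to_detector / d_along
            traced = np.flatnonzero(trace[v])
            assert traced.size, f"no trace in view {v}"
            nearest = np.min(np.abs(u[traced] - s))
            assert nearest <= 2.5 * g.detector_cell_size


class TestLMAR:
    @pytest.fixture
    def geom(self):
        return ScanGeometry(source_to_iso=100.0, detector_to_iso=50.0,
                            n_views=3, detector_cell_size=1.0, n_detectors=7,
                            image_extent=16.0, image_matrix=16)

    def test_single_run_linear_fill(self, geom):
        row = [0.0, 1.0, 2.0, 99.0, 99.0, 5.0, 6.0]
        trace = np.zeros((3, 7), dtype=bool)
        trace[:, 3:5] = True
        sino = Sinogram(np.array([row] * 3), geom)
        out = lmar_inpaint(sino, trace)
        assert np.allclose(out.values[0], [0, 1, 2, 3, 4, 5, 6])

    def test_empty_trace_is_identity(self, geom):
        vals = np.random.default_rng(0).random((3, 7))
        sino = Sinogram(vals, geom)
        out = lmar_inpaint(sino, np.zeros((3, 7), dtype=bool))
        assert np.array_equal(out.values, vals)

    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_matches_per_run_interpolation_oracle(self, geom, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((3, 7))
        trace = rng.random((3, 7)) < 0.35
        trace[:, 0] = trace[:, -1] = False  # keep anchors at the edges
        out = lmar_inpaint(Sinogram(vals.copy(), geom), trace).values
        # oracle: walk each row, fill each maximal run from its neighbors
        expected = vals.copy()
        for v in range(3):
            d = 0
            while d < 7:
                if trace[v, d]:
                    d0 = d
                    while d < 7 and trace[v, d]:
                        d += 1
                    left, right = vals[v, d0 - 1], vals[v, d]
                    for k in range(d0, d):
                        t = (k - (d0 - 1)) / (d - (d0 - 1))
                        expected[v, k] = left + t * (right - left)
                else:
                    d += 1
        assert np.allclose(out, expected, atol=1e-12)
        assert np.array_equal(out[~trace], vals[~trace])  # bit-exact outside

    def test_fully_traced_row_falls_back_to_view_interpolation(self, geom):
        vals = np.tile(np.array([[1.0], [3.0], [5.0]]), (1, 7))
        trace = np.zeros((3, 7), dtype=bool)
        trace[1] = True
        with pytest.warns(UserWarning, match="fully traced"):
            out = lmar_inpaint(Sinogram(vals, geom), trace)
        assert np.allclose(out.values[1], 3.0)


class TestBuildPrior:
    def test_uniform_soft_tissue_disk_maps_to_itself(self):
        vals = np.zeros((32, 32))
        img = _hu_image(vals, fov_radius=100.0)
        prior = build_prior(img, MARConfig(mu_water=0.02))
        assert prior.unit == "mu"
        assert np.allclose(prior.values, hu_to_mu(0.0, 0.02))

    def test_bone_values_preserved_exactly(self):
        vals = np.zeros((32, 32))
        vals[10:14, 10:14] = 1200.0
        img = _hu_image(vals, fov_radius=100.0)
        prior = build_prior(img, MARConfig(mu_water=0.02))
        assert np.allclose(prior.values[10:14, 10:14], hu_to_mu(1200.0, 0.02))

    def test_streaked_soft_tissue_flattened_to_clean_mean(self):
        """Streak outliers beyond the artifact tolerance are excluded from
        the flat soft-tissue value."""
        rng = np.random.default_rng(1)
        vals = rng.normal(50.0, 10.0, (32, 32))
        vals[::7] = 400.0  # streak rows, still below the bone threshold
        img = _hu_image(vals, fov_radius=100.0)
        cfg = MARConfig(mu_water=0.02)
        prior = build_prior(img, cfg)
        clean = vals[np.abs(vals - np.median(vals)) <= cfg.artifact_tol_hu]
        soft = prior.values[1, 1]
        assert soft == pytest.approx(hu_to_mu(clean.mean(), 0.02), rel=1e-9)

    def test_all_air_image_rejected(self):
        img = _hu_image(np.full((16, 16), -1000.0), fov_radius=100.0)
        with pytest.raises(ValueError, match="soft-tissue"):
            build_prior(img, MARConfig(mu_water=0.02))


class TestNMAR:
    @pytest.fixture
    def geom(self):
        return ScanGeometry(source_to_iso=100.0, detector_to_iso=50.0,
                            n_views=4, detector_cell_size=1.0, n_detectors=16,
                            image_extent=16.0, image_matrix=16)

    def test_constant_prior_reduces_to_lmar(self, geom):
        rng = np.random.default_rng(5)
        vals = rng.random((4, 16)) + 1.0
        trace = np.zeros((4, 16), dtype=bool)
        trace[:, 5:9] = True
        sino = Sinogram(vals, geom)
        prior = Sinogram(np.ones((4, 16)), geom)
        out = nmar_inpaint(sino, prior, trace)
        lmar = lmar_inpaint(sino, trace)
        assert np.allclose(out.values, lmar.values, atol=1e-12)

    def test_exact_recovery_when_prior_is_truth(self, geom):
        """If the prior sinogram equals the uncorrupted truth, the
        normalized sinogram is 1 across the trace and inpainting returns
        the truth exactly."""
        u = np.linspace(-1, 1, 16)
        truth = np.stack([2.0 + np.cos(1.3 * u + 0.2 * v) for v in range(4)])
        trace = np.zeros((4, 16), dtype=bool)
        trace[:, 6:11] = True
        corrupted = truth.copy()
        corrupted[trace] = 13.0
        out = nmar_inpaint(Sinogram(corrupted, geom),
                           Sinogram(truth, geom), trace)
        assert np.allclose(out.values, truth, rtol=1e-10)

    def test_empty_trace_is_identity(self, geom):
        vals = np.random.default_rng(0).random((4, 16)) + 0.5
        sino = Sinogram(vals, geom)
        out = nmar_inpaint(sino, Sinogram(vals * 2, geom),
                           np.zeros((4, 16), dtype=bool))
        assert np.array_equal(out.values, vals)

    def test_untraced_samples_bit_exact(self, geom):
        rng = np.random.default_rng(9)
        vals = rng.random((4, 16)) + 1.0
        prior = rng.random((4, 16)) + 0.5
        trace = rng.random((4, 16)) < 0.3
        out = nmar_inpaint(Sinogram(vals.copy(), geom),
                           Sinogram(prior, geom), trace)
        assert np.array_equal(out.values[~trace], vals[~trace])

    def test_shape_mismatch_rejected(self, geom):
        sino = Sinogram(np.ones((4, 16)), geom)
        small = Sinogram(np.ones((4, 80)), geom, detector_oversample=5)
        with pytest.raises(ValueError, match="shape"):
            nmar_inpaint(sino, small, np.zeros((4, 16), dtype=bool))


@pytest.fixture(scope="module")
def untruncated_case(small_geom, spectrum, atten):
    """Everything (including a 5 mm steel-like rod) inside the FOV;
    band-limited soft tissue and bone so the comparison probes the
    pipelines, not the resolution limit of reprojection."""
    ph = make_ellipse_phantom(
        [{"material": "water", "center": (0, 0), "axes": (32, 28),
          "soft_edge": 3.0},
         {"material": "bone", "center": (-12, 6), "axes": (6, 6),
          "soft_edge": 2.0},
         {"material": "metal", "center": (10, -8), "axes": (2.5, 2.5),
          "density": 0.12}],
        small_geom)
    p = simulate_measurement(ph, small_geom, spectrum, atten,
                             NoiseModel(enabled=False))
    return ph, p


class TestPipelines:
    def test_no_metal_previous_pipeline_is_plain_fbp(self, small_geom,
                                                     spectrum, atten,
                                                     mu_water_eff):
        ph = make_ellipse_phantom(
            [{"material": "water", "center": (0, 0), "axes": (30, 25)}],
            small_geom)
        p = simulate_measurement(ph, small_geom, spectrum, atten,
                                 NoiseModel(enabled=False))
        res = previous_pipeline(p, small_geom,
                                cfg=MARConfig(mu_water=mu_water_eff),
                                method="lmar")
        assert not res.metal_mask.any()
        plain = fbp_reconstruct(
            p, fov_radius=small_geom.small_fov_radius()).masked()
        assert np.allclose(res.image.values, plain.values, atol=1e-12)

    @pytest.mark.parametrize("method", ["lmar", "nmar"])
    def test_untruncated_limit_pipelines_agree(self, untruncated_case,
                                               small_geom, mu_water_eff,
                                               method):
        """With no truncation both pipelines degenerate to classic MAR and
        agree within 1% RMSE."""
        _, p = untruncated_case
        cfg = MARConfig(mu_water=mu_water_eff)
        prev = previous_pipeline(p, small_geom, cfg=cfg, method=method)
        prop = proposed_pipeline(p, small_geom, cfg=cfg, method=method)
        fov = prev.image.fov_mask()
        num = np.sqrt(np.mean((prev.image.values - prop.image.values)[fov] ** 2))
        den = np.sqrt(np.mean(prev.image.values[fov] ** 2))
        assert num <= 0.01 * den

    def test_metal_reinsertion_toggle(self, untruncated_case, small_geom,
                                      mu_water_eff):
        _, p = untruncated_case
        cfg_on = MARConfig(mu_water=mu_water_eff)
        cfg_off = MARConfig(mu_water=mu_water_eff, reinsert_metal=False)
        with_metal = proposed_pipeline(p, small_geom, cfg=cfg_on,
                                       method="lmar")
        without = proposed_pipeline(p, small_geom, cfg=cfg_off,
                                    method="lmar")
        mask = with_metal.metal_mask
        assert mask.any()
        assert with_metal.image.values[mask].max() \
            > 2 * without.image.values[mask].max()
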