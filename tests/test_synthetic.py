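"""Synthetic vessel populations, renderings, TSS series, area pairs."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label as sk_label

import vasculometry as vm
from vasculometry.synthetic import PlacementError


class TestVesselPopulation:
    def test_single_circular_vessel_identity(self):
        """One circle of d=10 um: d_h is exactly 10, VD is 1 per region."""
        spec = vm.VesselSpec(
            diameter_dist={"name": "class_mixture", "edges": [10.0, 10.0 + 1e-9], "weights": [1.0]},
            aspect_ratio_range=(1.0, 1.0),
            n_vessels=1,
        )
        gt = vm.generate_vessel_population(spec, 1e4, seed=0)
        assert gt.d_h == pytest.approx(10.0, rel=1e-6)
        assert gt.VD == pytest.approx(vm.vessel_density(1, 1e4))
        assert len(gt.vessels) == 1

    def test_determinism_and_seed_sensitivity(self):
        spec = vm.VesselSpec(n_vessels=50)
        a = vm.generate_vessel_population(spec, 2e4, seed=7)
        b = vm.generate_vessel_population(spec, 2e4, seed=7)
        c = vm.generate_vessel_population(spec, 2e4, seed=8)
        pd.testing.assert_frame_equal(a.vessels, b.vessels)
        assert not a.vessels["cx_px"].equals(c.vessels["cx_px"])

    def test_class_mixture_abundance_recovery(self):
        """A mixture with 60% of mass below 8 um reproduces that abundance
        over many seeds within binomial error."""
        spec = vm.VesselSpec(
            diameter_dist={
                "name": "class_mixture",
                "edges": [4.0, 8.0, 12.0, 16.0],
                "weights": [0.6, 0.3, 0.1],
            },
            n_vessels=40,
        )
        count_small = total = 0
        for seed in range(100):
            gt = vm.generate_vessel_population(spec, 1e5, seed=seed)
            count_small += int((gt.vessels["d_um"] < 8.0).sum())
            total += len(gt.vessels)
        p_hat = count_small / total
        se = np.sqrt(0.6 * 0.4 / total)
        assert abs(p_hat - 0.6) < 4 * se

    def test_ground_truth_self_consistency(self):
        """Derived truths equal the morphometry/hydraulics operations applied
        to the true geometry, to machine precision."""
        gt = vm.generate_vessel_population(vm.VesselSpec(n_vessels=40), 3e4, seed=2)
        d = gt.vessels["d_um"].to_numpy()
        assert gt.d_h == pytest.approx(vm.hydraulically_weighted_diameter(d), rel=1e-14)
        assert gt.VD == pytest.approx(vm.vessel_density(len(d), 3e4), rel=1e-14)
        assert gt.K == pytest.approx(vm.conductivity(d, 3e4), rel=1e-14)
        assert gt.A_lumen_rel == pytest.approx(
            gt.vessels["lumen_area_um2"].sum() / 3e4, rel=1e-14
        )
        # per-vessel d consistency with the axes
        for r in gt.vessels.itertuples(index=False):
            assert r.d_um == pytest.approx(vm.idealized_diameter(r.a_um, r.b_um), rel=1e-12)

    def test_placement_failure_names_density(self):
        spec = vm.VesselSpec(
            diameter_dist={"name": "class_mixture", "edges": [18.0, 20.0], "weights": [1.0]},
            n_vessels=200,
            max_attempts=2000,
        )
        with pytest.raises(PlacementError, match="density"):
            vm.generate_vessel_population(spec, 5e3, seed=0)


class TestRendering:
    def test_noiseless_three_components(self, three_ellipse_image):
        img, truth = three_ellipse_image
        midway = (0.15 + 0.85) / 2
        labels = sk_label(img > midway)
        assert labels.max() == 3

    def test_separated_lumina_share_no_pixels(self):
        """With min_gap_px >= 1 and no noise, rasterized lumina are disjoint:
        component count equals the vessel count."""
        spec = vm.VesselSpec(n_vessels=30, min_gap_px=2)
        gt = vm.generate_vessel_population(spec, 2e4, seed=5)
        side = int(round(np.sqrt(2e4) / 0.2))
        img, _ = vm.render_cross_section(
            gt, vm.ImageSpec(width_px=side, height_px=side, pixel_size_um=0.2, noise_sd=0.0)
        )
        labels = sk_label(img > 0.5)
        assert labels.max() == 30

    def test_discretization_error_shrinks_with_pixel_size(self, three_ellipse_image):
        _, truth = three_ellipse_image
        true_area = truth.vessels["lumen_area_um2"].sum()
        errs = {}
        for px in (0.4, 0.1):
            side = int(round(24.0 / px))
            img, _ = vm.render_cross_section(
                truth,
                vm.ImageSpec(width_px=side, height_px=side, pixel_size_um=px, noise_sd=0.0),
            )
            raster_area = (img > 0.5).sum() * px**2
            errs[px] = abs(raster_area - true_area) / true_area
        assert errs[0.1] < errs[0.4]

    def test_clipping_contract(self, three_ellipse_image):
        _, truth = three_ellipse_image
        spec = vm.ImageSpec(
            width_px=120, height_px=120, pixel_size_um=0.2,
            background_level=0.2, lumen_level=0.8, noise_sd=0.5, seed=3,
        )
        img, _ = vm.render_cross_section(truth, spec)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_out_of_frame_vessel_identified(self, three_ellipse_image):
        _, truth = three_ellipse_image
        small = vm.ImageSpec(width_px=40, height_px=40, pixel_size_um=0.2, noise_sd=0.0)
        with pytest.raises(ValueError, match="vessel"):
            vm.render_cross_section(truth, small)

    def test_render_determinism(self, small_truth):
        side = int(round(np.sqrt(2e4) / 0.2))
        spec = vm.ImageSpec(width_px=side, height_px=side, pixel_size_um=0.2,
                            noise_sd=0.05, seed=9)
        img1, _ = vm.render_cross_section(small_truth, spec)
        img2, _ = vm.render_cross_section(small_truth, spec)
        assert np.array_equal(img1, img2)


class TestTssSeries:
    def test_initial_value(self):
        t = vm.generate_tss_series(4, 32, 0.07, [0.0], 0.0, 0)
        assert t["brix"].iloc[0] == pytest.approx(4.0)

    def test_asymptote(self):
        t = vm.generate_tss_series(4, 32, 0.07, [1000.0], 0.0, 0)
        assert t["brix"].iloc[0] == pytest.approx(32.0, rel=1e-9)

    def test_evaluated_point(self):
        # Y(30) = 128 / (28 e^{-2.1} + 4)
        t = vm.generate_tss_series(4, 32, 0.07, [30.0], 0.0, 0)
        expected = 32 * 4 / ((32 - 4) * np.exp(-0.07 * 30) + 4)
        assert t["brix"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(17.23, abs=0.01)

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            vm.generate_tss_series(32, 32, 0.07, [0, 10], 0.0, 0)
        with pytest.raises(ValueError):
            vm.generate_tss_series(4, 32, -0.1, [0, 10], 0.0, 0)


class TestAreaPairs:
    def test_collinear_when_r_is_one(self):
        df = vm.generate_area_pairs(50, 1e5, "receptacle", 1.0, 0.0, seed=1)
        r = np.corrcoef(df["a_xylem_um2"], df["a_phloem_um2"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_brush_regime_ratio_above_one(self):
        df = vm.generate_area_pairs(1000, 1e5, "brush", 0.8, 0.2, seed=2)
        assert (df["a_phloem_um2"] / df["a_xylem_um2"]).mean() > 1.0

    def test_receptacle_regime_ratio_below_one(self):
        df = vm.generate_area_pairs(1000, 1e5, "receptacle", 0.8, 0.2, seed=3)
        assert (df["a_phloem_um2"] / df["a_xylem_um2"]).mean() < 1.0

    def test_large_n_convergence(self):
        df = vm.generate_area_pairs(10_000, 1e5, "brush", 0.9, 0.3, seed=4)
        r = np.corrcoef(df["a_xylem_um2"], df["a_phloem_um2"])[0, 1]
        assert abs(r - 0.9) < 0.02

    def test_infeasible_configuration_rejected(self):
        with pytest.raises(ValueError):
            vm.generate_area_pairs(10, 1e5, "brush", 0.5, 0.0, seed=0)
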