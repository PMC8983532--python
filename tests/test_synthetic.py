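"""Generator contracts: determinism, identity cases, and ground truth."""

import numpy as np
import pytest

import desmoquant as dq
from desmoquant.core import GeometryError
from desmoquant.synthetic import (
    CurveSimParams,
    FragmentSimParams,
    MapSimParams,
    generate_force_curve,
    generate_fragment_image,
    network_from_polylines,
)


class TestMonolayer:
    def test_identity_case_is_constant_image(self):
        params = dq.MonolayerParams(enrichment_ratio=1.0, patchiness=0.0,
                                    noise_sd=0.0, cytoplasm_mean=42.0, rng_seed=0)
        image, _, _ = dq.generate_monolayer(params)
        assert np.all(image.pixels == 42.0)

    def test_same_seed_gives_bit_identical_images(self):
        params = dq.MonolayerParams(noise_sd=8.0, patchiness=0.3,
                                    patch_amplitude=1.0, rng_seed=9)
        img1, mask1, _ = dq.generate_monolayer(params)
        img2, mask2, _ = dq.generate_monolayer(params)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(mask1.labels, mask2.labels)

    def test_intensities_are_clipped_nonnegative(self):
        params = dq.MonolayerParams(cytoplasm_mean=5.0, noise_sd=50.0, rng_seed=1)
        image, _, _ = dq.generate_monolayer(params)
        assert image.pixels.min() >= 0.0

    def test_truth_border_pixels_carry_enrichment(self):
        image, _, truth = dq.generate_monolayer(dq.MonolayerParams(
            enrichment_ratio=3.0, cytoplasm_mean=100.0, rng_seed=4))
        bp = truth.border_pixels
        assert np.all(image.pixels[bp[:, 0], bp[:, 1]] == 300.0)

    def test_too_small_image_raises(self):
        with pytest.raises(GeometryError):
            dq.generate_monolayer(dq.MonolayerParams(image_shape=(8, 8),
                                                     n_cells=20, rng_seed=0))

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError):
            dq.generate_monolayer(dq.MonolayerParams(n_cells=1, rng_seed=0))


class TestFilamentNetwork:
    def test_single_unbranched_filament(self):
        _, net = dq.generate_filament_network(dq.FilamentNetworkParams(
            n_seeds=1, branch_prob=0.0, rng_seed=0))
        assert net.n_edges == 1
        assert net.n_junctions == 0

    def test_two_crossing_filaments_make_one_junction(self):
        _, net = network_from_polylines([[(10, 10), (90, 90)],
                                         [(10, 90), (90, 10)]], (100, 100))
        assert net.n_edges == 4
        assert net.n_junctions == 1
        assert net.n_endpoints == 4

    def test_same_seed_gives_identical_graph_and_image(self):
        p = dq.FilamentNetworkParams(rng_seed=7, noise_sd=3.0)
        img1, net1 = dq.generate_filament_network(p)
        img2, net2 = dq.generate_filament_network(p)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert net1.n_edges == net2.n_edges
        assert net1.n_junctions == net2.n_junctions

    def test_zero_area_image_rejected(self):
        with pytest.raises(GeometryError):
            dq.generate_filament_network(dq.FilamentNetworkParams(
                image_shape=(0, 100), rng_seed=0))


class TestForceCurve:
    def test_invalid_binding_force_rejected(self):
        with pytest.raises(ValueError):
            CurveSimParams(binding=True, unbinding_force_pN=-1.0)

    def test_step_position_must_fit_z_range(self):
        with pytest.raises(ValueError):
            CurveSimParams(binding=True, step_position_nm=2000.0, z_length_um=1.5)

    def test_same_seed_gives_identical_curves(self):
        p = CurveSimParams(binding=True, baseline_noise_sd_pN=5.0, rng_seed=12)
        c1, _ = generate_force_curve(p)
        c2, _ = generate_force_curve(p)
        assert np.array_equal(c1.force_pN, c2.force_pN)

    def test_noise_propagation_of_recovered_force(self):
        """Monte Carlo: recovered force scatters within 3x its propagated SD."""
        errs = []
        for seed in range(200):
            curve, truth = generate_force_curve(CurveSimParams(
                binding=True, unbinding_force_pN=50.0, step_position_nm=80.0,
                baseline_noise_sd_pN=5.0, n_points=800, rng_seed=seed))
            events = dq.detect_unbinding_events(curve, 6.0)
            if events:
                errs.append(events[0].force_pN - truth.force_pN)
        assert len(errs) > 180
        # pre/post medians over ~5-8 samples: SD ~ sigma * sqrt(pi/2) * sqrt(2/5)
        propagated_sd = 5.0 * np.sqrt(np.pi / 2) * np.sqrt(1 / 5 + 1 / 8)
        assert abs(np.mean(errs)) < 3 * propagated_sd


class TestForceMap:
    def test_default_map_has_1200_curves(self):
        fmap = dq.generate_force_map(MapSimParams(
            curve_params=CurveSimParams(n_points=100), rng_seed=0))
        assert fmap.n_curves == 1200
        assert fmap.shape == (20, 60)

    def test_every_grid_point_has_one_curve(self):
        fmap = dq.generate_force_map(MapSimParams(
            region_um=(1.0, 1.0), grid_spacing_um=0.2,
            border_stripe=dq.synthetic.BorderStripe(center_um=0.5, width_um=0.4),
            curve_params=CurveSimParams(n_points=100), rng_seed=0))
        assert all(len(row) == fmap.shape[1] for row in fmap.curves)

    def test_empty_stripe_rejected(self):
        with pytest.raises(GeometryError):
            dq.generate_force_map(MapSimParams(
                border_stripe=dq.synthetic.BorderStripe(center_um=10.0, width_um=0.1),
                curve_params=CurveSimParams(n_points=100), rng_seed=0))


class TestFragments:
    def test_blank_image(self):
        img, n = generate_fragment_image(FragmentSimParams(
            n_fragments=0, debris_count=0, rng_seed=0))
        assert n == 0 and not img.any()

    def test_component_conservation_before_filtering(self):
        params = FragmentSimParams(n_fragments=15, debris_count=7, rng_seed=3)
        img, n = generate_fragment_image(params)
        raw = dq.count_fragments(img, min_size_px=0)
        assert raw.n_fragments == params.n_fragments + params.debris_count

    def test_debris_strictly_smaller_than_min_fragment_size(self):
        params = FragmentSimParams(n_fragments=5, debris_count=5,
                                   min_frag_px=50, rng_seed=1)
        img, _ = generate_fragment_image(params)
        sizes = sorted(dq.count_fragments(img, min_size_px=0).component_sizes)
        assert sum(1 for s in sizes if s < 50) == 5
        assert sum(1 for s in sizes if s >= 50) == 5

    def test_same_seed_gives_identical_images(self):
        p = FragmentSimParams(n_fragments=10, debris_count=3, rng_seed=8)
        img1, _ = generate_fragment_image(p)
        img2, _ = generate_fragment_image(p)
        assert np.array_equal(img1, img2)

    def test_impossible_packing_raises(self):
        with pytest.raises(GeometryError):
            generate_fragment_image(FragmentSimParams(
                image_shape=(40, 40), n_fragments=100,
                min_frag_px=100, max_frag_px=200, rng_seed=0))
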