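"""Thresholding, skeleton graph extraction, pruning, and density metrics."""

import numpy as np
import pytest

import desmoquant as dq
from desmoquant.core import DesmoquantError, ThresholdError
from desmoquant.skeleton import _extract_graph


def _plus_mask(size=21, center=10, halfwidth=0):
    m = np.zeros((size, size), dtype=bool)
    m[center - halfwidth:center + halfwidth + 1, 2:size - 2] = True
    m[2:size - 2, center - halfwidth:center + halfwidth + 1] = True
    return m


class TestBinarize:
    def test_fixed_threshold_exact_two_level(self):
        img = np.zeros((10, 10))
        img[3:6, 3:6] = 100.0
        res = dq.binarize(img, method="fixed", threshold=50)
        assert res.threshold == 50
        assert np.array_equal(res.mask, img >= 50)

    def test_otsu_on_constant_image_raises(self):
        with pytest.raises(ThresholdError):
            dq.binarize(np.full((10, 10), 3.0), method="otsu")

    def test_threshold_above_max_gives_empty_mask_and_zero_metrics(self):
        img = np.random.default_rng(0).uniform(0, 10, (32, 32))
        res = dq.binarize(img, method="fixed", threshold=99)
        graph = dq.skeletonize(res)
        m = dq.skeleton_metrics(graph, (0, 0, 32, 32), pixel_size_um=0.161)
        assert (m.n_bundles, m.n_junctions) == (0, 0)
        assert m.bundle_density == 0.0

    def test_otsu_foreground_covers_filament_centerlines(self):
        from skimage.draw import line

        image, net = dq.generate_filament_network(dq.FilamentNetworkParams(rng_seed=1))
        mask = dq.binarize(image, method="otsu").mask
        for coords in net.edge_lines:
            for (r0, c0), (r1, c1) in zip(coords[:-1], coords[1:]):
                rr, cc = line(int(round(r0)), int(round(c0)),
                              int(round(r1)), int(round(c1)))
                assert mask[rr, cc].mean() > 0.95


class TestSkeletonGraph:
    def test_straight_bar_is_single_branch(self):
        bar = np.zeros((20, 30), dtype=bool)
        bar[8:13, 5:25] = True
        g = dq.skeletonize(bar)
        assert g.n_branches == 1
        assert g.n_junctions == 0
        assert g.n_endpoints == 2

    @pytest.mark.parametrize("halfwidth", [0, 1])
    def test_plus_sign_four_branches_one_junction(self, halfwidth):
        g = dq.skeletonize(_plus_mask(halfwidth=halfwidth))
        assert g.n_branches == 4
        assert g.n_junctions == 1

    def test_empty_mask_gives_empty_graph(self):
        g = dq.skeletonize(np.zeros((10, 10), dtype=bool))
        assert g.n_branches == 0 and g.n_junctions == 0

    def test_skeleton_is_unit_width_and_idempotent(self):
        from skimage.morphology import skeletonize as thin

        g = dq.skeletonize(_plus_mask(halfwidth=2))
        s = g.skeleton
        assert not (s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()
        assert np.array_equal(thin(s), s)

    def test_pixels_partition_into_edges_and_junctions(self):
        image, _ = dq.generate_filament_network(dq.FilamentNetworkParams(rng_seed=4))
        g = dq.skeletonize(dq.binarize(image, "fixed", 50))
        covered = np.zeros_like(g.skeleton, dtype=int)
        for e in g.edges:
            covered[e.pixels[:, 0], e.pixels[:, 1]] += 1
        for pix in g.junction_pixels.values():
            covered[pix[:, 0], pix[:, 1]] += 1
        assert np.array_equal(covered > 0, g.skeleton)
        assert covered.max() == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_recovers_generated_network_counts(self, seed):
        """Branch/junction counts match the arrangement graph within 10%
        at zero noise (compared at the 6 px rendering resolution)."""
        image, net = dq.generate_filament_network(dq.FilamentNetworkParams(rng_seed=seed))
        g = dq.prune_spurs(dq.skeletonize(dq.binarize(image, "fixed", 50)), 3)
        true_edges, true_junc = net.coarse_counts(6.0)
        rec_edges, rec_junc = g.coarse_counts(6.0)
        assert abs(rec_edges - true_edges) <= max(1, 0.1 * true_edges)
        assert abs(rec_junc - true_junc) <= max(1, 0.1 * true_junc)


class TestPruneSpurs:
    def test_zero_min_length_is_identity(self):
        g = dq.skeletonize(_plus_mask())
        assert dq.prune_spurs(g, 0) is g

    def test_spur_removal_dissolves_junction(self):
        # horizontal path with a 2 px vertical spur
        m = np.zeros((20, 20), dtype=bool)
        m[10, 2:18] = True
        m[8:10, 10] = True
        g = _extract_graph(m)
        assert g.n_junctions == 1
        pruned = dq.prune_spurs(g, 3)
        assert pruned.n_junctions == 0
        assert pruned.n_branches == 1

    def test_pruning_is_idempotent(self):
        image, _ = dq.generate_filament_network(dq.FilamentNetworkParams(rng_seed=5))
        g = dq.skeletonize(dq.binarize(image, "fixed", 50))
        once = dq.prune_spurs(g, 4)
        twice = dq.prune_spurs(once, 4)
        assert np.array_equal(once.skeleton, twice.skeleton)
        assert twice.n_branches == once.n_branches


class TestSkeletonMetrics:
    def test_single_branch_density_arithmetic(self):
        # 1 branch fully inside a 10 um^2 ROI -> 0.1 bundles per um^2
        bar = np.zeros((40, 40), dtype=bool)
        bar[20, 5:35] = True
        g = dq.skeletonize(bar)
        px = 0.5  # 0.25 um^2 per pixel -> 40 px ROI = 10 um^2
        m = dq.skeleton_metrics(g, (19, 3, 21, 23), pixel_size_um=px)
        assert m.roi_area_um2 == pytest.approx(10.0)
        assert m.n_bundles == 1
        assert m.n_junctions == 0
        assert m.bundle_density == pytest.approx(0.1)

    def test_density_scales_inversely_with_area(self):
        image, _ = dq.generate_filament_network(
            dq.FilamentNetworkParams(image_shape=(128, 128), rng_seed=3))
        g = dq.skeletonize(dq.binarize(image, "fixed", 50))
        m1 = dq.skeleton_metrics(g, (0, 0, 128, 128), pixel_size_um=0.161)
        # grow the ROI by padding the skeleton into a larger empty frame
        big = np.zeros((256, 128), dtype=bool)
        big[:128] = g.skeleton
        g2 = dq.SkeletonGraph(skeleton=big, edges=g.edges,
                              junction_pixels=g.junction_pixels)
        m2 = dq.skeleton_metrics(g2, (0, 0, 256, 128), pixel_size_um=0.161)
        assert m2.n_bundles == m1.n_bundles
        assert m2.bundle_density == pytest.approx(m1.bundle_density / 2)
        assert m2.junction_density == pytest.approx(m1.junction_density / 2)

    def test_zero_area_roi_raises(self):
        g = dq.skeletonize(np.zeros((10, 10), dtype=bool))
        with pytest.raises((DesmoquantError, ValueError)):
            dq.skeleton_metrics(g, (5, 5, 5, 5), pixel_size_um=0.161)

    def test_denser_networks_score_higher_densities(self):
        sparse_p = dict(n_seeds=3, branch_prob=0.01)
        dense_p = dict(n_seeds=8, branch_prob=0.05)
        means = {}
        for name, kw in (("sparse", sparse_p), ("dense", dense_p)):
            bd, jd = [], []
            for seed in range(8):
                image, _ = dq.generate_filament_network(
                    dq.FilamentNetworkParams(rng_seed=seed, **kw))
                g = dq.skeletonize(dq.binarize(image, "fixed", 50))
                m = dq.skeleton_metrics(g, (0, 0, 256, 256), pixel_size_um=0.161)
                bd.append(m.bundle_density)
                jd.append(m.junction_density)
            means[name] = (np.mean(bd), np.mean(jd))
        assert means["dense"][0] > means["sparse"][0]
        assert means["dense"][1] > means["sparse"][1]
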