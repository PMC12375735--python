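"""Skeletonization and branch-graph decomposition."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from vesselmorph.skeleton import (
    build_graph,
    densities,
    prune_spurs,
    skeletonize,
)
from vesselmorph.synthetic import NoiseModel, render_network, sample_tree

_SQRT2 = np.sqrt(2.0)


def _y_skeleton():
    """Symmetric Y: three 21-pixel arms meeting at one pixel."""
    s = np.zeros((64, 64), bool)
    s[10:31, 32] = True                     # vertical arm, ends at (30, 32)
    for k in range(1, 21):
        s[30 + k, 32 - k] = True            # down-left diagonal
        s[30 + k, 32 + k] = True            # down-right diagonal
    s[30, 32] = True
    return s


class TestSkeletonize:
    def test_empty_mask_empty_skeleton(self):
        out = skeletonize(np.zeros((10, 10), bool))
        assert out.shape == (10, 10) and not out.any()

    def test_single_pixel_survives(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert (skeletonize(m) == m).all()

    def test_capsule_thins_to_centerline(self, clean_capsule):
        _, _, mask, _ = clean_capsule
        skel = skeletonize(mask)
        assert (skel <= mask).all()
        # one-pixel-wide: the shaft column has exactly one centerline pixel
        assert skel[:, 70].sum() == 1
        assert skel[50, 70]  # on the true centerline row

    def test_annulus_preserves_hole(self):
        yy, xx = np.mgrid[:60, :60]
        r = np.hypot(yy - 30, xx - 30)
        ring = (r > 10) & (r < 18)
        skel = skeletonize(ring)
        assert (skel <= ring).all()
        # topology preserved: background still split into inside + outside
        _, n_bg = ndi.label(~skel)
        assert n_bg == 2

    def test_component_count_preserved(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((80, 80), bool)
        for _ in range(6):
            y, x = rng.integers(10, 70, 2)
            mask[y - 4 : y + 4, x - 4 : x + 4] = True
        eight = np.ones((3, 3), int)
        _, n_before = ndi.label(mask, structure=eight)
        _, n_after = ndi.label(skeletonize(mask), structure=eight)
        assert n_before == n_after


class TestBuildGraph:
    def test_straight_line_single_branch(self):
        s = np.zeros((5, 120), bool)
        s[2, 10:111] = True  # 101 pixels
        g = build_graph(s, 1.0)
        assert g.n_branches == 1
        assert g.n_endpoints == 2
        assert g.n_branch_points == 0
        assert g.branches[0].length_um == pytest.approx(100.0)

    @pytest.mark.parametrize("method", ["chord", "steps"])
    def test_diagonal_line_length(self, method):
        s = np.eye(51, dtype=bool)
        g = build_graph(s, 1.0, length_method=method)
        assert g.n_branches == 1
        assert g.branches[0].length_um == pytest.approx(50 * _SQRT2)

    def test_y_graph(self):
        g = build_graph(_y_skeleton(), 1.0)
        assert g.n_branches == 3
        assert g.n_branch_points == 1
        assert g.n_endpoints == 3

    def test_pixel_size_scales_length(self):
        s = np.zeros((3, 50), bool)
        s[1, 5:46] = True
        g = build_graph(s, 2.5)
        assert g.branches[0].length_um == pytest.approx(40 * 2.5)

    def test_empty_skeleton_empty_graph(self):
        g = build_graph(np.zeros((8, 8), bool), 1.0)
        assert g.n_branches == 0 and g.n_branch_points == 0

    def test_isolated_pixel_zero_length_branch(self):
        s = np.zeros((5, 5), bool)
        s[2, 2] = True
        g = build_graph(s, 1.0)
        assert g.n_branches == 1
        assert g.branches[0].length_um == 0.0

    def test_closed_loop_is_one_branch_without_endpoints(self):
        yy, xx = np.mgrid[:60, :60]
        r = np.hypot(yy - 30, xx - 30)
        ring_skel = skeletonize((r > 10) & (r < 18))
        g = build_graph(ring_skel, 1.0)
        assert g.n_branches == 1
        assert g.n_endpoints == 0
        b = g.branches[0]
        assert b.node_a == -1 and b.node_b == -1
        # perimeter of a ~14-px-radius digital circle
        assert b.length_um == pytest.approx(2 * np.pi * 14, rel=0.08)

    def test_slab_pixels_partition_into_branches(self):
        spec = sample_tree(depth=3, seed=17)
        _, mask, _ = render_network(spec)
        skel = skeletonize(mask)
        g = build_graph(skel, 1.0)
        seen = {}
        for b in g.branches:
            for p in b.pixels:
                if not g.junction_pixels[p]:
                    assert p not in seen or g.nodes.get(seen[p], ("",))[0], (
                        f"pixel {p} in two branches"
                    )
        # every skeleton pixel is covered by some branch or junction cluster
        covered = np.zeros_like(skel)
        for b in g.branches:
            for p in b.pixels:
                covered[p] = True
        covered |= g.junction_pixels
        assert (covered == skel).all()

    def test_deterministic(self):
        spec = sample_tree(depth=3, seed=23)
        _, mask, _ = render_network(spec)
        skel = skeletonize(mask)
        g1 = build_graph(skel, 1.0)
        g2 = build_graph(skel, 1.0)
        assert [b.pixels for b in g1.branches] == [b.pixels for b in g2.branches]

    def test_junction_merge_collapses_split_triple_points(self):
        # two 3-way points bridged by a short slab run; merging absorbs the
        # bridge into one junction cluster
        s = np.zeros((20, 40), bool)
        s[10, 5:16] = True          # left arm into junction A near (10, 15)
        s[5:10, 15] = True          # up arm at A
        s[10, 16:21] = True         # short bridge
        s[10, 21:31] = True         # right arm from junction B near (10, 20)
        s[11:16, 20] = True         # down arm at B
        g0 = build_graph(s, 1.0)
        assert g0.n_branch_points == 2
        assert g0.n_branches == 5
        g1 = build_graph(s, 1.0, junction_merge_um=6.0)
        assert g1.n_branch_points == 1
        assert g1.n_branches == 4


class TestPruneSpurs:
    def test_spur_removed_and_branches_remerge(self):
        s = np.zeros((20, 40), bool)
        s[10, 5:35] = True  # long horizontal branch
        s[7:10, 20] = True  # 3-pixel spur upward
        g0 = build_graph(s, 1.0)
        assert g0.n_branches == 3
        pruned = prune_spurs(s, 1.0, min_length_um=5.0)
        g1 = build_graph(pruned, 1.0)
        assert g1.n_branches == 1
        assert g1.n_branch_points == 0

    def test_zero_threshold_is_identity(self):
        s = np.zeros((10, 10), bool)
        s[5, 2:8] = True
        assert (prune_spurs(s, 1.0, 0.0) == s).all()

    def test_whole_component_never_removed(self):
        s = np.zeros((10, 10), bool)
        s[5, 4:7] = True  # short isolated branch, two endpoints
        assert (prune_spurs(s, 1.0, 10.0) == s).all()


class TestDensities:
    def test_counts_per_normalised_area(self):
        s = np.zeros((100, 100), bool)
        s[50, 10:90] = True
        g = build_graph(s, 1.0)
        roi = np.ones((100, 100), bool)  # 10,000 µm² at 1 µm/pixel
        d = densities(g, s, roi, 1.0)
        assert d.branch_density == pytest.approx(1.0)
        assert d.branch_point_density == 0.0

    def test_branch_point_density(self):
        skel = np.zeros((100, 200), bool)
        skel[:64, :64] = _y_skeleton()
        g = build_graph(skel, 1.0)
        roi = np.ones((100, 200), bool)  # 20,000 µm²
        d = densities(g, skel, roi, 1.0)
        assert d.branch_point_density == pytest.approx(0.5)

    def test_mask_equal_roi_gives_density_one(self):
        roi = np.ones((20, 20), bool)
        g = build_graph(np.zeros((20, 20), bool), 1.0)
        d = densities(g, roi, roi, 1.0)
        assert d.vascular_density == 1.0

    def test_zero_roi_area_is_error(self):
        g = build_graph(np.zeros((5, 5), bool), 1.0)
        with pytest.raises(ValueError, match="ROI"):
            densities(g, np.zeros((5, 5), bool), np.zeros((5, 5), bool), 1.0)


class TestTreeRecovery:
    """Noise-free rendered trees: the skeleton graph recovers the generative
    topology exactly (branch, branch-point and endpoint counts)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_ground_truth(self, seed):
        spec = sample_tree(seed=seed, psf_sigma=0.0, noise_model=NoiseModel("none"))
        _, mask, truth = render_network(spec)
        g = build_graph(skeletonize(mask), spec.pixel_size)
        assert g.n_branches == len(spec.segments)
        assert g.n_branch_points == truth.n_junctions
        assert g.n_endpoints == truth.n_endpoints
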