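"""Generator correctness: capsule rendering, spec-graph ground truth,
tree sampling and two-group study construction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vesselmorph.synthetic import (
    NoiseModel,
    StudyDesign,
    VesselNetworkSpec,
    VesselSegment,
    generate_study,
    population_metrics,
    render_network,
    sample_tree,
    spec_from_yaml,
    spec_to_yaml,
)


def test_spec_yaml_roundtrip(tmp_path):
    spec = sample_tree(depth=2, seed=31)
    path = tmp_path / "spec.yaml"
    spec_to_yaml(spec, path)
    back = spec_from_yaml(path)
    assert back == spec


class TestSegmentValidation:
    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            VesselSegment((0.0, 0.0), (1.0, 1.0), 0.0)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            VesselSegment((3.0, 3.0), (3.0, 3.0), 1.0)

    def test_out_of_bounds_segment_rejected(self):
        seg = VesselSegment((5.0, 5.0), (5.0, 98.0), 4.0)
        with pytest.raises(ValueError, match="bounds"):
            VesselNetworkSpec((seg,), image_shape=(100, 100))

    def test_nonpositive_pixel_size_rejected(self):
        seg = VesselSegment((50.0, 30.0), (50.0, 70.0), 3.0)
        with pytest.raises(ValueError, match="pixel_size"):
            VesselNetworkSpec((seg,), image_shape=(100, 100), pixel_size=0.0)

    def test_background_must_be_darker(self):
        seg = VesselSegment((50.0, 30.0), (50.0, 70.0), 3.0)
        with pytest.raises(ValueError, match="foreground"):
            VesselNetworkSpec(
                (seg,), image_shape=(100, 100),
                foreground_intensity=10.0, background_intensity=20.0,
            )


class TestRenderNetwork:
    def test_capsule_geometry(self, clean_capsule):
        spec, image, mask, truth = clean_capsule
        # 11-pixel wide capsule at mid-shaft, exact analytic length
        assert mask[:, 70].sum() == 11
        assert truth.total_length_um == pytest.approx(100.0, abs=1e-12)
        assert truth.n_junctions == 0
        assert truth.n_endpoints == 2

    def test_empty_network(self):
        spec = VesselNetworkSpec((), image_shape=(40, 40), psf_sigma=0.0,
                                 noise_model=NoiseModel("none"))
        image, mask, truth = render_network(spec)
        assert not mask.any()
        assert truth.total_length_um == 0
        assert truth.n_junctions == 0
        assert len(truth.branches) == 0
        assert np.allclose(image.pixels, spec.background_intensity)

    def test_y_network_topology(self):
        hub = (60.0, 60.0)
        segs = tuple(
            VesselSegment(hub, (60.0 + 30 * math.sin(a), 60.0 + 30 * math.cos(a)), 3.0)
            for a in (0.0, 2.1, 4.2)
        )
        _, _, truth = render_network(
            VesselNetworkSpec(segs, image_shape=(120, 120))
        )
        assert truth.n_junctions == 1
        assert truth.n_endpoints == 3

    def test_mask_invariant_to_noise(self):
        seg = VesselSegment((30.0, 10.0), (30.0, 50.0), 4.0)
        base = dict(segments=(seg,), image_shape=(60, 60), seed=7)
        _, m0, _ = render_network(VesselNetworkSpec(noise_model=NoiseModel("none"), **base))
        _, m1, _ = render_network(
            VesselNetworkSpec(noise_model=NoiseModel("gaussian", sd=10.0), **base)
        )
        _, m2, _ = render_network(
            VesselNetworkSpec(noise_model=NoiseModel("poisson", scale=2.0), **base)
        )
        assert (m0 == m1).all() and (m0 == m2).all()

    def test_rendering_deterministic(self):
        seg = VesselSegment((30.0, 10.0), (30.0, 50.0), 4.0)
        spec = VesselNetworkSpec((seg,), image_shape=(60, 60), seed=11)
        a, _, _ = render_network(spec)
        b, _, _ = render_network(spec)
        assert (a.pixels == b.pixels).all()

    def test_area_fraction_in_unit_interval(self, clean_capsule):
        *_, truth = clean_capsule
        assert 0.0 < truth.area_fraction < 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        y0=st.floats(15, 85), x0=st.floats(15, 85),
        y1=st.floats(15, 85), x1=st.floats(15, 85),
        r=st.floats(1.0, 8.0),
    )
    def test_truth_length_is_euclidean(self, y0, x0, y1, x1, r):
        if math.dist((y0, x0), (y1, x1)) < 1e-6:
            return
        seg = VesselSegment((y0 + 10, x0 + 10), (y1 + 10, x1 + 10), r)
        spec = VesselNetworkSpec((seg,), image_shape=(120, 120), psf_sigma=0.0,
                                 noise_model=NoiseModel("none"))
        _, _, truth = render_network(spec)
        assert truth.total_length_um == pytest.approx(seg.length, rel=1e-12)


class TestSampleTree:
    def test_depth_one_is_single_segment(self):
        spec = sample_tree(depth=1, seed=3)
        assert len(spec.segments) == 1
        _, _, truth = render_network(spec)
        assert truth.n_junctions == 0

    def test_same_seed_reproduces_spec(self):
        a = sample_tree(depth=3, seed=5)
        b = sample_tree(depth=3, seed=5)
        assert a.segments == b.segments

    def test_radius_taper_rule(self):
        spec = sample_tree(depth=3, root_radius=10.0, taper=0.7, seed=2,
                           image_shape=(768, 768))
        radii = sorted({round(s.radius, 6) for s in spec.segments})
        assert radii == [pytest.approx(10 * 0.7**2), pytest.approx(7.0), 10.0]

    def test_segment_count_is_full_binary_tree(self):
        spec = sample_tree(depth=3, seed=9)
        assert len(spec.segments) == 2**3 - 1

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            sample_tree(depth=0)

    def test_impossible_tree_raises(self):
        with pytest.raises(RuntimeError, match="could not fit"):
            sample_tree(depth=3, length_range=(300.0, 400.0),
                        image_shape=(128, 128), max_tries=5)


class TestGenerateStudy:
    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n_per_group"):
            StudyDesign(n_per_group=1)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError, match="multipliers"):
            StudyDesign(group_effects={"control": (1, 1), "KO": (-0.5, 1)})

    def test_zero_short_multiplier_removes_short_branches(self):
        design = StudyDesign(
            group_effects={"control": (1.0, 1.0), "KO": (0.0, 1.0)}, seed=4
        )
        for s in generate_study(design, place=False):
            n_short = (s.branches["length_um"] <= 20.0).sum()
            if s.group == "KO":
                assert n_short == 0
            else:
                assert n_short > 0

    def test_ground_truth_identical_with_and_without_placement(self):
        design = StudyDesign(n_per_group=2, seed=8)
        a = generate_study(design, place=False)
        b = generate_study(design, place=True)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.branches, sb.branches)
            assert sb.spec is not None and sa.spec is None

    def test_deterministic_per_seed(self):
        design = StudyDesign(n_per_group=2, seed=12)
        a = generate_study(design, place=False)
        b = generate_study(design, place=False)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.branches, sb.branches)

    def test_placed_segments_match_population(self):
        design = StudyDesign(n_per_group=2, seed=3)
        s = generate_study(design, place=True)[0]
        assert len(s.spec.segments) == len(s.branches)
        placed_lengths = sorted(seg.length for seg in s.spec.segments)
        truth_lengths = sorted(s.branches["length_um"])
        assert np.allclose(placed_lengths, truth_lengths)

    def test_population_metrics_conservation(self):
        design = StudyDesign(n_per_group=2, seed=6)
        s = generate_study(design, place=False)[0]
        m = population_metrics(s.branches)
        assert m["small_radius_total_length_um"] + m[
            "large_radius_total_length_um"
        ] == pytest.approx(m["total_length_um"], rel=1e-12)
        assert sum(m["bin_counts"]) == m["n_branches"]
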