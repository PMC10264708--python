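"""Per-frame trait operations against analytic values and brute-force oracles."""

import math

import numpy as np
import pytest

from conftest import hull_area_oracle, longest_path_oracle, random_blob_mask
from rhizotrace.config import RunConfig
from rhizotrace.mask_io import BinaryRootMask
from rhizotrace.skeletonize import Skeleton, skeletonize
from rhizotrace.skelgraph import build_graph
from rhizotrace.synthetic import RootSpec, RootSystemSpec, render_mask
from rhizotrace.traits import (
    Landmarks,
    bounding_box_width,
    convex_hull_area,
    extract_traits,
    longest_root,
    primary_root_angle,
    rga,
    root_area,
    seminal_tips,
    srga,
    total_root_length,
)


def mask_from_pixels(pixels, shape=(20, 20), scale=1.0):
    g = np.zeros(shape, bool)
    for x, y in pixels:
        g[y, x] = True
    return BinaryRootMask(g, scale=scale)


class TestMaskTraits:
    def test_root_area_scaling(self):
        g = np.zeros((10, 10), bool)
        g.ravel()[:37] = True
        assert root_area(BinaryRootMask(g)) == 37.0
        assert root_area(BinaryRootMask(g, scale=0.2)) == pytest.approx(1.48)
        assert root_area(BinaryRootMask(np.zeros((3, 3), bool))) == 0.0

    def test_hull_of_single_pixel_and_rectangle(self):
        assert convex_hull_area(mask_from_pixels([(4, 4)])) == 0.0
        rect = [(x, y) for x in range(2, 13) for y in range(1, 22)]
        m = mask_from_pixels(rect, shape=(25, 25))
        assert convex_hull_area(m) == pytest.approx((11 - 1) * (21 - 1))

    def test_hull_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="no foreground"):
            convex_hull_area(BinaryRootMask(np.zeros((4, 4), bool)))

    @pytest.mark.parametrize("seed", range(8))
    def test_hull_matches_half_plane_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 18, size=(25, 2))
        m = mask_from_pixels([tuple(p) for p in pts])
        ys, xs = np.nonzero(m.grid)
        expected = hull_area_oracle(np.stack([xs, ys], axis=1))
        assert convex_hull_area(m) == pytest.approx(expected)

    def test_bbox_width_inclusive_extent(self):
        assert bounding_box_width(mask_from_pixels([(4, 4)])) == 1.0
        span = mask_from_pixels([(x, 3) for x in range(5, 21)], shape=(25, 25))
        assert bounding_box_width(span) == 16.0
        vertical = mask_from_pixels([(7, y) for y in range(2, 18)],
                                    shape=(25, 25))
        assert bounding_box_width(vertical) == 1.0


class TestAngles:
    def test_primary_angle_vertical_and_diagonal(self):
        assert primary_root_angle([(3, y) for y in range(10)]) \
            == pytest.approx(90.0)
        assert primary_root_angle([(i, i) for i in range(10)]) \
            == pytest.approx(45.0)

    def test_primary_angle_identical_pixels_error(self):
        with pytest.raises(ValueError, match="distinct"):
            primary_root_angle([(3, 3), (3, 3)])

    def test_primary_angle_jitter_stays_within_1deg(self):
        rng = np.random.default_rng(0)
        base = np.array([(i, i) for i in np.linspace(0, 60, 80)])
        jit = base + rng.uniform(-0.5, 0.5, size=base.shape)
        # orthogonal-regression oracle: SVD of centred coordinates
        c = jit - jit.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        expected = math.degrees(math.atan2(vt[0, 1], vt[0, 0])) % 180 or 180
        got = primary_root_angle([tuple(p) for p in jit])
        assert got == pytest.approx(expected, abs=1e-6)
        assert abs(got - 45.0) < 1.0

    def test_rga_examples(self):
        lm = Landmarks(grain=(10.0, 10.0))
        assert rga(lm, [(40.0, 60.0)]) == pytest.approx(
            math.degrees(math.atan(50 / 30)))
        assert rga(lm, [(10.0, 50.0)]) == pytest.approx(90.0)
        # the farthest tip defines the angle
        near, far = (40.0, 20.0), (10.0, 70.0)
        assert rga(lm, [near, far]) == pytest.approx(90.0)
        with pytest.raises(ValueError, match="coincides"):
            rga(lm, [(10.0, 10.0)])

    def test_srga_examples(self):
        lm = Landmarks(grain=(0.0, 0.0))
        assert srga(lm, (3.0, 4.0), (6.0, 8.0)) == pytest.approx(0.0)
        assert srga(lm, (1.0, 0.0), (-2.0, 0.0)) == pytest.approx(180.0)
        half = math.radians(54.65)
        t1 = (math.sin(half) * 50, math.cos(half) * 50)
        t2 = (-math.sin(half) * 50, math.cos(half) * 50)
        assert srga(lm, t1, t2) == pytest.approx(109.3)
        with pytest.raises(ValueError, match="coincides"):
            srga(lm, (0.0, 0.0), (1.0, 1.0))


def skel_graph(pixels, shape=(30, 30), scale=1.0):
    g = np.zeros(shape, bool)
    for x, y in pixels:
        g[y, x] = True
    return build_graph(Skeleton(g, scale=scale))


class TestLongestRoot:
    def test_single_edge(self):
        g = skel_graph([(5, y) for y in range(5, 15)])
        res = longest_root(g, Landmarks(grain=(5.0, 4.0)))
        assert res.length_mm == pytest.approx(9.0)

    def test_y_graph_prefers_long_branch(self):
        stem = [(8, y) for y in range(0, 11)]
        long_b = [(8, 11 + i) for i in range(9)]
        short_b = [(8 + 1 + i, 11 + i) for i in range(3)]
        g = skel_graph(stem + long_b + short_b)
        res = longest_root(g, Landmarks(grain=(8.0, 0.0)))
        start = longest_path_oracle(g.multi,
                                    res.nodes[0])
        assert res.length_mm == pytest.approx(start)
        # the long branch tip is the terminus
        assert res.pixels[-1] == (8, 19)

    def test_empty_graph_is_an_error(self):
        g = skel_graph([])
        with pytest.raises(ValueError, match="no root material"):
            longest_root(g, Landmarks(grain=(1.0, 1.0)))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration_on_random_graphs(self, seed):
        rng = np.random.default_rng(300 + seed)
        s = skeletonize(random_blob_mask(rng, side=28, density=0.4))
        g = build_graph(s)
        if g.n_nodes == 0:
            pytest.skip("empty skeleton draw")
        # anchor the grain on a node so oracle and implementation agree on
        # the start
        node0 = g.nodes()[0]
        lm = Landmarks(grain=(float(node0.position[0]),
                              float(node0.position[1])))
        res = longest_root(g, lm)
        assert res.length_mm == pytest.approx(
            longest_path_oracle(g.multi, node0.id))

    def test_cycle_graph_traverses_ring(self):
        ring = [(2, 0), (3, 1), (4, 2), (3, 3), (2, 4), (1, 3), (0, 2), (1, 1)]
        g = skel_graph(ring, shape=(6, 6))
        res = longest_root(g, Landmarks(grain=(2.0, 0.0)))
        assert res.length_mm == pytest.approx(8 * math.sqrt(2))


class TestSeminalTips:
    def test_manual_tips_pass_through(self):
        g = skel_graph([(5, y) for y in range(5, 15)])
        lm = Landmarks(grain=(5.0, 4.0), manual_tips=((1.0, 2.0), (3.0, 4.0)))
        assert seminal_tips(g, lm, k=2) == [(1.0, 2.0), (3.0, 4.0)]

    def test_symmetric_two_branch_returns_both_tips(self):
        stem = [(10, y) for y in range(0, 6)]
        left = [(10 - i, 6 + i) for i in range(1, 8)]
        right = [(10 + i, 6 + i) for i in range(1, 8)]
        g = skel_graph(stem + [(10, 6)] + left + right, shape=(20, 22))
        tips = seminal_tips(g, Landmarks(grain=(10.0, 0.0)), k=2)
        assert sorted(tips) == [(3.0, 13.0), (17.0, 13.0)]

    def test_too_many_tips_requested_is_an_error(self):
        g = skel_graph([(5, y) for y in range(5, 15)])
        with pytest.raises(ValueError, match="fewer than"):
            seminal_tips(g, Landmarks(grain=(5.0, 4.0)), k=3)


class TestExtractTraits:
    CFG = RunConfig(scale_mm_per_px=1.0, min_object_px=5, fill_holes_max_px=4,
                    seed_exclusion_radius_px=0.0)

    def test_empty_frame_gives_zero_record_absent_angles(self):
        m = BinaryRootMask(np.zeros((20, 20), bool))
        rec = extract_traits(m, Landmarks(grain=(10.0, 10.0)), self.CFG)
        assert rec.root_area == rec.total_root_length == 0.0
        assert rec.primary_root_angle is None
        assert rec.rga is None and rec.srga is None

    def test_single_straight_root_recovery(self):
        spec = RootSystemSpec(
            grain=(40.0, 5.0),
            roots=(RootSpec(heading_deg=20.0, emergence_has=0.0,
                            growth_rate_mm_h=1.0, max_length_mm=60.0),),
            height=90, width=90, scale_mm_per_px=1.0, rng_seed=0,
        )
        mask = render_mask(spec, 60.0)
        rec = extract_traits(mask, Landmarks(grain=spec.grain), self.CFG)
        assert rec.total_root_length == pytest.approx(60.0, rel=0.05)
        assert rec.longest_root_length == pytest.approx(60.0, rel=0.05)
        assert rec.longest_root_length <= rec.total_root_length + 1e-9

    def test_three_root_system_invariants(self):
        spec = RootSystemSpec(
            grain=(60.0, 8.0),
            roots=(
                RootSpec(0.0, 0.0, 1.0, 50.0),
                RootSpec(-45.0, 0.0, 1.0, 40.0),
                RootSpec(45.0, 0.0, 1.0, 40.0),
            ),
            height=90, width=120, scale_mm_per_px=1.0, rng_seed=0,
        )
        mask = render_mask(spec, 60.0)
        rec = extract_traits(mask, Landmarks(grain=spec.grain), self.CFG)
        assert rec.longest_root_length <= rec.total_root_length
        ys, xs = np.nonzero(mask.grid)
        bbox_area = (xs.max() - xs.min() + 1) * (ys.max() - ys.min() + 1)
        assert rec.convex_hull_area <= bbox_area
        assert rec.bounding_box_width >= 0

    def test_seed_exclusion_removes_grain_blob(self):
        g = np.zeros((30, 30), bool)
        g[5:9, 13:17] = True  # grain blob only
        cfg = self.CFG.with_(seed_exclusion_radius_px=6.0, min_object_px=0)
        rec = extract_traits(BinaryRootMask(g), Landmarks(grain=(15.0, 7.0)),
                             cfg)
        assert rec.root_area == 0.0

    def test_rotation_by_90_maps_traits(self):
        spec = RootSystemSpec(
            grain=(30.0, 5.0),
            roots=(RootSpec(heading_deg=25.0, emergence_has=0.0,
                            growth_rate_mm_h=1.0, max_length_mm=45.0),),
            height=70, width=70, scale_mm_per_px=1.0, rng_seed=3,
        )
        mask = render_mask(spec, 45.0)
        rec = extract_traits(mask, Landmarks(grain=spec.grain), self.CFG)
        rot_grid = np.rot90(mask.grid)  # (x, y) -> (y, W-1-x)
        H, W = mask.grid.shape
        rot_mask = BinaryRootMask(rot_grid, scale=1.0)
        rot_lm = Landmarks(grain=(spec.grain[1], W - 1 - spec.grain[0]))
        rot = extract_traits(rot_mask, rot_lm, self.CFG)
        assert rot.root_area == rec.root_area
        assert rot.convex_hull_area == pytest.approx(rec.convex_hull_area)
        assert rot.total_root_length == pytest.approx(
            rec.total_root_length, rel=0.02)
        expected_angle = (rec.primary_root_angle + 90.0) % 180.0
        assert rot.primary_root_angle == pytest.approx(
            expected_angle, abs=1.0)

    def test_scale_linearity(self):
        spec = RootSystemSpec(
            grain=(30.0, 5.0),
            roots=(RootSpec(heading_deg=-15.0, emergence_has=0.0,
                            growth_rate_mm_h=1.0, max_length_mm=40.0),),
            height=60, width=60, scale_mm_per_px=1.0, rng_seed=1,
        )
        grid = render_mask(spec, 40.0).grid
        lm = Landmarks(grain=spec.grain)
        rec1 = extract_traits(BinaryRootMask(grid, scale=1.0), lm,
                              self.CFG.with_(scale_mm_per_px=1.0))
        rec2 = extract_traits(BinaryRootMask(grid, scale=0.5), lm,
                              self.CFG.with_(scale_mm_per_px=0.5))
        assert rec2.total_root_length == pytest.approx(
            rec1.total_root_length * 0.5)
        assert rec2.root_area == pytest.approx(rec1.root_area * 0.25)
        assert rec2.convex_hull_area == pytest.approx(
            rec1.convex_hull_area * 0.25)
        assert rec2.primary_root_angle == pytest.approx(
            rec1.primary_root_angle)

    def test_total_root_length_on_raw_graph_is_edge_sum(self):
        stem = [(8, y) for y in range(0, 11)]
        g = skel_graph(stem)
        assert total_root_length(g) == pytest.approx(10.0)


class TestOverlayAndPersistence:
    def test_overlay_marks_skeleton_and_primary(self, tmp_path):
        from rhizotrace.skelgraph import build_graph
        from rhizotrace.skeletonize import skeletonize
        from rhizotrace.synthetic import gp_like, render_mask
        from rhizotrace.traits import render_overlay

        spec = gp_like(0)
        mask = render_mask(spec, 120.0)
        g = build_graph(skeletonize(mask))
        pr = longest_root(g, Landmarks(grain=spec.grain))
        out = tmp_path / "overlay.png"
        img = render_overlay(mask, g, pr, path=out)
        assert img.shape == (*mask.shape, 3)
        assert out.exists()
        assert (img[..., 1] == 200).any()  # skeleton drawn
        assert (img[..., 0] == 230).any()  # primary path drawn

    def test_skeleton_png_and_csv_roundtrip(self, tmp_path):
        import imageio.v3 as iio

        from rhizotrace.skeletonize import skeletonize

        g = np.zeros((10, 10), bool)
        g[2, 2:8] = True
        s = skeletonize(BinaryRootMask(g))
        s.save_png(tmp_path / "s.png")
        s.save_csv(tmp_path / "s.csv")
        back = iio.imread(tmp_path / "s.png") > 0
        assert (back == s.grid).all()
        rows = (tmp_path / "s.csv").read_text().strip().splitlines()
        assert rows[0] == "x,y"
        assert len(rows) - 1 == s.grid.sum()
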